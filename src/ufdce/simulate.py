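"""Synthetic ultrafast DCE-MRI study generator.

Builds a fully synthetic breast-lesion cohort: per-lesion tissue
concentration curves from an extended Tofts model driven by a population
arterial input function (AIF), and — optionally — 4D spoiled-gradient-echo
signal volumes with a two-flip-angle T1-mapping pair, lesion masks and
Rician noise, mimicking a 3 T ultrafast acquisition (4.5 s/phase, one
pre-contrast plus 29 post-contrast phases).

Time convention: the contrast injection starts at the beginning of the
first post-contrast phase (t = 0). Post-contrast frame ``i`` (0-based)
carries the timestamp ``(i + 1) * dt``, i.e. the end of its acquisition
window, so a 9-phase set (1 pre + 8 post) covers 36 s of post-contrast
time while its nominal scan duration is 40.5 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ufdce.exceptions import InvalidSpecError

__all__ = [
    "AcquisitionParams",
    "KineticSpec",
    "LogNormal",
    "KineticDistribution",
    "CohortSpec",
    "Lesion",
    "StudyVolumes",
    "SyntheticStudy",
    "population_aif",
    "tofts_concentration",
    "simulate_cohort",
    "render_signal",
    "add_rician_noise",
]

#: reference contrast dose (mmol/kg) at which the population AIF was fit
REFERENCE_DOSE = 0.1

# Population AIF shape parameters (bi-Gaussian plus exponential-sigmoid
# tail; Parker et al. parametrisation, times in minutes, output mmol/L).
DEFAULT_AIF_PARAMS: dict[str, float] = {
    "A1": 0.809,      # mmol * min
    "T1": 0.17046,    # min
    "sigma1": 0.0563, # min
    "A2": 0.330,
    "T2": 0.365,
    "sigma2": 0.132,
    "alpha": 1.050,   # mmol/L
    "beta": 0.1685,   # 1/min
    "s": 38.078,      # 1/min
    "tau": 0.483,     # min
}


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and physics context of the dynamic protocol.

    Parameters
    ----------
    tr_dce : float
        Repetition time of the dynamic SPGR sequence (ms).
    flip_dce : float
        Flip angle of the dynamic sequence (degrees).
    dt : float
        Temporal resolution (seconds per phase).
    n_pre, n_post : int
        Pre- and post-contrast phase counts.
    tr_t1map : float
        Repetition time of the two-flip-angle T1-mapping sequence (ms).
    flips_t1map : tuple of float
        The two T1-mapping flip angles (degrees); must be distinct.
    r1 : float
        Longitudinal relaxivity of the contrast agent (L mmol^-1 s^-1).
        Default is representative of gadobutrol at 3 T.
    """

    tr_dce: float = 4.46
    flip_dce: float = 11.0
    dt: float = 4.5
    n_pre: int = 1
    n_post: int = 29
    tr_t1map: float = 5.03
    flips_t1map: tuple[float, float] = (2.0, 10.0)
    r1: float = 5.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidSpecError(f"dt must be positive, got {self.dt}")
        if self.n_pre < 1 or self.n_post < 1:
            raise InvalidSpecError("n_pre and n_post must each be >= 1")
        if self.tr_dce <= 0 or self.tr_t1map <= 0:
            raise InvalidSpecError("repetition times must be positive")
        a, b = self.flips_t1map
        for f in (self.flip_dce, a, b):
            if not 0 < f <= 90:
                raise InvalidSpecError(f"flip angle {f} outside (0, 90] deg")
        if a == b:
            raise InvalidSpecError("T1-mapping flip angles must be distinct")
        if self.r1 <= 0:
            raise InvalidSpecError("relaxivity r1 must be positive")

    @property
    def n_phases(self) -> int:
        return self.n_pre + self.n_post

    def post_times(self) -> np.ndarray:
        """Timestamps (s after injection start) of the post-contrast frames."""
        return self.dt * np.arange(1, self.n_post + 1)


@dataclass(frozen=True)
class KineticSpec:
    """Extended-Tofts kinetic parameters for one lesion.

    ktrans is the volume transfer constant (min^-1), ve the extravascular
    extracellular volume fraction, vp the plasma volume fraction, and
    onset_delay the bolus arrival delay after injection start (s).
    """

    ktrans: float
    ve: float
    vp: float
    onset_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise InvalidSpecError("ktrans must be >= 0")
        if self.ktrans > 0 and not 0 < self.ve <= 1:
            raise InvalidSpecError("ve must be in (0, 1] when ktrans > 0")
        if not 0 <= self.vp < 1:
            raise InvalidSpecError("vp must be in [0, 1)")
        if self.onset_delay < 0:
            raise InvalidSpecError("onset_delay must be >= 0")


@dataclass(frozen=True)
class LogNormal:
    """Log-normal distribution parametrised by median and log-scale sigma."""

    median: float
    sigma: float

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class KineticDistribution:
    """Per-field log-normal distributions over KineticSpec draws."""

    ktrans: LogNormal
    ve: LogNormal = LogNormal(0.3, 0.3)
    vp: LogNormal = LogNormal(0.02, 0.5)
    # bolus reaches lesion tissue ~25 s after injection start (injection
    # plus saline flush plus transit), so the shortest dynamic sets only
    # partially cover the wash-in
    onset_delay: LogNormal = LogNormal(25.0, 0.2)

    def draw(self, rng: np.random.Generator, size: int) -> list[KineticSpec]:
        kt = self.ktrans.draw(rng, size)
        ve = np.clip(self.ve.draw(rng, size), 1e-6, 1.0)
        vp = np.clip(self.vp.draw(rng, size), 0.0, 0.5)
        d = self.onset_delay.draw(rng, size)
        return [KineticSpec(float(k), float(v), float(p), float(od))
                for k, v, p, od in zip(kt, ve, vp, d)]


# Benign lesions wash in slowly (low ktrans), malignant quickly; the
# spread is wide enough that the two groups overlap, as in clinical data.
DEFAULT_BENIGN = KineticDistribution(ktrans=LogNormal(0.05, 0.5))
DEFAULT_MALIGNANT = KineticDistribution(ktrans=LogNormal(0.25, 0.5))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and nuisance parameters of the synthetic study."""

    n_benign: int = 55
    n_malignant: int = 96
    benign_kinetics: KineticDistribution = DEFAULT_BENIGN
    malignant_kinetics: KineticDistribution = DEFAULT_MALIGNANT
    t10_lesion: LogNormal = LogNormal(1300.0, 0.1)  # ms, lesion tissue at 3 T
    noise_sigma: float = 0.02  # Rician sigma relative to baseline signal
    dose: float = REFERENCE_DOSE  # mmol/kg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise InvalidSpecError("cohort counts must each be >= 1")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if self.dose <= 0:
            raise InvalidSpecError("dose must be positive")

    @property
    def n_total(self) -> int:
        return self.n_benign + self.n_malignant


@dataclass(frozen=True)
class Lesion:
    lesion_id: str
    label: str  # "benign" | "malignant"
    curve: np.ndarray  # mmol/L at the post-contrast timestamps
    kinetics: KineticSpec
    t10: float  # ms


@dataclass
class StudyVolumes:
    """Rendered signal volumes of a synthetic study.

    dynamic : (nx, ny, nz, n_phases) SPGR magnitude signal.
    t1map_pair : two (nx, ny, nz) pre-contrast images at the two
        T1-mapping flip angles.
    labelmap : (nx, ny, nz) integer map; voxel value k > 0 marks lesion
        ``lesions[k-1]``, 0 is background.
    m0, t10_background : scalars of the rendering model.
    """

    dynamic: np.ndarray
    t1map_pair: tuple[np.ndarray, np.ndarray]
    labelmap: np.ndarray
    m0: float
    t10_background: float

    def mask(self, index: int) -> np.ndarray:
        """Boolean VOI mask of lesion ``index`` (0-based)."""
        return self.labelmap == index + 1


@dataclass
class SyntheticStudy:
    acquisition: AcquisitionParams
    lesions: list[Lesion]
    timestamps: np.ndarray  # post-contrast sample times, s after injection
    volumes: StudyVolumes | None = None

    @property
    def labels(self) -> list[str]:
        return [les.label for les in self.lesions]


def population_aif(
    t: np.ndarray | float,
    dose: float = REFERENCE_DOSE,
    params: dict[str, float] | None = None,
) -> np.ndarray:
    """Population plasma concentration Cp(t) after a bolus injection.

    Bi-Gaussian first and second pass plus an exponentially decaying
    sigmoid washout tail, anchored so that Cp(0) = 0 and scaled linearly
    in the injected dose. Default parameters put the first-pass peak
    about 10 s after injection start.

    Parameters
    ----------
    t : array_like
        Time since injection start (s); must be non-negative.
    dose : float
        Injected dose (mmol/kg); the curve is linear in dose around the
        0.1 mmol/kg reference.
    params : dict, optional
        Override AIF shape parameters (keys of ``DEFAULT_AIF_PARAMS``).

    Returns
    -------
    ndarray
        Plasma concentration (mmol/L), same shape as ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (injection starts at t=0)")
    p = dict(DEFAULT_AIF_PARAMS)
    if params:
        p.update(params)

    def raw(tm: np.ndarray) -> np.ndarray:
        g1 = p["A1"] / (p["sigma1"] * math.sqrt(2 * math.pi)) * np.exp(
            -((tm - p["T1"]) ** 2) / (2 * p["sigma1"] ** 2)
        )
        g2 = p["A2"] / (p["sigma2"] * math.sqrt(2 * math.pi)) * np.exp(
            -((tm - p["T2"]) ** 2) / (2 * p["sigma2"] ** 2)
        )
        tail = p["alpha"] * np.exp(-p["beta"] * tm) / (
            1.0 + np.exp(-p["s"] * (tm - p["tau"]))
        )
        return g1 + g2 + tail

    tm = t / 60.0  # shape parameters are in minutes
    base = raw(np.zeros(1))[0]  # pre-injection pedestal, subtracted
    cp = np.clip(raw(tm) - base, 0.0, None)
    return cp * (dose / REFERENCE_DOSE)


def _expconv_linear(cp: np.ndarray, t: np.ndarray, kep: float) -> np.ndarray:
    """Convolution of a piecewise-linear Cp with exp(-kep * t).

    Exact per-interval update assuming Cp linear between samples; stable
    for any kep >= 0 (reduces to cumulative trapezoid at kep = 0).
    """
    n = t.size
    out = np.zeros(n)
    if n < 2:
        return out
    h = np.diff(t)
    kh = kep * h
    small = kh < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.exp(-kh)
        f0 = np.where(small, h, (1.0 - e) / kep)          # ∫ e^{-kep(h-u)} du
        f1 = np.where(small, h / 2.0, 1.0 / kep - (1.0 - e) / (kep**2 * h))
    c0, c1 = cp[:-1], cp[1:]
    step = c0 * f0 + (c1 - c0) * f1
    for i in range(n - 1):
        out[i + 1] = out[i] * e[i] + step[i]
    return out


def tofts_concentration(
    spec: KineticSpec,
    aif: tuple[np.ndarray, np.ndarray],
    t: np.ndarray,
) -> np.ndarray:
    """Tissue concentration from the extended Tofts model.

    C(t) = vp * Cp(t - d) + Ktrans * ∫_0^{t-d} Cp(τ) exp(-kep (t-d-τ)) dτ
    with kep = Ktrans / ve and d the onset delay. The convolution is
    evaluated exactly for a piecewise-linear Cp on the AIF grid and the
    result interpolated onto the requested sample times.

    Parameters
    ----------
    spec : KineticSpec
    aif : (times, values)
        Plasma curve sampled on a grid at least as fine as ``t`` (s, mmol/L).
    t : array_like
        Output sample times (s since injection start).
    """
    if spec.ktrans > 0 and spec.ve <= 0:
        raise InvalidSpecError("ve must be positive when ktrans > 0")
    ta, ca = (np.asarray(a, dtype=float) for a in aif)
    t = np.asarray(t, dtype=float)
    if ta.size >= 2 and t.size >= 2:
        if np.min(np.diff(ta)) > np.min(np.diff(t)) * (1 + 1e-9):
            raise ValueError("AIF grid must be at least as fine as the output grid")

    resp = spec.vp * ca
    if spec.ktrans > 0:
        kep = spec.ktrans / spec.ve / 60.0  # min^-1 -> s^-1
        resp = resp + (spec.ktrans / 60.0) * _expconv_linear(ca, ta, kep)

    shifted = t - spec.onset_delay
    out = np.interp(shifted, ta, resp, left=0.0, right=resp[-1] if resp.size else 0.0)
    out[shifted < 0] = 0.0
    return np.clip(out, 0.0, None)


def _aif_grid(acq: AcquisitionParams, dose: float, dt_fine: float) -> tuple[np.ndarray, np.ndarray]:
    t_max = acq.dt * acq.n_post + 60.0  # headroom for onset delays
    ta = np.arange(0.0, t_max + dt_fine, dt_fine)
    return ta, population_aif(ta, dose=dose)


def simulate_cohort(
    cohort: CohortSpec,
    acq: AcquisitionParams | None = None,
    dt_fine: float = 0.1,
) -> SyntheticStudy:
    """Draw a lesion cohort and synthesise its concentration curves.

    Benign and malignant lesions are drawn from their respective kinetic
    distributions; each lesion's curve is an extended-Tofts response to
    the population AIF sampled at the post-contrast timestamps. Fully
    reproducible for a fixed ``cohort.seed``.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(cohort.seed)
    times = acq.post_times()
    ta, ca = _aif_grid(acq, cohort.dose, dt_fine)

    specs = cohort.benign_kinetics.draw(rng, cohort.n_benign)
    specs += cohort.malignant_kinetics.draw(rng, cohort.n_malignant)
    labels = ["benign"] * cohort.n_benign + ["malignant"] * cohort.n_malignant
    t10s = cohort.t10_lesion.draw(rng, cohort.n_total)

    lesions = []
    width = len(str(cohort.n_total))
    for i, (spec, label, t10) in enumerate(zip(specs, labels, t10s)):
        curve = tofts_concentration(spec, (ta, ca), times)
        lesions.append(
            Lesion(f"L{i + 1:0{width}d}", label, curve, spec, float(t10))
        )
    return SyntheticStudy(acquisition=acq, lesions=lesions, timestamps=times)


# ---------------------------------------------------------------------------
# volume rendering

_BLOCK = (3, 3, 3)  # voxels per lesion VOI
_GAP = 1            # background voxels between blocks
_M0 = 1000.0        # equilibrium signal scale (a.u.)
_T10_BACKGROUND = 1000.0  # ms


def _spgr(m0: float | np.ndarray, t1_ms: np.ndarray, tr_ms: float, alpha_deg: float) -> np.ndarray:
    a = math.radians(alpha_deg)
    e = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return m0 * math.sin(a) * (1.0 - e) / (1.0 - e * math.cos(a))


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Rician-distributed magnitude of ``signal`` plus complex Gaussian noise.

    Each channel receives independent N(0, sigma) noise; the returned
    magnitude is biased upward by about sigma^2 / (2 signal) at high SNR.
    """
    if sigma < 0:
        raise InvalidSpecError("noise sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def render_signal(
    study: SyntheticStudy,
    cohort: CohortSpec,
    noise_seed: int | None = None,
) -> SyntheticStudy:
    """Render 4D SPGR signal volumes for a curve-level study.

    Each lesion occupies a 3x3x3 voxel block on a regular lattice. Voxel
    T1 follows 1/T1(t) = 1/T10 + r1 * C(t); the dynamic series is the
    SPGR signal at (tr_dce, flip_dce) and the pre-contrast two-flip-angle
    pair is rendered at (tr_t1map, flips_t1map). Rician noise with sigma
    = ``cohort.noise_sigma`` x mean baseline lesion signal is applied to
    every image. Returns a new study carrying the volumes.
    """
    if cohort.noise_sigma < 0:
        raise InvalidSpecError("noise_sigma must be >= 0")
    acq = study.acquisition
    n = len(study.lesions)
    grid = math.ceil(math.sqrt(n))
    bx, by, bz = _BLOCK
    nx = grid * (bx + _GAP) + _GAP
    ny = grid * (by + _GAP) + _GAP
    nz = bz + 2 * _GAP
    n_ph = acq.n_phases

    labelmap = np.zeros((nx, ny, nz), dtype=np.int32)
    t10_vol = np.full((nx, ny, nz), _T10_BACKGROUND)
    conc = np.zeros((nx, ny, nz, n_ph))  # pre-contrast frames stay at 0

    for k, les in enumerate(study.lesions):
        ix, iy = divmod(k, grid)
        x0 = _GAP + ix * (bx + _GAP)
        y0 = _GAP + iy * (by + _GAP)
        sl = np.s_[x0:x0 + bx, y0:y0 + by, _GAP:_GAP + bz]
        labelmap[sl] = k + 1
        t10_vol[sl] = les.t10
        conc[sl][..., acq.n_pre:] = les.curve

    r1_t = 1000.0 / t10_vol[..., None] + acq.r1 * conc  # s^-1
    t1_t = 1000.0 / r1_t  # ms
    dynamic = _spgr(_M0, t1_t, acq.tr_dce, acq.flip_dce)
    pair = tuple(
        _spgr(_M0, t10_vol, acq.tr_t1map, a) for a in acq.flips_t1map
    )

    if cohort.noise_sigma > 0:
        baseline = float(np.mean(dynamic[labelmap > 0, 0]))
        sigma = cohort.noise_sigma * baseline
        seed = cohort.seed + 1 if noise_seed is None else noise_seed
        rng = np.random.default_rng(seed)
        dynamic = add_rician_noise(dynamic, sigma, rng)
        pair = tuple(add_rician_noise(p, sigma, rng) for p in pair)

    volumes = StudyVolumes(
        dynamic=dynamic,
        t1map_pair=pair,  # type: ignore[arg-type]
        labelmap=labelmap,
        m0=_M0,
        t10_background=_T10_BACKGROUND,
    )
    return replace(study, volumes=volumes)
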