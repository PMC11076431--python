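"""Signal-to-concentration conversion for SPGR dynamic imaging.

Implements the spoiled-gradient-echo (SPGR) signal equation, the
closed-form two-point variable-flip-angle (VFA) T1 estimate, and the
per-timepoint inversion of a dynamic signal curve into a contrast-agent
concentration curve via 1/T1(t) = 1/T10 + r1 * C(t).

Unit discipline: T1 and TR are carried in milliseconds at the interface;
relaxation-rate bookkeeping happens in s^-1 (the single ms -> s
conversion is the factor 1000 in ``signal_to_concentration``).
Concentrations are mmol/L, relaxivity L mmol^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ufdce.exceptions import NonPhysicalSignalError
from ufdce.simulate import AcquisitionParams

__all__ = [
    "T1MapEntry",
    "ConcentrationSeries",
    "spgr_signal",
    "fit_t1_vfa",
    "signal_to_concentration",
]


@dataclass(frozen=True)
class T1MapEntry:
    """Baseline T1 (ms) and equilibrium signal scale for one voxel/lesion."""

    t10: float
    m0: float

    def __post_init__(self) -> None:
        if self.t10 <= 0 or self.m0 <= 0:
            raise ValueError("t10 and m0 must be positive")


@dataclass
class ConcentrationSeries:
    """A lesion's concentration-time curve.

    times are seconds after injection start, values mmol/L. ``n_clipped``
    counts samples clipped up to zero; ``nonphysical`` marks samples whose
    signal was inconsistent with the SPGR model (value set to NaN).
    """

    times: np.ndarray
    values: np.ndarray
    lesion_id: str = ""
    n_clipped: int = 0
    nonphysical: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.nonphysical.size == 0:
            self.nonphysical = np.zeros(self.times.shape, dtype=bool)

    def __len__(self) -> int:
        return self.times.size


def spgr_signal(
    m0: float | np.ndarray,
    t1: float | np.ndarray,
    tr: float,
    alpha: float,
) -> float | np.ndarray:
    """Spoiled-gradient-echo steady-state signal.

    S = m0 sin(a) (1 - E) / (1 - E cos(a)),  E = exp(-TR/T1),
    with T1 and TR in ms and the flip angle ``alpha`` in degrees.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0) or tr <= 0:
        raise ValueError("t1 and tr must be positive")
    if not 0 < alpha <= 90:
        raise ValueError("alpha must be in (0, 90] degrees")
    a = math.radians(alpha)
    e = np.exp(-tr / t1)
    s = m0 * math.sin(a) * (1.0 - e) / (1.0 - e * math.cos(a))
    return float(s) if np.isscalar(m0) and s.ndim == 0 else s


def fit_t1_vfa(
    s1: float | np.ndarray,
    s2: float | np.ndarray,
    alpha1: float,
    alpha2: float,
    tr: float,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Closed-form two-point VFA T1 estimate.

    Linearises the SPGR equation as y = E x + m0 (1 - E) with
    y = S/sin(a), x = S/tan(a); the slope through the two points gives
    E = exp(-TR/T1). Exact for noiseless SPGR inputs.

    Returns ``(t1_ms, m0)``. Scalar inputs with a slope outside (0, 1)
    raise :class:`NonPhysicalSignalError`; for array inputs such entries
    are returned as NaN.

    """
    if alpha1 == alpha2:
        raise ValueError("flip angles must be distinct")
    scalar = np.isscalar(s1) and np.isscalar(s2)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("signals must be positive")
    a1, a2 = math.radians(alpha1), math.radians(alpha2)
    y1, x1 = s1 / math.sin(a1), s1 / math.tan(a1)
    y2, x2 = s2 / math.sin(a2), s2 / math.tan(a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (y2 - y1) / (x2 - x1)
    valid = (e > 0) & (e < 1)
    if scalar and not bool(valid):
        raise NonPhysicalSignalError(
            f"VFA slope E={float(e):.4g} outside (0, 1): signals inconsistent "
            "with the SPGR model"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -tr / np.log(np.where(valid, e, 0.5)), np.nan)
        m0 = np.where(valid, (y1 - e * x1) / (1.0 - e), np.nan)
    if scalar:
        return float(t1), float(m0)
    return t1, m0


def signal_to_concentration(
    signal_curve: np.ndarray,
    s_pre: float,
    t10: float,
    acq: AcquisitionParams,
    lesion_id: str = "",
) -> ConcentrationSeries:
    """Invert a dynamic SPGR signal curve into a concentration curve.

    The equilibrium scale m0 is estimated from the pre-contrast baseline
    ``s_pre`` and the known ``t10`` at the dynamic sequence settings;
    each post-contrast sample is then inverted for T1(t) and converted
    via C(t) = (1/r1) (1/T1(t) - 1/T10) with rates in s^-1.

    Samples whose signal implies E outside (0, 1) are flagged
    non-physical and returned as NaN; negative concentrations (noise
    below baseline) are clipped to zero and counted in ``n_clipped``.
    """
    if s_pre <= 0:
        raise ValueError("s_pre must be positive")
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    sig = np.asarray(signal_curve, dtype=float)
    if sig.size != acq.n_post:
        raise ValueError(
            f"signal curve has {sig.size} samples, expected n_post={acq.n_post}"
        )
    a = math.radians(acq.flip_dce)
    m0 = s_pre / spgr_signal(1.0, t10, acq.tr_dce, acq.flip_dce)

    # S = m0 sin a (1-E)/(1-E cos a)  =>  E = (m0 sin a - S)/(m0 sin a - S cos a)
    ms = m0 * math.sin(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (ms - sig) / (ms - sig * math.cos(a))
    nonphysical = ~((e > 0) & (e < 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_ms = -acq.tr_dce / np.log(np.where(nonphysical, 0.5, e))
    r1_t = 1000.0 / t1_ms  # s^-1
    r10 = 1000.0 / t10
    conc = (r1_t - r10) / acq.r1
    conc[nonphysical] = np.nan
    neg = conc < 0
    n_clipped = int(np.count_nonzero(neg))
    conc[neg] = 0.0
    return ConcentrationSeries(
        times=acq.post_times(),
        values=conc,
        lesion_id=lesion_id,
        n_clipped=n_clipped,
        nonphysical=nonphysical,
    )
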