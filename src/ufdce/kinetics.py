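"""Truncated dynamic sets and semi-quantitative kinetic parameters.

The full dynamic series (1 pre-contrast + 29 post-contrast phases at
4.5 s/phase) is cut into eight nested dynamic sets with nominal scan
durations 40.5, 54, 67.5, 81, 94.5, 108, 121.5 and 135 s. For every
lesion and every set two parameters are measured on the concentration
curve:

maximum slope (MS)
    the steepest slope over consecutive samples, including the segment
    from the (t=0, C=0) injection baseline to the first post-contrast
    sample; negative results are floored at zero.

initial area under the curve (iAUC)
    the trapezoidal integral of C from t=0 to 60 s after injection; for
    sets whose post-contrast coverage ends before 60 s the integral runs
    only to the last sampled timepoint and the record is flagged
    truncated. If 60 s falls between samples the endpoint is linearly
    interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ufdce.exceptions import UndefinedParameterError
from ufdce.relaxometry import ConcentrationSeries
from ufdce.simulate import AcquisitionParams, SyntheticStudy

__all__ = [
    "DEFAULT_PHASE_COUNTS",
    "IAUC_WINDOW",
    "DynamicSet",
    "build_dynamic_sets",
    "truncate_curve",
    "max_slope",
    "iauc",
    "compute_parameters",
]

#: default truncation grid: every third phase from 9 to the full 30
DEFAULT_PHASE_COUNTS = (9, 12, 15, 18, 21, 24, 27, 30)

#: nominal iAUC integration window (s after injection start)
IAUC_WINDOW = 60.0


@dataclass(frozen=True)
class DynamicSet:
    """A truncation of the dynamic series to ``phase_count`` phases.

    ``duration`` is the nominal scan duration phase_count * dt in
    seconds (the pre-contrast phase counts toward the duration).
    """

    phase_count: int
    duration: float
    label: str


def _format_duration(d: float) -> str:
    return f"SD_{d:g}s"


def build_dynamic_sets(
    acq: AcquisitionParams,
    phase_counts: list[int] | tuple[int, ...] | None = None,
) -> list[DynamicSet]:
    """Build the truncated dynamic sets for an acquisition.

    With the default grid this yields eight sets with durations
    40.5 s (9 phases) through 135 s (30 phases) at dt = 4.5 s.
    """
    counts = list(DEFAULT_PHASE_COUNTS if phase_counts is None else phase_counts)
    if counts != sorted(counts):
        raise ValueError("phase_counts must be sorted ascending")
    sets = []
    for pc in counts:
        if pc < acq.n_pre + 1:
            raise ValueError(f"phase count {pc} leaves no post-contrast phase")
        if pc > acq.n_phases:
            raise ValueError(
                f"phase count {pc} exceeds the {acq.n_phases} available phases"
            )
        d = pc * acq.dt
        sets.append(DynamicSet(phase_count=pc, duration=d, label=_format_duration(d)))
    return sets


def truncate_curve(
    curve: ConcentrationSeries,
    dset: DynamicSet,
    acq: AcquisitionParams,
) -> ConcentrationSeries:
    """Keep the first ``phase_count - n_pre`` post-contrast samples."""
    if len(curve) != acq.n_post:
        raise ValueError(
            f"curve has {len(curve)} samples, expected the full {acq.n_post}"
        )
    n_keep = dset.phase_count - acq.n_pre
    return ConcentrationSeries(
        times=curve.times[:n_keep],
        values=curve.values[:n_keep],
        lesion_id=curve.lesion_id,
        n_clipped=curve.n_clipped,
        nonphysical=curve.nonphysical[:n_keep],
    )


def _with_baseline(curve: ConcentrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Prepend the (t=0, C=0) injection anchor, dropping NaN samples."""
    ok = np.isfinite(curve.values)
    t = np.concatenate(([0.0], curve.times[ok]))
    c = np.concatenate(([0.0], curve.values[ok]))
    return t, c


def max_slope(curve: ConcentrationSeries) -> float:
    """Maximum slope over consecutive segments (mmol L^-1 s^-1).

    The segment from the injection baseline (0, 0) to the first sample is
    included; a globally negative maximum is floored at 0. Several
    segments sharing the maximum resolve to the earliest (irrelevant for
    the value, stated for determinism of any segment-index use).
    """
    t, c = _with_baseline(curve)
    if t.size < 2:
        raise UndefinedParameterError("need at least 2 points for max slope")
    slopes = np.diff(c) / np.diff(t)
    return float(max(np.max(slopes), 0.0))


def iauc(
    curve: ConcentrationSeries,
    dset: DynamicSet | None = None,
    window: float = IAUC_WINDOW,
) -> tuple[float, float, bool]:
    """Initial area under the concentration curve.

    Returns ``(iauc, iauc_window, truncated)`` where ``iauc_window`` is
    the actual integration window min(window, last timestamp) and
    ``truncated`` flags windows shorter than the nominal one.
    """
    t, c = _with_baseline(curve)
    if t.size < 2:
        raise UndefinedParameterError("need at least 1 finite sample for iAUC")
    t_end = float(t[-1])
    truncated = t_end < window
    w = min(window, t_end)
    if not truncated and t_end > window:
        keep = t <= window
        t = np.append(t[keep], window)
        c = np.append(c[keep], np.interp(window, *_with_baseline(curve)))
    area = float(np.trapezoid(c, t))
    return max(area, 0.0), w, truncated


def _iter_series(study) -> list[tuple[ConcentrationSeries, str]]:
    if isinstance(study, SyntheticStudy):
        return [
            (
                ConcentrationSeries(study.timestamps, les.curve, les.lesion_id),
                les.label,
            )
            for les in study.lesions
        ]
    return list(study)  # iterable of (ConcentrationSeries, label)


def compute_parameters(
    study: SyntheticStudy | list[tuple[ConcentrationSeries, str]],
    sets: list[DynamicSet],
    acq: AcquisitionParams | None = None,
    window: float = IAUC_WINDOW,
    smooth: bool = False,
) -> pd.DataFrame:
    """Measure MS and iAUC for every lesion at every dynamic set.

    Parameters
    ----------
    study : SyntheticStudy or iterable of (ConcentrationSeries, label)
        Source of full-length concentration curves with lesion labels.
    sets : list of DynamicSet
    acq : AcquisitionParams, optional
        Required when ``study`` is not a SyntheticStudy.
    window : float
        Nominal iAUC window (s).
    smooth : bool
        Apply a 3-point moving average to each curve before measuring
        MS (off by default; the 4.5 s sampling is already coarse).

    Returns
    -------
    DataFrame
        Long format, one row per lesion x duration with columns
        lesion_id, label, duration_label, duration_s, ms, iauc,
        iauc_window, truncated. Lesions for which a parameter is
        undefined yield a missing record (logged).
    """
    if isinstance(study, SyntheticStudy):
        acq = study.acquisition
    elif acq is None:
        raise ValueError("acq is required when passing raw curves")
    rows = []
    for series, label in _iter_series(study):
        for dset in sets:
            trunc = truncate_curve(series, dset, acq)
            if smooth:
                v = trunc.values
                if v.size >= 3:
                    sm = v.copy()
                    sm[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
                    trunc = ConcentrationSeries(
                        trunc.times, sm, trunc.lesion_id, trunc.n_clipped
                    )
            try:
                ms = max_slope(trunc)
                area, w, truncated = iauc(trunc, dset, window=window)
            except UndefinedParameterError:
                continue  # missing record; caller sees the reduced count
            rows.append(
                {
                    "lesion_id": series.lesion_id,
                    "label": label,
                    "duration_label": dset.label,
                    "duration_s": dset.duration,
                    "ms": ms,
                    "iauc": area,
                    "iauc_window": w,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "label", "duration_label", "duration_s",
            "ms", "iauc", "iauc_window", "truncated",
        ],
    )
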