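"""Diagnostic-performance statistics for benign/malignant discrimination.

Covers the statistical workflow applied to the per-lesion kinetic
parameters: a Kolmogorov-Smirnov normality gate routing group
comparisons to Student's t or Mann-Whitney U; ROC analysis with DeLong
variance for AUC confidence intervals and paired AUC comparisons;
Youden-index cutoffs with the full confusion-metric panel
(Clopper-Pearson exact CIs); paired cross-duration comparisons with
Bonferroni correction; and two-way random-effects ICC for rater /
session agreement.

The positive class is ``malignant`` throughout and the decision rule is
score >= cutoff => malignant (both kinetic parameters are larger in
malignancy).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ufdce.exceptions import InsufficientDataError

__all__ = [
    "GroupComparison",
    "AucResult",
    "MetricCI",
    "RocResult",
    "PairedMatrix",
    "IccResult",
    "normality_gate",
    "compare_groups",
    "roc_auc",
    "delong_paired_test",
    "youden_cutoff",
    "confusion_metrics",
    "paired_duration_tests",
    "icc_agreement",
]

POSITIVE_LABEL = "malignant"
NEGATIVE_LABEL = "benign"


def _binarize(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        known = np.isin(arr, (NEGATIVE_LABEL, POSITIVE_LABEL))
        if not known.all():
            raise ValueError(f"labels must be '{NEGATIVE_LABEL}'/'{POSITIVE_LABEL}'")
        return (arr == POSITIVE_LABEL).astype(int)
    y = arr.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("numeric labels must be 0 (benign) or 1 (malignant)")
    return y


# ---------------------------------------------------------------------------
# normality gate and group comparison

def normality_gate(values, alpha: float = 0.05) -> str:
    """Route a sample to parametric or nonparametric tests.

    One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's own mean and standard deviation. Returns
    ``"normal"`` (p >= alpha) or ``"non-normal"``. Degenerate samples
    (zero variance) are non-normal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("normality test needs n >= 3")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return "non-normal"
    p = stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue
    return "normal" if p >= alpha else "non-normal"


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    duration_label: str
    benign_mean: float
    benign_sd: float
    malignant_mean: float
    malignant_sd: float
    test: str  # "t" | "mann-whitney"
    statistic: float
    p: float


def compare_groups(
    benign,
    malignant,
    parameter: str = "",
    duration_label: str = "",
    alpha: float = 0.05,
    test: str = "auto",
) -> GroupComparison:
    """Compare a parameter between benign and malignant lesions.

    With ``test="auto"`` (default), Student's t test when both groups
    pass the normality gate, Mann-Whitney U otherwise (exact p for small
    samples without ties). ``test`` may force ``"t"`` or
    ``"mann-whitney"``. Two-sided throughout.
    """
    b = np.asarray(benign, dtype=float)
    m = np.asarray(malignant, dtype=float)
    if b.size < 2 or m.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if test not in ("auto", "t", "mann-whitney"):
        raise ValueError("test must be 'auto', 't' or 'mann-whitney'")

    def gate(x: np.ndarray) -> str:
        return normality_gate(x, alpha) if x.size >= 3 else "non-normal"

    if test == "auto":
        test = (
            "t"
            if gate(b) == "normal" and gate(m) == "normal"
            else "mann-whitney"
        )
    if test == "t":
        res = stats.ttest_ind(m, b, equal_var=True)
    else:
        res = stats.mannwhitneyu(m, b, alternative="two-sided")
    p = float(res.pvalue)
    if not np.isfinite(p):  # both groups constant and identical
        p = 1.0
    return GroupComparison(
        parameter=parameter,
        duration_label=duration_label,
        benign_mean=float(b.mean()),
        benign_sd=float(b.std(ddof=1)),
        malignant_mean=float(m.mean()),
        malignant_sd=float(m.std(ddof=1)),
        test=test,
        statistic=float(res.statistic),
        p=p,
    )


# ---------------------------------------------------------------------------
# ROC / DeLong

def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    return auc, psi.mean(axis=1), psi.mean(axis=0)


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci: tuple[float, float]  # DeLong 95% CI, clipped to [0, 1]


def roc_auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """Empirical AUC with a DeLong confidence interval.

    The AUC equals the Mann-Whitney probability that a malignant lesion
    scores above a benign one (ties counted 1/2); the standard error
    comes from the DeLong structural-components variance.
    """
    s = np.asarray(scores, dtype=float)
    y = _binarize(labels)
    auc, v10, v01 = _delong_components(s, y)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return AucResult(auc=auc, se=se, ci=ci)


def _paired_auc_variance(a: np.ndarray, b: np.ndarray, y: np.ndarray):
    """AUCs of two paired score vectors and the DeLong variance of their difference."""
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return auc_a, auc_b, var


def delong_paired_test(scores_a, scores_b, labels) -> float:
    """DeLong test for two correlated AUCs measured on the same lesions.

    Two-sided p for H0: AUC(a) = AUC(b), using the covariance of the
    structural components. A zero-variance AUC difference (e.g. identical
    scores) is degenerate and reported as p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _binarize(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    auc_a, auc_b, var = _paired_auc_variance(a, b, y)
    if var <= 0 or not np.isfinite(var):
        warnings.warn(
            "zero variance of the AUC difference; DeLong test degenerate, p=1",
            stacklevel=2,
        )
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Youden cutoff and confusion panel

@dataclass(frozen=True)
class MetricCI:
    """One proportion metric: exact percent, counts and Clopper-Pearson CI."""

    pct: float  # rounded to 2 decimals
    numer: int
    denom: int
    ci: tuple[float, float]  # percent, 2 decimals


@dataclass(frozen=True)
class RocResult:
    parameter: str
    duration_label: str
    auc: AucResult
    cutoff: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, MetricCI | None]
    informative: bool = True


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, MetricCI | None]:
    """Sensitivity, specificity, PPV, NPV, accuracy (%) with exact 95% CIs.

    Percentages are rounded to 2 decimals; confidence intervals are
    Clopper-Pearson exact on the appropriate denominators. A metric with
    an empty denominator (e.g. PPV with no predicted positives) is
    reported as None.
    """
    for name, v in {"tp": tp, "fp": fp, "tn": tn, "fn": fn}.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("need at least one lesion in each true class")
    total = tp + fp + tn + fn

    def metric(numer: int, denom: int) -> MetricCI | None:
        if denom == 0:
            return None
        lo, hi = proportion_confint(numer, denom, alpha=0.05, method="beta")
        return MetricCI(
            pct=round(100.0 * numer / denom, 2),
            numer=numer,
            denom=denom,
            ci=(round(100.0 * lo, 2), round(100.0 * hi, 2)),
        )

    return {
        "sensitivity": metric(tp, tp + fn),
        "specificity": metric(tn, tn + fp),
        "ppv": metric(tp, tp + fp),
        "npv": metric(tn, tn + fn),
        "accuracy": metric(tp + tn, total),
    }


def youden_cutoff(
    scores,
    labels,
    parameter: str = "",
    duration_label: str = "",
) -> RocResult:
    """Youden-index optimal cutoff with the full diagnostic panel.

    Candidate cutoffs are the midpoints between consecutive sorted
    unique scores; a lesion is called malignant when score >= cutoff.
    Ties in the Youden index J resolve to the lowest such cutoff. When
    all scores are equal no cutoff is informative: the result carries
    J = 0 and ``informative=False``.
    """
    s = np.asarray(scores, dtype=float)
    y = _binarize(labels)
    auc = roc_auc(s, labels)
    uniq = np.unique(s)
    if uniq.size < 2:
        cut = float(uniq[0])
        tp_, fn_ = int(y.sum()), 0
        fp_, tn_ = int((1 - y).sum()), 0
        return RocResult(
            parameter, duration_label, auc, cut, 0.0, tp_, fp_, tn_, fn_,
            confusion_metrics(tp_, fp_, tn_, fn_), informative=False,
        )
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pred = s[None, :] >= cands[:, None]  # (n_cands, n)
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    fn = int(y.sum()) - tp
    tn = int((1 - y).sum()) - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest) maximizer
    cut = float(cands[best])
    tp_, fp_, tn_, fn_ = int(tp[best]), int(fp[best]), int(tn[best]), int(fn[best])
    return RocResult(
        parameter=parameter,
        duration_label=duration_label,
        auc=auc,
        cutoff=cut,
        youden_j=float(j[best]),
        tp=tp_,
        fp=fp_,
        tn=tn_,
        fn=fn_,
        metrics=confusion_metrics(tp_, fp_, tn_, fn_),
    )


# ---------------------------------------------------------------------------
# paired cross-duration comparisons

@dataclass
class PairedMatrix:
    """All pairwise cross-duration comparisons for one parameter/group.

    ``p_raw`` and ``p_adj`` are symmetric DataFrames indexed by duration
    label (diagonal NaN); ``p_adj`` is Bonferroni-adjusted over all
    pairs, capped at 1 (rendered "> 0.99" in reports). ``tests`` records
    the route per pair ("paired-t" or "wilcoxon"); a Friedman omnibus
    over all durations is reported alongside.
    """

    parameter: str
    group: str
    labels: list[str]
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    tests: pd.DataFrame
    friedman_statistic: float
    friedman_p: float
    n_lesions: int
    n_excluded: int


def paired_duration_tests(
    records: pd.DataFrame,
    parameter: str,
    group: str,
    alpha: float = 0.05,
) -> PairedMatrix:
    """Paired comparisons of one parameter across all scan durations.

    Lesions of ``group`` with complete records across all durations are
    pivoted to a lesions x durations matrix (incomplete lesions excluded
    listwise). Each of the C(d, 2) duration pairs is tested with a
    paired t test when the paired differences pass the normality gate
    and the Wilcoxon signed-rank test otherwise; p values are Bonferroni
    adjusted by the number of pairs.
    """
    sub = records[records["label"] == group]
    wide = sub.pivot_table(
        index="lesion_id", columns="duration_label", values=parameter,
        sort=False,
    )
    order = (
        sub[["duration_label", "duration_s"]]
        .drop_duplicates()
        .sort_values("duration_s")["duration_label"]
        .tolist()
    )
    wide = wide[order]
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0)
    n_excluded = n_before - wide.shape[0]
    if wide.shape[0] < 3:
        raise InsufficientDataError("need >= 3 complete lesions for paired tests")

    pairs = list(itertools.combinations(order, 2))
    m = len(pairs)
    p_raw = pd.DataFrame(np.nan, index=order, columns=order)
    p_adj = pd.DataFrame(np.nan, index=order, columns=order)
    tests = pd.DataFrame("", index=order, columns=order)
    for la, lb in pairs:
        d = (wide[lb] - wide[la]).to_numpy()
        if np.allclose(d, 0.0):
            p, route = 1.0, "degenerate"
        elif d.std(ddof=1) > 0 and normality_gate(d, alpha) == "normal":
            p = float(stats.ttest_rel(wide[lb], wide[la]).pvalue)
            route = "paired-t"
        else:
            p = float(stats.wilcoxon(d).pvalue)
            route = "wilcoxon"
        adj = min(1.0, m * p)
        for i, j in ((la, lb), (lb, la)):
            p_raw.loc[i, j] = p
            p_adj.loc[i, j] = adj
            tests.loc[i, j] = route

    cols = [wide[c].to_numpy() for c in order]
    if len(cols) < 3 or all(np.allclose(c, cols[0]) for c in cols[1:]):
        # Friedman needs >= 3 conditions; identical columns are trivially null
        fr_stat, fr_p = float("nan") if len(cols) < 3 else 0.0, 1.0
    else:
        fr = stats.friedmanchisquare(*cols)
        fr_stat, fr_p = float(fr.statistic), float(fr.pvalue)
    return PairedMatrix(
        parameter=parameter,
        group=group,
        labels=order,
        p_raw=p_raw,
        p_adj=p_adj,
        tests=tests,
        friedman_statistic=fr_stat,
        friedman_p=fr_p,
        n_lesions=wide.shape[0],
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# ICC

@dataclass(frozen=True)
class IccResult:
    parameter: str
    duration_label: str
    icc: float
    ci: tuple[float, float]
    design: str = "ICC(2,1) two-way random, single measures, absolute agreement"


def icc_agreement(
    ratings_a,
    ratings_b,
    parameter: str = "",
    duration_label: str = "",
    alpha: float = 0.05,
) -> IccResult:
    """Agreement ICC between two raters or sessions on the same lesions.

    Two-way random-effects, single-measures, absolute-agreement ICC
    (ICC(2,1)) from the ANOVA decomposition, with the McGraw & Wong
    F-based confidence interval. Zero between-lesion variance leaves the
    ICC undefined (NaN).
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratings must be paired (equal length)")
    n = a.size
    if n < 5:
        raise InsufficientDataError("ICC needs n >= 5 paired ratings")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr == 0:
        return IccResult(parameter, duration_label, float("nan"), (float("nan"),) * 2)
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(2,1)
    if mse == 0 and msc == 0:
        ci = (icc, icc)  # perfect agreement, no error term
    else:
        if mse == 0:
            v = float((k - 1) * (n - 1))  # limit of the Satterthwaite df
        else:
            fj = msc / mse
            nom = (k - 1) * (n - 1) * (
                k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
            ) ** 2
            den = (n - 1) * k**2 * icc**2 * fj**2 + (
                n * (1 + (k - 1) * icc) - k * icc
            ) ** 2
            v = nom / den
        f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lb = n * (msr - f2u * mse) / (
            f2u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ub = n * (f2l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2l * msr
        )
        ci = (float(lb), float(ub))
    return IccResult(parameter, duration_label, float(icc), ci)
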