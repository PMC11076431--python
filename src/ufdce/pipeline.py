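"""End-to-end orchestration: simulate -> (relaxometry) -> kinetics -> diagnostics.

A single :class:`RunConfig` drives the whole study. Two execution
profiles exist: ``curves`` analyses the simulated lesion concentration
curves directly (fast default), ``volumes`` renders 4D SPGR signal
volumes, re-estimates T1 from the two-flip-angle pair and recovers the
concentration curves through the relaxometry chain before analysis.
Everything downstream of the seed is deterministic; reports carry the
config hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ufdce import io as ufio
from ufdce.diagnostics import (
    IccResult,
    PairedMatrix,
    compare_groups,
    delong_paired_test,
    icc_agreement,
    paired_duration_tests,
    youden_cutoff,
)
from ufdce.kinetics import (
    DEFAULT_PHASE_COUNTS,
    IAUC_WINDOW,
    build_dynamic_sets,
    compute_parameters,
)
from ufdce.relaxometry import ConcentrationSeries, fit_t1_vfa, signal_to_concentration
from ufdce.simulate import (
    AcquisitionParams,
    CohortSpec,
    KineticDistribution,
    LogNormal,
    SyntheticStudy,
    render_signal,
    simulate_cohort,
)

logger = logging.getLogger("ufdce")

__all__ = ["RunConfig", "RunReport", "run_end_to_end", "make_figures",
           "measure_curves_from_volumes"]

PARAMETERS = ("ms", "iauc")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of an end-to-end run."""

    cohort: CohortSpec = CohortSpec()
    acquisition: AcquisitionParams = AcquisitionParams()
    phase_counts: tuple[int, ...] = DEFAULT_PHASE_COUNTS
    iauc_window: float = IAUC_WINDOW
    alpha: float = 0.05
    smooth: bool = False
    reread_jitter: float = 0.05  # relative sd of the emulated repeat read
    profile: str = "curves"  # "curves" | "volumes"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("curves", "volumes"):
            raise ValueError("profile must be 'curves' or 'volumes'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.reread_jitter < 0:
            raise ValueError("reread_jitter must be >= 0")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def logn(x) -> LogNormal:
            return LogNormal(**x) if isinstance(x, dict) else x

        def kdist(x) -> KineticDistribution:
            if isinstance(x, dict):
                return KineticDistribution(**{k: logn(v) for k, v in x.items()})
            return x

        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("benign_kinetics", "malignant_kinetics"):
                if key in c:
                    c[key] = kdist(c[key])
            if "t10_lesion" in c:
                c["t10_lesion"] = logn(c["t10_lesion"])
            d["cohort"] = CohortSpec(**c)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            a = dict(d["acquisition"])
            if "flips_t1map" in a:
                a["flips_t1map"] = tuple(a["flips_t1map"])
            d["acquisition"] = AcquisitionParams(**a)
        if "phase_counts" in d:
            d["phase_counts"] = tuple(d["phase_counts"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, cohort=dataclasses.replace(self.cohort, seed=seed)
        )


@dataclass
class RunReport:
    """All result tables of one run, plus provenance.

    Every reported number is recomputable from ``records`` (the
    per-lesion, per-duration parameter table) which is itself written as
    an intermediate CSV.
    """

    config: RunConfig
    records: pd.DataFrame
    group_table: pd.DataFrame
    roc_panel: pd.DataFrame
    paired_matrices: dict[tuple[str, str], PairedMatrix]
    auc_pair_matrices: dict[str, pd.DataFrame]
    icc_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def duration_labels(self) -> list[str]:
        return (
            self.records[["duration_label", "duration_s"]]
            .drop_duplicates()
            .sort_values("duration_s")["duration_label"]
            .tolist()
        )


def measure_curves_from_volumes(
    study: SyntheticStudy,
) -> list[tuple[ConcentrationSeries, str]]:
    """Recover VOI-mean concentration curves through the relaxometry chain.

    For each lesion: average the dynamic signal over its mask, estimate
    T1 from the VOI-mean two-flip-angle pair, and invert the SPGR signal
    into concentration using the mean pre-contrast baseline.
    """
    if study.volumes is None:
        raise ValueError("study has no rendered volumes; call render_signal first")
    acq = study.acquisition
    vol = study.volumes
    a1, a2 = acq.flips_t1map
    out = []
    for k, les in enumerate(study.lesions):
        mask = vol.mask(k)
        dyn = vol.dynamic[mask].mean(axis=0)  # (n_phases,)
        s_pre = float(dyn[: acq.n_pre].mean())
        s1 = float(vol.t1map_pair[0][mask].mean())
        s2 = float(vol.t1map_pair[1][mask].mean())
        t10_fit, _ = fit_t1_vfa(s1, s2, a1, a2, acq.tr_t1map)
        series = signal_to_concentration(
            dyn[acq.n_pre:], s_pre, t10_fit, acq, lesion_id=les.lesion_id
        )
        out.append((series, les.label))
    return out


def _auc_pair_matrix(
    records: pd.DataFrame, parameter: str, order: list[str]
) -> pd.DataFrame:
    """Bonferroni-adjusted DeLong p values for all duration pairs of one parameter."""
    wide = records.pivot_table(
        index=["lesion_id", "label"], columns="duration_label", values=parameter,
        sort=False,
    )[order].dropna()
    labels = wide.index.get_level_values("label").to_numpy()
    pairs = list(itertools.combinations(order, 2))
    m = len(pairs)
    mat = pd.DataFrame(np.nan, index=order, columns=order)
    import warnings
    for la, lb in pairs:
        with warnings.catch_warnings():
            # identical scores at two durations are expected (fixed iAUC
            # window); the degenerate DeLong p=1 is the intended result
            warnings.simplefilter("ignore", UserWarning)
            p = delong_paired_test(wide[la].to_numpy(), wide[lb].to_numpy(), labels)
        adj = min(1.0, m * p)
        mat.loc[la, lb] = adj
        mat.loc[lb, la] = adj
    return mat


def _reread(records: pd.DataFrame, jitter: float, seed: int) -> pd.DataFrame:
    """Emulated repeat measurement: seeded multiplicative jitter per record."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out = records.copy()
    for p in PARAMETERS:
        out[p] = records[p] * (1.0 + jitter * rng.standard_normal(len(records)))
    return out


def run_end_to_end(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the full study: simulation, measurement, diagnostics, report.

    Deterministic for a fixed seed. With ``outdir`` set, all intermediate
    CSVs, the config and a JSON summary are written there.
    """
    logger.info("simulate: %d benign + %d malignant lesions (profile=%s)",
                config.cohort.n_benign, config.cohort.n_malignant, config.profile)
    study = simulate_cohort(config.cohort, config.acquisition)
    if config.profile == "volumes":
        study = render_signal(study, config.cohort)
        curves = measure_curves_from_volumes(study)
        n_clip = sum(s.n_clipped for s, _ in curves)
        if n_clip:
            logger.warning("relaxometry clipped %d negative samples to 0", n_clip)
        source: SyntheticStudy | list = curves
    else:
        source = study

    sets = build_dynamic_sets(config.acquisition, list(config.phase_counts))
    records = compute_parameters(
        source, sets, acq=config.acquisition,
        window=config.iauc_window, smooth=config.smooth,
    )
    n_expected = len(study.lesions) * len(sets)
    if len(records) < n_expected:
        logger.warning("%d of %d records missing", n_expected - len(records), n_expected)
    order = [s.label for s in sets]

    group_rows, roc_rows = [], []
    for dset in sets:
        sub = records[records["duration_label"] == dset.label]
        ben = sub[sub["label"] == "benign"]
        mal = sub[sub["label"] == "malignant"]
        for p in PARAMETERS:
            gc = compare_groups(
                ben[p], mal[p], parameter=p, duration_label=dset.label,
                alpha=config.alpha,
            )
            group_rows.append(dataclasses.asdict(gc))
            rr = youden_cutoff(
                sub[p].to_numpy(), sub["label"].to_numpy(),
                parameter=p, duration_label=dset.label,
            )
            row = {
                "parameter": p,
                "duration_label": dset.label,
                "duration_s": dset.duration,
                "cutoff": rr.cutoff,
                "auc": round(rr.auc.auc, 3),
                "auc_lo": round(rr.auc.ci[0], 3),
                "auc_hi": round(rr.auc.ci[1], 3),
                "tp": rr.tp, "fp": rr.fp, "tn": rr.tn, "fn": rr.fn,
            }
            for name, m in rr.metrics.items():
                row[name] = None if m is None else m.pct
                row[f"{name}_lo"] = None if m is None else m.ci[0]
                row[f"{name}_hi"] = None if m is None else m.ci[1]
            roc_rows.append(row)
    group_table = pd.DataFrame(group_rows)
    roc_panel = pd.DataFrame(roc_rows)

    paired = {
        (p, g): paired_duration_tests(records, p, g, alpha=config.alpha)
        for p in PARAMETERS
        for g in ("benign", "malignant")
    }
    auc_pairs = {p: _auc_pair_matrix(records, p, order) for p in PARAMETERS}

    reread = _reread(records, config.reread_jitter, config.seed)
    icc_rows = []
    for dset in sets:
        for p in PARAMETERS:
            a = records[records["duration_label"] == dset.label][p].to_numpy()
            b = reread[reread["duration_label"] == dset.label][p].to_numpy()
            res: IccResult = icc_agreement(a, b, parameter=p,
                                           duration_label=dset.label)
            icc_rows.append(
                {
                    "parameter": p,
                    "duration_label": dset.label,
                    "icc": res.icc,
                    "icc_lo": res.ci[0],
                    "icc_hi": res.ci[1],
                    "design": res.design,
                }
            )
    icc_table = pd.DataFrame(icc_rows)

    import ufdce
    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "profile": config.profile,
        "ufdce_version": ufdce.__version__,
        "n_lesions": len(study.lesions),
        "n_records": len(records),
    }
    report = RunReport(
        config=config,
        records=records,
        group_table=group_table,
        roc_panel=roc_panel,
        paired_matrices=paired,
        auc_pair_matrices=auc_pairs,
        icc_table=icc_table,
        provenance=provenance,
    )
    if outdir is not None:
        _write_report(report, study, Path(outdir))
    return report


def _render_p(p: float) -> str:
    if p > 0.99:
        return "> 0.99"
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3g}"


def _write_report(report: RunReport, study: SyntheticStudy, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ufio.save_study(study, out / "study", cohort=report.config.cohort)
    report.records.to_csv(out / "records.csv", index=False)
    report.group_table.to_csv(out / "group_comparison.csv", index=False)
    report.roc_panel.to_csv(out / "roc_panel.csv", index=False)
    for (p, g), mat in report.paired_matrices.items():
        mat.p_adj.to_csv(out / f"paired_{p}_{g}.csv")
    for p, mat in report.auc_pair_matrices.items():
        mat.to_csv(out / f"auc_pairs_{p}.csv")
    report.icc_table.to_csv(out / "icc.csv", index=False)
    report.config.to_yaml(out / "config.yaml")
    summary = {
        "provenance": report.provenance,
        "auc": {
            f"{row.parameter}@{row.duration_label}": row.auc
            for row in report.roc_panel.itertuples()
        },
        "friedman": {
            f"{p}/{g}": _render_p(m.friedman_p)
            for (p, g), m in report.paired_matrices.items()
        },
        "icc_min": float(report.icc_table["icc"].min()),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def make_figures(report: RunReport, outdir: str | Path) -> list[Path]:
    """Line plots of parameter vs scan duration per group and ROC overlays.

    Writes one duration-trend figure per parameter (group mean +/- sd)
    and one ROC overlay per parameter (all durations), as PNG files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = report.records
    if (rec["label"] == "benign").sum() == 0 or (rec["label"] == "malignant").sum() == 0:
        raise ValueError("both benign and malignant lesions are required for figures")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    order = report.duration_labels
    durations = (
        rec[["duration_label", "duration_s"]]
        .drop_duplicates()
        .set_index("duration_label")["duration_s"]
    )
    paths = []
    for p in PARAMETERS:
        fig, ax = plt.subplots(figsize=(6, 4))
        for grp, color in (("benign", "tab:blue"), ("malignant", "tab:red")):
            sub = rec[rec["label"] == grp]
            means = sub.groupby("duration_label")[p].mean().reindex(order)
            sds = sub.groupby("duration_label")[p].std().reindex(order)
            x = durations.reindex(order).to_numpy()
            ax.errorbar(x, means, yerr=sds, label=grp, color=color,
                        marker="o", capsize=3)
        ax.set_xticks(durations.reindex(order).to_numpy())
        ax.set_xlabel("scan duration (s)")
        ax.set_ylabel(p.upper())
        ax.legend()
        ax.set_title(f"{p.upper()} vs scan duration")
        path = out / f"trend_{p}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)

        fig, ax = plt.subplots(figsize=(5, 5))
        for lab in order:
            sub = rec[rec["duration_label"] == lab]
            scores = sub[p].to_numpy()
            y = (sub["label"].to_numpy() == "malignant").astype(int)
            thr = np.unique(scores)[::-1]
            tpr = [0.0]
            fpr = [0.0]
            for t in thr:
                pred = scores >= t
                tpr.append(float((pred & (y == 1)).sum() / max(y.sum(), 1)))
                fpr.append(float((pred & (y == 0)).sum() / max((1 - y).sum(), 1)))
            ax.plot(fpr, tpr, label=lab, lw=1)
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC: {p.upper()}")
        ax.legend(fontsize=7)
        path = out / f"roc_{p}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
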