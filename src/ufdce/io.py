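"""Reading and writing study artifacts (CSV, JSON, NIfTI)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ufdce.relaxometry import ConcentrationSeries
from ufdce.simulate import AcquisitionParams, CohortSpec, SyntheticStudy

__all__ = ["save_study", "load_curves", "write_curves_csv"]


def write_curves_csv(
    curves: list[tuple[ConcentrationSeries, str]], path: Path
) -> None:
    rows = []
    for series, label in curves:
        for t, c in zip(series.times, series.values):
            rows.append(
                {
                    "lesion_id": series.lesion_id,
                    "label": label,
                    "time_s": t,
                    "conc_mM": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_study(
    study: SyntheticStudy, outdir: str | Path, cohort: CohortSpec | None = None
) -> Path:
    """Write a synthetic study to ``outdir``.

    Emits ``lesions.csv`` (id, label, kinetic truth, t10), ``curves.csv``
    (long-format concentration curves) and a ``study_meta.json`` sidecar
    with the acquisition parameters and seed. When the study carries
    rendered volumes they are written as NIfTI: the 4D dynamic series,
    the two-flip-angle pair and the integer lesion label map.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    acq = study.acquisition

    pd.DataFrame(
        [
            {
                "id": les.lesion_id,
                "label": les.label,
                "ktrans": les.kinetics.ktrans,
                "ve": les.kinetics.ve,
                "vp": les.kinetics.vp,
                "onset_delay": les.kinetics.onset_delay,
                "t10": les.t10,
            }
            for les in study.lesions
        ]
    ).to_csv(out / "lesions.csv", index=False)

    write_curves_csv(
        [
            (ConcentrationSeries(study.timestamps, les.curve, les.lesion_id), les.label)
            for les in study.lesions
        ],
        out / "curves.csv",
    )

    meta = {
        "acquisition": {
            "tr_dce": acq.tr_dce,
            "flip_dce": acq.flip_dce,
            "dt": acq.dt,
            "n_pre": acq.n_pre,
            "n_post": acq.n_post,
            "tr_t1map": acq.tr_t1map,
            "flips_t1map": list(acq.flips_t1map),
            "r1": acq.r1,
        },
        "seed": None if cohort is None else cohort.seed,
        "n_lesions": len(study.lesions),
        "has_volumes": study.volumes is not None,
    }
    (out / "study_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    if study.volumes is not None:
        vol = study.volumes
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(vol.dynamic.astype(np.float32), affine),
                 out / "dynamic.nii.gz")
        for img, flip in zip(vol.t1map_pair, acq.flips_t1map):
            nib.save(
                nib.Nifti1Image(img.astype(np.float32), affine),
                out / f"t1map_flip{flip:g}.nii.gz",
            )
        nib.save(nib.Nifti1Image(vol.labelmap.astype(np.int16), affine),
                 out / "lesion_labelmap.nii.gz")
    return out


def load_curves(
    outdir: str | Path,
) -> tuple[list[tuple[ConcentrationSeries, str]], AcquisitionParams]:
    """Load the concentration curves and acquisition metadata of a saved study."""
    out = Path(outdir)
    meta = json.loads((out / "study_meta.json").read_text())
    am = meta["acquisition"]
    am["flips_t1map"] = tuple(am["flips_t1map"])
    acq = AcquisitionParams(**am)
    df = pd.read_csv(out / "curves.csv")
    curves = []
    for lesion_id, grp in df.groupby("lesion_id", sort=False):
        grp = grp.sort_values("time_s")
        curves.append(
            (
                ConcentrationSeries(
                    grp["time_s"].to_numpy(), grp["conc_mM"].to_numpy(), str(lesion_id)
                ),
                str(grp["label"].iloc[0]),
            )
        )
    return curves, acq
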