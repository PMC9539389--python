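"""NIfTI / CSV input-output and pipeline orchestration.

Per-subject volumes are written as uncompressed NIfTI with a common affine;
`read_subject` refuses volumes whose shapes or affines disagree.  All CSVs
are UTF-8, comma-separated, '.' decimal, with a header row.  Every output
directory carries a ``provenance.json`` with the serialized configuration
and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import PipelineConfig, TrialConfig
from .effects import run_analysis_suite
from .geometry import LesionComponent
from .power import patient_average_metric, power_table
from .synthetic import PatientRecord, SyntheticSubject, SyntheticTrial, TissueAtlas, simulate_trial
from .units import build_unit_tables

logger = logging.getLogger(__name__)

_SUBJECT_VOLUMES = ("atlas", "mask", "mtr_m0", "mtr_m6", "t1w_m0", "truth")


def _nifti(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data), affine)


def write_subject(subject: SyntheticSubject, out_dir: str | Path, affine: np.ndarray | None = None) -> Path:
    """Write one subject's volumes (atlas, mask, mtr_m0, mtr_m6, t1w_m0, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    volumes = {
        "atlas": subject.atlas.labels.astype(np.int16),
        "mask": subject.lesion_mask.astype(np.uint8),
        "mtr_m0": subject.mtr_baseline.astype(np.float64),
        "mtr_m6": subject.mtr_followup.astype(np.float64),
        "t1w_m0": subject.t1w_baseline.astype(np.float64),
        "truth": subject.truth.astype(np.float64),
    }
    for name, data in volumes.items():
        nib.save(_nifti(data, affine), out / f"{name}.nii")
    return out


def read_subject(subject_dir: str | Path, patient: PatientRecord | None = None) -> SyntheticSubject:
    """Load a subject directory, enforcing voxel-aligned, shape-consistent volumes."""
    d = Path(subject_dir)
    images = {}
    for name in _SUBJECT_VOLUMES:
        path = d / f"{name}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing volume: {path}")
        images[name] = nib.load(str(path), mmap=False)

    ref_name = _SUBJECT_VOLUMES[0]
    ref = images[ref_name]
    for name, img in images.items():
        if img.shape != ref.shape:
            raise ValueError(f"{name}.nii shape {img.shape} != {ref_name}.nii shape {ref.shape}")
        if not np.allclose(img.affine, ref.affine, atol=1e-6):
            raise ValueError(f"{name}.nii affine differs from {ref_name}.nii; volumes must be voxel-aligned")

    data = {name: np.asarray(img.dataobj) for name, img in images.items()}
    for name in ("mtr_m0", "mtr_m6", "t1w_m0"):
        if not np.isfinite(data[name]).all():
            raise ValueError(f"{name}.nii contains non-finite values")
    return SyntheticSubject(
        patient=patient,
        atlas=TissueAtlas(labels=data["atlas"].astype(np.int8)),
        lesion_mask=data["mask"].astype(bool),
        components=[],
        mtr_baseline=data["mtr_m0"].astype(float),
        mtr_followup=data["mtr_m6"].astype(float),
        t1w_baseline=data["t1w_m0"].astype(float),
        truth=data["truth"].astype(float),
    )


def write_trial(trial: SyntheticTrial, out_dir: str | Path) -> Path:
    """Write a whole trial: per-subject NIfTI, patients CSV, lesion truth CSV, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial.patients.to_csv(out / "patients.csv", index=False)

    lesion_rows = []
    for subj in trial.subjects:
        write_subject(subj, out / f"sub-{subj.patient.patient_id:03d}")
        for comp in subj.components:
            lesion_rows.append(
                {
                    "patient_id": subj.patient.patient_id,
                    "lesion_id": comp.lesion_id,
                    "tissue_class": comp.tissue_class,
                    "size": comp.size,
                }
            )
    pd.DataFrame(lesion_rows).to_csv(out / "lesions.csv", index=False)
    trial.config.to_yaml(out / "config.yaml")
    return out


def read_trial(trial_dir: str | Path) -> SyntheticTrial:
    """Load a trial directory back into memory (components are relabelled downstream)."""
    d = Path(trial_dir)
    config = TrialConfig.from_yaml(d / "config.yaml")
    patients_df = pd.read_csv(d / "patients.csv")
    subjects = []
    for _, row in patients_df.iterrows():
        patient = PatientRecord(
            patient_id=int(row["patient_id"]),
            arm=str(row["arm"]),
            age_band=int(row["age_band"]),
            gender=int(row["gender"]),
            centre=int(row["centre"]),
            edss_band=int(row["edss_band"]),
        )
        subjects.append(read_subject(d / f"sub-{patient.patient_id:03d}", patient))
    atlas = subjects[0].atlas
    return SyntheticTrial(config=config, atlas=atlas, subjects=subjects, patients=patients_df)


def run_pipeline(config: PipelineConfig, trial: SyntheticTrial | None = None) -> dict:
    """Simulate (optionally), analyse, and write the full output tree.

    Stages: simulate -> unit tables (MTR change, decomposition, banding,
    stratification) -> mixed-model fits and report -> patient-averaged power
    planning.  Returns the in-memory artefacts; everything is also written
    under ``config.out_dir`` with a provenance block.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if trial is None:
        logger.info("stage simulate: %d patients on grid %s", config.trial.n_patients, config.trial.grid_shape)
        trial = simulate_trial(config.trial, seed=config.seed)

    logger.info("stage tables: building unit tables")
    tables = build_unit_tables(trial, connectivity=config.connectivity)
    for level in ("lesion", "component", "segment", "voxel"):
        df = tables[level]
        if not df.empty:
            df.to_csv(out / f"units_{level}.csv", index=False)

    strata_json = {
        "::".join(map(str, key)): {
            "scheme": sd.scheme,
            "cutpoints": [float(c) for c in sd.cutpoints],
        }
        for key, sd in tables["strata"].items()
        if sd is not None
    }
    (out / "strata.json").write_text(json.dumps(strata_json, indent=2))

    if not config.run_fit:
        provenance = {"config": config.to_dict(), "seed": config.seed}
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        return {"trial": trial, "tables": tables, "report": None, "power": None}

    logger.info("stage fit: running the analysis grid")
    report = run_analysis_suite(
        tables,
        use_reml=config.use_reml,
        voxel_subsample_cap=config.voxel_subsample_cap,
        seed=config.seed,
    )
    report.to_csv(out / "report.csv", index=False)

    logger.info("stage power: patient-averaged sample-size planning")
    power_df = None
    lesion = tables["lesion"]
    if not lesion.empty:
        try:
            _, summary = patient_average_metric(lesion)
            power_df = power_table(
                deltas=[1.3, 1.4, 1.5, 1.6, 1.7, 1.8],
                sd_followup=summary["placebo_sd_followup"],
                rho=summary["placebo_rho"],
            )
            power_df.to_csv(out / "power_table.csv", index=False)
        except ValueError as err:
            logger.warning("power stage skipped: %s", err)

    provenance = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_report_rows": int(len(report)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return {"trial": trial, "tables": tables, "report": report, "power": power_df}
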