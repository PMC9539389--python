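"""Long-format analysis unit tables.

Turns per-subject volumes plus lesion decompositions into tidy tables with
one row per analysis unit -- whole lesion, lesion component (core / rim /
perilesional cuff), within-lesion segment, or individual voxel -- each
carrying its baseline and follow-up MTR, nesting identifiers, arm, the four
binary minimisation covariates, and subgroup labels (tissue class,
cohort-level baseline-MTR / baseline-T1 strata, size strata, CSF-distance
band).

Pure WM lesions have their outermost voxel layer stripped for voxel- and
segment-level tables, to mitigate partial volume effects; CGM and DGM
lesions are left intact (stripping would leave too few voxels, as in the
source trial).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .banding import assign_lesion_band, build_bands
from .config import CGM, DGM, PURE_CGM, PURE_DGM, PURE_WM, WM, COMPONENT_ROLES
from .geometry import decompose_lesions, strip_outer_layer
from .stratify import MEDIAN_SPLIT, QUARTILES, assign_stratum, build_segments, fit_cutpoints

logger = logging.getLogger(__name__)

# scheme per pure tissue class: quartiles for WM, median split for the
# less numerous grey-matter lesion classes
_LESION_SCHEME = {PURE_WM: QUARTILES, PURE_CGM: MEDIAN_SPLIT, PURE_DGM: MEDIAN_SPLIT}
_VOXEL_TISSUE_LABEL = {PURE_WM: WM, PURE_CGM: CGM, PURE_DGM: DGM}


def _covariate_row(patient) -> dict:
    return {
        "patient_id": patient.patient_id,
        "arm": patient.arm,
        "age_band": patient.age_band,
        "gender": patient.gender,
        "centre": patient.centre,
        "edss_band": patient.edss_band,
    }


def _mean_at(volume: np.ndarray, voxels: np.ndarray) -> float:
    return float(volume[tuple(voxels.T)].mean())


def build_unit_tables(trial, connectivity: int = 6) -> dict:
    """Build lesion / component / segment / voxel unit tables for a trial.

    ``trial`` needs ``subjects`` (with mtr_baseline, mtr_followup,
    t1w_baseline, lesion_mask, atlas) and a shared atlas; decompositions and
    band maps are recomputed here with the stated connectivity so the tables
    are self-consistent regardless of how the volumes were produced.

    Returns a dict with keys ``lesion``, ``component``, ``segment``,
    ``voxel`` (DataFrames) and ``strata`` (the fitted cutpoint definitions).
    """
    band_map = trial.band_map
    if band_map is None:
        band_map = build_bands(trial.atlas.labels)

    lesion_rows: list[dict] = []
    component_rows: list[dict] = []
    voxel_parts: list[pd.DataFrame] = []
    per_subject: list[dict] = []

    for subj in trial.subjects:
        cov = _covariate_row(subj.patient)
        components, dm = decompose_lesions(subj.lesion_mask, subj.atlas.labels, connectivity)
        per_subject.append({"subject": subj, "components": components, "dm": dm, "cov": cov})

        for comp in components:
            uid = f"p{cov['patient_id']}_l{comp.lesion_id}"
            compartment = "cgm" if comp.tissue_class == PURE_CGM else "wm"
            band = assign_lesion_band(comp, band_map, compartment=compartment)
            lesion_rows.append(
                {
                    "unit_id": uid,
                    "lesion_id": uid,
                    "level": "lesion",
                    "tissue_class": comp.tissue_class,
                    "size": comp.size,
                    "baseline": _mean_at(subj.mtr_baseline, comp.voxels),
                    "followup": _mean_at(subj.mtr_followup, comp.voxels),
                    "t1_baseline": _mean_at(subj.t1w_baseline, comp.voxels),
                    "band": band,
                    **cov,
                }
            )
            for role in COMPONENT_ROLES:
                vox = dm.role_voxels(comp.lesion_id, role)
                if len(vox) == 0:
                    continue  # empty cores / fully excluded cuffs are skipped
                component_rows.append(
                    {
                        "unit_id": f"{uid}_{role}",
                        "lesion_id": uid,
                        "level": "component",
                        "tissue_class": comp.tissue_class,
                        "role": role,
                        "n_voxels": len(vox),
                        "baseline": _mean_at(subj.mtr_baseline, vox),
                        "followup": _mean_at(subj.mtr_followup, vox),
                        **cov,
                    }
                )

    lesion_df = pd.DataFrame(lesion_rows)
    component_df = pd.DataFrame(component_rows)

    # ---- cohort-level lesion strata (baseline MTR, baseline T1, size) ----
    strata: dict = {}
    if not lesion_df.empty:
        for tissue, scheme in _LESION_SCHEME.items():
            sel = lesion_df["tissue_class"] == tissue
            for var, col in (("baseline-MTR", "baseline"), ("baseline-T1", "t1_baseline"), ("size", "size")):
                colname = {"baseline-MTR": "mtr_stratum", "baseline-T1": "t1_stratum", "size": "size_stratum"}[var]
                if colname not in lesion_df:
                    lesion_df[colname] = 0
                try:
                    sd = fit_cutpoints(lesion_df.loc[sel, col], scheme, variable=var, level="lesion", tissue=tissue)
                except ValueError as err:
                    logger.info("lesion strata skipped: %s", err)
                    continue
                strata[("lesion", var, tissue)] = sd
                lesion_df.loc[sel, colname] = assign_stratum(lesion_df.loc[sel, col].to_numpy(), sd)

    # ---- voxel-level tables (pure lesions only, WM interior-stripped) ----
    eligible: list[tuple[dict, object, np.ndarray]] = []  # (subject entry, component, voxels)
    for entry in per_subject:
        for comp in entry["components"]:
            if comp.tissue_class not in _VOXEL_TISSUE_LABEL:
                continue
            vox = (
                strip_outer_layer(comp, connectivity)
                if comp.tissue_class == PURE_WM
                else comp.voxels
            )
            if len(vox) == 0:
                logger.info(
                    "lesion p%s_l%d excluded from voxel-level analysis: no interior voxels",
                    entry["cov"]["patient_id"],
                    comp.lesion_id,
                )
                continue
            eligible.append((entry, comp, vox))

    # cohort voxel-level cutpoints per tissue, from eligible voxels' baselines
    voxel_strata: dict = {}
    for tissue in _VOXEL_TISSUE_LABEL:
        for var, volname in (("baseline-MTR", "mtr_baseline"), ("baseline-T1", "t1w_baseline")):
            pooled = [
                getattr(e["subject"], volname)[tuple(v.T)]
                for e, c, v in eligible
                if c.tissue_class == tissue
            ]
            if not pooled:
                continue
            vals = np.concatenate(pooled)
            try:
                voxel_strata[(var, tissue)] = fit_cutpoints(
                    vals, QUARTILES, variable=var, level="voxel", tissue=tissue
                )
            except ValueError as err:
                logger.info("voxel strata skipped: %s", err)
    strata.update({("voxel",) + k: v for k, v in voxel_strata.items()})

    segment_rows: list[dict] = []
    for entry, comp, vox in eligible:
        subj, cov = entry["subject"], entry["cov"]
        uid = f"p{cov['patient_id']}_l{comp.lesion_id}"
        base = subj.mtr_baseline[tuple(vox.T)]
        fup = subj.mtr_followup[tuple(vox.T)]
        t1 = subj.t1w_baseline[tuple(vox.T)]
        labels = subj.atlas.labels[tuple(vox.T)]

        mtr_sd = voxel_strata.get(("baseline-MTR", comp.tissue_class))
        t1_sd = voxel_strata.get(("baseline-T1", comp.tissue_class))
        mtr_q = assign_stratum(base, mtr_sd) if mtr_sd else np.zeros(len(vox), dtype=int)
        t1_q = assign_stratum(t1, t1_sd) if t1_sd else np.zeros(len(vox), dtype=int)

        if comp.tissue_class == PURE_CGM:
            band = band_map.cgm_band[tuple(vox.T)]
        else:
            band = band_map.wm_dgm_band[tuple(vox.T)]

        voxel_parts.append(
            pd.DataFrame(
                {
                    "unit_id": [f"{uid}_v{i}" for i in range(len(vox))],
                    "lesion_id": uid,
                    "level": "voxel",
                    "tissue_class": comp.tissue_class,
                    "baseline": base,
                    "followup": fup,
                    "t1_baseline": t1,
                    "mtr_quartile": np.atleast_1d(mtr_q),
                    "t1_quartile": np.atleast_1d(t1_q),
                    "band": band,
                    "atlas_label": labels,
                    **cov,
                }
            )
        )

        for var, sd, volume in (("baseline-MTR", mtr_sd, subj.mtr_baseline), ("baseline-T1", t1_sd, subj.t1w_baseline)):
            if sd is None:
                continue
            segs = build_segments(comp, volume, sd, eligible_voxels=vox)
            for _, seg in segs.iterrows():
                members = seg["voxels"]
                segment_rows.append(
                    {
                        "unit_id": f"{uid}_{var}_q{seg['stratum']}",
                        "lesion_id": uid,
                        "level": "segment",
                        "tissue_class": comp.tissue_class,
                        "variable": var,
                        "stratum": seg["stratum"],
                        "n_voxels": seg["n_voxels"],
                        "baseline": _mean_at(subj.mtr_baseline, members),
                        "followup": _mean_at(subj.mtr_followup, members),
                        **cov,
                    }
                )

    voxel_df = pd.concat(voxel_parts, ignore_index=True) if voxel_parts else pd.DataFrame()
    segment_df = pd.DataFrame(segment_rows)

    for df in (lesion_df, component_df, segment_df, voxel_df):
        if not df.empty:
            df["change"] = df["followup"] - df["baseline"]

    return {
        "lesion": lesion_df,
        "component": component_df,
        "segment": segment_df,
        "voxel": voxel_df,
        "strata": strata,
    }
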