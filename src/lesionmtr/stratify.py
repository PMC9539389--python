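"""Cohort-level quartile / median stratification of baseline values.

Cutpoints are computed from baseline only (never follow-up), pooled over the
whole cohort within tissue class, separately per analysis level: lesion-level
cuts from whole-lesion means, voxel-level cuts from voxel values.  Pure WM
units use quartiles; CGM and DGM lesion-level analyses use a median split
because pure GM lesions are too few for quartiles.  Quantiles interpolate
linearly between order statistics; a value equal to a cutpoint falls in the
lower stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LesionComponent

logger = logging.getLogger(__name__)

QUARTILES = "quartiles"
MEDIAN_SPLIT = "median-split"


@dataclass
class StrataDefinition:
    variable: str  # "baseline-MTR" | "baseline-T1" | ...
    level: str  # "lesion" | "voxel"
    tissue: str
    scheme: str  # QUARTILES | MEDIAN_SPLIT
    cutpoints: tuple[float, ...]

    @property
    def n_strata(self) -> int:
        return len(self.cutpoints) + 1


def fit_cutpoints(
    values,
    scheme: str = QUARTILES,
    variable: str = "baseline-MTR",
    level: str = "lesion",
    tissue: str = "pure-WM",
) -> StrataDefinition:
    """Empirical quantile cutpoints pooled over the cohort within one tissue."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if scheme == QUARTILES:
        if values.size < 4:
            raise ValueError(
                f"need >= 4 values for quartiles in stratum ({variable}, {tissue}, {level}); got {values.size}"
            )
        cuts = tuple(np.quantile(values, [0.25, 0.5, 0.75]))
    elif scheme == MEDIAN_SPLIT:
        if values.size < 2:
            raise ValueError(
                f"need >= 2 values for a median split in stratum ({variable}, {tissue}, {level}); got {values.size}"
            )
        cuts = (float(np.quantile(values, 0.5)),)
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    if len(set(cuts)) < len(cuts):
        logger.warning(
            "degenerate cutpoints for (%s, %s, %s): tied values collapse strata; "
            "units at the ties fall in the lowest stratum",
            variable,
            tissue,
            level,
        )
    return StrataDefinition(variable=variable, level=level, tissue=tissue, scheme=scheme, cutpoints=cuts)


def assign_stratum(values, strata: StrataDefinition) -> np.ndarray:
    """Stratum index 1..k (1 = lowest); value equal to a cutpoint goes lower.

    Non-finite values get stratum 0 (excluded) with a logged count.
    """
    values = np.asarray(values, dtype=float)
    scalar = values.ndim == 0
    values = np.atleast_1d(values)
    out = np.zeros(values.shape, dtype=np.int8)
    finite = np.isfinite(values)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("assign_stratum: %d non-finite values excluded", n_bad)
    cuts = np.asarray(strata.cutpoints)
    # value <= cut -> lower stratum, hence strict comparison counts
    out[finite] = 1 + (values[finite, None] > cuts[None, :]).sum(axis=1)
    return int(out[0]) if scalar else out


def build_segments(
    component: LesionComponent,
    voxel_values: np.ndarray,
    strata: StrataDefinition,
    eligible_voxels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Group a lesion's voxels into segments by their baseline stratum.

    ``voxel_values`` is a volume of the stratifying baseline variable;
    ``eligible_voxels`` restricts to an interior voxel set (the outer-layer
    strip for pure WM lesions).  Returns one row per nonempty segment with
    the member voxel index array and counts; callers attach mean outcomes.
    """
    vox = component.voxels if eligible_voxels is None else eligible_voxels
    if len(vox) == 0:
        return pd.DataFrame(columns=["lesion_id", "stratum", "n_voxels", "voxels"])
    vals = voxel_values[tuple(np.asarray(vox).T)]
    strat = assign_stratum(vals, strata)
    rows = []
    for s in np.unique(strat):
        if s == 0:
            continue
        members = np.asarray(vox)[strat == s]
        rows.append({"lesion_id": component.lesion_id, "stratum": int(s), "n_voxels": len(members), "voxels": members})
    return pd.DataFrame(rows)
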