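"""Concentric distance bands from the CSF surfaces.

White-matter and deep-grey voxels are banded by Euclidean distance from the
ventricular CSF: per subject the distances are divided into 10 bins, bins 1
and 10 are dropped to mitigate partial volume effects at the surfaces, and
the survivors renumbered 1..8 with band 1 nearest the ventricles.  The
cortical ribbon gets 2 bands by a per-subject median split of distance from
the outer CSF: the nearer half is band 2 (outer), the farther half band 1
(inner).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import CGM, CSF_OUTER, CSF_VENTRICULAR, DGM, WM
from .geometry import LesionComponent

logger = logging.getLogger(__name__)

N_WMDGM_BANDS = 10
DROPPED_BANDS = (1, 10)


@dataclass
class BandMap:
    """Band index per voxel; 0 where excluded or not banded.

    ``wm_dgm_band`` holds renumbered bands 1..8 over WM and DGM voxels
    (raw bins 2..9); ``cgm_band`` holds 1 (inner) or 2 (outer) over the
    cortical ribbon.  Distance volumes are retained for audit.
    """

    wm_dgm_band: np.ndarray
    cgm_band: np.ndarray
    ventricular_distance: np.ndarray
    outer_csf_distance: np.ndarray


def build_bands(
    atlas_labels: np.ndarray,
    scheme: str = "equal-width",
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> BandMap:
    """Build the WM/DGM ventricular-distance bands and the 2 CGM depth bands.

    ``scheme`` is 'equal-width' (default: bins of equal distance width between
    0 and the subject's maximum) or 'equal-count' (deciles of the distance
    distribution).
    """
    if hasattr(atlas_labels, "labels"):  # accept a TissueAtlas directly
        atlas_labels = atlas_labels.labels
    atlas_labels = np.asarray(atlas_labels)
    vcsf = atlas_labels == CSF_VENTRICULAR
    ocsf = atlas_labels == CSF_OUTER
    if not vcsf.any() or not ocsf.any():
        raise ValueError("atlas must contain nonempty ventricular and outer CSF compartments")
    wmdgm = (atlas_labels == WM) | (atlas_labels == DGM)
    cgm = atlas_labels == CGM
    if not wmdgm.any() or not cgm.any():
        raise ValueError("atlas must contain nonempty WM/DGM and CGM compartments")

    dist_v = ndimage.distance_transform_edt(~vcsf, sampling=spacing)
    dist_o = ndimage.distance_transform_edt(~ocsf, sampling=spacing)

    d = dist_v[wmdgm]
    if scheme == "equal-width":
        edges = np.linspace(0.0, d.max(), N_WMDGM_BANDS + 1)
    elif scheme == "equal-count":
        edges = np.quantile(d, np.linspace(0.0, 1.0, N_WMDGM_BANDS + 1))
    else:
        raise ValueError(f"unknown banding scheme: {scheme!r}")
    # right-closed bins; clip so the maximum lands in the last bin
    raw = np.clip(np.searchsorted(edges[1:-1], d, side="left") + 1, 1, N_WMDGM_BANDS)
    wm_band = np.zeros(atlas_labels.shape, dtype=np.int8)
    renumbered = np.where(np.isin(raw, DROPPED_BANDS), 0, raw - 1)
    wm_band[wmdgm] = renumbered

    dc = dist_o[cgm]
    med = np.median(dc)
    cgm_band = np.zeros(atlas_labels.shape, dtype=np.int8)
    # nearer the outer CSF (<= median) -> band 2 (outer); farther -> band 1 (inner)
    cgm_band[cgm] = np.where(dc <= med, 2, 1)

    return BandMap(
        wm_dgm_band=wm_band,
        cgm_band=cgm_band,
        ventricular_distance=dist_v,
        outer_csf_distance=dist_o,
    )


def assign_lesion_band(
    component: LesionComponent, band_map: BandMap, compartment: str = "wm"
) -> int | None:
    """Band containing the plurality of a lesion's banded voxels.

    Ties break toward the lower (nearer-CSF) band.  Returns None when the
    lesion has no banded voxels (e.g. wholly inside the dropped bins); such
    lesions are excluded from band analyses.
    """
    vol = band_map.wm_dgm_band if compartment == "wm" else band_map.cgm_band
    bands = vol[tuple(component.voxels.T)]
    bands = bands[bands > 0]
    if bands.size == 0:
        logger.info("lesion %d has no banded voxels; excluded from band analyses", component.lesion_id)
        return None
    values, counts = np.unique(bands, return_counts=True)
    # np.unique returns ascending values: argmax takes the first (lowest band) on ties
    return int(values[np.argmax(counts)])
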