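"""Lesion labelling and morphological decomposition.

Each T2-style lesion is split into an outer *rim* (the voxels removed by a
one-voxel-layer erosion) and a central *core* (the erosion itself), and
surrounded by three concentric perilesional *cuffs* of normal-appearing
tissue built by successive one-voxel 3D dilations.  Any voxel reachable by
the cuffs of more than one lesion is excluded from all of them, and cuffs
never enter CSF or other lesions.

"One voxel layer" uses a face-adjacent (6-connectivity) structuring element
by default, configurable to 26-connectivity; component labelling uses the
same element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import (
    CEREBELLAR_GM,
    CGM,
    CSF_LABELS,
    DGM,
    MIXED,
    PURE_CEREBELLAR,
    PURE_CGM,
    PURE_DGM,
    PURE_WM,
    WM,
)

logger = logging.getLogger(__name__)


def structuring_element(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6- (faces) or 26- (full cube) adjacency."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class LesionComponent:
    """A connected lesion component.

    ``voxels`` is an (n, 3) integer array of 0-based indices, sorted in
    raster (C) order so that component identity is reproducible.
    """

    lesion_id: int
    voxels: np.ndarray
    tissue_class: str | None = None

    @property
    def size(self) -> int:
        return len(self.voxels)

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class DecompositionMap:
    """Per-lesion core/rim/cuff voxel assignments plus the exclusion log."""

    shape: tuple[int, ...]
    core: dict[int, np.ndarray] = field(default_factory=dict)
    rim: dict[int, np.ndarray] = field(default_factory=dict)
    cuffs: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    excluded_voxels: np.ndarray | None = None  # voxels dropped for multi-lesion cuff membership

    def role_voxels(self, lesion_id: int, role: str) -> np.ndarray:
        if role == "core":
            return self.core[lesion_id]
        if role == "rim":
            return self.rim[lesion_id]
        return self.cuffs[lesion_id][role]


def label_components(lesion_mask: np.ndarray, connectivity: int = 6) -> list[LesionComponent]:
    """Connected components of a binary mask, ids ordered by first voxel in raster order."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.ndim != 3:
        raise ValueError("lesion_mask must be 3-D")
    labelled, n = ndimage.label(lesion_mask, structure=structuring_element(connectivity))
    if n == 0:
        return []
    flat = labelled.ravel(order="C")
    # first raster position of each label determines its id
    first_pos = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reverse scan so earlier positions overwrite
    for pos in nz[::-1]:
        first_pos[flat[pos]] = pos
    order = np.argsort(first_pos[1:], kind="stable")
    components = []
    for new_id, old in enumerate(order, start=1):
        vox = np.argwhere(labelled == old + 1)
        components.append(LesionComponent(lesion_id=new_id, voxels=vox))
    return components


def classify_tissue(component: LesionComponent, atlas_labels: np.ndarray) -> str:
    """Purity class of a lesion: pure-WM / pure-CGM / pure-DGM / pure-cerebellar / mixed."""
    labels = atlas_labels[tuple(component.voxels.T)]
    if np.isin(labels, CSF_LABELS).any():
        raise ValueError(f"lesion {component.lesion_id} contains CSF voxels; lesions may not be in CSF")
    uniq = np.unique(labels)
    if len(uniq) == 1:
        return {WM: PURE_WM, CGM: PURE_CGM, DGM: PURE_DGM, CEREBELLAR_GM: PURE_CEREBELLAR}[int(uniq[0])]
    return MIXED


def _component_submask(component: LesionComponent, shape: tuple[int, ...], pad: int):
    """Bounding-box submask with ``pad`` voxels of margin, clipped to the grid."""
    lo = np.maximum(component.voxels.min(axis=0) - pad, 0)
    hi = np.minimum(component.voxels.max(axis=0) + pad + 1, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = np.zeros(tuple(hi - lo), dtype=bool)
    sub[tuple((component.voxels - lo).T)] = True
    return sub, sl, lo


def split_core_rim(component: LesionComponent, connectivity: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Erode the lesion by one voxel layer: (core, rim) voxel index arrays.

    The core may be empty for thin lesions; callers skip such lesions in
    core-level analyses.
    """
    if component.size == 0:
        raise ValueError("component is empty")
    sub, _, lo = _component_submask(component, tuple(np.max(component.voxels, axis=0) + 2), pad=1)
    eroded = ndimage.binary_erosion(sub, structure=structuring_element(connectivity), border_value=0)
    core = np.argwhere(eroded) + lo
    rim = np.argwhere(sub & ~eroded) + lo
    return core, rim


def strip_outer_layer(component: LesionComponent, connectivity: int = 6) -> np.ndarray:
    """Interior voxels after removing the outermost layer (== core of split_core_rim).

    Used to mitigate partial volume effects in voxel- and segment-level
    analyses of pure WM lesions only.
    """
    core, _ = split_core_rim(component, connectivity)
    return core


def make_cuffs(
    components: list[LesionComponent],
    lesion_mask: np.ndarray,
    atlas_labels: np.ndarray,
    connectivity: int = 6,
    restrict_to_lesion_tissue: bool = False,
) -> DecompositionMap:
    """Three concentric perilesional cuffs per lesion by successive 1-voxel dilations.

    Cuff voxels are restricted to normal-appearing (non-lesional, non-CSF)
    tissue.  A voxel claimed by the cuffs of two or more lesions is removed
    from all of them, jointly across the three rings, and logged.  With
    ``restrict_to_lesion_tissue`` the cuffs of a pure lesion are further
    confined to that lesion's own tissue class.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    shape = lesion_mask.shape
    struct = structuring_element(connectivity)
    allowed_global = ~lesion_mask & ~np.isin(atlas_labels, CSF_LABELS)

    dm = DecompositionMap(shape=shape)
    claim_count = np.zeros(shape, dtype=np.int16)
    ring_store: dict[int, dict[str, np.ndarray]] = {}

    tissue_of = {PURE_WM: WM, PURE_CGM: CGM, PURE_DGM: DGM, PURE_CEREBELLAR: CEREBELLAR_GM}
    for comp in components:
        core, rim = split_core_rim(comp, connectivity)
        dm.core[comp.lesion_id] = core
        dm.rim[comp.lesion_id] = rim

        sub, sl, lo = _component_submask(comp, shape, pad=4)
        allowed = allowed_global[sl]
        if restrict_to_lesion_tissue and comp.tissue_class in tissue_of:
            allowed = allowed & (atlas_labels[sl] == tissue_of[comp.tissue_class])
        prev = sub
        rings = {}
        claimed_here = np.zeros_like(sub)
        for k in range(1, 4):
            dil = ndimage.binary_dilation(prev, structure=struct)
            ring = dil & ~prev & allowed
            rings[f"cuff{k}"] = ring
            claimed_here |= ring
            prev = dil
        ring_store[comp.lesion_id] = {"rings": rings, "sl": sl, "lo": lo}
        claim_count[sl] += claimed_here.astype(np.int16)

    contested = claim_count >= 2
    n_excluded = int(contested.sum())
    dm.excluded_voxels = np.argwhere(contested)
    if n_excluded:
        logger.info("cuff construction: %d voxels claimed by >1 lesion excluded from all cuffs", n_excluded)

    for comp in components:
        entry = ring_store[comp.lesion_id]
        sl, lo = entry["sl"], entry["lo"]
        keep = ~contested[sl]
        dm.cuffs[comp.lesion_id] = {
            name: np.argwhere(ring & keep) + lo for name, ring in entry["rings"].items()
        }
    return dm


def decompose_lesions(
    lesion_mask: np.ndarray,
    atlas_labels: np.ndarray,
    connectivity: int = 6,
    restrict_to_lesion_tissue: bool = False,
) -> tuple[list[LesionComponent], DecompositionMap]:
    """Label, classify and decompose every lesion in a mask in one call."""
    components = label_components(lesion_mask, connectivity)
    for comp in components:
        comp.tissue_class = classify_tissue(comp, atlas_labels)
    dm = make_cuffs(components, lesion_mask, atlas_labels, connectivity, restrict_to_lesion_tissue)
    return components, dm
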