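import numpy as np
import pytest

from lesionmtr.config import CGM, CSF_OUTER, DGM, WM
from lesionmtr.geometry import (
    LesionComponent,
    classify_tissue,
    decompose_lesions,
    label_components,
    make_cuffs,
    split_core_rim,
    strip_outer_layer,
)

from _oracles import brute_dilate, brute_erode, flood_fill_components
from conftest import random_mask


def _component_from_mask(mask):
    comps = label_components(mask, 6)
    assert len(comps) == 1
    return comps[0]


def _wm_atlas(shape):
    return np.full(shape, WM, dtype=np.int8)


# ---------------------------------------------------------------------------
# labelling


def test_face_and_corner_adjacency():
    m = np.zeros((4, 4, 4), bool)
    m[1, 1, 1] = m[1, 1, 2] = True  # share a face
    assert len(label_components(m, 6)) == 1
    m = np.zeros((4, 4, 4), bool)
    m[1, 1, 1] = m[2, 2, 2] = True  # share only a corner
    assert len(label_components(m, 6)) == 2
    assert len(label_components(m, 26)) == 1


def test_empty_mask_gives_empty_list():
    assert label_components(np.zeros((5, 5, 5), bool), 6) == []


@pytest.mark.parametrize("connectivity", [6, 26])
def test_labelling_matches_flood_fill_oracle(connectivity, rng):
    for _ in range(25):
        mask = random_mask(rng)
        comps = label_components(mask, connectivity)
        oracle = flood_fill_components(mask, connectivity)
        assert len(comps) == oracle.max()
        # identical partitions: each component maps onto exactly one oracle label
        for comp in comps:
            labels = oracle[tuple(comp.voxels.T)]
            assert len(np.unique(labels)) == 1
            assert (oracle == labels[0]).sum() == comp.size


def test_component_ids_follow_raster_order():
    m = np.zeros((5, 5, 5), bool)
    m[4, 4, 4] = True
    m[0, 0, 0] = True
    comps = label_components(m, 6)
    assert tuple(comps[0].voxels[0]) == (0, 0, 0)
    assert comps[0].lesion_id == 1


# ---------------------------------------------------------------------------
# tissue classification


def test_classify_pure_and_mixed():
    atlas = _wm_atlas((6, 6, 6))
    atlas[3:, :, :] = CGM
    atlas[0, 0, :] = DGM

    vox_wm = np.array([[1, 1, 1], [1, 1, 2]])
    assert classify_tissue(LesionComponent(1, vox_wm), atlas) == "pure-WM"
    vox_dgm = np.array([[0, 0, 1], [0, 0, 2]])
    assert classify_tissue(LesionComponent(2, vox_dgm), atlas) == "pure-DGM"
    vox_mixed = np.array([[2, 1, 1], [2, 1, 2], [2, 1, 3], [3, 1, 1]])  # 3 WM + 1 CGM
    assert classify_tissue(LesionComponent(3, vox_mixed), atlas) == "mixed"


def test_lesion_in_csf_is_an_error():
    atlas = _wm_atlas((4, 4, 4))
    atlas[1, 1, 1] = CSF_OUTER
    with pytest.raises(ValueError):
        classify_tissue(LesionComponent(1, np.array([[1, 1, 1]])), atlas)


# ---------------------------------------------------------------------------
# core / rim / strip


def test_single_voxel_lesion_has_empty_core():
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    core, rim = split_core_rim(_component_from_mask(m), 6)
    assert len(core) == 0
    assert len(rim) == 1 and tuple(rim[0]) == (2, 2, 2)


@pytest.mark.parametrize("side, n_core, n_rim", [(3, 1, 26), (5, 27, 98)])
def test_solid_cube_core_rim_counts(side, n_core, n_rim):
    m = np.zeros((side + 4,) * 3, bool)
    m[2 : 2 + side, 2 : 2 + side, 2 : 2 + side] = True
    core, rim = split_core_rim(_component_from_mask(m), 6)
    assert len(core) == n_core and len(rim) == n_rim
    # partition invariant
    assert len(core) + len(rim) == side**3


def test_strip_outer_layer_equals_core(rng):
    for _ in range(10):
        mask = random_mask(rng, p=0.5)
        for comp in label_components(mask, 6):
            core, _ = split_core_rim(comp, 6)
            stripped = strip_outer_layer(comp, 6)
            assert sorted(map(tuple, core)) == sorted(map(tuple, stripped))


@pytest.mark.parametrize("connectivity", [6, 26])
def test_core_rim_match_brute_force_erosion(connectivity, rng):
    for _ in range(25):
        mask = random_mask(rng)
        expected = brute_erode(mask, connectivity)
        got = np.zeros_like(mask)
        for comp in label_components(mask, connectivity):
            core, rim = split_core_rim(comp, connectivity)
            if len(core):
                got[tuple(core.T)] = True
            assert len(core) + len(rim) == comp.size
        assert np.array_equal(got, expected)


# ---------------------------------------------------------------------------
# cuffs


def test_point_lesion_octahedral_cuff_shells():
    m = np.zeros((11, 11, 11), bool)
    m[5, 5, 5] = True
    atlas = _wm_atlas(m.shape)
    comps = label_components(m, 6)
    dm = make_cuffs(comps, m, atlas, connectivity=6)
    assert len(dm.cuffs[1]["cuff1"]) == 6
    assert len(dm.cuffs[1]["cuff2"]) == 18
    assert len(dm.cuffs[1]["cuff3"]) == 38


def test_multi_lesion_cuff_exclusion_midline():
    # two single-voxel lesions 3 apart along an axis: the midline voxel is
    # reachable by both cuff systems and must vanish from both
    m = np.zeros((9, 9, 9), bool)
    m[4, 4, 2] = True
    m[4, 4, 6] = True
    atlas = _wm_atlas(m.shape)
    comps = label_components(m, 6)
    dm = make_cuffs(comps, m, atlas, connectivity=6)
    mid = (4, 4, 4)
    for lesion_id in (1, 2):
        for ring in ("cuff1", "cuff2", "cuff3"):
            vox = dm.cuffs[lesion_id][ring]
            assert mid not in set(map(tuple, vox))
    assert mid in set(map(tuple, dm.excluded_voxels))


def test_cuffs_avoid_csf():
    m = np.zeros((9, 9, 9), bool)
    m[4, 4, 4] = True
    atlas = _wm_atlas(m.shape)
    atlas[:, :, 5:] = CSF_OUTER  # lesion sits against a CSF wall
    dm = make_cuffs(label_components(m, 6), m, atlas, connectivity=6)
    for ring in ("cuff1", "cuff2", "cuff3"):
        vox = dm.cuffs[1][ring]
        if len(vox):
            assert (atlas[tuple(vox.T)] != CSF_OUTER).all()


@pytest.mark.parametrize("connectivity", [6, 26])
def test_cuff_rings_match_brute_force_dilation(connectivity, rng):
    """On isolated single-lesion masks, rings equal successive brute dilation differences."""
    for _ in range(10):
        m = np.zeros((10, 10, 10), bool)
        centre = rng.integers(3, 7, size=3)
        m[tuple(centre)] = True
        for off in rng.integers(-1, 2, size=(3, 3)):
            v = np.clip(centre + off, 0, 9)
            m[tuple(v)] = True
        atlas = _wm_atlas(m.shape)
        dm = make_cuffs(label_components(m, connectivity), m, atlas, connectivity)
        assert len(dm.cuffs) == len(label_components(m, connectivity))
        if len(dm.cuffs) != 1:
            continue
        d1 = brute_dilate(m, connectivity)
        d2 = brute_dilate(d1, connectivity)
        d3 = brute_dilate(d2, connectivity)
        expected = {"cuff1": d1 & ~m, "cuff2": d2 & ~d1, "cuff3": d3 & ~d2}
        for ring, exp in expected.items():
            got = np.zeros_like(m)
            vox = dm.cuffs[1][ring]
            if len(vox):
                got[tuple(vox.T)] = True
            assert np.array_equal(got, exp)


def test_decomposition_invariants_on_random_trial_geometry(default_small_trial):
    """Partition and disjointness over a realistic multi-lesion configuration."""
    trial = default_small_trial
    subj = trial.subjects[0]
    comps, dm = decompose_lesions(subj.lesion_mask, subj.atlas.labels, 6)
    claimed = {}
    for comp in comps:
        core = set(map(tuple, dm.core[comp.lesion_id]))
        rim = set(map(tuple, dm.rim[comp.lesion_id]))
        lesion = set(map(tuple, comp.voxels))
        assert core | rim == lesion and not core & rim
        assert len(core) <= comp.size
        rings = [set(map(tuple, dm.cuffs[comp.lesion_id][r])) for r in ("cuff1", "cuff2", "cuff3")]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not rings[i] & rings[j]
        allcuff = set().union(*rings)
        assert not allcuff & set(map(tuple, np.argwhere(subj.lesion_mask)))
        for v in allcuff:
            assert v not in claimed, "voxel in cuffs of two lesions"
            claimed[v] = comp.lesion_id
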