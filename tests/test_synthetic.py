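import numpy as np
import pytest

from lesionmtr.config import (
    CEREBELLAR_GM,
    CGM,
    CSF_OUTER,
    CSF_VENTRICULAR,
    DGM,
    WM,
    EffectSpec,
    TrialConfig,
)
from lesionmtr.synthetic import (
    generate_atlas,
    plant_lesions,
    simulate_trial,
)

from conftest import noiseless_uniform_config, small_config


# ---------------------------------------------------------------------------
# atlas


def test_atlas_has_all_six_labels_and_partitions_grid():
    atlas = generate_atlas((48, 48, 48), seed=1)
    counts = np.bincount(atlas.labels.ravel(), minlength=7)
    for lab in (CSF_VENTRICULAR, DGM, WM, CGM, CEREBELLAR_GM, CSF_OUTER):
        assert counts[lab] >= 1
    assert counts[1:].sum() == 48**3 and counts[0] == 0


def test_atlas_deterministic_and_seed_sensitive():
    a = generate_atlas((48, 48, 48), seed=1)
    b = generate_atlas((48, 48, 48), seed=1)
    c = generate_atlas((48, 48, 48), seed=2)
    assert np.array_equal(a.labels, b.labels)
    assert not np.array_equal(a.labels, c.labels)


def test_atlas_csf_compartments_topologically_separated():
    from scipy import ndimage

    atlas = generate_atlas((48, 48, 48), seed=1)
    csf = np.isin(atlas.labels, (CSF_VENTRICULAR, CSF_OUTER))
    labelled, n = ndimage.label(csf, structure=ndimage.generate_binary_structure(3, 3))
    inner = set(np.unique(labelled[atlas.labels == CSF_VENTRICULAR]))
    outer = set(np.unique(labelled[atlas.labels == CSF_OUTER]))
    assert not inner & outer  # no connected path between the two CSF compartments


def test_atlas_too_small_raises():
    with pytest.raises(ValueError):
        generate_atlas((16, 16, 16), seed=1)


# ---------------------------------------------------------------------------
# lesions


def test_zero_lesions_gives_empty_mask(rng):
    atlas = generate_atlas((32, 32, 32), seed=1)
    cfg = small_config()
    out = plant_lesions(atlas, cfg, rng, counts={})
    assert not out.mask.any() and out.components == []


def test_lesions_avoid_csf_and_do_not_overlap(rng):
    atlas = generate_atlas((48, 48, 48), seed=1)
    cfg = small_config(grid_shape=(48, 48, 48))
    out = plant_lesions(atlas, cfg, rng, counts={"pure-WM": 8, "mixed": 4, "pure-CGM": 3})
    csf = np.isin(atlas.labels, (CSF_VENTRICULAR, CSF_OUTER))
    assert not (out.mask & csf).any()
    total = sum(c.size for c in out.components)
    assert total == out.mask.sum()  # no overlap between planted lesions


def test_planted_purity_classes_are_consistent(rng):
    atlas = generate_atlas((48, 48, 48), seed=1)
    cfg = small_config(grid_shape=(48, 48, 48))
    out = plant_lesions(atlas, cfg, rng, counts={"pure-WM": 5, "mixed": 3, "pure-CGM": 2})
    for comp in out.components:
        labels = set(atlas.labels[tuple(comp.voxels.T)])
        if comp.tissue_class == "pure-WM":
            assert labels == {WM}
        elif comp.tissue_class == "pure-CGM":
            assert labels == {CGM}
        elif comp.tissue_class == "mixed":
            assert WM in labels and (CGM in labels or DGM in labels)


def test_plant_lesions_deterministic():
    atlas = generate_atlas((32, 32, 32), seed=1)
    cfg = small_config()
    a = plant_lesions(atlas, cfg, np.random.default_rng(7), counts={"pure-WM": 5})
    b = plant_lesions(atlas, cfg, np.random.default_rng(7), counts={"pure-WM": 5})
    assert np.array_equal(a.mask, b.mask)
    assert [c.voxels.tolist() for c in a.components] == [c.voxels.tolist() for c in b.components]


# ---------------------------------------------------------------------------
# trial simulation


def test_trial_deterministic_under_seed():
    cfg = small_config(n_patients=4)
    a = simulate_trial(cfg, seed=9)
    b = simulate_trial(cfg, seed=9)
    assert a.patients.equals(b.patients)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.mtr_baseline, sb.mtr_baseline)
        assert np.array_equal(sa.mtr_followup, sb.mtr_followup)
        assert np.array_equal(sa.t1w_baseline, sb.t1w_baseline)


def test_noiseless_null_followup_equals_baseline():
    es = EffectSpec(tau_by_tissue={"wm": 0.0, "cgm": 0.0, "dgm": 0.0, "cerebellar_gm": 0.0})
    cfg = small_config(
        n_patients=4, sigma_patient=0.0, sigma_lesion=0.0, sigma_voxel=0.0,
        t1_coupling=(80.0, 8.0, 0.0), effect_spec=es,
    )
    trial = simulate_trial(cfg, seed=2)
    for subj in trial.subjects:
        assert np.array_equal(subj.mtr_followup, subj.mtr_baseline)


def test_noiseless_uniform_effect_is_planted_exactly():
    trial = simulate_trial(noiseless_uniform_config(tau=1.5, n_patients=6), seed=4)
    planted_any = False
    for subj in trial.subjects:
        delta = subj.mtr_followup - subj.mtr_baseline
        if subj.patient.arm == "placebo":
            assert np.array_equal(subj.truth, np.zeros_like(subj.truth))
            assert np.allclose(delta, 0.0)
        else:
            assert np.allclose(delta[subj.lesion_mask], 1.5)
            assert np.allclose(subj.truth[subj.lesion_mask], 1.5)
            planted_any = planted_any or subj.lesion_mask.any()
    assert planted_any


def test_placebo_truth_identically_zero(default_small_trial):
    for subj in default_small_trial.subjects:
        if subj.patient.arm == "placebo":
            assert not subj.truth.any()


def test_arm_balance_within_minimisation_strata(default_small_trial):
    df = default_small_trial.patients.copy()
    counts = df.groupby(["age_band", "gender", "centre", "edss_band", "arm"]).size().unstack(fill_value=0)
    for _, row in counts.iterrows():
        assert abs(row.get("active", 0) - row.get("placebo", 0)) <= 1


def test_t1_coupling_tracks_baseline(default_small_trial):
    subj = default_small_trial.subjects[0]
    brain = subj.atlas.labels != CSF_OUTER
    r = np.corrcoef(subj.t1w_baseline[brain], subj.mtr_baseline[brain])[0, 1]
    assert r > 0.5  # damage lowers both MTR and T1-weighted intensity


def test_lesional_baseline_reduced_vs_surrounding(default_small_trial):
    subj = default_small_trial.subjects[0]
    wm = subj.atlas.labels == WM
    lesional = subj.mtr_baseline[wm & subj.lesion_mask]
    nawm = subj.mtr_baseline[wm & ~subj.lesion_mask]
    assert lesional.mean() < nawm.mean() - 2.0


def test_placebo_voxel_correlation_matches_closed_form_oracle():
    """r = var(shared) / (var(shared) + sigma_voxel^2), pooled over >= 1e4 voxels."""
    cfg = small_config(
        n_patients=26, grid_shape=(40, 40, 40), sigma_voxel=2.0, lesion_mtr_deficit=8.0,
        lesions_per_patient={"pure-WM": 10.0, "mixed": 5.0, "pure-CGM": 2.0,
                             "pure-DGM": 0.5, "pure-cerebellar": 0.0},
    )
    trial = simulate_trial(cfg, seed=6)
    base, fup, shared = [], [], []
    for subj in trial.subjects:
        if subj.patient.arm != "placebo":
            continue
        m = subj.lesion_mask
        base.append(subj.mtr_baseline[m])
        fup.append(subj.mtr_followup[m])
        shared.append(subj.shared_field[m])
    base, fup, shared = map(np.concatenate, (base, fup, shared))
    assert len(base) >= 10_000
    r_emp = np.corrcoef(base, fup)[0, 1]
    var_shared = shared.var()
    r_pred = var_shared / (var_shared + cfg.sigma_voxel**2)
    # Monte-Carlo tolerance: Fisher-z SE at this n is ~0.01; allow 4x
    assert r_emp == pytest.approx(r_pred, abs=0.04)
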