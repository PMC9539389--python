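import numpy as np
import pandas as pd
import pytest

from lesionmtr.power import (
    CeilingSpec,
    PowerSpec,
    ancova_per_arm_n,
    ancova_total_n,
    ceiling_effect,
    patient_average_metric,
    power_table,
)
from lesionmtr.synthetic import simulate_trial
from lesionmtr.units import build_unit_tables

from conftest import small_config

# frozen z-values for the closed-form oracle (two-sided 5%, 80% / 90% power)
Z975 = 1.959964
Z80 = 0.841621
Z90 = 1.281552


def test_ceiling_effect_cases():
    assert ceiling_effect(CeilingSpec(5.92, 0.5)) == pytest.approx(2.96)
    assert ceiling_effect(CeilingSpec(3.1, 1.0)) == pytest.approx(3.1)  # full recovery = the gap
    assert ceiling_effect(CeilingSpec(0.0, 0.5)) == 0.0
    with pytest.raises(ValueError):
        CeilingSpec(5.92, 0.0)
    with pytest.raises(ValueError):
        CeilingSpec(-1.0, 0.5)


def test_ancova_n_matches_closed_form_oracle():
    spec = PowerSpec(delta=0.5, sd_followup=1.0, rho=0.0, alpha=0.05, power=0.80)
    oracle = int(np.ceil(2 * (Z975 + Z80) ** 2 * 1.0 * (1 - 0.0) / 0.25))
    assert oracle == 63
    assert ancova_per_arm_n(spec) == 63
    assert ancova_total_n(spec) == 126


def test_baseline_correlation_reduces_n():
    base = ancova_total_n(PowerSpec(delta=0.5, sd_followup=1.0, rho=0.0))
    shrunk = ancova_total_n(PowerSpec(delta=0.5, sd_followup=1.0, rho=0.99))
    assert shrunk < base


def test_monotonicities():
    ref = dict(delta=1.5, sd_followup=2.0, rho=0.6, alpha=0.05, power=0.80)
    n0 = ancova_total_n(PowerSpec(**ref))
    assert ancova_total_n(PowerSpec(**{**ref, "delta": 1.8})) <= n0
    assert ancova_total_n(PowerSpec(**{**ref, "rho": 0.9})) <= n0
    assert ancova_total_n(PowerSpec(**{**ref, "alpha": 0.10})) <= n0
    assert ancova_total_n(PowerSpec(**{**ref, "power": 0.90})) >= n0
    assert ancova_total_n(PowerSpec(**{**ref, "sd_followup": 3.0})) >= n0


def test_rho_zero_equals_classical_two_sample_size():
    spec = PowerSpec(delta=0.8, sd_followup=2.5, rho=0.0, alpha=0.05, power=0.90)
    classical = int(np.ceil(2 * (Z975 + Z90) ** 2 * 2.5**2 / 0.8**2))
    assert ancova_per_arm_n(spec) == classical


def test_t_correction_adds_one_per_arm():
    spec = PowerSpec(delta=0.5, sd_followup=1.0, rho=0.0)
    assert ancova_per_arm_n(spec, t_correction=True) == ancova_per_arm_n(spec) + 1


def test_power_table_strictly_decreasing_over_delta_sweep():
    df = power_table([1.3, 1.4, 1.5, 1.6, 1.7, 1.8], sd_followup=2.0, rho=0.8)
    for col in ("total_n_power_80", "total_n_power_90"):
        assert (np.diff(df[col]) < 0).all()
    assert (df["total_n_power_90"] > df["total_n_power_80"]).all()
    assert (df[["total_n_power_80", "total_n_power_90"]] % 2 == 0).all().all()


def test_power_ratio_90_to_80():
    """Pre-rounding ratio of 90% to 80% sizes is the z-sum ratio ~1.3387."""
    ratio = (Z975 + Z90) ** 2 / (Z975 + Z80) ** 2
    assert ratio == pytest.approx(1.3386, abs=1e-3)
    df = power_table(np.linspace(1.3, 1.8, 6), sd_followup=2.0, rho=0.8)
    got = df["total_n_power_90"] / df["total_n_power_80"]
    # rounded totals stay within rounding distance (1 per arm on each side)
    lo = (df["total_n_power_80"] * ratio - 2) / df["total_n_power_80"]
    hi = (df["total_n_power_80"] * ratio + 2) / df["total_n_power_80"]
    assert ((got >= lo) & (got <= hi)).all()


# ---------------------------------------------------------------------------
# patient-averaged metrics


def test_one_lesion_per_patient_identity():
    t = pd.DataFrame(
        {
            "patient_id": [0, 1, 2, 3],
            "arm": ["placebo", "placebo", "placebo", "active"],
            "baseline": [30.0, 32.0, 31.0, 29.0],
            "followup": [30.5, 32.5, 30.8, 30.0],
        }
    )
    per_patient, summary = patient_average_metric(t)
    assert np.allclose(per_patient["followup"], t["followup"])
    assert summary["n_patients"] == 4


def test_pearson_r_of_identical_vectors_is_one():
    t = pd.DataFrame(
        {
            "patient_id": [0, 1, 2],
            "arm": ["placebo"] * 3,
            "baseline": [30.0, 32.0, 31.0],
            "followup": [30.0, 32.0, 31.0],
        }
    )
    _, summary = patient_average_metric(t)
    assert summary["placebo_rho"] == pytest.approx(1.0)


def test_zero_qualifying_patients_errors():
    t = pd.DataFrame({"patient_id": [0], "arm": ["placebo"], "baseline": [30.0], "followup": [30.0]})
    with pytest.raises(ValueError):
        patient_average_metric(t, lesion_filter=lambda df: df["baseline"] > 100)


def test_recovered_sigma_rho_match_generator_moments():
    """Placebo (sigma, rho) from the patient-averaged metric agree with the
    closed-form moments implied by the generator's realized shared fields."""
    cfg = small_config(n_patients=40)
    trial = simulate_trial(cfg, seed=17)
    tables = build_unit_tables(trial)
    _, summary = patient_average_metric(tables["lesion"])

    # oracle: per-patient shared metric (no voxel noise) plus exact per-patient
    # voxel-noise variance sigma_v^2 * mean_l (1/n_vox) / L^2
    shared_means, noise_vars = [], []
    for subj in trial.subjects:
        if subj.patient.arm != "placebo" or not subj.components:
            continue
        vals = [subj.shared_field[tuple(c.voxels.T)].mean() for c in subj.components]
        sizes = np.array([c.size for c in subj.components], dtype=float)
        shared_means.append(np.mean(vals))
        noise_vars.append(cfg.sigma_voxel**2 * np.sum(1.0 / sizes) / len(sizes) ** 2)
    shared_means = np.asarray(shared_means)
    vn = float(np.mean(noise_vars))
    vs = float(np.var(shared_means, ddof=1))
    sd_pred = np.sqrt(vs + vn)
    rho_pred = vs / (vs + vn)
    assert summary["placebo_sd_followup"] == pytest.approx(sd_pred, rel=0.25)
    assert summary["placebo_rho"] == pytest.approx(rho_pred, abs=0.05)
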