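"""Baseline-adjusted treatment effects and a quartile-interaction test.

Plants a grey-matter-favouring effect (WM 0.2 pu, CGM 1.4 pu, DGM 2.0 pu --
the generator default, echoing the pattern seen in remyelination trial
readouts), then estimates per-tissue adjusted differences with mixed models
and tests whether WM voxel effects vary across baseline-MTR quartiles.
"""

from lesionmtr import (
    TrialConfig,
    build_unit_tables,
    fit_adjusted_difference,
    fit_subgroup_interaction,
    simulate_trial,
)

trial = simulate_trial(TrialConfig(n_patients=20, grid_shape=(40, 40, 40)), seed=7)
tables = build_unit_tables(trial)

lesion = tables["lesion"]
print("whole-lesion adjusted active-placebo differences (pu):")
for tissue in ("pure-WM", "pure-CGM"):
    est = fit_adjusted_difference(lesion[lesion["tissue_class"] == tissue])
    lo, hi = est.ci95
    print(f"  {tissue:9s}: {est.adjusted_difference:+.2f} (95% CI {lo:+.2f} to {hi:+.2f}), "
          f"p = {est.p_value:.3f}, n = {est.n_active}+{est.n_placebo}")

wm_vox = tables["voxel"][tables["voxel"]["tissue_class"] == "pure-WM"]
res = fit_subgroup_interaction(wm_vox, "mtr_quartile")
print("\nWM-voxel effects by baseline-MTR quartile (1 = most damaged):")
for e in res.estimates:
    print(f"  quartile {e.subgroup_label}: {e.adjusted_difference:+.2f} pu")
print(f"interaction p = {res.p_interaction:.3f}")
print("With the default uniform-by-quartile effect this interaction should "
      "usually be non-significant; plant quartile multipliers to change that.")
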