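# lesionmtr

Within-lesion and between-lesion treatment-effect analysis of the
magnetisation transfer ratio (MTR) for remyelination trials in multiple
sclerosis, plus a synthetic two-arm trial generator to exercise the whole
pipeline when real scans are unavailable.

MTR is a semi-quantitative MRI index that tracks myelin density:

    MTR = 100 * (MToff - MTon) / MToff     [percentage units, pu]

A remyelinating drug should raise lesional MTR between baseline and
follow-up. Whether it does — and whether the response depends on *where* a
lesion sits (tissue class, distance from the CSF) and *how damaged* it is
(baseline MTR, T1-weighted intensity) — is what this package quantifies.

## Who this is for

Analysts of two-arm longitudinal MRI trials who need:

- **MTR and change maps** from MTon/MToff pairs (`lesionmtr.mtr`);
- **lesion decomposition**: connected-component labelling, tissue-purity
  classification (pure WM / cortical GM / deep GM / cerebellar / mixed), a
  one-voxel-layer erosion into core and rim, and three perilesional cuffs by
  successive 1-voxel dilations with a multi-lesion exclusion rule
  (`lesionmtr.geometry`);
- **CSF-distance banding**: 10 equal-width ventricular-distance bands over
  WM/DGM per subject (bands 1 and 10 dropped, survivors renumbered 1–8) and
  2 cortical depth bands by median split (`lesionmtr.banding`);
- **cohort stratification**: tissue-specific quartile (WM) or median (GM)
  cutpoints of baseline MTR, baseline T1-weighted intensity and lesion size,
  applied at lesion, segment and voxel level (`lesionmtr.stratify`);
- **treatment effects**: linear mixed models with patient and, where units
  nest within lesions, lesion random intercepts, adjusting for the baseline
  value and the four binary minimisation covariates (age band, gender,
  centre, EDSS band); per-subgroup adjusted differences and joint Wald
  interaction tests (`lesionmtr.effects`);
- **trial planning**: the remyelination ceiling (lesion–NAWM gap × a
  recoverable fraction) and ANCOVA sample sizes
  `n/arm = ceil(2 (z_{1-a/2}+z_pow)² σ² (1-ρ²) / Δ²)` (`lesionmtr.power`);
- **a synthetic trial generator** (`lesionmtr.synthetic`) producing a
  schematic brain atlas, planted lesions with reduced baseline MTR, shared
  patient/lesion random intercepts and independent voxel noise calibrated so
  placebo lesional voxels show baseline–follow-up Pearson r in the
  0.74–0.96 range, and planted treatment effects that may vary by tissue,
  baseline-MTR quartile, distance band and core/rim/cuff role.

The model fitted at every level is

    followup ~ arm + baseline + age_band + gender + centre + edss_band
               + (1 | patient) [+ (1 | lesion) for nested units]

by REML with logged fallbacks (ML, then the reduced model when a variance
component sits on the boundary). Subgroup analyses add `subgroup` and
`arm:subgroup` terms; with no separate arm main effect, each `arm:subgroup`
coefficient is directly that subgroup's adjusted treatment difference, and
the interaction p is the joint Wald test that they are all equal.

## Worked example

```python
from lesionmtr import (TrialConfig, simulate_trial, build_unit_tables,
                       fit_adjusted_difference, fit_subgroup_interaction)

trial = simulate_trial(TrialConfig(n_patients=20, grid_shape=(40, 40, 40)), seed=7)
tables = build_unit_tables(trial)
lesion = tables["lesion"]
for tissue in ("pure-WM", "pure-CGM"):
    est = fit_adjusted_difference(lesion[lesion["tissue_class"] == tissue])
    print(tissue, est.adjusted_difference, est.ci95, est.p_value)
```

prints (seed 7, generator defaults: planted WM effect 0.2 pu, CGM 1.4 pu):

```
whole-lesion adjusted active-placebo differences (pu):
  pure-WM  : +0.13 (95% CI +0.01 to +0.26), p = 0.041, n = 51+49
  pure-CGM : +1.35 (95% CI +1.17 to +1.52), p = 0.000, n = 17+13
```

The CGM estimate recovers the planted 1.4 pu grey-matter effect within its
confidence interval; the WM estimate sits near its small planted value. The
`examples/` directory holds five narrative scripts (simulation, MTR +
decomposition, banding + strata, treatment effects, power planning); each
runs in seconds and prints what its numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at reduced scale (12 patients on
a 32³ grid): simulate → unit tables (decomposition, banding, strata) →
mixed-model analysis grid → power planning, printing a row count for the
report it produced and writing the results JSON.

## Layout

```
src/lesionmtr/        config, synthetic, mtr, geometry, banding, stratify,
                      units, effects, power, io
tests/                unit + property tests, brute-force oracles,
                      test_acceptance.py (calibration, power, recovery)
examples/             five runnable narrative scripts
docs/methods.md       model, assumptions, defaults, limitations
```
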