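# Methods

## The estimation problem

A two-arm trial measures lesional MTR at baseline and follow-up. Treatment
effects are estimated at four nested levels — whole lesion, lesion
component/segment, and individual voxel — with the same working model
throughout:

    followup = b0 + tau * arm + b1 * baseline
             + b2 * age_band + b3 * gender + b4 * centre + b5 * edss_band
             + u_patient [+ u_lesion] + e

`tau` is the adjusted active−placebo difference in pu. `u_patient` is a
patient random intercept; a lesion random intercept `u_lesion` is added
whenever units nest within lesions (components, segments, voxels). The four
binary covariates are the minimisation factors balanced at randomisation and
are always adjusted for alongside the baseline value of the outcome.

Two facts shape the inference:

1. **Main treatment contrasts are wholly between-patient** — no patient has
   both treated and untreated lesions — so their precision is limited by the
   number of patients.
2. **Subgroup-interaction contrasts are largely within-patient** — one
   patient contributes lesions to several quartiles or bands — so
   interaction tests can be decisively significant even when every
   per-subgroup effect is not.

## Fitting and fallbacks

Variance components are estimated by REML (statsmodels `MixedLM`) with a
logged fallback chain: REML → ML → drop the lesion component → ordinary
least squares. The last step is not a concession: when the baseline
covariate absorbs the shared intercepts (they enter baseline and follow-up
identically in the generator), the patient variance genuinely sits on the
boundary and the reduced model *is* the correct model; `MixedLM` signals
this with a singular Hessian. A numerically perfect fit (noise-free
synthetic data) short-circuits to exact OLS with zero-width intervals.

Wald inference with normal quantiles is used for coefficients, and a joint
Wald chi-square for the interaction test (contrasts of the `arm:subgroup`
coefficients against equality, computed directly from the fixed-effects
covariance block). Before fitting, the outcome and baseline are centred —
this leaves every arm contrast untouched and stabilises the optimiser. If a
covariate perfectly separates the arms (possible in very small simulated
cohorts), it is dropped from the adjustment with a logged note; under
randomisation this does not bias the estimate. p < 0.05 two-sided is the
significance convention and no multiplicity correction is applied by
default (`multiplicity_correction` in `PipelineConfig` enables
Benjamini–Hochberg for users who want it).

Voxel-level fits may subsample units above a documented cap
(`voxel_subsample_cap`, default 4000, seeded) — estimates, not wall-clock
parity, are the contract.

## Geometry conventions

- "One voxel layer" means the 6-connectivity (face-adjacent) structuring
  element by default, configurable to 26; component labelling uses the same
  element, and all test oracles are parameterised by the same choice.
- Core = one-layer erosion of the lesion; rim = lesion − core. Empty cores
  (thin lesions) are skipped in core-level analyses, not errors.
- Cuffs 1–3 are successive one-layer dilation shells restricted to
  non-lesional, non-CSF tissue; any voxel claimed by the cuffs of two or
  more lesions is excluded from all of them, jointly across the three
  rings, after all dilations. A config switch can further restrict cuffs to
  the lesion's own tissue class.
- Pure WM lesions have the outermost voxel layer stripped for voxel- and
  segment-level analyses (partial-volume mitigation); CGM/DGM lesions do
  not, because stripping leaves too few voxels there.
- WM/DGM banding: Euclidean distance from ventricular CSF, 10 equal-width
  per-subject bins (equal-count optional), bins 1 and 10 dropped, survivors
  renumbered 1–8 (1 nearest the ventricles). CGM: median split of distance
  from the outer CSF; nearer half is band 2 (outer). Per-subject banding is
  a design choice; whether a cohort-wise definition was used in practice is
  not documented anywhere authoritative, and per-subject is reproducible
  without registration.
- A lesion's band is the plurality band of its banded voxels; ties break
  toward the lower (nearer-CSF) band; lesions with no banded voxels are
  excluded from band analyses with a log entry.
- Quantiles interpolate linearly between order statistics; a value equal to
  a cutpoint falls in the lower stratum. Cutpoints are cohort-level, fitted
  on baseline only, per tissue and per level (lesion-level cuts from
  whole-lesion means, voxel-level cuts from voxel values of the analysis's
  eligible voxel sets). T1 "intensity" is the non-quantitative T1-weighted
  value used raw within cohort (a hook exists for per-subject
  normalisation).

## The synthetic trial generator

The generator's job is to produce data with exactly the statistical
structure the analysis assumes, with known ground truth:

    baseline(v) = tissue_mean - deficit(depth(v)) + u_patient + u_lesion + e0(v)
    followup(v) = [same systematic part]          + u_patient + u_lesion
                  + arm * tau(v) + e1(v)

- **Atlas**: nested ellipsoidal shells — central ventricular CSF, a deep-GM
  shell, WM bulk, a cortical ribbon thick enough for two depth bands, an
  outer CSF rind, and a small cerebellar-GM pocket. Schematic, not
  anatomical: the analysis needs only tissue labels, two CSF surfaces and
  distances. Semi-axes are jittered a few percent by the seed.
- **Lesions**: random ellipsoids clipped to their intended tissue (pure
  classes) or straddling a WM/GM boundary (mixed), never in CSF, kept one
  voxel apart so component labelling recovers exactly the planted lesions
  under either connectivity. Counts are Poisson per patient and class, with
  a cohort guarantee of at least one pure-WM and one pure-CGM lesion when
  the requested means permit. Cerebellar lesions default to zero (they were
  excluded from the main analyses this mirrors).
- **Arms**: stratified alternation within the 16 minimisation strata after
  a seeded shuffle — balance within ±1 per stratum, which is what the
  covariate adjustment consumes; true minimisation is not simulated.
- **Planted effects**: `tau(v) = tau_by_tissue[tissue]` times optional
  multipliers over the voxel's baseline-MTR quartile, distance band, and
  core/rim/cuff role. Labels are computed with the very operators the
  analysis uses (same connectivity, same stripped eligible voxel sets, same
  cohort cutpoints), so planted and estimated subgroups agree by
  construction. Placebo subjects have an identically zero truth volume.
- **T1-weighted volume**: a linear transform of baseline MTR plus
  independent noise (default intercept 80, slope 8 per pu, SD 15) — damage
  lowers both.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| n_patients | 49 | cohort size of the trial setting this emulates |
| tissue MTR means | WM 38, CGM 32, DGM 34, cerebellar 33 pu | typical 3T values |
| lesion deficit | 8 pu at centre | lesional MTR clearly below NAWM |
| within-lesion gradient | 1 pu per voxel of depth | damage worst centrally |
| sigma_patient / sigma_lesion / sigma_voxel | 1.0 / 1.5 / 1.3 pu | chosen once from the closed-form ratio r = var(shared)/(var(shared)+sigma_voxel²) so placebo lesional-voxel baseline–follow-up r lands mid-range of the observed 0.74–0.96 window |
| planted tau | WM 0.2, CGM 1.4, DGM 2.0 pu | direction and rough magnitude of observed adjusted differences in this trial setting |
| lesions/patient | WM 5, mixed 4, CGM 1.5, DGM 0.5 | keeps the real mix's flavour (WM and mixed common, pure GM rare) at a scale a 48³ grid can hold |

The variance decomposition across patient/lesion/voxel levels is a free
choice, not an estimate — no public data constrain it.

### What the generator does *not* emulate

MRI physics (bias fields, motion, distortion), registration error,
longitudinal atrophy, anatomical lesion shapes and spatial clustering,
scanner differences beyond a binary centre covariate. A green test
therefore establishes that the *pipeline* is correct and calibrated under
the stated error structure — not that it is robust to real-world artefacts.

## Power module

The remyelination ceiling is `gap × fraction` (defaults 5.92 pu × 0.5 =
2.96 pu): complete repair cannot lift lesional MTR above normal-appearing
white matter, and ex-vivo evidence points to about half the gap being
recoverable. Sample sizes use the normal-approximation ANCOVA formula
`n/arm = ceil(2 (z_{1-α/2}+z_power)² σ² (1-ρ²) / Δ²)` with an optional +1
per-arm t correction; totals are reported as twice the per-arm ceiling.
`patient_average_metric` aggregates whole-lesion values per patient
(patients, not lesions, are randomised) and returns the placebo follow-up
SD and baseline–follow-up Pearson r ready to feed the formula. Note that
the schematic generator's patient-averaged metrics are nearly noise-free
(ρ → 1), so synthetic-world sample sizes are unrealistically small; the
formula itself is exercised against closed-form oracles.

## Numerical conventions

- Voxel coordinates are 0-based array indices; world coordinates only via
  the NIfTI affine (identity / 1 mm isotropic by default, honoured if
  anisotropic).
- CSVs are UTF-8, comma-separated, '.' decimal, with header; NIfTI is the
  only image format; every pipeline output directory carries a
  `provenance.json` with the full configuration and seed.
- Determinism: one root seed spawns independent child generators per
  subject; rerunning a pipeline with the same config and seed reproduces
  all CSV outputs byte-identically.
- Monte-Carlo test bands were fixed a priori: the type-I band is the
  central 99% binomial interval under a 5% rate, recovery uses 3 standard
  errors, coverage must fall in [90%, 98%].

## Known limitations

- The mixed model for voxels nested in lesions nested in patients uses two
  nested random intercepts; richer structures (random slopes, patient×lesion
  interactions) are not fitted.
- Interaction p-values rely on the normal approximation; with very few
  lesions per subgroup they can be anticonservative.
- The T1 stratification uses raw synthetic intensities; real multi-scanner
  T1-weighted data would need normalisation before cohort pooling.
- The equal-width band rule and per-subject banding are one reasonable
  reading of a procedure whose exact rule is not documented; the config
  exposes equal-count binning as the alternative.
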