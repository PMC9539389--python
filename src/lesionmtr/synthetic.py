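"""Synthetic two-arm remyelination trial generator.

Builds a schematic brain (nested ellipsoidal shells: ventricular CSF, deep
grey, white matter bulk, a cortical ribbon thick enough for two depth bands,
an outer CSF rind, and a small cerebellar grey pocket), plants ellipsoidal
lesions of known tissue class, and simulates baseline and follow-up MTR
volumes with a three-level error structure:

    baseline(v)  = tissue_mean - deficit(depth) + b_patient + b_lesion + eps0(v)
    followup(v)  = [systematic part] + b_patient + b_lesion + arm * tau(v) + eps1(v)

Random intercepts b_patient and b_lesion are shared between timepoints;
voxel noise is drawn independently per timepoint, which together produce
the strong baseline--follow-up correlation observed in placebo lesional
voxels.  The planted effect tau(v) is the per-tissue effect times optional
multipliers over the voxel's eventual baseline-MTR quartile, CSF-distance
band, and core/rim/cuff role -- labels computed with the very operators the
downstream analysis uses, so planted and estimated subgroups agree by
construction.

The T1-weighted volume is a linear transform of baseline MTR plus
independent noise (damage lowers both MTR and T1-weighted intensity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .banding import BandMap, build_bands
from .config import (
    CEREBELLAR_GM,
    CGM,
    CSF_OUTER,
    CSF_VENTRICULAR,
    DGM,
    MIXED,
    PURE_CEREBELLAR,
    PURE_CGM,
    PURE_DGM,
    PURE_WM,
    WM,
    EffectSpec,
    TrialConfig,
)
from .geometry import LesionComponent, decompose_lesions, label_components, structuring_element
from .stratify import QUARTILES, assign_stratum, fit_cutpoints

logger = logging.getLogger(__name__)

_CSF_MTR = 2.0  # pu; nominal CSF value, outside all analyses

_LABEL_TO_TISSUE_KEY = {WM: "wm", CGM: "cgm", DGM: "dgm", CEREBELLAR_GM: "cerebellar_gm"}
_PURE_CLASS_TO_LABEL = {
    PURE_WM: WM,
    PURE_CGM: CGM,
    PURE_DGM: DGM,
    PURE_CEREBELLAR: CEREBELLAR_GM,
}


@dataclass
class TissueAtlas:
    """Integer-labelled schematic tissue atlas (see config for label codes)."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.labels, labels)


@dataclass
class PatientRecord:
    """Arm plus the four binary minimisation covariates of the trial."""

    patient_id: int
    arm: str  # "placebo" | "active"
    age_band: int  # 0: <=40, 1: >40 years
    gender: int
    centre: int  # 0/1, the two trial centres
    edss_band: int  # 0: <=4.0, 1: >4.0


@dataclass
class LesionSet:
    components: list[LesionComponent]
    mask: np.ndarray


@dataclass
class SyntheticSubject:
    patient: PatientRecord
    atlas: TissueAtlas
    lesion_mask: np.ndarray
    components: list[LesionComponent]
    mtr_baseline: np.ndarray
    mtr_followup: np.ndarray | None
    t1w_baseline: np.ndarray | None
    truth: np.ndarray | None
    # internal generative bookkeeping used by the second simulation pass
    shared_field: np.ndarray | None = None  # systematic + random intercepts, no voxel noise
    eps_baseline: np.ndarray | None = None


@dataclass
class SyntheticTrial:
    config: TrialConfig
    atlas: TissueAtlas
    subjects: list[SyntheticSubject]
    patients: pd.DataFrame
    band_map: BandMap | None = None
    planting_strata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(grid_shape: tuple[int, int, int], seed: int = 0) -> TissueAtlas:
    """Nested-shell schematic atlas; every voxel gets exactly one of 6 labels.

    Geometry is ellipsoidal and slightly jittered by ``seed`` (a few percent
    of the semi-axes) so different seeds give different, but deterministic,
    anatomies.  Raises if the grid cannot hold all shells.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 32 for s in grid_shape):
        raise ValueError(f"grid_shape must be 3-D with every axis >= 32; got {grid_shape}")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0.97, 1.03, size=3)

    centre = (np.array(grid_shape) - 1) / 2.0
    semi = (np.array(grid_shape) / 2.0 - 0.5) * jitter
    s = float(semi.min())

    idx = np.indices(grid_shape, dtype=float)
    rho = np.sqrt(sum(((idx[i] - centre[i]) / semi[i]) ** 2 for i in range(3)))
    r = rho * s  # effective radius in voxel units along the tightest axis

    vcsf_r = max(2.5, 0.15 * s)
    dgm_r = vcsf_r + max(2.0, 0.10 * s)
    rind = 2.0
    cgm_thick = max(4.5, 0.18 * s)
    cgm_in = s - rind - cgm_thick
    if cgm_in - dgm_r < 3.0:
        raise ValueError(
            f"grid {grid_shape} too small to fit all atlas shells "
            f"(white-matter bulk would be {cgm_in - dgm_r:.1f} voxels thick)"
        )

    labels = np.full(grid_shape, CSF_OUTER, dtype=np.int8)
    labels[r < s - rind] = CGM
    labels[r < cgm_in] = WM
    labels[r < dgm_r] = DGM
    labels[r < vcsf_r] = CSF_VENTRICULAR

    # small cerebellar grey pocket carved out of the white matter bulk
    cb_centre = centre + np.array([0.0, 0.0, 1.0]) * (dgm_r + cgm_in) / 2.0
    cb_r = max(2.0, 0.08 * s)
    d_cb = np.sqrt(sum((idx[i] - cb_centre[i]) ** 2 for i in range(3)))
    labels[(d_cb < cb_r) & (labels == WM)] = CEREBELLAR_GM

    atlas = TissueAtlas(labels=labels)
    for lab in (CSF_VENTRICULAR, DGM, WM, CGM, CEREBELLAR_GM, CSF_OUTER):
        if not (labels == lab).any():
            raise ValueError(f"atlas construction failed: label {lab} empty on grid {grid_shape}")
    return atlas


# ---------------------------------------------------------------------------
# lesions


def plant_lesions(
    atlas: TissueAtlas,
    config: TrialConfig,
    rng: np.random.Generator,
    counts: dict[str, int] | None = None,
) -> LesionSet:
    """Plant non-overlapping ellipsoidal lesions of requested tissue classes.

    Lesions never enter CSF; pure-class lesions are clipped to their tissue,
    mixed lesions straddle a WM/GM boundary.  Planted lesions keep a one-voxel
    separation so connected-component labelling recovers them exactly.  An
    infeasible placement is skipped with a warning after bounded retries.
    """
    if counts is None:
        counts = {
            cls: int(rng.poisson(mean)) if mean > 0 else 0
            for cls, mean in config.lesions_per_patient.items()
        }
    shape = atlas.shape
    labels = atlas.labels
    sep_struct = structuring_element(26)  # separation must hold under either connectivity

    non_csf = ~atlas.mask(CSF_VENTRICULAR, CSF_OUTER)
    gm = atlas.mask(CGM, DGM)
    wm_boundary = ndimage.binary_dilation(gm, structure=sep_struct) & (labels == WM)

    candidates: dict[str, np.ndarray] = {}
    for cls, lab in _PURE_CLASS_TO_LABEL.items():
        candidates[cls] = np.argwhere(labels == lab)
    candidates[MIXED] = np.argwhere(wm_boundary)

    lesion_mask = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)
    components: list[LesionComponent] = []
    next_id = 1
    rlo, rhi = config.lesion_radius_range

    for cls in (PURE_WM, MIXED, PURE_CGM, PURE_DGM, PURE_CEREBELLAR):
        n_wanted = counts.get(cls, 0)
        cand = candidates[cls]
        for _ in range(n_wanted):
            placed = False
            for _attempt in range(40):
                if len(cand) == 0:
                    break
                c = cand[rng.integers(len(cand))]
                radii = rng.uniform(rlo, rhi, size=3)
                lo = np.maximum((c - np.ceil(radii)).astype(int), 0)
                hi = np.minimum((c + np.ceil(radii)).astype(int) + 1, shape)
                sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
                sub_idx = np.indices(tuple(hi - lo), dtype=float)
                ell = (
                    sum(((sub_idx[i] + lo[i] - c[i]) / radii[i]) ** 2 for i in range(3)) <= 1.0
                )
                if cls in _PURE_CLASS_TO_LABEL:
                    ell &= labels[sl] == _PURE_CLASS_TO_LABEL[cls]
                else:
                    ell &= non_csf[sl]
                if not ell.any() or (ell & blocked[sl]).any():
                    continue
                if cls == MIXED:
                    sub_labels = labels[sl][ell]
                    if not ((sub_labels == WM).any() and np.isin(sub_labels, (CGM, DGM)).any()):
                        continue
                lesion_mask[sl] |= ell
                blocked[sl] |= ndimage.binary_dilation(ell, structure=sep_struct)
                vox = np.argwhere(ell) + lo
                vox = vox[np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))]
                components.append(LesionComponent(lesion_id=next_id, voxels=vox, tissue_class=cls))
                next_id += 1
                placed = True
                break
            if not placed and n_wanted > 0:
                logger.warning("could not place a %s lesion after bounded retries; skipped", cls)
    return LesionSet(components=components, mask=lesion_mask)


def _lesion_depth(mask: np.ndarray) -> np.ndarray:
    """Erosion depth (in one-voxel layers, taxicab metric) inside a lesion mask."""
    return ndimage.distance_transform_cdt(mask, metric="taxicab").astype(float)


# ---------------------------------------------------------------------------
# timepoints


def _systematic_baseline(atlas: TissueAtlas, lesion_mask: np.ndarray, config: TrialConfig) -> np.ndarray:
    """Noise-free baseline MTR: tissue means minus the lesional deficit profile."""
    labels = atlas.labels
    vol = np.full(atlas.shape, _CSF_MTR)
    for lab, key in _LABEL_TO_TISSUE_KEY.items():
        vol[labels == lab] = config.tissue_mtr_means[key]
    if lesion_mask.any():
        depth = _lesion_depth(lesion_mask)
        lab_img, n = ndimage.label(lesion_mask, structure=structuring_element(config.connectivity))
        if n:
            maxima = ndimage.maximum(depth, labels=lab_img, index=np.arange(1, n + 1))
            dmax = np.zeros_like(depth)
            inside = lab_img > 0
            dmax[inside] = np.asarray(maxima)[lab_img[inside] - 1]
            reduction = np.clip(
                config.lesion_mtr_deficit - config.within_lesion_gradient * (dmax - depth),
                0.0,
                None,
            )
            vol[inside] -= reduction[inside]
    return vol


def _tau_volume(
    subject: SyntheticSubject,
    effect_spec: EffectSpec,
    band_map: BandMap | None,
    voxel_quartile_strata: dict | None,
    connectivity: int,
) -> np.ndarray:
    """Planted per-voxel treatment effect, using the analysis's own label operators."""
    labels = subject.atlas.labels
    tau = np.zeros(subject.atlas.shape)
    tissue_tau = np.zeros_like(tau)
    for lab, key in _LABEL_TO_TISSUE_KEY.items():
        tissue_tau[labels == lab] = effect_spec.tau_by_tissue.get(key, 0.0)

    if effect_spec.uniform:
        tau[subject.lesion_mask] = tissue_tau[subject.lesion_mask]
        return tau

    components, dm = decompose_lesions(subject.lesion_mask, labels, connectivity)
    comp_mult = effect_spec.component_multipliers
    role_map = {"core": comp_mult.get("core", 1.0), "rim": comp_mult.get("rim", 1.0)}
    for comp in components:
        for role, mult in role_map.items():
            vox = dm.role_voxels(comp.lesion_id, role)
            if len(vox):
                tau[tuple(vox.T)] = tissue_tau[tuple(vox.T)] * mult
        for k in (1, 2, 3):
            mult = comp_mult.get(f"cuff{k}", 0.0)
            if mult:
                vox = dm.role_voxels(comp.lesion_id, f"cuff{k}")
                if len(vox):
                    tau[tuple(vox.T)] = tissue_tau[tuple(vox.T)] * mult

    if any(m != 1.0 for m in effect_spec.quartile_multipliers) and voxel_quartile_strata:
        qmult = np.asarray(effect_spec.quartile_multipliers)
        for lab, strata in voxel_quartile_strata.items():
            sel = (labels == lab) & subject.lesion_mask
            if sel.any():
                q = assign_stratum(subject.mtr_baseline[sel], strata)
                tau[sel] *= qmult[np.asarray(q) - 1]

    if effect_spec.band_multipliers and band_map is not None:
        bm = effect_spec.band_multipliers
        wm_sel = np.isin(labels, (WM, DGM)) & (tau != 0)
        mult = np.ones_like(tau)
        bands = band_map.wm_dgm_band
        for b, m in bm.items():
            mult[wm_sel & (bands == b)] = m
        cgm_sel = (labels == CGM) & (tau != 0)
        for b, m in bm.items():
            mult[cgm_sel & (band_map.cgm_band == b)] = m
        tau *= mult
    return tau


def simulate_timepoints(
    subject: SyntheticSubject,
    effect_spec: EffectSpec,
    rng: np.random.Generator,
    config: TrialConfig,
    band_map: BandMap | None = None,
    voxel_quartile_strata: dict | None = None,
) -> SyntheticSubject:
    """Fill in follow-up MTR, T1-weighted baseline, and the truth volume.

    Requires ``subject.mtr_baseline`` and the generative bookkeeping fields
    from the first pass.  Placebo subjects get a truth volume of exactly
    zero; active subjects' truth equals the configured tau at each affected
    voxel.
    """
    active = subject.patient.arm == "active"
    tau = _tau_volume(subject, effect_spec, band_map, voxel_quartile_strata, config.connectivity)
    truth = tau if active else np.zeros_like(tau)

    eps1 = (
        rng.normal(0.0, config.sigma_voxel, size=subject.atlas.shape)
        if config.sigma_voxel > 0
        else 0.0
    )
    followup = subject.shared_field + truth + eps1

    t1_icept, t1_slope, t1_sd = config.t1_coupling
    t1_noise = rng.normal(0.0, t1_sd, size=subject.atlas.shape) if t1_sd > 0 else 0.0
    t1w = t1_icept + t1_slope * subject.mtr_baseline + t1_noise

    subject.mtr_followup = followup
    subject.t1w_baseline = t1w
    subject.truth = truth
    return subject


# ---------------------------------------------------------------------------
# cohort


def assign_arms(covariates: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Stratified alternation within minimisation strata; balance within +-1 per stratum."""
    n = len(covariates)
    strata = covariates @ (2 ** np.arange(covariates.shape[1]))
    arms = [""] * n
    start = 0
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        members = rng.permutation(members)
        for j, idx in enumerate(members):
            arms[idx] = ("active", "placebo")[(j + start) % 2]
        start ^= len(members) % 2  # alternate the leading arm across strata for global balance
    return arms


def generate_patients(n_patients: int, rng: np.random.Generator) -> list[PatientRecord]:
    cov = rng.integers(0, 2, size=(n_patients, 4))
    arms = assign_arms(cov, rng)
    return [
        PatientRecord(
            patient_id=i,
            arm=arms[i],
            age_band=int(cov[i, 0]),
            gender=int(cov[i, 1]),
            centre=int(cov[i, 2]),
            edss_band=int(cov[i, 3]),
        )
        for i in range(n_patients)
    ]


def simulate_trial(config: TrialConfig, seed: int | None = None) -> SyntheticTrial:
    """Generate a full synthetic two-arm trial.

    Two passes: baselines (with patient/lesion intercepts and voxel noise)
    are generated for every subject first; when the effect specification
    modulates by baseline-MTR quartile, the cohort-level voxel cutpoints are
    then fitted with the analysis's own stratification operator before
    follow-up volumes are produced.
    """
    if seed is not None:
        config = TrialConfig.from_dict({**config.to_dict(), "seed": seed})
    root = np.random.SeedSequence(config.seed)
    atlas_seed, patient_seed, *subject_seeds = root.spawn(2 + config.n_patients)

    atlas = generate_atlas(config.grid_shape, seed=int(atlas_seed.generate_state(1)[0] % 2**31))
    patients = generate_patients(config.n_patients, np.random.default_rng(patient_seed))

    needs_labels = not config.effect_spec.uniform
    band_map = build_bands(atlas.labels) if needs_labels else None

    subjects: list[SyntheticSubject] = []
    rngs = [np.random.default_rng(s) for s in subject_seeds]
    for i, patient in enumerate(patients):
        rng = rngs[i]
        counts = {
            cls: int(rng.poisson(mean)) if mean > 0 else 0
            for cls, mean in config.lesions_per_patient.items()
        }
        if i == 0:  # cohort guarantee: at least one pure-WM and one pure-GM lesion
            if config.lesions_per_patient.get(PURE_WM, 0) > 0:
                counts[PURE_WM] = max(counts[PURE_WM], 1)
            if config.lesions_per_patient.get(PURE_CGM, 0) > 0:
                counts[PURE_CGM] = max(counts[PURE_CGM], 1)
        lesions = plant_lesions(atlas, config, rng, counts=counts)

        systematic = _systematic_baseline(atlas, lesions.mask, config)
        b_patient = rng.normal(0.0, config.sigma_patient) if config.sigma_patient > 0 else 0.0
        shared = systematic + b_patient
        if config.sigma_lesion > 0:
            for comp in lesions.components:
                shared[tuple(comp.voxels.T)] += rng.normal(0.0, config.sigma_lesion)
        eps0 = (
            rng.normal(0.0, config.sigma_voxel, size=atlas.shape)
            if config.sigma_voxel > 0
            else np.zeros(atlas.shape)
        )
        subjects.append(
            SyntheticSubject(
                patient=patient,
                atlas=atlas,
                lesion_mask=lesions.mask,
                components=lesions.components,
                mtr_baseline=shared + eps0,
                mtr_followup=None,
                t1w_baseline=None,
                truth=None,
                shared_field=shared,
                eps_baseline=eps0,
            )
        )

    voxel_quartile_strata = None
    if needs_labels and any(m != 1.0 for m in config.effect_spec.quartile_multipliers):
        # cutpoints are fitted exactly as the analysis fits them: pooled over
        # pure lesions of each tissue, with the WM outer layer stripped
        from .geometry import strip_outer_layer

        pure_of = {WM: PURE_WM, CGM: PURE_CGM, DGM: PURE_DGM}
        voxel_quartile_strata = {}
        for lab, pure_cls in pure_of.items():
            pooled = []
            for s in subjects:
                for comp in s.components:
                    if comp.tissue_class != pure_cls:
                        continue
                    vox = (
                        strip_outer_layer(comp, config.connectivity)
                        if pure_cls == PURE_WM
                        else comp.voxels
                    )
                    if len(vox):
                        pooled.append(s.mtr_baseline[tuple(vox.T)])
            vals = np.concatenate(pooled) if pooled else np.empty(0)
            if vals.size >= 4:
                voxel_quartile_strata[lab] = fit_cutpoints(
                    vals, QUARTILES, variable="baseline-MTR", level="voxel", tissue=pure_cls
                )

    for i, subject in enumerate(subjects):
        simulate_timepoints(
            subject,
            config.effect_spec,
            rngs[i],
            config,
            band_map=band_map,
            voxel_quartile_strata=voxel_quartile_strata,
        )

    patient_df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "arm": p.arm,
                "age_band": p.age_band,
                "gender": p.gender,
                "centre": p.centre,
                "edss_band": p.edss_band,
            }
            for p in patients
        ]
    )
    return SyntheticTrial(
        config=config,
        atlas=atlas,
        subjects=subjects,
        patients=patient_df,
        band_map=band_map,
        planting_strata={"voxel_quartiles": voxel_quartile_strata},
    )
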