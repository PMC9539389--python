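"""Configuration objects for the synthetic trial generator and the analysis pipeline.

All MTR quantities are expressed in percentage units (pu), the native scale of
the magnetisation transfer ratio.  Voxel coordinates are 0-based array indices
with unit (1 mm isotropic) spacing unless a NIfTI affine says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

# Tissue labels used by the schematic atlas.  Every voxel carries exactly one.
CSF_VENTRICULAR = 1
DGM = 2
WM = 3
CGM = 4
CEREBELLAR_GM = 5
CSF_OUTER = 6

TISSUE_NAMES: Mapping[int, str] = {
    CSF_VENTRICULAR: "csf_ventricular",
    DGM: "dgm",
    WM: "wm",
    CGM: "cgm",
    CEREBELLAR_GM: "cerebellar_gm",
    CSF_OUTER: "csf_outer",
}

CSF_LABELS = (CSF_VENTRICULAR, CSF_OUTER)
GM_LABELS = (CGM, DGM, CEREBELLAR_GM)

# Lesion tissue classes (purity of the atlas labels of member voxels).
PURE_WM = "pure-WM"
PURE_CGM = "pure-CGM"
PURE_DGM = "pure-DGM"
PURE_CEREBELLAR = "pure-cerebellar"
MIXED = "mixed"

COMPONENT_ROLES = ("core", "rim", "cuff1", "cuff2", "cuff3")


@dataclass
class EffectSpec:
    """True treatment effect planted at follow-up, in pu.

    The effect at a lesional voxel is ``tau_by_tissue[tissue]`` multiplied by
    the quartile / band / component multipliers for that voxel's eventual
    analysis labels.  All-ones multipliers reduce to a uniform per-tissue
    effect.  Component multipliers may extend the effect into the perilesional
    cuffs (roles cuff1..cuff3); their default is zero there.
    """

    tau_by_tissue: dict[str, float] = field(
        default_factory=lambda: {"wm": 0.2, "cgm": 1.4, "dgm": 2.0, "cerebellar_gm": 1.0}
    )
    quartile_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    band_multipliers: dict[int, float] | None = None
    component_multipliers: dict[str, float] = field(
        default_factory=lambda: {"core": 1.0, "rim": 1.0, "cuff1": 0.0, "cuff2": 0.0, "cuff3": 0.0}
    )

    def __post_init__(self) -> None:
        import math

        for v in self.tau_by_tissue.values():
            if not math.isfinite(v):
                raise ValueError("tau_by_tissue values must be finite")
        if len(self.quartile_multipliers) != 4:
            raise ValueError("quartile_multipliers must have exactly 4 entries")
        for m in self.quartile_multipliers:
            if not math.isfinite(m):
                raise ValueError("quartile multipliers must be finite")

    @property
    def uniform(self) -> bool:
        """True when no label-dependent modulation is requested.

        In that case the generator can skip computing quartile, band and
        component labels entirely (fast path).
        """
        quart_flat = all(m == 1.0 for m in self.quartile_multipliers)
        band_flat = self.band_multipliers is None or all(
            m == 1.0 for m in self.band_multipliers.values()
        )
        comp = self.component_multipliers
        comp_flat = (
            comp.get("core", 1.0) == 1.0
            and comp.get("rim", 1.0) == 1.0
            and all(comp.get(k, 0.0) == 0.0 for k in ("cuff1", "cuff2", "cuff3"))
        )
        return quart_flat and band_flat and comp_flat


@dataclass
class TrialConfig:
    """Stated world of the synthetic two-arm trial.

    Defaults mirror the source trial where stated (49 patients, two arms,
    four binary minimisation covariates, lesional MTR reduced relative to
    surrounding tissue) and are otherwise scaled to a schematic 48-cubed
    brain.  Noise SDs are calibrated so that placebo lesional-voxel
    baseline--follow-up correlation falls inside the observed 0.737-0.955
    range (see docs/methods.md).
    """

    n_patients: int = 49
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    lesions_per_patient: dict[str, float] = field(
        default_factory=lambda: {
            PURE_WM: 5.0,
            MIXED: 4.0,
            PURE_CGM: 1.5,
            PURE_DGM: 0.5,
            PURE_CEREBELLAR: 0.0,  # trial excluded its 5 cerebellar lesions
        }
    )
    lesion_radius_range: tuple[float, float] = (1.5, 3.5)
    tissue_mtr_means: dict[str, float] = field(
        default_factory=lambda: {"wm": 38.0, "cgm": 32.0, "dgm": 34.0, "cerebellar_gm": 33.0}
    )
    lesion_mtr_deficit: float = 8.0
    within_lesion_gradient: float = 1.0
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    sigma_patient: float = 1.0
    sigma_lesion: float = 1.5
    sigma_voxel: float = 1.3
    t1_coupling: tuple[float, float, float] = (80.0, 8.0, 15.0)  # intercept, slope, noise SD
    connectivity: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 32 per axis to hold the atlas shells")
        for name in ("sigma_patient", "sigma_lesion", "sigma_voxel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(m <= 0 for m in self.tissue_mtr_means.values()):
            raise ValueError("tissue_mtr_means must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "effect_spec" in d and isinstance(d["effect_spec"], dict):
            es = dict(d["effect_spec"])
            if "quartile_multipliers" in es:
                es["quartile_multipliers"] = tuple(es["quartile_multipliers"])
            d["effect_spec"] = EffectSpec(**es)
        for key in ("grid_shape", "lesion_radius_range", "t1_coupling"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """Options tying the stages into one reproducible pipeline run."""

    out_dir: str = "pipeline_out"
    trial: TrialConfig = field(default_factory=TrialConfig)
    connectivity: int = 6
    banding_scheme: str = "equal-width"  # or "equal-count"
    use_reml: bool = True
    run_fit: bool = True  # False: stop after geometry/tables outputs
    voxel_subsample_cap: int = 4000
    multiplicity_correction: bool = False  # optional Benjamini-Hochberg
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
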