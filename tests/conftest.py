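import logging

import numpy as np
import pytest

from lesionmtr.config import EffectSpec, TrialConfig
from lesionmtr.synthetic import simulate_trial

logging.getLogger("lesionmtr").setLevel(logging.ERROR)


def small_config(**overrides) -> TrialConfig:
    """A 32-cubed, 8-patient configuration for fast tests."""
    defaults = dict(
        n_patients=8,
        grid_shape=(32, 32, 32),
        lesions_per_patient={
            "pure-WM": 5.0,
            "mixed": 2.0,
            "pure-CGM": 2.0,
            "pure-DGM": 0.5,
            "pure-cerebellar": 0.0,
        },
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


def noiseless_uniform_config(tau: float = 1.5, **overrides) -> TrialConfig:
    """All SDs zero, uniform planted effect tau at every lesion and cuff voxel."""
    es = EffectSpec(
        tau_by_tissue={"wm": tau, "cgm": tau, "dgm": tau, "cerebellar_gm": tau},
        component_multipliers={"core": 1, "rim": 1, "cuff1": 1, "cuff2": 1, "cuff3": 1},
    )
    return small_config(
        sigma_patient=0.0,
        sigma_lesion=0.0,
        sigma_voxel=0.0,
        t1_coupling=(80.0, 8.0, 0.0),
        effect_spec=es,
        **overrides,
    )


@pytest.fixture(scope="session")
def default_small_trial():
    """One noisy default-parameter trial shared across read-only tests."""
    return simulate_trial(small_config(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, max_side: int = 12, p: float = 0.35) -> np.ndarray:
    shape = tuple(rng.integers(4, max_side + 1, size=3))
    return rng.random(shape) < p
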