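"""Sample-size planning for future remyelination trials.

Sizes are computed for patient-averaged lesional MTR metrics (patients, not
lesions, are randomised) analysed by ANCOVA: a two-arm comparison of
follow-up means adjusted for baseline, whose variance is deflated by
(1 - rho^2) where rho is the placebo baseline--follow-up correlation.

The remyelination ceiling bounds plausible effects: complete repair cannot
raise lesional MTR above normal-appearing white matter, and ex-vivo data
suggest only about half that gap is recoverable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CeilingSpec:
    """Lesion-to-NAWM MTR gap (pu) and the recoverable fraction."""

    lesion_nawm_gap: float = 5.92
    remyelination_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.lesion_nawm_gap < 0:
            raise ValueError("lesion_nawm_gap must be >= 0")
        if not 0 < self.remyelination_fraction <= 1:
            raise ValueError("remyelination_fraction must be in (0, 1]")


@dataclass
class PowerSpec:
    """Inputs to the ANCOVA sample-size formula."""

    delta: float  # target treatment effect, pu
    sd_followup: float  # placebo follow-up SD, pu
    rho: float  # placebo baseline--follow-up Pearson correlation
    alpha: float = 0.05  # two-sided significance level
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sd_followup <= 0:
            raise ValueError("sd_followup must be > 0")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def ceiling_effect(spec: CeilingSpec) -> float:
    """Maximum plausible treatment effect in pu: gap times recoverable fraction."""
    return spec.lesion_nawm_gap * spec.remyelination_fraction


def ancova_per_arm_size(spec: PowerSpec) -> float:
    """Un-rounded per-arm size: 2 (z_{1-alpha/2} + z_power)^2 sigma^2 (1 - rho^2) / delta^2."""
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    return float(2 * (z_a + z_b) ** 2 * spec.sd_followup**2 * (1 - spec.rho**2) / spec.delta**2)


def ancova_per_arm_n(spec: PowerSpec, t_correction: bool = False) -> int:
    """Per-arm sample size for the baseline-adjusted two-arm comparison.

    The ceiling of :func:`ancova_per_arm_size`, optionally +1 per arm as the
    usual first-order t-distribution correction.
    """
    return math.ceil(ancova_per_arm_size(spec)) + (1 if t_correction else 0)


def ancova_total_n(spec: PowerSpec, t_correction: bool = False, ceiling: CeilingSpec | None = None) -> int:
    """Total participants across both arms (2 x per-arm ceiling)."""
    if ceiling is not None and spec.delta >= ceiling_effect(ceiling):
        logger.warning(
            "target effect %.2f pu is at or above the remyelination ceiling %.2f pu",
            spec.delta,
            ceiling_effect(ceiling),
        )
    return 2 * ancova_per_arm_n(spec, t_correction)


def power_table(
    deltas,
    sd_followup: float,
    rho: float,
    alpha: float = 0.05,
    powers=(0.80, 0.90),
    t_correction: bool = False,
) -> pd.DataFrame:
    """Total-sample-size table over a sweep of target effects and power levels."""
    rows = []
    for d in deltas:
        row = {"delta_pu": d}
        for p in powers:
            spec = PowerSpec(delta=d, sd_followup=sd_followup, rho=rho, alpha=alpha, power=p)
            row[f"total_n_power_{int(round(p * 100))}"] = ancova_total_n(spec, t_correction)
        rows.append(row)
    return pd.DataFrame(rows)


def patient_average_metric(
    lesion_table: pd.DataFrame, lesion_filter=None
) -> tuple[pd.DataFrame, dict]:
    """Per-patient mean of whole-lesion values over qualifying lesions.

    Returns the per-patient table (baseline, followup, change, n_lesions,
    arm) and a summary dict with the placebo arm's follow-up SD and
    baseline--follow-up Pearson r, ready to feed a PowerSpec.  Patients with
    no qualifying lesion are excluded and counted.
    """
    t = lesion_table if lesion_filter is None else lesion_table[lesion_filter(lesion_table)]
    all_patients = lesion_table["patient_id"].nunique()
    if t.empty or t["patient_id"].nunique() == 0:
        raise ValueError("no patients with qualifying lesions")
    per_patient = (
        t.groupby(["patient_id", "arm"], observed=True)
        .agg(baseline=("baseline", "mean"), followup=("followup", "mean"), n_lesions=("baseline", "size"))
        .reset_index()
    )
    per_patient["change"] = per_patient["followup"] - per_patient["baseline"]
    n_excluded = all_patients - per_patient["patient_id"].nunique()
    if n_excluded:
        logger.info("patient_average_metric: %d patients without qualifying lesions excluded", n_excluded)

    plc = per_patient[per_patient["arm"] == "placebo"]
    summary = {
        "n_patients": int(len(per_patient)),
        "n_excluded": int(n_excluded),
        "placebo_sd_followup": float(plc["followup"].std(ddof=1)) if len(plc) > 1 else float("nan"),
        "placebo_rho": float(np.corrcoef(plc["baseline"], plc["followup"])[0, 1])
        if len(plc) > 1
        else float("nan"),
        "placebo_mean_followup": float(plc["followup"].mean()) if len(plc) else float("nan"),
    }
    return per_patient, summary
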