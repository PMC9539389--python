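"""Baseline-adjusted treatment-effect estimation with nested random intercepts.

The working model at every level is

    followup ~ arm + baseline + age_band + gender + centre + edss_band

with a random intercept per patient and, for units nested within lesions
(components, segments, voxels), an additional lesion random intercept.
Variance components are estimated by REML, falling back to ML and then to
the reduced model (ultimately OLS) when a fit fails to converge or a
variance component collapses to the boundary; all fallbacks are logged.
The adjusted active-placebo difference is the arm coefficient with a Wald
95% CI and two-sided p under the normal approximation (unit counts are
large, and the shared random intercepts are absorbed by the baseline
adjustment, so residual information is unit- rather than patient-limited).

Subgroup analyses add subgroup main effects and arm-within-subgroup terms;
with no separate arm main effect each arm:subgroup coefficient is directly
that subgroup's adjusted treatment difference, and the interaction test is
the joint Wald test that all pairwise differences of these coefficients are
zero.  These interaction contrasts are strongly within-patient (a patient
contributes lesions to several subgroups) and hence better powered than the
wholly between-patient main treatment comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

COVARIATES = ["age_band", "gender", "centre", "edss_band"]
# patient-level fixed parameters: intercept, arm, and the four covariates
_N_BETWEEN_PATIENT_PARAMS = 6


def _arm_inference(est: float, se: float, n_patients: int) -> tuple[tuple[float, float], float]:
    """Wald CI and two-sided p for the adjusted treatment difference.

    Normal approximation throughout: unit counts are large, and the random
    intercepts shared between timepoints are absorbed by the baseline
    adjustment, so residual information is unit- rather than patient-limited.
    """
    if se > 0:
        q = float(stats.norm.ppf(0.975))
        return (est - q * se, est + q * se), float(2 * stats.norm.sf(abs(est) / se))
    return (est, est), float("nan")


@dataclass
class EffectEstimate:
    """Adjusted active-placebo difference for one (sub)group of units."""

    subgroup_label: object
    adjusted_difference: float
    ci95: tuple[float, float]
    p_value: float
    n_active: int
    n_placebo: int
    unadjusted: pd.DataFrame | None = None  # per-arm mean (SD) change
    model_note: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if np.isfinite(lo) and np.isfinite(hi) and not (lo <= self.adjusted_difference <= hi):
            raise ValueError("CI does not bracket the estimate")


@dataclass
class InteractionResult:
    factor: str
    p_interaction: float
    estimates: list[EffectEstimate] = field(default_factory=list)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    if table.empty:
        raise ValueError("empty unit table")
    arms = set(table["arm"].unique())
    if arms - {"active", "placebo"}:
        raise ValueError(f"unknown arm labels: {arms}")
    if len(arms) < 2:
        raise ValueError("single-arm table: both arms are required to estimate a difference")
    for arm in ("active", "placebo"):
        if table.loc[table["arm"] == arm, "patient_id"].nunique() < 2:
            raise ValueError(f"need >= 2 patients in the {arm} arm")
    table["arm_active"] = (table["arm"] == "active").astype(float)
    return table


def _identifiable_covariates(table: pd.DataFrame) -> list[str]:
    """Covariates to adjust for, dropping any that make the arm effect unidentifiable.

    In very small simulated cohorts a binary covariate can perfectly separate
    the arms (every treated patient male, say); adjusting for it then leaves
    the treatment effect with no independent information.  Such covariates
    are removed with a logged note -- the estimate stays unbiased because the
    covariates are balanced by design.
    """
    pat = table.drop_duplicates("patient_id")
    arm = (pat["arm"] == "active").to_numpy(float)

    def arm_in_span(cols: list[str]) -> bool:
        X = np.column_stack([np.ones(len(pat))] + [pat[c].to_numpy(float) for c in cols])
        return np.linalg.matrix_rank(np.column_stack([X, arm])) == np.linalg.matrix_rank(X)

    kept = list(COVARIATES)
    while kept and arm_in_span(kept):
        for c in list(kept):
            if not arm_in_span([k for k in kept if k != c]):
                kept.remove(c)
                logger.warning("covariate %r perfectly predicts arm in this table; dropped from adjustment", c)
                break
        else:  # no single removal frees the arm column; shed one and retry
            dropped = kept.pop()
            logger.warning("covariate %r dropped to identify the arm effect", dropped)
    return kept


def _needs_lesion_re(table: pd.DataFrame) -> bool:
    if "lesion_id" not in table.columns or table["lesion_id"].isna().all():
        return False
    level = table["level"].iloc[0] if "level" in table.columns else None
    if level == "lesion":
        return False
    return bool((table.groupby("lesion_id").size() > 1).any())


def _fit_fixed_effects(
    table: pd.DataFrame, formula: str, nested: bool, use_reml: bool = True
) -> tuple[pd.Series, pd.DataFrame, str]:
    """Fit the model, returning fixed-effect estimates, their covariance, and a note.

    Fallback chain: MixedLM REML -> MixedLM ML -> drop the lesion variance
    component -> OLS.  A numerically perfect OLS fit (noise-free synthetic
    data) short-circuits to exact OLS estimates with zero-width intervals.
    """
    # centring the outcome and baseline improves optimiser conditioning and
    # leaves every arm contrast untouched
    table = table.copy()
    table["baseline"] = table["baseline"] - table["baseline"].mean()
    table["followup"] = table["followup"] - table["followup"].mean()

    ols = smf.ols(formula, data=table).fit()
    resid_var = float(np.var(ols.resid))
    scale_ref = max(float(np.var(table["followup"])), 1.0)
    if resid_var <= 1e-12 * scale_ref:
        cov = pd.DataFrame(
            np.zeros((len(ols.params), len(ols.params))),
            index=ols.params.index,
            columns=ols.params.index,
        )
        return ols.params, cov, "exact fit (zero residual variance); OLS"

    attempts: list[tuple[str, dict]] = []
    if nested:
        attempts.append(("MixedLM REML, patient + lesion intercepts", {"reml": True, "vc": True}))
        attempts.append(("MixedLM ML, patient + lesion intercepts", {"reml": False, "vc": True}))
    attempts.append(("MixedLM REML, patient intercept", {"reml": True, "vc": False}))
    attempts.append(("MixedLM ML, patient intercept", {"reml": False, "vc": False}))
    if not use_reml:
        attempts = [(n.replace("REML", "ML"), {**kw, "reml": False}) for n, kw in attempts]

    for note, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    formula,
                    data=table,
                    groups=table["patient_id"],
                    re_formula="1",
                    vc_formula={"lesion": "0 + C(lesion_id)"} if kw["vc"] else None,
                )
                res = model.fit(reml=kw["reml"], method=["lbfgs", "bfgs"])
            fe = res.fe_params
            cov = res.cov_params().loc[fe.index, fe.index]
            if not np.isfinite(cov.to_numpy()).all() or (np.diag(cov.to_numpy()) <= 0).any():
                raise np.linalg.LinAlgError("degenerate fixed-effect covariance")
            if not res.converged:
                raise RuntimeError("optimizer did not converge")
            boundary = float(res.cov_re.iloc[0, 0]) <= 1e-8 * res.scale
            if boundary and kw["vc"]:
                logger.info("patient variance at boundary; estimates from %s retained", note)
            return fe, cov, note
        except Exception as err:  # noqa: BLE001 - each failure falls through, logged
            logger.info("model fit failed (%s): %s; falling back", note, err)

    # a singular Hessian almost always means the patient variance collapsed
    # to the boundary; the reduced model with no random intercept is OLS
    logger.info("variance components at boundary or mixed fits failed; reduced model = OLS")
    return ols.params, pd.DataFrame(
        ols.cov_params(), index=ols.params.index, columns=ols.params.index
    ), "OLS (reduced model: random-intercept variance at boundary)"


def summarise_unadjusted(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Per-arm (and optional subgroup) mean (SD) change with unit counts."""
    table = table.copy()
    table["change"] = table["followup"] - table["baseline"]
    keys = ["arm"] + (by or [])
    out = (
        table.groupby(keys, observed=True)["change"]
        .agg(n="size", mean_change="mean", sd_change=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def fit_adjusted_difference(
    table: pd.DataFrame, use_reml: bool = True, include_lesion_re: bool | None = None
) -> EffectEstimate:
    """Adjusted active-placebo difference over all units of one table."""
    table = _validate(table)
    nested = _needs_lesion_re(table) if include_lesion_re is None else include_lesion_re
    covars = _identifiable_covariates(table)
    formula = "followup ~ arm_active + baseline" + "".join(f" + {c}" for c in covars)
    fe, cov, note = _fit_fixed_effects(table, formula, nested, use_reml)
    if len(covars) < len(COVARIATES):
        note += f"; adjusted for {covars} only (arm identifiability)"

    est = float(fe["arm_active"])
    se = float(np.sqrt(cov.loc["arm_active", "arm_active"]))
    ci, p = _arm_inference(est, se, table["patient_id"].nunique())
    return EffectEstimate(
        subgroup_label=None,
        adjusted_difference=est,
        ci95=ci,
        p_value=p,
        n_active=int((table["arm"] == "active").sum()),
        n_placebo=int((table["arm"] == "placebo").sum()),
        unadjusted=summarise_unadjusted(table),
        model_note=note,
    )


def fit_subgroup_interaction(
    table: pd.DataFrame, factor: str, use_reml: bool = True, include_lesion_re: bool | None = None
) -> InteractionResult:
    """Per-subgroup adjusted differences plus the joint equality (interaction) test."""
    table = _validate(table)
    table = table[table[factor].notna() & (table[factor] != 0)].copy()
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 subgroups of {factor!r}; got {levels}")
    table["_sub"] = pd.Categorical(table[factor], categories=levels)
    nested = _needs_lesion_re(table) if include_lesion_re is None else include_lesion_re

    covars = _identifiable_covariates(table)
    formula = (
        "followup ~ baseline" + "".join(f" + {c}" for c in covars) + " + C(_sub) + C(_sub):arm_active"
    )
    fe, cov, note = _fit_fixed_effects(table, formula, nested, use_reml)
    if len(covars) < len(COVARIATES):
        note += f"; adjusted for {covars} only (arm identifiability)"

    names = [f"C(_sub)[{lev}]:arm_active" for lev in levels]
    missing = [n for n in names if n not in fe.index]
    if missing:
        raise RuntimeError(f"interaction coefficients missing from design: {missing}")

    unadj = summarise_unadjusted(table, by=[factor])
    estimates = []
    one_armed = []
    for lev, name in zip(levels, names):
        est = float(fe[name])
        se = float(np.sqrt(cov.loc[name, name]))
        sub = table[table[factor] == lev]
        n_a = int((sub["arm"] == "active").sum())
        n_p = int((sub["arm"] == "placebo").sum())
        flag = "" if (n_a and n_p) else "single-arm subgroup"
        if flag:
            one_armed.append(name)
        ci, p = _arm_inference(est, se, table["patient_id"].nunique())
        estimates.append(
            EffectEstimate(
                subgroup_label=lev,
                adjusted_difference=est,
                ci95=ci,
                p_value=p,
                n_active=n_a,
                n_placebo=n_p,
                unadjusted=unadj[unadj[factor] == lev],
                model_note=flag or note,
            )
        )

    # joint Wald test that all estimable arm-within-subgroup effects are equal
    test_names = [n for n in names if n not in one_armed]
    p_int = float("nan")
    if len(test_names) >= 2:
        L = np.zeros((len(test_names) - 1, len(fe)))
        cols = {n: i for i, n in enumerate(fe.index)}
        for row, name in enumerate(test_names[1:]):
            L[row, cols[test_names[0]]] = -1.0
            L[row, cols[name]] = 1.0
        c = L @ fe.to_numpy()
        V = L @ cov.to_numpy() @ L.T
        try:
            chi2 = float(c @ np.linalg.solve(V, c))
            p_int = float(stats.chi2.sf(chi2, df=len(test_names) - 1))
        except np.linalg.LinAlgError:
            logger.warning("singular covariance in interaction test; p left undefined")
    return InteractionResult(factor=factor, p_interaction=p_int, estimates=estimates)


# ---------------------------------------------------------------------------
# the full Tables 1-3 style analysis grid


def _enough(table: pd.DataFrame, min_per_arm: int = 3) -> bool:
    if table.empty:
        return False
    counts = table.groupby("arm").size()
    pat = table.groupby("arm")["patient_id"].nunique()
    return (
        counts.get("active", 0) >= min_per_arm
        and counts.get("placebo", 0) >= min_per_arm
        and pat.get("active", 0) >= 2
        and pat.get("placebo", 0) >= 2
    )


def _subsample(table: pd.DataFrame, cap: int, rng: np.random.Generator) -> pd.DataFrame:
    if cap and len(table) > cap:
        idx = rng.choice(len(table), size=cap, replace=False)
        return table.iloc[np.sort(idx)]
    return table


def run_analysis_suite(
    tables: dict,
    use_reml: bool = True,
    voxel_subsample_cap: int = 4000,
    seed: int = 0,
    min_per_arm: int = 3,
) -> pd.DataFrame:
    """Run the full analysis grid over lesion, component, segment, and voxel tables.

    Mirrors the report structure of a remyelination trial readout: whole
    lesions by tissue with baseline-MTR / baseline-T1 / size strata and
    distance band; core/rim/cuff components by tissue; MTR- and T1-defined
    segments by tissue; voxels by tissue with quartile and band subgroups.
    Strata with insufficient units are skipped and listed in the ``note``
    column of a skip row.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def record(level, tissue, factor, est: EffectEstimate, p_int=np.nan, variable=""):
        unadj = est.unadjusted
        arm_stats = {}
        if unadj is not None:
            for arm in ("active", "placebo"):
                sel = unadj[unadj["arm"] == arm]
                arm_stats[f"mean_change_{arm}"] = float(sel["mean_change"].iloc[0]) if len(sel) else np.nan
                arm_stats[f"sd_change_{arm}"] = float(sel["sd_change"].iloc[0]) if len(sel) else np.nan
        rows.append(
            {
                "level": level,
                "tissue": tissue,
                "variable": variable,
                "factor": factor,
                "subgroup": est.subgroup_label,
                "n_active": est.n_active,
                "n_placebo": est.n_placebo,
                **arm_stats,
                "adjusted_difference": est.adjusted_difference,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "p_value": est.p_value,
                "p_interaction": p_int,
                "note": est.model_note,
            }
        )

    def skip(level, tissue, factor, reason, variable=""):
        rows.append(
            {
                "level": level,
                "tissue": tissue,
                "variable": variable,
                "factor": factor,
                "subgroup": None,
                "n_active": 0,
                "n_placebo": 0,
                "adjusted_difference": np.nan,
                "ci_lo": np.nan,
                "ci_hi": np.nan,
                "p_value": np.nan,
                "p_interaction": np.nan,
                "note": f"skipped: {reason}",
            }
        )

    def run_block(table, level, tissue, factor=None, variable="", cap=0):
        if not _enough(table, min_per_arm):
            skip(level, tissue, factor or "overall", "insufficient units", variable)
            return
        sub = _subsample(table, cap, rng)
        try:
            if factor is None:
                est = fit_adjusted_difference(sub, use_reml)
                record(level, tissue, "overall", est, variable=variable)
            else:
                res = fit_subgroup_interaction(sub, factor, use_reml)
                for est in res.estimates:
                    record(level, tissue, factor, est, p_int=res.p_interaction, variable=variable)
        except (ValueError, RuntimeError) as err:
            skip(level, tissue, factor or "overall", str(err), variable)

    tissues = ("pure-WM", "pure-CGM", "pure-DGM")

    lesion = tables.get("lesion", pd.DataFrame())
    for tissue in tissues:
        t = lesion[lesion["tissue_class"] == tissue] if not lesion.empty else pd.DataFrame()
        run_block(t, "lesion", tissue)
        for factor, variable in (
            ("mtr_stratum", "baseline-MTR"),
            ("t1_stratum", "baseline-T1"),
            ("size_stratum", "size"),
            ("band", "band"),
        ):
            if t.empty or factor not in t.columns:
                skip("lesion", tissue, factor, "insufficient units", variable)
                continue
            run_block(t[t[factor].notna()], "lesion", tissue, factor, variable)

    component = tables.get("component", pd.DataFrame())
    for tissue in tissues:
        t = component[component["tissue_class"] == tissue] if not component.empty else pd.DataFrame()
        run_block(t, "component", tissue, "role", "component")

    segment = tables.get("segment", pd.DataFrame())
    for tissue in tissues:
        for variable in ("baseline-MTR", "baseline-T1"):
            t = (
                segment[(segment["tissue_class"] == tissue) & (segment["variable"] == variable)]
                if not segment.empty
                else pd.DataFrame()
            )
            run_block(t, "segment", tissue, "stratum", variable)

    voxel = tables.get("voxel", pd.DataFrame())
    for tissue in tissues:
        t = voxel[voxel["tissue_class"] == tissue] if not voxel.empty else pd.DataFrame()
        run_block(t, "voxel", tissue, cap=voxel_subsample_cap)
        for factor, variable in (
            ("mtr_quartile", "baseline-MTR"),
            ("t1_quartile", "baseline-T1"),
            ("band", "band"),
        ):
            run_block(t, "voxel", tissue, factor, variable, cap=voxel_subsample_cap)

    return pd.DataFrame(rows)
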