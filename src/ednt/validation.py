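"""Monte-Carlo validation harnesses: parameter recovery and calibration.

These run the *entire* pipeline — schedule, trial simulation,
classification, RT filtering, scoring, regression — on cohorts with
known population parameters, so that coverage, bias and type-I error of
the end-to-end analysis can be measured rather than assumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .effects import cohort_effects
from .inference import empty_model, fit_nested_models
from .preprocess import preprocess
from .simulate import CohortParams, PopulationEffect, simulate_study


def run_cohort_replicate(
    cohort: CohortParams,
    seed: int,
    fit_model3: bool = False,
    alpha: float = 0.05,
) -> dict:
    """One end-to-end replicate; returns summary statistics.

    The replicate simulates a study, preprocesses it with the default
    switches, scores effects, and reports the empty-model mean/CI and
    two-tailed one-sample p for PES and DD (and, optionally, the model-3
    sex x age interaction estimate for DD).
    """
    study = simulate_study(cohort, seed=seed)
    variant = "child" if cohort.group == "child" else "adult"
    classified, screening = preprocess(study.trials, study.schedule, variant)
    included = set(screening.loc[screening["included"], "subject_id"])
    effects = cohort_effects(classified[classified["subject_id"].isin(included)])
    table = effects.merge(study.subjects, on="subject_id", how="left")

    out: dict = {"n_included": len(included)}
    tcrit = None
    for name, col in (("pes", "pes_ms"), ("dd", "dd_ms")):
        res = empty_model(table[col])
        tcrit = sps.t.ppf(1 - alpha / 2, res["df"])
        out[f"{name}_mean"] = res["intercept"]
        out[f"{name}_ci_lo"] = res["intercept"] - tcrit * res["se"]
        out[f"{name}_ci_hi"] = res["intercept"] + tcrit * res["se"]
        out[f"{name}_p"] = res["p"]
        out[f"{name}_n"] = res["n"]
    if fit_model3:
        fits = fit_nested_models(table, "DD", include_sex=True)
        fit3 = fits[-1]
        out["dd_interaction_est"] = float(fit3.params["sex_x_age"])
        out["dd_interaction_se"] = float(fit3.bse["sex_x_age"])
        margin = sps.t.ppf(1 - alpha / 2, fit3.df_resid) * out["dd_interaction_se"]
        out["dd_interaction_ci_lo"] = out["dd_interaction_est"] - margin
        out["dd_interaction_ci_hi"] = out["dd_interaction_est"] + margin
    return out


def recovery_study(
    n_replicates: int,
    seed: int,
    cohort: CohortParams | None = None,
    fit_model3: bool = False,
) -> pd.DataFrame:
    """Replicate table for a recovery/calibration study.

    The default cohort carries no covariate structure: n=154 children
    with true PES ~ N(238, 374^2) and true DD ~ N(58, 185^2) ms — the
    child-sample effect scale — so the population grand means are the
    coverage targets.
    """
    if cohort is None:
        cohort = recovery_cohort_params()
    seeds = np.random.default_rng(seed).integers(2**31, size=n_replicates)
    rows = [
        run_cohort_replicate(cohort, int(s), fit_model3=fit_model3) for s in seeds
    ]
    return pd.DataFrame(rows)


def recovery_cohort_params(
    n_subjects: int = 154,
    pes_mean: float = 238.0,
    pes_sd: float = 374.0,
    dd_mean: float = 58.0,
    dd_sd: float = 185.0,
    dd_sex_by_age: float = 0.0,
) -> CohortParams:
    """Child-scale cohort with flat covariate structure (coverage target
    = the population grand mean)."""
    return CohortParams(
        n_subjects=n_subjects,
        pes_population=PopulationEffect(pes_mean, pes_sd),
        dd_population=PopulationEffect(dd_mean, dd_sd, sex_by_age_coef_ms=dd_sex_by_age),
    )


def null_cohort_params(n_subjects: int = 154) -> CohortParams:
    """Cohort with all true effects identically zero (type-I calibration)."""
    return CohortParams(
        n_subjects=n_subjects,
        pes_population=PopulationEffect(0.0, 0.0),
        dd_population=PopulationEffect(0.0, 0.0),
    )


def coverage(replicates: pd.DataFrame, effect: str, truth: float) -> float:
    """Share of replicates whose empty-model 95% CI covers ``truth``."""
    lo = replicates[f"{effect}_ci_lo"]
    hi = replicates[f"{effect}_ci_hi"]
    return float(((lo <= truth) & (truth <= hi)).mean())


def rejection_rate(replicates: pd.DataFrame, effect: str, alpha: float = 0.05) -> float:
    """Share of replicates whose empty-model test rejects at ``alpha``."""
    return float((replicates[f"{effect}_p"] < alpha).mean())
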