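"""End-to-end orchestration: simulate/load -> preprocess -> score -> model.

A :class:`PipelineConfig` fully determines a run: the task variant, every
seed, the preprocessing switches and the modeling options.  Identical
configs (and inputs) produce identical outputs, and every exclusion or
filter decision is counted in the report metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ednt_io
from .effects import cohort_effects, reliability, split_half_effects
from .inference import (
    correlation_matrix,
    empty_model,
    fit_nested_models,
    johnson_neyman,
    simple_slopes,
)
from .preprocess import preprocess
from .schedule import get_variant
from .simulate import CohortParams, mother_cohort_params, simulate_study


@dataclass
class PipelineConfig:
    variant: str = "child"
    simulate: bool = True
    seed: int = 0
    n_subjects: int | None = None
    forbid_repeat_nogo: bool = True
    pe_lookback_across_blocks: bool = False
    sd_rule_scope: str = "all_blocks"  # or "post_block1"
    two_sided_sd: bool = False
    standardize_props: bool = False  # default: center only
    ros_alpha: float = 0.05
    trials_path: str | None = None
    subjects_path: str | None = None
    schedule_path: str | None = None
    out_dir: str = "ednt_report"
    cohort_overrides: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _cohort_params(config: PipelineConfig) -> CohortParams:
    base = CohortParams() if config.variant == "child" else mother_cohort_params()
    if config.n_subjects is not None:
        base.n_subjects = config.n_subjects
    for key, value in config.cohort_overrides.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown cohort parameter {key!r}")
        setattr(base, key, value)
    return base


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write the report bundle; return the tables."""
    variant = get_variant(config.variant)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        study = simulate_study(
            _cohort_params(config),
            variant,
            seed=config.seed,
            forbid_repeat_nogo=config.forbid_repeat_nogo,
        )
        trials, subjects, schedule = study.trials, study.subjects, study.schedule
        study.truth.to_csv(out / "truth.csv", index=False)
    else:
        if not (config.trials_path and config.subjects_path):
            raise ValueError("non-simulated runs require trials_path and subjects_path")
        trials = ednt_io.read_trials(config.trials_path)
        subjects = ednt_io.read_subjects(config.subjects_path)
        schedule = (
            ednt_io.read_schedule(config.schedule_path) if config.schedule_path else None
        )

    classified, screening = preprocess(
        trials,
        schedule,
        variant,
        pe_lookback_across_blocks=config.pe_lookback_across_blocks,
        sd_scope=config.sd_rule_scope,
        two_sided_sd=config.two_sided_sd,
    )
    included = set(screening.loc[screening["included"], "subject_id"])
    kept_classified = classified[classified["subject_id"].isin(included)]

    effects = cohort_effects(kept_classified)
    cohort = effects.merge(subjects, on="subject_id", how="left")

    half_a, half_b = split_half_effects(kept_classified)
    rel = pd.DataFrame(
        [vars(reliability(half_a, half_b, eff)) for eff in ("PES", "DD")]
    )

    corr_cols = [c for c in ("sex", "age_months", "raven_raw", "pi_prop", "pe_prop",
                             "mean_rt_ms", "dd_ms", "pes_ms") if c in cohort.columns]
    corr = correlation_matrix(cohort, corr_cols)

    include_sex = variant.name == "child"
    model_frames, comparison_rows, empties = [], [], {}
    ros_payload: dict = {}
    slopes = None
    for outcome in ("PES", "DD"):
        ycol = {"PES": "pes_ms", "DD": "dd_ms"}[outcome]
        empties[outcome] = empty_model(cohort[ycol])
        fits = fit_nested_models(
            cohort, outcome, include_sex=include_sex,
            standardize_props=config.standardize_props,
        )
        for fit in fits:
            model_frames.append(fit.summary_frame())
            comparison_rows.append(
                {
                    "outcome": outcome,
                    "model_id": fit.model_id,
                    "n": fit.n,
                    "r2_adj": fit.rsquared_adj,
                    "delta_r2": fit.delta_r2,
                    "delta_f": fit.delta_f,
                    "delta_f_df1": fit.delta_f_df[0] if fit.delta_f_df else None,
                    "delta_f_df2": fit.delta_f_df[1] if fit.delta_f_df else None,
                    "delta_f_p": fit.delta_f_p,
                }
            )
        if outcome == "DD" and include_sex:
            fit3 = fits[-1]
            slopes = simple_slopes(fit3)
            modeled = cohort.dropna(subset=[ycol, "age_months", "raven_raw", "sex"])
            mean_m = float(modeled["age_months"].mean())
            sd_m = float(modeled["age_months"].std(ddof=1))
            rng_m = (float(modeled["age_months"].min()), float(modeled["age_months"].max()))
            for sex in (0, 1):
                ros = johnson_neyman(
                    fit3, sex, mean_m, sd_m, rng_m, alpha=config.ros_alpha
                )
                payload = vars(ros).copy()
                if ros.boundary_age_months is not None:
                    payload["boundary_age"] = ednt_io.format_age_months(
                        round(ros.boundary_age_months)
                    )
                ros_payload[ros.sex_group] = payload

    models = pd.concat(model_frames, ignore_index=True)
    comparisons = pd.DataFrame(comparison_rows)

    # --- write bundle ---
    ednt_io.write_trials(out / "trials.csv", trials)
    subjects.to_csv(out / "subjects.csv", index=False)
    if schedule is not None:
        schedule.to_csv(out / "schedule.csv", index=False)
    classified.to_csv(out / "classified_trials.csv", index=False)
    screening.to_csv(out / "screening.csv", index=False)
    effects.to_csv(out / "effects.csv", index=False)
    rel.to_csv(out / "reliability.csv", index=False)
    corr["r"].to_csv(out / "correlations_r.csv")
    corr["p_adj"].to_csv(out / "correlations_p_adj.csv")
    models.to_csv(out / "models.csv", index=False)
    comparisons.to_csv(out / "model_comparison.csv", index=False)
    if slopes is not None:
        slopes.to_csv(out / "simple_slopes.csv", index=False)
    (out / "ros.json").write_text(json.dumps(ros_payload, indent=2, default=str))

    drop_counts = classified["drop_reason"].value_counts().to_dict()
    metadata = {
        "config": asdict(config),
        "n_subjects_input": int(trials["subject_id"].nunique()),
        "n_subjects_included": len(included),
        "exclusions": screening.loc[~screening["included"], "reason"]
        .value_counts()
        .to_dict(),
        "drop_reason_counts": {k: int(v) for k, v in drop_counts.items()},
        "empty_models": empties,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, default=float))

    return {
        "trials": trials,
        "subjects": subjects,
        "schedule": schedule,
        "classified": classified,
        "screening": screening,
        "effects": effects,
        "cohort": cohort,
        "reliability": rel,
        "correlations": corr,
        "models": models,
        "comparisons": comparisons,
        "simple_slopes": slopes,
        "ros": ros_payload,
        "empty_models": empties,
    }
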