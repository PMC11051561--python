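"""Synthetic EDNT cohorts with known reactive/proactive control parameters.

The generator is the package's test bed: each simulated subject carries a
*true* post-error slowing (PES) and delayed disinhibition (DD) effect in
milliseconds, injected additively into Go reaction times, so that the
downstream classification/scoring pipeline can be validated by parameter
recovery.  Population defaults are calibrated to the child and mother
samples this analysis targets (n=155 children aged 43-70 months, ~51%
boys, grand PES ~238 ms, grand DD ~58 ms with large between-child spread;
adult effects 40-50% smaller with far less spread).

Generative model, per subject i with sex s_i (0=male, 1=female) and
within-cohort standardized age z_i:

    true_pes_i = m_pes + a_pes s_i + b_pes z_i + c_pes s_i z_i + e_i
    true_dd_i  = m_dd  + a_dd  s_i + b_dd  z_i + c_dd  s_i z_i + u_i

with e, u independent centered Gaussians.  Raven raw scores are linked to
age by a linear-Gaussian draw calibrated to a target correlation.  Errors
are trialwise-independent Bernoulli events (Go errors split between wrong
key and omission; NoGo false alarms), and Go RTs are

    rt = base_rt + true_pes * [previous trial in block was an error]
               + true_dd  * [stimulus was the previous block's NoGo rule]
               + congruency_cost * [incongruent block] + noise

truncated into (150 ms, deadline].  Noise is lognormal with matched
mean/SD by default (RT distributions are right-skewed); a normal family
is available for algebraic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schedule import (
    ADULT,
    CHILD,
    BlockSchedule,
    N_TRIALS_PER_BLOCK,
    StimulusSpec,
    TaskVariant,
    build_schedule,
    get_variant,
    schedule_to_frame,
)

PE, NPE = "PE", "NPE"
PI, NPI, NOT_APPLICABLE = "PI", "NPI", "not_applicable"


@dataclass
class PopulationEffect:
    """Population law of one true effect (all units: ms)."""

    mean_ms: float
    sd_ms: float
    sex_coef_ms: float = 0.0
    age_coef_ms: float = 0.0
    sex_by_age_coef_ms: float = 0.0


@dataclass
class BetaRate:
    """Beta-distributed per-subject probability with given mean/concentration."""

    mean: float
    concentration: float = 10.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean probability must lie in [0, 1]")
        if self.mean in (0.0, 1.0):
            return np.full(n, self.mean)
        a = self.mean * self.concentration
        b = (1.0 - self.mean) * self.concentration
        return rng.beta(a, b, size=n)


@dataclass
class CohortParams:
    """Population-level description of a simulated sample."""

    n_subjects: int = 155
    group: str = "child"  # "child" or "mother"
    sex_ratio_male: float = 0.51
    age_range_months: tuple[int, int] = (43, 70)
    pes_population: PopulationEffect = field(
        default_factory=lambda: PopulationEffect(216.7, 374.0, 47.6, 32.6, 0.0)
    )
    dd_population: PopulationEffect = field(
        default_factory=lambda: PopulationEffect(22.9, 185.0, 75.9, -8.4, 62.6)
    )
    raven_mean: float = 18.6
    raven_sd: float = 4.5
    raven_age_correlation: float = 0.37
    base_rt_mean_ms: float = 1676.0
    base_rt_sd_ms: float = 305.0
    rt_noise_sd_ms: float = 700.0
    go_error_rate: BetaRate = field(default_factory=lambda: BetaRate(0.10, 10.0))
    nogo_false_alarm_rate: BetaRate = field(default_factory=lambda: BetaRate(0.35, 10.0))
    rt_family: str = "lognormal"  # or "normal"
    congruency_cost_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(self.raven_age_correlation) >= 1.0:
            raise ValueError("raven_age_correlation must satisfy |r| < 1")
        if self.rt_family not in ("lognormal", "normal"):
            raise ValueError("rt_family must be 'lognormal' or 'normal'")
        if self.age_range_months[0] > self.age_range_months[1]:
            raise ValueError("age_range_months must be (low, high)")


def mother_cohort_params(n_subjects: int = 174) -> CohortParams:
    """Defaults matching the adult (mothers) sample scale."""
    return CohortParams(
        n_subjects=n_subjects,
        group="mother",
        sex_ratio_male=0.0,
        age_range_months=(340, 618),
        pes_population=PopulationEffect(138.0, 88.7, 0.0, -4.2, 0.0),
        dd_population=PopulationEffect(33.3, 47.3, 0.0, -2.6, 0.0),
        raven_mean=18.2,
        raven_sd=6.2,
        raven_age_correlation=-0.10,
        base_rt_mean_ms=690.0,
        base_rt_sd_ms=118.0,
        rt_noise_sd_ms=280.0,
        go_error_rate=BetaRate(0.06, 20.0),
        nogo_false_alarm_rate=BetaRate(0.36, 20.0),
    )


@dataclass
class SubjectParams:
    """Per-subject generative parameters ("truth" for recovery tests)."""

    subject_id: str
    group: str
    sex: int
    age_months: int
    raven_raw: int
    base_rt_ms: float
    rt_noise_sd_ms: float
    true_pes_ms: float
    true_dd_ms: float
    p_go_error: float
    p_nogo_false_alarm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_go_error <= 1.0 and 0.0 <= self.p_nogo_false_alarm <= 1.0):
            raise ValueError("error probabilities must lie in [0, 1]")
        if self.base_rt_ms <= 150:
            raise ValueError("base_rt_ms must exceed the 150 ms perceptual floor")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def draw_cohort(params: CohortParams, seed: int) -> list[SubjectParams]:
    """Draw per-subject true parameters for one cohort.

    Age is uniform over the month range; Raven raw scores follow a
    linear-Gaussian link to standardized age with the requested
    correlation (then rounded/clipped to the 0-36 score range).
    """
    rng = np.random.default_rng(seed)
    n = params.n_subjects
    sex = (rng.random(n) >= params.sex_ratio_male).astype(int)  # 1 = female
    lo, hi = params.age_range_months
    age = rng.integers(lo, hi + 1, size=n)
    age_z = _zscore(age.astype(float))

    r = params.raven_age_correlation
    raven_z = r * age_z + np.sqrt(1 - r * r) * rng.standard_normal(n)
    raven = np.clip(np.rint(params.raven_mean + params.raven_sd * raven_z), 0, 36).astype(int)

    def effect(pop: PopulationEffect) -> np.ndarray:
        return (
            pop.mean_ms
            + pop.sex_coef_ms * sex
            + pop.age_coef_ms * age_z
            + pop.sex_by_age_coef_ms * sex * age_z
            + pop.sd_ms * rng.standard_normal(n)
        )

    true_pes = effect(params.pes_population)
    true_dd = effect(params.dd_population)
    base_rt = np.maximum(
        params.base_rt_mean_ms + params.base_rt_sd_ms * rng.standard_normal(n), 300.0
    )
    p_go = params.go_error_rate.draw(rng, n)
    p_fa = params.nogo_false_alarm_rate.draw(rng, n)

    width = len(str(n))
    return [
        SubjectParams(
            subject_id=f"S{i + 1:0{width}d}",
            group=params.group,
            sex=int(sex[i]),
            age_months=int(age[i]),
            raven_raw=int(raven[i]),
            base_rt_ms=float(base_rt[i]),
            rt_noise_sd_ms=params.rt_noise_sd_ms,
            true_pes_ms=float(true_pes[i]),
            true_dd_ms=float(true_dd[i]),
            p_go_error=float(p_go[i]),
            p_nogo_false_alarm=float(p_fa[i]),
        )
        for i in range(n)
    ]


def _schedule_arrays(schedule: list[BlockSchedule]):
    """Stack a schedule into flat arrays plus per-block previous-rule PI masks."""
    cats, faces, nogo, blockno, trialno, congr, pi_mask = [], [], [], [], [], [], []
    prev_rule = None
    for blk in schedule:
        for i, (stim, ng) in enumerate(zip(blk.trials, blk.is_nogo), start=1):
            cats.append(stim.category)
            faces.append(stim.face)
            nogo.append(ng)
            blockno.append(blk.block_index)
            trialno.append(i)
            congr.append(blk.congruent)
            if prev_rule is None:
                pi_mask.append(False)
            elif isinstance(prev_rule, StimulusSpec):
                pi_mask.append(stim == prev_rule)
            else:
                pi_mask.append(stim.face == prev_rule)
        prev_rule = blk.nogo_rule
    return (
        np.array(cats),
        np.array(faces),
        np.array(nogo, dtype=bool),
        np.array(blockno),
        np.array(trialno),
        np.array(congr, dtype=bool),
        np.array(pi_mask, dtype=bool),
    )


def _simulate_subject_arrays(
    schedule: list[BlockSchedule],
    sp: SubjectParams,
    seed: int | np.random.Generator,
    variant: TaskVariant,
    rt_family: str,
    congruency_cost_ms: float,
    go_omission_share: float,
) -> dict:
    n_expected = variant.n_blocks * N_TRIALS_PER_BLOCK
    cats, faces, nogo, blockno, trialno, congr, pi_mask = _schedule_arrays(schedule)
    if len(cats) != n_expected:
        raise ValueError(
            f"schedule has {len(cats)} trials; variant {variant.name!r} expects {n_expected}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cats)
    go = ~nogo

    # independent trialwise error process
    go_err = go & (rng.random(n) < sp.p_go_error)
    omission = go_err & (rng.random(n) < go_omission_share)
    false_alarm = nogo & (rng.random(n) < sp.p_nogo_false_alarm)
    error = go_err | false_alarm

    # post-error state: previous trial within the same block was an error
    prev_error = np.zeros(n, dtype=bool)
    prev_error[1:] = error[:-1]
    prev_error[trialno == 1] = False

    responded = (go & ~omission) | false_alarm
    deterministic = (
        sp.base_rt_ms
        + sp.true_pes_ms * prev_error
        + sp.true_dd_ms * pi_mask
        + congruency_cost_ms * (~congr)
    )
    s = sp.rt_noise_sd_ms
    if s > 0:
        z = rng.standard_normal(n)
        if rt_family == "lognormal":
            m = np.maximum(deterministic, 151.0)
            sigma2 = np.log1p((s / m) ** 2)
            rt = np.exp(np.log(m) - sigma2 / 2 + np.sqrt(sigma2) * z)
        elif rt_family == "normal":
            rt = deterministic + s * z
        else:
            raise ValueError("rt_family must be 'lognormal' or 'normal'")
    else:
        rt = deterministic.astype(float)
    rt = np.clip(rt, np.nextafter(150.0, np.inf), variant.response_deadline_ms)
    rt = np.where(responded, rt, np.nan)

    # response keys: congruent mapping is category itself, incongruent flips it
    mapped = np.where(
        congr, cats, np.where(cats == "day", "night", "day")
    )
    other = np.where(mapped == "day", "night", "day")
    key = np.where(responded, np.where(go_err & ~omission, other, mapped), "none")
    correct = np.where(nogo, ~responded, go & responded & ~go_err)

    return {
        "subject_id": np.repeat(sp.subject_id, n),
        "block": blockno,
        "trial_index": trialno,
        "category": cats,
        "face": faces,
        "is_nogo": nogo,
        "congruent_block": congr,
        "responded": responded,
        "response_key": key,
        "rt_ms": rt,
        "correct": correct.astype(bool),
        "true_pe_label": np.where(prev_error, PE, NPE),
        "true_pi_label": np.where(
            go & (blockno >= 2), np.where(pi_mask, PI, NPI), NOT_APPLICABLE
        ),
    }


def simulate_subject(
    schedule: list[BlockSchedule],
    sp: SubjectParams,
    seed: int | np.random.Generator,
    variant: TaskVariant | None = None,
    rt_family: str = "lognormal",
    congruency_cost_ms: float = 0.0,
    go_omission_share: float = 0.5,
) -> pd.DataFrame:
    """Simulate one subject's trial records over a schedule.

    Returns a frame with one row per trial, including ground-truth
    ``true_pe_label`` / ``true_pi_label`` columns emitted directly from
    the generative state, for oracle-equivalence tests against the
    classification stage.
    """
    if variant is None:
        variant = CHILD if sp.group == "child" else ADULT
    return pd.DataFrame(
        _simulate_subject_arrays(
            schedule, sp, seed, variant, rt_family, congruency_cost_ms, go_omission_share
        )
    )


@dataclass
class StudyTables:
    """Output bundle of :func:`simulate_study` (all CSV-ready frames)."""

    trials: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame
    schedule: pd.DataFrame

    def __iter__(self):
        return iter((self.trials, self.subjects, self.truth))


def simulate_study(
    cohort: CohortParams,
    variant: TaskVariant | str | None = None,
    seed: int = 0,
    forbid_repeat_nogo: bool = True,
) -> StudyTables:
    """Simulate a full study: trials, subjects, truth and schedule tables.

    Every subject receives an independently randomized schedule (rule
    assignment and trial order), as in the task itself.  All randomness
    descends from ``seed`` through a spawned seed sequence, so output is
    reproducible bit for bit.
    """
    if variant is None:
        variant = CHILD if cohort.group == "child" else ADULT
    elif isinstance(variant, str):
        variant = get_variant(variant)
    root = np.random.SeedSequence(seed)
    cohort_seed, trial_seed = root.spawn(2)
    subjects = draw_cohort(cohort, np.random.default_rng(cohort_seed))
    child_seqs = trial_seed.spawn(len(subjects))

    trial_chunks: list[dict] = []
    for sp, seq in zip(subjects, child_seqs):
        sched_seed, sim_seed = seq.spawn(2)
        sched = build_schedule(
            variant,
            np.random.default_rng(sched_seed).integers(2**31),
            forbid_repeat_nogo=forbid_repeat_nogo,
        )
        trial_chunks.append(
            _simulate_subject_arrays(
                sched,
                sp,
                np.random.default_rng(sim_seed),
                variant,
                cohort.rt_family,
                cohort.congruency_cost_ms,
                0.5,
            )
        )

    trials = pd.DataFrame(
        {k: np.concatenate([c[k] for c in trial_chunks]) for k in trial_chunks[0]}
    )
    # the schedule table is the stimulus/rule side of the same rows
    schedule = trials[
        ["subject_id", "block", "trial_index", "category", "face", "is_nogo", "congruent_block"]
    ].rename(columns={"trial_index": "trial"})
    truth = pd.DataFrame([asdict(sp) for sp in subjects])
    subjects_table = truth[["subject_id", "group", "sex", "age_months", "raven_raw"]].copy()
    return StudyTables(
        trials=trials,
        subjects=subjects_table,
        truth=truth,
        schedule=schedule,
    )
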