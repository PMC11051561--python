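"""Trial classification, screening and RT filtering.

Two trial taxonomies drive the analysis:

* post-error (PE) vs not-post-error (NPE): a trial is PE when the
  immediately preceding trial was an error — an incorrect Go (wrong key
  or omission) or a responded NoGo.  By default the lookback does not
  cross block boundaries (blocks are separated by instruction screens),
  so the first trial of every block is NPE; a switch allows carryover.
* previously inhibited (PI) vs not (NPI): a Go trial in block b >= 2 is
  PI when its stimulus was covered by block b-1's NoGo rule (face type
  for the child variant, exact stimulus for the adult variant).  The
  congruency of a block never enters this classification.

Effect scoring uses correct Go trials of blocks >= 2 that survive two RT
filters: responses faster than 150 ms (below the perceptual floor) are
removed, then trials slower than the subject's mean + 3 SD (computed over
the correct-Go RTs surviving the first filter) are removed.  The trimming
is upper-tail only and applied in a single pass; labels are fixed by the
raw sequence and never recomputed after filtering.  Subjects whose
correct-Go rate over the whole task is below 50% (chance) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import TaskVariant, get_variant
from .simulate import NOT_APPLICABLE, NPE, NPI, PE, PI

DROP_NONE = "none"
DROP_BLOCK1 = "block1"
DROP_NOT_CORRECT_GO = "not_correct_go"
DROP_RT_BELOW_150 = "rt_below_150"
DROP_RT_ABOVE_3SD = "rt_above_3sd"

RT_FLOOR_MS = 150.0
SD_MULTIPLIER = 3.0
GO_RATE_THRESHOLD = 0.50


@dataclass
class ScreeningResult:
    subject_id: str
    included: bool
    reason: str  # ok | go_accuracy_below_chance | incomplete | no_pe_trials
    correct_go_rate: float
    no_pe_trials: bool = False


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def screen_subject(
    trials: pd.DataFrame,
    n_blocks_expected: int | None = None,
) -> ScreeningResult:
    """Inclusion screening for one subject's raw trials.

    ``correct_go_rate`` is the share of correct responses among all Go
    trials of the whole task.  Exclusion reasons: a rate below 50%
    (chance), or an incomplete task (missing blocks).  A subject with no
    post-error trials anywhere in blocks >= 2 stays included but is
    flagged: their PES is undefined (they drop from PES modeling only).
    """
    _require_columns(trials, ("subject_id", "block", "trial_index", "is_nogo", "correct"), "trials")
    if trials.empty:
        raise ValueError("screen_subject requires a non-empty trial table")
    sid = str(trials["subject_id"].iloc[0])
    go = ~trials["is_nogo"].to_numpy(dtype=bool)
    if not go.any():
        raise ValueError(f"subject {sid} has zero Go trials")
    rate = float(trials.loc[go, "correct"].mean())

    incomplete = n_blocks_expected is not None and (
        trials["block"].nunique() < n_blocks_expected
    )

    # PE trials exist iff some correct Go trial in blocks >= 2 follows an
    # error within its block (pre-RT-filter approximation).
    t = trials.sort_values(["block", "trial_index"])
    err = ~t["correct"].to_numpy(dtype=bool)
    prev_err = np.zeros(len(t), dtype=bool)
    prev_err[1:] = err[:-1]
    prev_err[t["trial_index"].to_numpy() == 1] = False
    is_pe_candidate = (
        prev_err
        & (t["block"].to_numpy() >= 2)
        & ~t["is_nogo"].to_numpy(dtype=bool)
        & t["correct"].to_numpy(dtype=bool)
    )
    no_pe = not bool(is_pe_candidate.any())

    if rate < GO_RATE_THRESHOLD:
        return ScreeningResult(sid, False, "go_accuracy_below_chance", rate, no_pe)
    if incomplete:
        return ScreeningResult(sid, False, "incomplete", rate, no_pe)
    reason = "no_pe_trials" if no_pe else "ok"
    return ScreeningResult(sid, True, reason, rate, no_pe)


def screen_cohort(trials: pd.DataFrame, n_blocks_expected: int | None = None) -> pd.DataFrame:
    """Screening table, one row per subject (vectorized screen_subject)."""
    df = trials.sort_values(["subject_id", "block", "trial_index"]).reset_index(drop=True)
    go = ~df["is_nogo"].to_numpy(dtype=bool)
    correct = df["correct"].to_numpy(dtype=bool)
    sid = df["subject_id"]

    rate = pd.Series(correct[go], index=sid[go]).groupby(level=0).mean()
    blocks = df.groupby("subject_id")["block"].nunique()
    if not rate.index.equals(blocks.index):
        missing = blocks.index.difference(rate.index).tolist()
        raise ValueError(f"subjects with zero Go trials: {missing[:5]}")

    err = ~correct
    prev_err = np.zeros(len(df), dtype=bool)
    prev_err[1:] = err[:-1]
    prev_err[df["trial_index"].to_numpy() == 1] = False
    prev_err[sid.ne(sid.shift(1)).to_numpy()] = False
    pe_candidate = prev_err & (df["block"].to_numpy() >= 2) & go & correct
    has_pe = pd.Series(pe_candidate, index=sid).groupby(level=0).any()

    out = pd.DataFrame(
        {
            "correct_go_rate": rate,
            "no_pe_trials": ~has_pe,
        }
    ).reset_index()
    incomplete = (
        blocks.reindex(out["subject_id"]).to_numpy() < n_blocks_expected
        if n_blocks_expected is not None
        else np.zeros(len(out), dtype=bool)
    )
    below = out["correct_go_rate"].to_numpy() < GO_RATE_THRESHOLD
    out["included"] = ~(below | incomplete)
    out["reason"] = np.select(
        [below, incomplete, out["no_pe_trials"].to_numpy()],
        ["go_accuracy_below_chance", "incomplete", "no_pe_trials"],
        default="ok",
    )
    return out[["subject_id", "included", "reason", "correct_go_rate", "no_pe_trials"]]


def _rules_from_schedule(schedule: pd.DataFrame, variant: TaskVariant) -> pd.DataFrame:
    """Per (subject, block) NoGo rule derived from a schedule table.

    The rule is encoded as (category, face), with category ``"*"`` for a
    face-type rule (child variant, matching both day and night stimuli).
    """
    nogo = schedule[schedule["is_nogo"].astype(bool)]
    g = nogo.groupby(["subject_id", "block"])
    faces = g["face"].agg("nunique")
    if (faces != 1).any():
        bad = faces[faces != 1].index.tolist()[:3]
        raise ValueError(f"ambiguous NoGo rule for {bad}")
    out = g[["category", "face"]].first().rename(
        columns={"category": "rule_category", "face": "rule_face"}
    )
    if variant.nogo_rule_kind == "face":
        out["rule_category"] = "*"
    else:
        cats = g["category"].agg("nunique")
        if (cats != 1).any():
            bad = cats[cats != 1].index.tolist()[:3]
            raise ValueError(f"ambiguous NoGo rule for {bad}")
    return out.reset_index()


def classify_trials(
    trials: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
    variant: TaskVariant | str = "child",
    pe_lookback_across_blocks: bool = False,
) -> pd.DataFrame:
    """Attach PE/NPE and PI/NPI labels plus an initial drop reason.

    ``schedule`` may be omitted when the trial table itself carries the
    ``is_nogo`` flags of a full schedule (the rule of each block is then
    read off the NoGo trials).  PI is defined for Go trials of blocks
    >= 2 only; everything else gets ``not_applicable``.  Labels depend
    only on the raw sequence, never on RT filtering.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    _require_columns(
        trials,
        ("subject_id", "block", "trial_index", "category", "face", "is_nogo", "correct"),
        "trials",
    )
    df = trials.sort_values(["subject_id", "block", "trial_index"]).reset_index(drop=True)

    rule_source = schedule if schedule is not None else df
    if schedule is not None:
        known = set(zip(schedule["subject_id"], schedule["block"]))
        present = set(zip(df["subject_id"], df["block"]))
        orphan = present - known
        if orphan:
            raise ValueError(f"trials reference blocks absent from the schedule: {sorted(orphan)[:3]}")
    rules = _rules_from_schedule(rule_source, variant)
    rules = rules.sort_values(["subject_id", "block"])
    grp = rules.groupby("subject_id")
    rules["prev_rule_category"] = grp["rule_category"].shift(1)
    rules["prev_rule_face"] = grp["rule_face"].shift(1)
    df = df.merge(
        rules[["subject_id", "block", "prev_rule_category", "prev_rule_face"]],
        on=["subject_id", "block"],
        how="left",
    )

    # --- PE / NPE ---
    err = ~df["correct"].to_numpy(dtype=bool)
    prev_err = np.zeros(len(df), dtype=bool)
    prev_err[1:] = err[:-1]
    new_subject = df["subject_id"].ne(df["subject_id"].shift(1)).to_numpy()
    prev_err[new_subject] = False
    if not pe_lookback_across_blocks:
        prev_err[df["trial_index"].to_numpy() == 1] = False
    df["pe_label"] = np.where(prev_err, PE, NPE)

    # --- PI / NPI ---
    go = ~df["is_nogo"].to_numpy(dtype=bool)
    eligible = go & (df["block"].to_numpy() >= 2)
    face_match = df["prev_rule_face"].to_numpy() == df["face"].to_numpy()
    cat = df["prev_rule_category"].to_numpy()
    cat_match = (cat == "*") | (cat == df["category"].to_numpy())
    matches = face_match & cat_match & df["prev_rule_face"].notna().to_numpy()
    df["pi_label"] = np.where(eligible, np.where(matches, PI, NPI), NOT_APPLICABLE)
    df = df.drop(columns=["prev_rule_category", "prev_rule_face"])

    # --- initial drop reason (RT filters fill in the rest) ---
    correct_go = go & df["correct"].to_numpy(dtype=bool)
    reason = np.where(
        df["block"].to_numpy() < 2,
        DROP_BLOCK1,
        np.where(correct_go, DROP_NONE, DROP_NOT_CORRECT_GO),
    )
    df["drop_reason"] = reason
    df["kept"] = False
    return df


def apply_rt_filters(
    classified: pd.DataFrame,
    sd_scope: str = "all_blocks",
    two_sided: bool = False,
) -> pd.DataFrame:
    """Apply the 150 ms floor and the per-subject 3-SD trim; set ``kept``.

    Stage 1 removes correct-Go trials with RT < 150 ms.  Stage 2 computes
    each subject's mean and sample SD (ddof=1) of the surviving
    correct-Go RTs — over all blocks by default, or blocks >= 2 with
    ``sd_scope='post_block1'`` — and removes trials with RT > mean +
    3 SD (and symmetric lower trims when ``two_sided``).  A trial is
    ``kept`` when it is a correct Go trial of block >= 2 passing both
    stages.
    """
    if sd_scope not in ("all_blocks", "post_block1"):
        raise ValueError("sd_scope must be 'all_blocks' or 'post_block1'")
    df = classified.copy()
    rt = df["rt_ms"].to_numpy(dtype=float)
    correct_go = (~df["is_nogo"].to_numpy(dtype=bool)) & df["correct"].to_numpy(dtype=bool)

    fast = correct_go & (rt < RT_FLOOR_MS)
    df.loc[fast & (df["drop_reason"] == DROP_NONE), "drop_reason"] = DROP_RT_BELOW_150
    # block-1 correct-Go trials below the floor also leave the SD statistic
    survivors = correct_go & ~fast
    if sd_scope == "post_block1":
        survivors = survivors & (df["block"].to_numpy() >= 2)

    stats = df.loc[survivors].groupby("subject_id")["rt_ms"].agg(mean="mean", sd="std")
    stats["sd"] = stats["sd"].fillna(0.0)
    upper = df["subject_id"].map(stats["mean"] + SD_MULTIPLIER * stats["sd"])
    slow = survivors & (rt > upper.to_numpy(dtype=float))
    if two_sided:
        lower = df["subject_id"].map(stats["mean"] - SD_MULTIPLIER * stats["sd"])
        slow = slow | (survivors & (rt < lower.to_numpy(dtype=float)))
    df.loc[slow & (df["drop_reason"] == DROP_NONE), "drop_reason"] = DROP_RT_ABOVE_3SD
    # outliers in block 1 keep the block1 reason but still leave the pool

    df["kept"] = (df["drop_reason"] == DROP_NONE) & correct_go & (df["block"] >= 2)
    return df


def condition_proportions(kept: pd.DataFrame) -> pd.DataFrame:
    """Per-subject PE and PI proportions among kept correct-Go trials."""
    kept = kept[kept["kept"]]
    if kept.empty:
        return pd.DataFrame(columns=["subject_id", "pe_prop", "pi_prop", "n_kept"])
    g = kept.groupby("subject_id")
    out = pd.DataFrame(
        {
            "pe_prop": g["pe_label"].agg(lambda s: (s == PE).mean()),
            "pi_prop": g["pi_label"].agg(lambda s: (s == PI).mean()),
            "n_kept": g.size(),
        }
    )
    return out.reset_index()


def preprocess(
    trials: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
    variant: TaskVariant | str = "child",
    pe_lookback_across_blocks: bool = False,
    sd_scope: str = "all_blocks",
    two_sided_sd: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classification + filtering + screening in one call.

    Returns ``(classified, screening)``; ``classified`` keeps every trial
    of every subject (including screened-out ones) with its labels, drop
    reason and ``kept`` flag.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    classified = classify_trials(
        trials, schedule, variant, pe_lookback_across_blocks=pe_lookback_across_blocks
    )
    classified = apply_rt_filters(classified, sd_scope=sd_scope, two_sided=two_sided_sd)
    screening = screen_cohort(trials, n_blocks_expected=variant.n_blocks)
    return classified, screening
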