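"""Per-subject difference scores and split-half reliability.

PES = mean RT over kept PE trials minus mean RT over kept NPE trials;
DD = mean RT over kept PI trials minus mean over kept NPI trials.  Both
are plain differences of grand means per participant, in milliseconds.
An effect is missing (NaN) whenever one of its condition cells is empty
— never coerced to zero.

The odd-even split ranks a subject's kept trials by overall task order
*within each condition cell* (PE, NPE, PI, NPI separately) and assigns
odd ranks to half A and even ranks to half B; this guarantees both
halves contain each condition whenever the cell holds at least two
trials.  Reliability is the raw Pearson correlation of the two halves'
effects across subjects (no Spearman-Brown step-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import NPE, NPI, PE, PI


@dataclass
class SubjectEffects:
    subject_id: str
    pes_ms: float
    dd_ms: float
    mean_rt_ms: float
    pe_prop: float
    pi_prop: float
    n_kept: int


@dataclass
class ReliabilityResult:
    effect: str  # "PES" or "DD"
    r: float
    p: float
    n: int
    note: str = ""


def _cell_means(kept: pd.DataFrame, label_col: str) -> pd.DataFrame:
    return kept.pivot_table(
        index="subject_id", columns=label_col, values="rt_ms", aggfunc="mean"
    )


def _diff(cells: pd.DataFrame, pos: str, neg: str) -> pd.Series:
    a = cells[pos] if pos in cells else pd.Series(np.nan, index=cells.index)
    b = cells[neg] if neg in cells else pd.Series(np.nan, index=cells.index)
    return a - b


def cohort_effects(classified: pd.DataFrame) -> pd.DataFrame:
    """Effects table, one row per subject with any kept trials.

    Input is the classified+filtered trial table; only rows with
    ``kept`` are used (correct Go, blocks >= 2, surviving the RT
    filters).
    """
    kept = classified[classified["kept"]]
    if kept.empty:
        return pd.DataFrame(
            columns=["subject_id", "pes_ms", "dd_ms", "mean_rt_ms", "pe_prop", "pi_prop", "n_kept"]
        )
    pe_cells = _cell_means(kept, "pe_label")
    pi_cells = _cell_means(kept, "pi_label")
    g = kept.groupby("subject_id")
    out = pd.DataFrame(
        {
            "pes_ms": _diff(pe_cells, PE, NPE),
            "dd_ms": _diff(pi_cells, PI, NPI),
            "mean_rt_ms": g["rt_ms"].mean(),
            "pe_prop": g["pe_label"].agg(lambda s: (s == PE).mean()),
            "pi_prop": g["pi_label"].agg(lambda s: (s == PI).mean()),
            "n_kept": g.size(),
        }
    )
    return out.reset_index()


def compute_effects(kept: pd.DataFrame) -> SubjectEffects:
    """Effects for a single subject's kept trials."""
    table = cohort_effects(kept if "kept" in kept else kept.assign(kept=True))
    if len(table) != 1:
        raise ValueError("compute_effects expects the kept trials of exactly one subject")
    row = table.iloc[0]
    return SubjectEffects(
        subject_id=row["subject_id"],
        pes_ms=float(row["pes_ms"]),
        dd_ms=float(row["dd_ms"]),
        mean_rt_ms=float(row["mean_rt_ms"]),
        pe_prop=float(row["pe_prop"]),
        pi_prop=float(row["pi_prop"]),
        n_kept=int(row["n_kept"]),
    )


def split_half_effects(classified: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Odd/even half effects per subject (within-condition parity).

    Returns ``(half_a, half_b)`` frames shaped like :func:`cohort_effects`.
    Trials are ordered by (block, trial_index) within each condition cell
    of each subject; ranks 1,3,5,... go to half A.
    """
    kept = classified[classified["kept"]].sort_values(
        ["subject_id", "block", "trial_index"]
    )
    halves = []
    for parity in (0, 1):  # 0 -> odd ranks (cumcount 0,2,...) -> half A
        sub = kept.copy()
        pe_rank = sub.groupby(["subject_id", "pe_label"]).cumcount()
        pi_rank = sub.groupby(["subject_id", "pi_label"]).cumcount()
        pe_half = sub[pe_rank % 2 == parity]
        pi_half = sub[pi_rank % 2 == parity]
        pe_cells = _cell_means(pe_half, "pe_label")
        pi_cells = _cell_means(pi_half, "pi_label")
        g_all = sub.groupby("subject_id")
        # mean RT / n_kept of each half use the PE-parity split of the stream
        g = pe_half.groupby("subject_id")
        frame = pd.DataFrame(
            {
                "pes_ms": _diff(pe_cells, PE, NPE),
                "dd_ms": _diff(pi_cells, PI, NPI),
                "mean_rt_ms": g["rt_ms"].mean(),
                "n_kept": g.size(),
            }
        ).reindex(g_all.size().index)
        halves.append(frame.reset_index())
    return halves[0], halves[1]


def reliability(half_a: pd.DataFrame, half_b: pd.DataFrame, effect: str) -> ReliabilityResult:
    """Pearson split-half reliability of one effect across subjects."""
    col = {"PES": "pes_ms", "DD": "dd_ms"}[effect]
    merged = half_a[["subject_id", col]].merge(
        half_b[["subject_id", col]], on="subject_id", suffixes=("_a", "_b")
    ).dropna()
    n = len(merged)
    if n < 3:
        return ReliabilityResult(effect, np.nan, np.nan, n, "fewer than 3 complete subjects")
    a = merged[f"{col}_a"].to_numpy()
    b = merged[f"{col}_b"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return ReliabilityResult(effect, np.nan, np.nan, n, "zero variance in a half")
    r, p = sps.pearsonr(a, b)
    return ReliabilityResult(effect, float(r), float(p), n)
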