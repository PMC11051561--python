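"""CSV readers/writers and small format helpers.

Interchange formats (UTF-8 CSV, period decimal separator):

* trials — subject_id, block, trial_index, category, face, is_nogo,
  congruent_block, responded, response_key, rt_ms, correct.  A missing
  response is an empty rt_ms with response_key ``none``.
* subjects — subject_id, group, sex (0 = male, 1 = female), age_months,
  raven_raw, plus optional SES indicator columns.
* schedule — subject_id, block, trial, category, face, is_nogo,
  congruent_block.

Ages are stored in integer months; the years-months strings used in
developmental reporting ("4y-7m") are handled by
:func:`parse_age_string` / :func:`format_age_months`.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd

TRIAL_COLUMNS = (
    "subject_id",
    "block",
    "trial_index",
    "category",
    "face",
    "is_nogo",
    "congruent_block",
    "responded",
    "response_key",
    "rt_ms",
    "correct",
)
SUBJECT_COLUMNS = ("subject_id", "sex", "age_months", "raven_raw")

_AGE_RE = re.compile(r"^\s*(\d+)\s*y(?:ears?)?\s*[-_ ]?\s*(\d+)\s*m(?:onths?)?\s*$", re.I)


def parse_age_string(text: str) -> int:
    """'4y-7m' -> 55 months."""
    m = _AGE_RE.match(str(text))
    if not m:
        raise ValueError(f"cannot parse age string {text!r}; expected like '4y-7m'")
    years, months = int(m.group(1)), int(m.group(2))
    if months >= 12:
        raise ValueError(f"month part must be < 12 in {text!r}")
    return years * 12 + months


def format_age_months(months: int) -> str:
    """55 -> '4y-7m'."""
    months = int(months)
    return f"{months // 12}y-{months % 12}m"


def _check_columns(df: pd.DataFrame, mandatory: tuple[str, ...], path: str) -> None:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS + SUBJECT_COLUMNS
               and not c.startswith(("ses_", "true_", "pe_", "pi_", "drop", "kept", "group"))]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)


def read_trials(path: str) -> pd.DataFrame:
    """Read and validate a trial-level CSV."""
    df = pd.read_csv(path)
    _check_columns(df, ("subject_id", "block", "trial_index", "category", "face",
                        "is_nogo", "rt_ms", "correct"), str(path))
    for col in ("is_nogo", "correct"):
        df[col] = df[col].astype(bool)
    if "responded" in df.columns:
        df["responded"] = df["responded"].astype(bool)
    else:
        df["responded"] = df["rt_ms"].notna()
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    finite = df["rt_ms"].dropna()
    if len(finite) and (finite < 10).all():
        warnings.warn(
            f"{path}: all RTs are below 10 — values look like seconds, but this "
            "reader expects milliseconds; no rescaling was applied",
            stacklevel=2,
        )
    return df


def write_trials(path: str, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_subjects(path: str) -> pd.DataFrame:
    """Read and validate a subject-level covariate CSV."""
    df = pd.read_csv(path)
    _check_columns(df, SUBJECT_COLUMNS, str(path))
    bad = df[~df["sex"].isin([0, 1])]
    if len(bad):
        rows = (bad.index + 2).tolist()[:5]  # 1-based CSV rows incl. header
        raise ValueError(f"{path}: sex must be coded 0 (male) / 1 (female); bad rows {rows}")
    if df["age_months"].dtype == object:
        df["age_months"] = df["age_months"].map(parse_age_string)
    return df


def read_schedule(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("subject_id", "block", "trial", "category", "face", "is_nogo"), str(path))
    df["is_nogo"] = df["is_nogo"].astype(bool)
    return df
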