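"""Delimited-text dataset I/O with schema validation.

A dataset directory holds up to four tables as headered CSV: ``choices``
(trial records), ``judgments`` (line-scale time judgments), ``attention``
(attribute-attention outcomes) and ``truth`` (generator truth, present only
for synthetic cohorts).  Validation reports offending row numbers (0-based,
excluding the header) rather than failing wholesale.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

SS_DELAY_BY_CONDITION = {"immediate": 0.0, "non_immediate": 15.0}

CHOICE_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "block_id",
    "trial_index",
    "ss_amount",
    "ss_delay",
    "ll_amount",
    "ll_delay",
    "choice",
]
JUDGMENT_COLUMNS = ["participant_id", "group", "duration_days", "line_length_cm"]
ATTENTION_COLUMNS = ["participant_id", "group", "first_attention", "majority_attention"]

TABLE_NAMES = ("choices", "judgments", "attention", "truth")


def validate_choices(df: pd.DataFrame) -> None:
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"choices table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("empty choices table")
    problems: list[str] = []
    bad_cond = ~df["condition"].isin(SS_DELAY_BY_CONDITION)
    if bad_cond.any():
        problems.append(f"unknown condition at rows {df.index[bad_cond].tolist()[:10]}")
    expected = df["condition"].map(SS_DELAY_BY_CONDITION)
    mismatch = expected.notna() & (df["ss_delay"].astype(float) != expected)
    if mismatch.any():
        problems.append(
            "ss_delay inconsistent with condition at rows "
            f"{df.index[mismatch].tolist()[:10]}"
        )
    bad_choice = ~df["choice"].isin(["SS", "LL"])
    if bad_choice.any():
        problems.append(f"invalid choice at rows {df.index[bad_choice].tolist()[:10]}")
    dup = df.duplicated(
        subset=["participant_id", "condition", "block_id", "trial_index"], keep=False
    )
    if dup.any():
        problems.append(
            f"duplicate (participant, condition, block, trial) keys at rows "
            f"{df.index[dup].tolist()[:10]}"
        )
    if problems:
        raise ValidationError("; ".join(problems))


def validate_judgments(df: pd.DataFrame) -> None:
    missing = set(JUDGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"judgments table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("empty judgments table")
    problems = []
    bad_t = df["duration_days"].astype(float) <= 0
    if bad_t.any():
        problems.append(f"non-positive duration at rows {df.index[bad_t].tolist()[:10]}")
    bad_l = (df["line_length_cm"].astype(float) < 0) | (
        df["line_length_cm"].astype(float) > 28.5
    )
    if bad_l.any():
        problems.append(f"line length out of [0, 28.5] at rows {df.index[bad_l].tolist()[:10]}")
    if problems:
        raise ValidationError("; ".join(problems))


def validate_attention(df: pd.DataFrame) -> None:
    missing = set(ATTENTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"attention table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("empty attention table")
    problems = []
    for col in ("first_attention", "majority_attention"):
        bad = ~df[col].isin(["delay", "reward"])
        if bad.any():
            problems.append(f"invalid {col} at rows {df.index[bad].tolist()[:10]}")
    dup = df.duplicated(subset=["participant_id"], keep=False)
    if dup.any():
        problems.append(f"duplicate participant rows {df.index[dup].tolist()[:10]}")
    if problems:
        raise ValidationError("; ".join(problems))


_VALIDATORS = {
    "choices": validate_choices,
    "judgments": validate_judgments,
    "attention": validate_attention,
}


def write_dataset(path, tables: dict[str, pd.DataFrame]) -> None:
    """Write tables as headered CSV files under ``path`` (validated first)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if name not in TABLE_NAMES:
            raise ValidationError(f"unknown table {name!r}")
        validator = _VALIDATORS.get(name)
        if validator is not None:
            validator(df)
        df.to_csv(path / f"{name}.csv", index=False)


def read_dataset(path, names=None) -> dict[str, pd.DataFrame]:
    """Read and validate the CSV tables present under ``path``."""
    path = Path(path)
    if names is None:
        names = [n for n in TABLE_NAMES if (path / f"{n}.csv").exists()]
    if not names:
        raise ValidationError(f"no dataset tables found under {path}")
    out = {}
    for name in names:
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise ValidationError(f"missing table file {fp}")
        df = pd.read_csv(fp)
        validator = _VALIDATORS.get(name)
        if validator is not None:
            validator(df)
        out[name] = df
    return out
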