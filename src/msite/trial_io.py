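"""Reading, validating, filtering and n-1 annotation of trial tables.

Analysis-ready sets follow the published inclusion rules: early targets only,
responses inside a closed [150, 3000] ms window after target onset, main
(expect-early / expect-late) blocks only.  The n-1 annotation is always
computed on the unfiltered, session-ordered table, so filtering never changes
which trial counts as "previous".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "msite/trials/v1"

REQUIRED_COLUMNS = [
    "subject_id",
    "experiment_id",
    "spatial_uncertainty",
    "target_uncertainty",
    "block_index",
    "block_type",
    "trial_index",
    "sequence_modality",
    "target_modality",
    "target_position",
    "target_onset_ms",
    "target_direction",
    "response",
    "rt_ms",
    "correct",
]

PREV_COLUMNS = ["prev_target_modality", "prev_target_position", "prev_correct"]


class SchemaError(ValueError):
    """Input table does not match the trial schema."""


class IntegrityError(ValueError):
    """Ordering/uniqueness contract of the trial table is violated."""


@dataclass(frozen=True)
class FilterSpec:
    """Inclusion rules for the analysis set.

    ``rt_window_ms`` is a closed interval measured from target onset.  A row
    failing several rules is tallied once, under the first failing reason in
    the precedence window > position > block > response.
    """

    rt_window_ms: tuple[float, float] = (150.0, 3000.0)
    positions_included: frozenset = frozenset({"early"})
    require_response: bool = True
    blocks_included: frozenset = frozenset({"expect_early", "expect_late"})

    def validate(self) -> None:
        lo, hi = self.rt_window_ms
        if not lo < hi:
            raise ValueError(f"rt_window_ms lower bound must be < upper bound, got {self.rt_window_ms}")
        if not self.positions_included:
            raise ValueError("positions_included must be non-empty")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as delimited text with a schema-version header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def read_trials(path, max_bad_row_fraction: float = 0.05) -> pd.DataFrame:
    """Read and validate a trial table (TSV or CSV, ``#`` comments ignored).

    Raises :class:`SchemaError` naming any missing column.  Rows whose RT
    cannot be parsed are dropped and reported via a warning; more than
    ``max_bad_row_fraction`` of them raises instead.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: trial table contains a header but zero rows")
        return df

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    has_response = df["response"].astype(str) != "none"
    bad = rt.isna() & has_response & df["rt_ms"].notna()
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()) + 2)  # 1-based + header line
        if bad.mean() > max_bad_row_fraction:
            raise SchemaError(
                f"{bad.sum()} rows with unparsable rt_ms (> {max_bad_row_fraction:.0%}); "
                f"first offending file rows: {rows[:10]}"
            )
        warnings.warn(f"dropping {bad.sum()} rows with unparsable rt_ms (file rows {rows[:10]}...)")
        df = df.loc[~bad].copy()
        rt = rt.loc[~bad]
    df["rt_ms"] = rt
    df["correct"] = df["correct"].astype(bool)
    return df


def apply_filters(df: pd.DataFrame, spec: FilterSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Apply inclusion rules; return (retained rows, exclusion tally).

    The tally maps reason -> count with keys ``rt_window``, ``position``,
    ``block``, ``no_response`` and ``retained``; reason counts sum to
    ``rows_in - rows_out``.  The RT window applies to rows that carry a
    response; response-less rows are only excluded by the ``no_response``
    rule (when ``require_response`` is set).
    """
    spec = spec or FilterSpec()
    spec.validate()
    lo, hi = spec.rt_window_ms
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    has_resp = df["response"].notna() & (df["response"].astype(str) != "none")

    bad_window = has_resp & ((rt < lo) | (rt > hi) | rt.isna())
    bad_position = ~df["target_position"].isin(spec.positions_included)
    bad_block = ~df["block_type"].isin(spec.blocks_included)
    bad_response = spec.require_response & ~has_resp

    reason = np.full(len(df), "", dtype=object)
    for name, mask in [
        ("no_response", bad_response),
        ("block", bad_block),
        ("position", bad_position),
        ("rt_window", bad_window),
    ]:
        reason[np.asarray(mask, dtype=bool)] = name  # later = higher precedence

    keep = reason == ""
    tally = {
        "rt_window": int((reason == "rt_window").sum()),
        "position": int((reason == "position").sum()),
        "block": int((reason == "block").sum()),
        "no_response": int((reason == "no_response").sum()),
        "retained": int(keep.sum()),
    }
    return df.loc[keep].copy(), tally


def annotate_previous_trial(df: pd.DataFrame) -> pd.DataFrame:
    """Add n-1 columns (prev_target_modality, prev_target_position, prev_correct).

    Computed within subject in session order (``trial_index``); the n-1
    relation does not cross block boundaries, so the first trial of every
    block carries null n-1 fields.  Must run on the unfiltered table so that
    the previous trial may be of any type.
    """
    if df.duplicated(subset=["subject_id", "trial_index"]).any():
        dupes = df.loc[
            df.duplicated(subset=["subject_id", "trial_index"]), ["subject_id", "trial_index"]
        ]
        raise IntegrityError(
            f"duplicate trial_index within subject: {dupes.head(5).to_dict('records')}"
        )
    out = df.sort_values(["subject_id", "trial_index"], kind="mergesort").copy()
    grp = out.groupby(["subject_id", "block_index"], sort=False)
    out["prev_target_modality"] = grp["target_modality"].shift(1)
    out["prev_target_position"] = grp["target_position"].shift(1)
    out["prev_correct"] = grp["correct"].shift(1)  # object dtype with NaN at block starts
    return out
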