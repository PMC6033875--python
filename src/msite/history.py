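"""Trial-history (n-1) conditioned sensitivity analysis.

Each analyzed trial is classified by whether the previous trial of the same
block matched it in target modality and in target position (early/late),
under the restriction that the previous trial was answered correctly (no
post-error trials).  d' is then computed per subject for the 2 x 2 x 2 cell
structure (modality in {AV, best unisensory} x modality match x target-
position match) and handed to the mixed ANOVA with the uncertainty factors
between subjects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sdt import _count_cells
from .trial_io import PREV_COLUMNS

logger = logging.getLogger(__name__)

HISTORY_FACTORS = ["modality", "modality_match", "tp_match"]


def classify_history(df: pd.DataFrame) -> pd.DataFrame:
    """Add modality/TP match labels and a history inclusion flag.

    Requires the n-1 annotation columns.  A trial enters the history analysis
    only when its predecessor exists (not first in block) and was answered
    correctly; the exclusion reason is recorded in ``history_excluded``
    (``first_in_block`` or ``prev_incorrect``, empty when included).
    Matching is plain equality with the current trial's labels, so for a
    current unisensory trial a preceding AV trial counts as a modality
    mismatch, and an AV trial is a modality match only after another AV trial.
    """
    missing = [c for c in PREV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run annotate_previous_trial first; missing {missing}")
    out = df.copy()
    no_prev = out["prev_target_modality"].isna()
    prev_ok = out["prev_correct"].eq(True).to_numpy()
    out["history_excluded"] = np.select(
        [no_prev, ~prev_ok], ["first_in_block", "prev_incorrect"], default=""
    )
    included = out["history_excluded"] == ""
    out["modality_match"] = np.where(
        included,
        np.where(out["prev_target_modality"] == out["target_modality"], "match", "mismatch"),
        None,
    )
    out["tp_match"] = np.where(
        included,
        np.where(out["prev_target_position"] == out["target_position"], "match", "mismatch"),
        None,
    )
    return out


def history_dprime_cells(
    df: pd.DataFrame,
    best_modality: dict | pd.Series,
    correction: str = "loglinear",
    min_trials: int = 4,
) -> pd.DataFrame:
    """HistoryCell table: d' per subject x modality x modality-match x TP-match.

    ``df`` is the annotated, filtered analysis set; ``best_modality`` maps
    subject_id to the subject's best unisensory modality under the d' measure.
    Current trials are restricted to AV and that best modality (labelled
    ``best_uni``).  Subjects missing any of the eight cells (or lacking both
    target directions in one) are dropped from the returned table with a log
    entry; cells under ``min_trials`` are kept but flagged.
    """
    if isinstance(best_modality, pd.Series):
        best_modality = best_modality.to_dict()
    d = classify_history(df)
    d = d[(d["history_excluded"] == "") & (d["response"].astype(str) != "none")].copy()
    d["best_mod"] = d["subject_id"].map(best_modality)
    d = d[d["best_mod"].notna()]
    d = d[(d["target_modality"] == "AV") | (d["target_modality"] == d["best_mod"])]
    d["modality"] = np.where(d["target_modality"] == "AV", "AV", "best_uni")

    cells = _count_cells(d, ["subject_id"] + HISTORY_FACTORS, correction=correction)
    cells["low_n"] = cells["n_trials"] < min_trials
    if len(cells) == 0:
        return cells
    counts = cells.groupby("subject_id")["dprime"].count()
    incomplete = counts[counts < 8].index
    if len(incomplete):
        logger.warning(
            "dropping %d subject(s) with incomplete history cells: %s",
            len(incomplete), list(incomplete)[:10],
        )
        cells = cells[~cells["subject_id"].isin(incomplete)]
    return cells.reset_index(drop=True)


def history_exclusion_tally(classified: pd.DataFrame) -> dict:
    """Counts of history-analysis exclusions by reason (plus included trials)."""
    vc = classified["history_excluded"].value_counts()
    return {
        "included": int(vc.get("", 0)),
        "first_in_block": int(vc.get("first_in_block", 0)),
        "prev_incorrect": int(vc.get("prev_incorrect", 0)),
    }
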