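"""2AFC signal-detection scoring and max-criterion multisensory facilitation.

Per subject x target-modality x temporal-expectation cell this module counts
"higher" responses to higher- and lower-frequency targets, converts them to a
2AFC sensitivity d' = (z(H) - z(F)) / sqrt(2), and averages response times.
The best unisensory modality per subject is chosen by a two-step rule
(dominance across both expectation states, else the better average), and
multisensory facilitation (MSF) is the max-criterion contrast
AV - best[A, V] for d' and min[A, V] - AV for RT, so that positive values
always mean facilitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simulate import MAIN_BLOCK_TYPES

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))

BETWEEN_COLUMNS = ["experiment_id", "spatial_uncertainty", "target_uncertainty"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the two-step best-unisensory choice."""

    modality: str            # "A" or "V"
    resolved_by: str         # "dominance" or "average"
    tie_broken: bool = False # exact tie after step 2, resolved deterministically


def _corrected_rates(n_hits, n_higher, n_fa, n_lower, correction):
    n_hits = np.asarray(n_hits, dtype=float)
    n_higher = np.asarray(n_higher, dtype=float)
    n_fa = np.asarray(n_fa, dtype=float)
    n_lower = np.asarray(n_lower, dtype=float)
    if correction == "loglinear":
        h = (n_hits + 0.5) / (n_higher + 1.0)
        f = (n_fa + 0.5) / (n_lower + 1.0)
    elif correction == "clamp":
        h = np.clip(n_hits / n_higher, 1.0 / (2 * n_higher), 1.0 - 1.0 / (2 * n_higher))
        f = np.clip(n_fa / n_lower, 1.0 / (2 * n_lower), 1.0 - 1.0 / (2 * n_lower))
    elif correction == "none":
        h = n_hits / n_higher
        f = n_fa / n_lower
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return h, f


def dprime_2afc(n_hits, n_higher, n_fa, n_lower, correction="loglinear"):
    """2AFC sensitivity from response counts.

    H is the "higher"-response rate given higher-frequency targets, F given
    lower-frequency targets; d' = (z(H) - z(F)) / sqrt(2).  ``correction``
    guards against 0/1 rates: ``"loglinear"`` (default) adds 0.5 to each count
    and 1 to each denominator, ``"clamp"`` limits rates to [1/(2N), 1 - 1/(2N)],
    ``"none"`` uses raw rates (infinite at the extremes).
    """
    if n_higher <= 0 or n_lower <= 0:
        raise ValueError(
            f"need targets of both directions (n_higher={n_higher}, n_lower={n_lower})"
        )
    h, f = _corrected_rates(n_hits, n_higher, n_fa, n_lower, correction)
    return float((norm.ppf(h) - norm.ppf(f)) / SQRT2)


def te_state_of(df: pd.DataFrame) -> pd.Series:
    """Expectation state of each main trial.

    A target is temporally expected when it occurs at the block's probable
    position: early in expect-early blocks, late in expect-late blocks.
    Threshold/training trials get ``"none"``.
    """
    expected_pos = np.where(df["block_type"] == "expect_early", "early", "late")
    state = np.where(
        df["block_type"].isin(MAIN_BLOCK_TYPES),
        np.where(df["target_position"].to_numpy() == expected_pos, "expected", "unexpected"),
        "none",
    )
    return pd.Series(state, index=df.index, dtype=object)


def score_conditions(
    df: pd.DataFrame,
    min_trials: int = 4,
    correction: str = "loglinear",
    rt_correct_only: bool = False,
) -> pd.DataFrame:
    """Condition scores per subject x modality x expectation state.

    Expects a filtered analysis set (early targets in main blocks by default;
    any rows present are scored, with the state derived per trial).  Cells
    missing one target direction are dropped with a log entry; cells below
    ``min_trials`` responses are kept but flagged ``low_n``.  Mean RT uses all
    responded trials unless ``rt_correct_only`` is set.
    """
    d = df.copy()
    d["te_state"] = te_state_of(d)
    d = d[d["response"].astype(str) != "none"]
    group_cols = ["subject_id", "target_modality", "te_state"]
    cells = _count_cells(
        d, group_cols, correction=correction, rt_correct_only=rt_correct_only
    )
    cells = cells.rename(columns={"target_modality": "modality"})
    cells["low_n"] = cells["n_trials"] < min_trials
    return cells


def _count_cells(d, group_cols, correction="loglinear", rt_correct_only=False):
    """Grouped hit/false-alarm counts, d' and mean RT (shared cell aggregator)."""
    higher = (d["target_direction"] == "higher").to_numpy()
    resp_higher = (d["response"] == "higher").to_numpy()
    agg = d.assign(
        _higher=higher,
        _lower=~higher,
        _hit=resp_higher & higher,
        _fa=resp_higher & ~higher,
        _rt=np.where(
            d["correct"].to_numpy(dtype=bool) | (not rt_correct_only),
            d["rt_ms"], np.nan,
        ),
    )
    keep_meta = [c for c in BETWEEN_COLUMNS if c in d.columns]
    g = agg.groupby(group_cols, sort=True)
    out = g.agg(
        n_higher_targets=("_higher", "sum"),
        n_lower_targets=("_lower", "sum"),
        n_hits=("_hit", "sum"),
        n_fa=("_fa", "sum"),
        mean_rt_ms=("_rt", "mean"),
        n_trials=("_higher", "size"),
        **{c: (c, "first") for c in keep_meta},
    ).reset_index()
    ok = (out["n_higher_targets"] > 0) & (out["n_lower_targets"] > 0)
    if (~ok).any():
        logger.info("dropping %d cell(s) lacking one target direction", int((~ok).sum()))
        out = out[ok].reset_index(drop=True)
    h, f = _corrected_rates(
        out["n_hits"], out["n_higher_targets"], out["n_fa"], out["n_lower_targets"],
        correction,
    )
    out["hit_rate"] = h
    out["fa_rate"] = f
    out["dprime"] = (norm.ppf(h) - norm.ppf(f)) / SQRT2
    return out


def _cell_values(scores: pd.DataFrame, modality: str, measure: str) -> dict:
    col = "dprime" if measure == "dprime" else "mean_rt_ms"
    sub = scores[scores["modality"] == modality].set_index("te_state")[col]
    if not {"expected", "unexpected"} <= set(sub.index):
        raise ValueError(f"modality {modality}: need both expectation states, have {list(sub.index)}")
    return {"expected": float(sub["expected"]), "unexpected": float(sub["unexpected"])}


def select_best_unisensory(scores: pd.DataFrame, measure: str = "dprime") -> SelectionResult:
    """Two-step best-unisensory choice for one subject's scores.

    Step 1 picks the modality that is better (higher d', or lower mean RT) in
    both expectation states; on split dominance step 2 picks the better
    unweighted mean of the two cells.  An exact tie after step 2 is broken
    deterministically (more analyzed trials, then A) and flagged.
    """
    if measure not in ("dprime", "rt"):
        raise ValueError(f"measure must be 'dprime' or 'rt', got {measure!r}")
    a = _cell_values(scores, "A", measure)
    v = _cell_values(scores, "V", measure)
    better = (lambda x, y: x > y) if measure == "dprime" else (lambda x, y: x < y)

    a_dom = better(a["expected"], v["expected"]) and better(a["unexpected"], v["unexpected"])
    v_dom = better(v["expected"], a["expected"]) and better(v["unexpected"], a["unexpected"])
    if a_dom:
        return SelectionResult("A", "dominance")
    if v_dom:
        return SelectionResult("V", "dominance")

    mean_a = (a["expected"] + a["unexpected"]) / 2.0
    mean_v = (v["expected"] + v["unexpected"]) / 2.0
    if mean_a != mean_v:
        return SelectionResult("A" if better(mean_a, mean_v) else "V", "average")

    n_a = scores.loc[scores["modality"] == "A", "n_trials"].sum()
    n_v = scores.loc[scores["modality"] == "V", "n_trials"].sum()
    pick = "A" if n_a >= n_v else "V"
    return SelectionResult(pick, "average", tie_broken=True)


def preference_label(best_d: str, best_rt: str) -> str:
    """"auditory" if both measures pick A, "visual" if both pick V, else "mixed"."""
    if best_d == best_rt == "A":
        return "auditory"
    if best_d == best_rt == "V":
        return "visual"
    return "mixed"


def select_all_subjects(scores: pd.DataFrame) -> pd.DataFrame:
    """Best-unisensory selections and preference label for every subject."""
    rows = []
    for subject, sub in scores.groupby("subject_id", sort=True):
        sel_d = select_best_unisensory(sub, "dprime")
        sel_rt = select_best_unisensory(sub, "rt")
        rows.append(
            {
                "subject_id": subject,
                "best_modality_d": sel_d.modality,
                "resolved_by_d": sel_d.resolved_by,
                "tie_broken_d": sel_d.tie_broken,
                "best_modality_rt": sel_rt.modality,
                "resolved_by_rt": sel_rt.resolved_by,
                "tie_broken_rt": sel_rt.tie_broken,
                "preference_label": preference_label(sel_d.modality, sel_rt.modality),
            }
        )
    return pd.DataFrame(rows)


def build_msf_records(
    scores: pd.DataFrame,
    frequencies: pd.DataFrame | None = None,
    selections: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Multisensory-facilitation records, one row per subject x expectation state.

    ``msf_d = d'(AV) - d'(best[A,V])`` and ``msf_rt = RT(best[A,V]) - RT(AV)``
    with the subject-level best modality per measure, so positive values always
    indicate facilitation.  ``unidiff`` is the state-wise max[A,V] - min[A,V]
    spread (always >= 0).  ``frequencies`` (columns subject_id, freq_a, freq_v,
    e.g. the calibrated target-frequency offsets from the simulator sidecar)
    are normalized by their grand mean per modality across all subjects.
    Subjects without a complete AV cell pair are excluded with a log entry.
    """
    selections = selections if selections is not None else select_all_subjects(scores)
    sel = selections.set_index("subject_id")

    freq = None
    if frequencies is not None:
        freq = frequencies.set_index("subject_id")
        norm_a = freq["freq_a"].mean()
        norm_v = freq["freq_v"].mean()

    rows = []
    for subject, sub in scores.groupby("subject_id", sort=True):
        if subject not in sel.index:
            continue
        try:
            av_d = _cell_values(sub, "AV", "dprime")
            av_rt = _cell_values(sub, "AV", "rt")
            a_d, v_d = _cell_values(sub, "A", "dprime"), _cell_values(sub, "V", "dprime")
            a_rt, v_rt = _cell_values(sub, "A", "rt"), _cell_values(sub, "V", "rt")
        except ValueError as exc:
            logger.warning("excluding subject %s from MSF records: %s", subject, exc)
            continue
        best_d = sel.loc[subject, "best_modality_d"]
        best_rt = sel.loc[subject, "best_modality_rt"]
        meta = sub.iloc[0]
        for te in ("expected", "unexpected"):
            uni_d = a_d[te] if best_d == "A" else v_d[te]
            uni_rt = a_rt[te] if best_rt == "A" else v_rt[te]
            row = {
                "subject_id": subject,
                "te_state": te,
                "best_modality_d": best_d,
                "best_modality_rt": best_rt,
                "preference_label": sel.loc[subject, "preference_label"],
                "msf_d": av_d[te] - uni_d,
                "msf_rt": uni_rt - av_rt[te],
                "unidiff_d": abs(a_d[te] - v_d[te]),
                "unidiff_rt": abs(a_rt[te] - v_rt[te]),
                **{c: meta[c] for c in BETWEEN_COLUMNS if c in sub.columns},
            }
            if freq is not None and subject in freq.index:
                row["freq_a_norm"] = float(freq.loc[subject, "freq_a"] / norm_a)
                row["freq_v_norm"] = float(freq.loc[subject, "freq_v"] / norm_v)
            else:
                row["freq_a_norm"] = np.nan
                row["freq_v_norm"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def build_modality_te_cells(scores: pd.DataFrame, selections: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long table of the four within cells (modality best_uni/AV x expectation).

    This is the input of the sustained-effects mixed ANOVA: for each subject,
    the best unisensory modality's two cells (labelled ``best_uni``) and the
    AV cells, carrying d' and mean RT plus the between-subject factors.
    """
    selections = selections if selections is not None else select_all_subjects(scores)
    sel = selections.set_index("subject_id")
    rows = []
    for subject, sub in scores.groupby("subject_id", sort=True):
        if subject not in sel.index:
            continue
        for label, mod_d, mod_rt in (
            ("best_uni", sel.loc[subject, "best_modality_d"], sel.loc[subject, "best_modality_rt"]),
            ("AV", "AV", "AV"),
        ):
            try:
                d = _cell_values(sub, mod_d, "dprime")
                rt = _cell_values(sub, mod_rt, "rt")
            except ValueError as exc:
                logger.warning("subject %s lacks cells for ANOVA table: %s", subject, exc)
                break
            meta = sub.iloc[0]
            for te in ("expected", "unexpected"):
                rows.append(
                    {
                        "subject_id": subject,
                        "modality": label,
                        "te_state": te,
                        "dprime": d[te],
                        "mean_rt_ms": rt[te],
                        **{c: meta[c] for c in BETWEEN_COLUMNS if c in sub.columns},
                    }
                )
    out = pd.DataFrame(rows)
    # keep only subjects with all four cells
    if len(out):
        counts = out.groupby("subject_id")["modality"].count()
        complete = counts[counts == 4].index
        out = out[out["subject_id"].isin(complete)].reset_index(drop=True)
    return out
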