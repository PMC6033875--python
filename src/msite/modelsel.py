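"""Exhaustive-subset leave-one-out cross-validated regression of MSF.

All 2^8 - 1 = 255 non-empty subsets of eight predictors (spatial uncertainty,
target uncertainty, temporal expectation, normalized auditory and visual
target frequencies, auditory/visual preference indicators, and the
measure-matched unisensory performance difference) are fit by ordinary least
squares with an always-included intercept.  Each model's leave-one-out RMSE
(computed exactly via the hat-matrix identity e_i / (1 - h_ii)) ranks the
models; Spearman correlations between held-out predictions and observations,
Bonferroni-corrected over the set of reported models, plus full-data
coefficients and the per-predictor Proportionate Reduction of Error
(PRE = (SSE_without - SSE_with) / SSE_without) summarize the winners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

PREDICTORS = ("SpU", "TaU", "TE", "FreqA", "FreqV", "PrefA", "PrefV", "UniDiff")

NAMED_MODELS = {
    "physical": ("SpU", "TaU", "TE", "FreqA", "FreqV"),
    "individual": ("PrefA", "PrefV"),
    "uni_perf": ("UniDiff",),
    "full": PREDICTORS,
}


class FoldError(RuntimeError):
    """A cross-validation fold had a rank-deficient training design."""


@dataclass(frozen=True)
class PredictorMatrix:
    """Outcome vector and the eight-column predictor frame (fixed column order)."""

    y: np.ndarray
    X: pd.DataFrame
    measure: str

    @property
    def n(self) -> int:
        return len(self.y)


def build_predictor_matrix(msf: pd.DataFrame, measure: str = "dprime") -> PredictorMatrix:
    """Predictor matrix from MSF records (one row per subject x expectation state).

    Outcome: ``msf_d`` (AV - best[A,V] d') or ``msf_rt`` (min[A,V] - AV RT).
    Indicator coding: SpU/TaU = 1 under high uncertainty, TE = 1 for
    temporally unexpected targets, PrefA/PrefV = 1 for an auditory/visual
    preference (both 0 for mixed).  UniDiff is the measure-matched
    max[A,V] - min[A,V] spread.
    """
    if measure not in ("dprime", "rt"):
        raise ValueError(f"measure must be 'dprime' or 'rt', got {measure!r}")
    y_col = "msf_d" if measure == "dprime" else "msf_rt"
    uni_col = "unidiff_d" if measure == "dprime" else "unidiff_rt"
    X = pd.DataFrame(
        {
            "SpU": (msf["spatial_uncertainty"] == "high").astype(float),
            "TaU": (msf["target_uncertainty"] == "high").astype(float),
            "TE": (msf["te_state"] == "unexpected").astype(float),
            "FreqA": msf["freq_a_norm"].astype(float),
            "FreqV": msf["freq_v_norm"].astype(float),
            "PrefA": (msf["preference_label"] == "auditory").astype(float),
            "PrefV": (msf["preference_label"] == "visual").astype(float),
            "UniDiff": msf[uni_col].astype(float),
        },
        index=msf.index,
    )[list(PREDICTORS)]
    y = msf[y_col].to_numpy(dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        bad = msf.loc[X.isna().any(axis=1) | np.isnan(y), "subject_id"].unique()
        raise ValueError(f"missing predictor/outcome values for subjects {list(bad)}")
    return PredictorMatrix(y=y, X=X.reset_index(drop=True), measure=measure)


def enumerate_subsets(n_predictors: int) -> list[tuple[int, ...]]:
    """All 2^n - 1 non-empty predictor-index subsets, in canonical bitmask order."""
    if n_predictors < 1:
        raise ValueError(f"n_predictors must be >= 1, got {n_predictors}")
    subsets = []
    for mask in range(1, 2**n_predictors):
        subsets.append(tuple(i for i in range(n_predictors) if mask >> i & 1))
    return subsets


def _design(matrix: PredictorMatrix, subset: tuple[int, ...]) -> np.ndarray:
    cols = matrix.X.to_numpy()[:, list(subset)]
    return np.column_stack([np.ones(matrix.n), cols])


def loocv_model(matrix: PredictorMatrix, subset: tuple[int, ...]):
    """Leave-one-out predictions and RMSE for one predictor subset.

    Per fold an OLS model (intercept always included) fit on N-1 rows predicts
    the held-out row; for OLS the held-out residual equals
    ``e_i / (1 - h_ii)`` of the full fit, which is used here exactly.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    X = _design(matrix, subset)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need N > n_included + 1 (N={n}, predictors={p - 1})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise FoldError(f"rank-deficient design for subset {subset} (rank {rank} < {p})")
    beta, *_ = np.linalg.lstsq(X, matrix.y, rcond=None)
    resid = matrix.y - X @ beta
    XtX_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    if np.any(h >= 1.0 - 1e-12):
        bad = int(np.argmax(h))
        raise FoldError(f"fold {bad} of subset {subset}: leverage 1 (perfect-fit fold)")
    loo_resid = resid / (1.0 - h)
    preds = matrix.y - loo_resid
    rmse = float(np.sqrt(np.mean(loo_resid**2)))
    return rmse, preds


def rank_models(
    matrix: PredictorMatrix, bonferroni_family: int = 5
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Rank all non-empty subsets by LOOCV RMSE (rank 1 = smallest).

    Ties break by smaller subset size, then canonical subset order.  Spearman
    rho compares held-out predictions with observations (average ranks on
    ties); its p-value uses the t approximation and is Bonferroni-corrected
    with the number of reported correlations (default 5: best, physical,
    individual, uni_perf, full).  Returns the full result table and the named
    report rows.
    """
    n_pred = matrix.X.shape[1]
    rows = []
    for i, subset in enumerate(enumerate_subsets(n_pred)):
        rmse, preds = loocv_model(matrix, subset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant predictions -> rho undefined
            rho, p = spearmanr(preds, matrix.y)
        rho = float(rho) if np.isfinite(rho) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
        rows.append(
            {
                "model_id": i + 1,
                "predictors": "+".join(matrix.X.columns[j] for j in subset),
                "subset": subset,
                "n_predictors": len(subset),
                "rmse": rmse,
                "rho": rho,
                "p_raw": p,
                "p_bonf": min(1.0, bonferroni_family * p),
            }
        )
    results = pd.DataFrame(rows)
    order = results.sort_values(
        ["rmse", "n_predictors", "model_id"], kind="mergesort"
    ).index
    results.loc[order, "rank"] = np.arange(1, len(results) + 1)
    results["rank"] = results["rank"].astype(int)

    named: dict[str, pd.Series] = {"best": results.loc[results["rank"] == 1].iloc[0]}
    name_of = {}
    for name, cols in NAMED_MODELS.items():
        if set(cols) <= set(matrix.X.columns):
            name_of[tuple(sorted(matrix.X.columns.get_loc(c) for c in cols))] = name
    for _, row in results.iterrows():
        key = tuple(sorted(row["subset"]))
        if key in name_of:
            named[name_of[key]] = row
    return results, named


def fit_best_model(matrix: PredictorMatrix, subset: tuple[int, ...]) -> pd.DataFrame:
    """Full-data OLS coefficients with SE, p and per-predictor PRE.

    PRE refits the model with that single predictor removed (intercept
    retained): ``PRE = (SSE_without - SSE_with) / SSE_without``.  The
    intercept row carries no PRE.
    """
    X = _design(matrix, subset)
    names = ["intercept"] + [matrix.X.columns[j] for j in subset]
    cond = np.linalg.cond(X)
    if cond > 1e8:
        corr = np.corrcoef(X[:, 1:], rowvar=False) if X.shape[1] > 2 else None
        warnings.warn(
            f"ill-conditioned design (cond={cond:.3g}); predictor correlations:\n{corr}"
        )
    fit = sm.OLS(matrix.y, X).fit()
    sse_full = float(np.sum(fit.resid**2))

    rows = []
    for k, name in enumerate(names):
        pre = np.nan
        if k > 0:
            reduced = np.delete(X, k, axis=1)
            beta_r, *_ = np.linalg.lstsq(reduced, matrix.y, rcond=None)
            sse_r = float(np.sum((matrix.y - reduced @ beta_r) ** 2))
            pre = (sse_r - sse_full) / sse_r if sse_r > 0 else 0.0
        rows.append(
            {
                "term": name,
                "beta": float(fit.params[k]),
                "p": float(fit.pvalues[k]),
                "SE": float(fit.bse[k]),
                "PRE": pre,
            }
        )
    return pd.DataFrame(rows)
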