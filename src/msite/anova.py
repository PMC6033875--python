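"""Mixed repeated-measures ANOVA by direct sums-of-squares decomposition.

The designs here have any number of two-level within-subject factors crossed
with between-subject factors (subjects nested in the between cells, every
subject measured in every within cell).  Because all within factors have two
levels, every within-side effect is one degree of freedom and reduces to a
per-subject contrast score; the mixed ANOVA then decomposes exactly into

* a between stratum: a factorial ANOVA on subject means, error = subjects
  within groups;
* one stratum per within effect: a factorial ANOVA on the per-subject
  contrast scores, error = effect x subjects within groups.

This makes every F ratio auditable (with a single within factor and no
between factors, F equals the paired t-squared identically).  Sphericity is
moot with two-level factors.  Effect sizes: generalized eta-squared uses the
sum of all subject-level error strata in its denominator; eta2 is reported in
its partial form, SS_effect / (SS_effect + SS_error_of_that_effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist


class DesignError(ValueError):
    """The cell table is incomplete or unbalanced."""


def _check_layout(df, dv, within, subject, between):
    cols = [subject, dv] + list(within) + list(between)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DesignError(f"missing column(s): {missing}")
    for w in within:
        levels = sorted(df[w].unique())
        if len(levels) != 2:
            raise DesignError(f"within factor {w!r} must have exactly 2 levels, got {levels}")
    counts = df.groupby(subject)[dv].count()
    n_cells = 2 ** len(within)
    if not (counts == n_cells).all():
        bad = counts[counts != n_cells]
        raise DesignError(
            f"each subject needs exactly {n_cells} within cells; offending subjects: "
            f"{bad.head(5).to_dict()}"
        )
    if df[dv].isna().any():
        raise DesignError("missing cell values (no imputation is performed)")


def _factorial_ss(values: pd.DataFrame, dv: str, factors: list[str]):
    """Balanced fixed-effects factorial decomposition of one score per subject.

    Returns (dict effect-tuple -> (SS, df), residual SS, residual df).  Effects
    are estimated from cell means by inclusion-exclusion, so with equal cell
    sizes this is the classical (and Type-III-equivalent) decomposition; with
    unequal cell sizes it is the unweighted-means approximation.
    """
    n = len(values)
    grand = values[dv].mean()
    if not factors:
        return {}, float(((values[dv] - grand) ** 2).sum()), n - 1

    # effect estimate per row, built up by inclusion-exclusion over subsets
    effect_of: dict[tuple, pd.Series] = {}
    ss: dict[tuple, tuple[float, int]] = {}
    for k in range(1, len(factors) + 1):
        for eff in combinations(factors, k):
            cell_mean = values.groupby(list(eff))[dv].transform("mean")
            est = cell_mean - grand
            for j in range(1, k):
                for sub in combinations(eff, j):
                    est = est - effect_of[sub]
            effect_of[eff] = est
            df_eff = int(np.prod([values[f].nunique() - 1 for f in eff]))
            ss[eff] = (float((est**2).sum()), df_eff)

    full_cell_mean = values.groupby(factors)[dv].transform("mean")
    resid_ss = float(((values[dv] - full_cell_mean) ** 2).sum())
    n_groups = len(values.groupby(factors))
    return ss, resid_ss, n - n_groups


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject_id",
    between: list[str] | None = None,
    allow_unbalanced: bool = False,
) -> pd.DataFrame:
    """Full SS decomposition of a balanced mixed design (two-level within factors).

    ``df`` is a long cell table: one row per subject x within-cell, plus
    constant between-factor labels per subject.  Returns one row per effect
    with columns effect, SS_effect, SS_error, df_num, df_den, F, p, ges, eta2.
    """
    between = list(between or [])
    within = list(within)
    _check_layout(df, dv, within, subject, between)

    subj_info = df.groupby(subject)[between].first() if between else pd.DataFrame(
        index=df.groupby(subject).size().index
    )
    if between:
        changed = df.groupby(subject)[between].nunique()
        if (changed > 1).any().any():
            raise DesignError("between-subject factor varies within a subject")
        group_sizes = subj_info.groupby(between).size()
        if group_sizes.nunique() > 1 and not allow_unbalanced:
            raise DesignError(
                f"unequal between-group sizes {group_sizes.to_dict()}; "
                "pass allow_unbalanced=True for the unweighted-means approximation"
            )

    n_wcells = 2 ** len(within)
    level_hi = {w: sorted(df[w].unique())[1] for w in within}

    # per-subject scores: mean, and one contrast per within-effect subset
    pivot = df.set_index([subject] + within)[dv].unstack(within)
    scores = pd.DataFrame(index=pivot.index)
    scores["_mean"] = pivot.mean(axis=1)
    wide_cols = pivot.columns
    for k in range(1, len(within) + 1):
        for eff in combinations(within, k):
            signs = np.ones(len(wide_cols))
            for w in eff:
                if len(within) == 1:
                    lv = pd.Index(wide_cols)
                else:
                    lv = wide_cols.get_level_values(w)
                signs *= np.where(np.asarray(lv) == level_hi[w], 1.0, -1.0)
            scores["*".join(eff)] = (pivot * signs).sum(axis=1) / n_wcells
    scores = scores.join(subj_info)

    results = []
    error_pool = 0.0  # sum of all subject-level error SS (for generalized eta2)
    strata = []

    # between stratum, on subject means
    b_ss, b_resid, b_df = _factorial_ss(scores.reset_index(), "_mean", between)
    ss_sub_within_groups = n_wcells * b_resid
    error_pool += ss_sub_within_groups
    for eff, (ss_raw, df_num) in b_ss.items():
        strata.append((eff, n_wcells * ss_raw, df_num, ss_sub_within_groups, b_df))

    # one stratum per within effect
    for k in range(1, len(within) + 1):
        for eff in combinations(within, k):
            col = "*".join(eff)
            w_ss, w_resid, w_df = _factorial_ss(scores.reset_index(), col, between)
            n_subj = len(scores)
            ss_err = n_wcells * w_resid
            error_pool += ss_err
            grand_contrast = scores[col].mean()
            strata.append((eff, n_wcells * n_subj * grand_contrast**2, 1, ss_err, w_df))
            for beff, (ss_raw, df_num) in w_ss.items():
                strata.append((eff + beff, n_wcells * ss_raw, df_num, ss_err, w_df))

    for eff, ss_eff, df_num, ss_err, df_den in strata:
        if df_den <= 0:
            raise DesignError(f"no error degrees of freedom for effect {eff}")
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        p = float(f_dist.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        results.append(
            {
                "effect": "*".join(eff),
                "SS_effect": ss_eff,
                "SS_error": ss_err,
                "df_num": df_num,
                "df_den": df_den,
                "F": float(F),
                "p": p,
                "ges": ss_eff / (ss_eff + error_pool) if (ss_eff + error_pool) > 0 else 0.0,
                "eta2": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
            }
        )
    return pd.DataFrame(results)


@dataclass(frozen=True)
class PosthocResult:
    """A Bonferroni-corrected paired comparison."""

    contrast: str
    t: float
    df: int
    p_raw: float
    p_bonf: float
    cohens_d: float
    bf_h0: float | None = None


def posthoc_paired(
    x, y, contrast: str = "", m: int = 1, bf_if_nonsig: bool = True, alpha: float = 0.05
) -> PosthocResult:
    """Paired t-test with Cohen's d = mean(diff)/sd(diff) and Bonferroni over m.

    A Jeffreys-Zellner-Siow Bayes factor in favour of the null is attached for
    non-significant raw p-values (approximate; see :func:`bf_h0_paired`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two paired vectors of equal length >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError(f"degenerate contrast {contrast!r}: zero-variance difference")
    n = len(diff)
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p_raw = float(2 * t_dist.sf(abs(t), n - 1))
    bf = bf_h0_paired(t, n) if (bf_if_nonsig and p_raw >= alpha) else None
    return PosthocResult(
        contrast=contrast,
        t=t,
        df=n - 1,
        p_raw=p_raw,
        p_bonf=min(1.0, m * p_raw),
        cohens_d=float(diff.mean() / sd),
        bf_h0=bf,
    )


def bf_h0_paired(t: float, n: int, r: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor in favour of H0 for a paired/one-sample t statistic.

    Cauchy prior with scale ``r`` on the standardized effect (default
    sqrt(2)/2), evaluated by one-dimensional quadrature over the prior on the
    variance ratio g.  This approximates the default of common Bayesian
    t-test implementations; it is not guaranteed to match any particular
    published value to the printed digit.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    nu = n - 1

    def null_lik():
        return (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)

    def integrand(g):
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t**2 / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * (r**2 / (2.0 * np.pi)) ** 0.5
            * g ** -1.5
            * np.exp(-(r**2) / (2.0 * g))
        )

    alt, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(alt) or alt <= 0 or err > 1e-6 * max(alt, 1e-12):
        raise ArithmeticError(
            f"JZS integration failed (value={alt}, abserr={err}) for t={t}, n={n}"
        )
    return float(null_lik() / alt)
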