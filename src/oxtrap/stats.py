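"""Shared statistical machinery: ANOVA variants, multiplicity corrections,
and studentized-range post-hoc procedures.

Standard pieces (BH step-up, OLS two-way ANOVA, the studentized-range
distribution) delegate to statsmodels/scipy; the Student–Newman–Keuls
stepwise procedure and the repeated-measures one-way ANOVA are assembled
here on top of them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (cumulative-minimum enforced)."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def sidak_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: p_adj = 1 − (1 − p)^m."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    return 1.0 - (1.0 - p) ** m


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p over a list of group samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    if np.isnan(f):
        return float("nan"), float("nan")
    return float(f), float(p)


def oneway_anova_matrix(data: np.ndarray, labels: np.ndarray):
    """Row-wise one-way ANOVA of a genes × samples matrix.

    Returns (F, p) arrays; rows with zero variance everywhere give
    F = 0, p = 1, rows that are entirely degenerate give NaN.
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    n = data.shape[1]
    k = len(levels)
    grand = data.mean(axis=1, keepdims=True)
    ss_total = ((data - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(data.shape[0])
    ss_within = np.zeros(data.shape[0])
    for lv in levels:
        cols = labels == lv
        sub = data[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        ss_between += cols.sum() * (m[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(F, df_b, df_w)
    flat = ss_total <= 1e-12 * np.maximum(1.0, np.abs(grand[:, 0]))
    F = np.where(flat, 0.0, F)
    p = np.where(flat, 1.0, p)
    return F, p


def twoway_anova(df: pd.DataFrame, response: str, factor_a: str, factor_b: str,
                 interaction: bool = True) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA table (type II) via statsmodels OLS."""
    inter = f" + C({factor_a}):C({factor_b})" if interaction else ""
    model = ols(f"{response} ~ C({factor_a}) + C({factor_b}){inter}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return anova_lm(model, typ=2)


def rm_oneway_anova(df: pd.DataFrame, dv: str, within: str, subject: str):
    """Repeated-measures one-way ANOVA with the subject as blocking factor.

    Classic two-factor (condition + subject) sums-of-squares decomposition
    without interaction; F = MS_condition / MS_error with
    (k − 1, (k − 1)(n − 1)) degrees of freedom.  Subjects missing any
    condition are dropped.  Returns (F, p, df1, df2, ms_error).
    """
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"rm_oneway_anova: {n_dropped} subject(s) with missing "
                      "conditions dropped")
    y = complete.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 complete subjects and >=2 conditions")
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return (0.0, 1.0, df1, df2, 0.0) if ss_cond <= 1e-12 else (np.inf, 0.0, df1, df2, 0.0)
    F = (ss_cond / df1) / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return float(F), p, df1, df2, float(ms_err)


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    diff: float
    p: float
    significant: bool


def tukey_pairwise(
    means: pd.Series, n_per_group, ms_error: float, df_error: int, alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Tukey HSD on group means given a shared error mean square.

    ``n_per_group`` is a scalar or a per-level mapping; unbalanced designs
    use the Tukey–Kramer harmonic pairing.
    """
    levels = list(means.index)
    k = len(levels)
    if np.isscalar(n_per_group):
        n_map = {lv: float(n_per_group) for lv in levels}
    else:
        n_map = {lv: float(n_per_group[lv]) for lv in levels}
    out = []
    for a, b in itertools.combinations(levels, 2):
        nh = 2.0 / (1.0 / n_map[a] + 1.0 / n_map[b])
        se = np.sqrt(ms_error / nh)
        diff = means[a] - means[b]
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_error))
        out.append(PairwiseComparison(a, b, float(diff), p, p < alpha))
    return out


def snk_pairwise(
    means: pd.Series, n_per_group, ms_error: float, df_error: int, alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Student–Newman–Keuls stepwise studentized-range procedure.

    Means are ordered; a pair spanning r ordered means is tested against
    the studentized-range critical value for r means, working from the
    widest stretch inward.  A pair is declared non-significant without
    testing if any stretch containing it was non-significant, which keeps
    the stepwise decisions coherent.
    """
    ordered = means.sort_values()
    levels = list(ordered.index)
    k = len(levels)
    if np.isscalar(n_per_group):
        n_map = {lv: float(n_per_group) for lv in levels}
    else:
        n_map = {lv: float(n_per_group[lv]) for lv in levels}
    pos = {lv: i for i, lv in enumerate(levels)}
    sig: dict[tuple[int, int], bool] = {}
    pval: dict[tuple[int, int], float] = {}
    for span in range(k, 1, -1):  # widest first
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = levels[i], levels[j]
            blocked = any(
                not sig.get((ii, jj), True)
                for ii in range(0, i + 1)
                for jj in range(j, k)
                if (ii, jj) != (i, j) and (ii, jj) in sig
            )
            nh = 2.0 / (1.0 / n_map[a] + 1.0 / n_map[b])
            se = np.sqrt(ms_error / nh)
            diff = ordered.iloc[j] - ordered.iloc[i]
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(studentized_range.sf(q, span, df_error))
            pval[(i, j)] = p
            sig[(i, j)] = (p < alpha) and not blocked
    out = []
    for a, b in itertools.combinations(means.index, 2):
        i, j = sorted((pos[a], pos[b]))
        out.append(
            PairwiseComparison(a, b, float(means[a] - means[b]), pval[(i, j)], sig[(i, j)])
        )
    return out
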