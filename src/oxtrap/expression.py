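"""TRAP-RNAseq downstream analysis.

Covers the desk-scale statistics applied after alignment and counting:
median-of-ratios library-size normalization, the expressed-gene filter
(normalized count above threshold in every sample of at least one group),
per-gene ANOVA differential expression on log2 normalized counts with
Benjamini–Hochberg correction and a Student–Newman–Keuls (or Tukey)
post-hoc, fold-change cutoffs, marker-gene definition (positive/input
fold change > 5 at q < 0.05), enrichment-score cell-type list construction
with cross-type uniqueness, multi-study consensus markers, cross-study
fold-change correlation, and 2^−ΔΔCt qPCR relative quantification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from oxtrap.stats import bh_adjust, oneway_anova_matrix, snk_pairwise, tukey_pairwise

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene × sample read counts with sample metadata.

    ``counts`` is genes × samples (non-negative integers); ``meta`` is
    indexed by sample with columns fraction, treatment, study, subject.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.columns.equals(self.meta.index):
            if set(self.counts.columns) != set(self.meta.index):
                raise ValueError("metadata must cover exactly the count samples")
            self.meta = self.meta.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("fraction", "treatment", "study", "subject"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
            if self.meta[col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing values")


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-gene geometric mean across samples, using only
    genes with nonzero counts in every sample; each sample's factor is the
    median over reference genes of count/geomean.  ``pseudo_reference``
    falls back to adding 0.5 to all counts when no gene is nonzero
    everywhere.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in every sample; rerun with "
                "pseudo_reference=True to use a 0.5-pseudocount reference"
            )
        x = x + 0.5
        allpos = np.ones(x.shape[0], dtype=bool)
    ref = x[allpos]
    log_geomean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def filter_expressed(
    normalized: pd.DataFrame, groups: pd.Series, threshold: float = 20.0
) -> pd.Index:
    """Genes with normalized count > threshold in every sample of ≥1 group.

    Implements the vendor-style detection filter: a gene counts as
    expressed when there exists a group in which 100% of the samples
    exceed the threshold.
    """
    groups = groups.reindex(normalized.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    keep = np.zeros(len(normalized), dtype=bool)
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} is empty")
        keep |= (normalized[cols] > threshold).all(axis=1).to_numpy()
    before, after = len(normalized), int(keep.sum())
    logger.info("filter_expressed: %d of %d genes retained", after, before)
    return normalized.index[keep]


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the design it came from."""

    table: pd.DataFrame  # group means, fc, p, q, optional post-hoc flags
    factor: str
    fc_between: tuple[str, str]
    posthoc: str | None = None


def differential_expression(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str = "fraction",
    factor2: str | None = None,
    fc_between: tuple[str, str] = ("positive", "input"),
    posthoc: str | None = None,
    alpha: float = 0.05,
) -> DEResult:
    """Per-gene ANOVA on log2(normalized + 1) with BH correction.

    One-way across the levels of ``factor`` (vectorized), or two-way with
    ``factor2`` (per-gene OLS).  The fold change is the ratio of normalized
    group means between ``fc_between`` levels with a 0.5 pseudocount
    guarding zero denominators.  ``posthoc`` ∈ {None, "snk", "tukey"} adds
    stepwise Student–Newman–Keuls or Tukey HSD significance flags per
    pairwise level comparison of ``factor``.
    """
    meta = meta.loc[normalized.columns]
    labels = meta[factor].to_numpy()
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"level {lv!r} of {factor!r} needs >= 2 replicates")
    logdata = np.log2(normalized.to_numpy(dtype=float) + 1.0)

    if factor2 is None:
        F, p = oneway_anova_matrix(logdata, labels)
    else:
        from oxtrap.stats import twoway_anova

        F = np.empty(len(normalized))
        p = np.empty(len(normalized))
        base = pd.DataFrame({"a": meta[factor].to_numpy(),
                             "b": meta[factor2].to_numpy()})
        for i in range(len(normalized)):
            df = base.assign(y=logdata[i])
            if df["y"].var() == 0:
                F[i], p[i] = 0.0, 1.0
                continue
            tab = twoway_anova(df, "y", "a", "b")
            F[i] = tab.loc["C(a)", "F"]
            p[i] = tab.loc["C(a)", "PR(>F)"]

    q = bh_adjust(p)

    table = pd.DataFrame(index=normalized.index)
    means = {}
    for lv in levels:
        cols = meta.index[meta[factor] == lv]
        means[lv] = normalized[cols].mean(axis=1)
        table[f"mean_{lv}"] = means[lv]
    num, den = fc_between
    if num in means and den in means:
        table["fc"] = (means[num] + 0.5) / (means[den] + 0.5)
    else:
        table["fc"] = np.nan
    table["F"] = F
    table["p"] = p
    table["q"] = q

    if posthoc is not None:
        if posthoc not in ("snk", "tukey"):
            raise ValueError("posthoc must be None, 'snk' or 'tukey'")
        fn = snk_pairwise if posthoc == "snk" else tukey_pairwise
        n_map = {lv: int((labels == lv).sum()) for lv in levels}
        n_total = len(labels)
        dfe = n_total - len(levels)
        flags = {f"{posthoc}_{a}_vs_{b}": np.zeros(len(table), dtype=bool)
                 for a, b in itertools.combinations(levels, 2)}
        for i in range(len(table)):
            gm = pd.Series(
                {lv: logdata[i, labels == lv].mean() for lv in levels}
            )
            sse = sum(
                ((logdata[i, labels == lv] - gm[lv]) ** 2).sum() for lv in levels
            )
            mse = sse / dfe if dfe else 0.0
            for cmp_ in fn(gm, n_map, mse, dfe, alpha):
                key = f"{posthoc}_{cmp_.level_a}_vs_{cmp_.level_b}"
                if key not in flags:
                    key = f"{posthoc}_{cmp_.level_b}_vs_{cmp_.level_a}"
                flags[key][i] = cmp_.significant
        for key, col in flags.items():
            table[key] = col

    return DEResult(table=table, factor=factor, fc_between=fc_between, posthoc=posthoc)


def apply_fc_cutoff(
    de: DEResult | pd.DataFrame, fc_cutoff: float = 1.25, q_cutoff: float = 0.05
) -> pd.Index:
    """Significant genes whose fold change exceeds |fc_cutoff| either way."""
    table = de.table if isinstance(de, DEResult) else de
    keep = (table["q"] < q_cutoff) & (
        (table["fc"] > fc_cutoff) | (table["fc"] < 1.0 / fc_cutoff)
    )
    return table.index[keep.fillna(False)]


@dataclass
class MarkerList:
    """A cell type's marker genes with their enrichment evidence."""

    cell_type: str
    genes: list[str]
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)
    study: str = ""


def define_marker_genes(
    de: DEResult | pd.DataFrame,
    cell_type: str,
    fc_cutoff: float = 5.0,
    q_cutoff: float = 0.05,
    study: str = "",
) -> MarkerList:
    """Markers: positive/input fold change > fc_cutoff at BH q < q_cutoff."""
    table = de.table if isinstance(de, DEResult) else de
    keep = ((table["q"] < q_cutoff) & (table["fc"] > fc_cutoff)).fillna(False)
    genes = sorted(table.index[keep])
    return MarkerList(
        cell_type=cell_type,
        genes=genes,
        evidence=table.loc[genes, ["fc", "q"]].copy(),
        study=study,
    )


def build_celltype_lists(
    scores: pd.DataFrame, cutoff: float = 3.5, study: str = ""
) -> dict[str, MarkerList]:
    """Cell-type lists from a gene × cell-type mean enrichment-score table.

    Pass 1 keeps genes scoring ≥ cutoff (inclusive) for a cell type;
    pass 2 removes genes qualifying for more than one cell type from all
    lists, so each final list is unique to its type.
    """
    qualify = {ct: set(scores.index[scores[ct] >= cutoff]) for ct in scores.columns}
    counts: dict[str, int] = {}
    for genes in qualify.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    out = {}
    for ct, genes in qualify.items():
        uniq = sorted(g for g in genes if counts[g] == 1)
        out[ct] = MarkerList(
            cell_type=ct,
            genes=uniq,
            evidence=scores.loc[uniq, [ct]].rename(columns={ct: "score"}),
            study=study,
        )
    return out


def consensus_markers(
    study_lists: Mapping[str, Sequence[str]],
    min_studies: int = 2,
    reference: Sequence[str] | None = None,
) -> dict:
    """Genes shared by ≥ ``min_studies`` study lists, with overlap counts.

    With a cell-sorting ``reference`` list, also reports the intersection
    — the isolation-method-independent marker set.
    """
    if len(study_lists) < 2:
        raise ValueError("need lists from >= 2 studies")
    membership: dict[str, set[str]] = {}
    for study, genes in study_lists.items():
        for g in genes:
            membership.setdefault(g, set()).add(study)
    consensus = sorted(g for g, s in membership.items() if len(s) >= min_studies)
    overlap_counts = {
        combo: len([g for g, s in membership.items() if s == set(combo)])
        for r in range(1, len(study_lists) + 1)
        for combo in itertools.combinations(sorted(study_lists), r)
    }
    result = {
        "consensus": consensus,
        "n_consensus": len(consensus),
        "overlap_counts": overlap_counts,
    }
    if reference is not None:
        independent = sorted(set(consensus) & set(reference))
        result["method_independent"] = independent
        result["n_method_independent"] = len(independent)
    return result


def crossstudy_fc_correlation(
    fc_by_study: Mapping[str, pd.Series] | pd.DataFrame, min_shared: int = 10
) -> pd.DataFrame:
    """Pairwise Pearson r of log2 fold changes over each pair's shared genes."""
    if isinstance(fc_by_study, pd.DataFrame):
        fc_by_study = {c: fc_by_study[c].dropna() for c in fc_by_study.columns}
    studies = sorted(fc_by_study)
    out = pd.DataFrame(np.eye(len(studies)), index=studies, columns=studies)
    for a, b in itertools.combinations(studies, 2):
        sa, sb = fc_by_study[a], fc_by_study[b]
        shared = sa.index.intersection(sb.index)
        if len(shared) < min_shared:
            r = np.nan
        else:
            x = np.log2(sa[shared].to_numpy(dtype=float))
            y = np.log2(sb[shared].to_numpy(dtype=float))
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = np.nan
            else:
                r = float(sps.pearsonr(x, y).statistic)
        out.loc[a, b] = out.loc[b, a] = r
    return out


def relative_quantification(
    cts: pd.DataFrame,
    control_gene: str,
    calibrator_samples: Sequence[str],
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """2^−ΔΔCt relative quantification.

    ΔCt = Ct_target − Ct_control per sample; ΔΔCt subtracts the calibrator
    group's mean ΔCt per gene; RQ = 2^−ΔΔCt.  Samples missing the control
    gene are dropped and logged.  Returns a long table (sample, gene,
    delta_ct, ddct, rq).
    """
    wide = cts.pivot_table(index=sample_col, columns=gene_col, values=ct_col)
    if control_gene not in wide.columns:
        raise ValueError(f"control gene {control_gene!r} not measured")
    missing = wide.index[wide[control_gene].isna()]
    if len(missing):
        logger.warning("relative_quantification: dropping samples without "
                       "control Ct: %s", list(missing))
        wide = wide.drop(index=missing)
    targets = [g for g in wide.columns if g != control_gene]
    delta = wide[targets].sub(wide[control_gene], axis=0)
    cal = [s for s in calibrator_samples if s in delta.index]
    if not cal:
        raise ValueError("no calibrator sample present after filtering")
    ddct = delta - delta.loc[cal].mean(axis=0)
    rq = np.power(2.0, -ddct)
    out = (
        pd.concat(
            {"delta_ct": delta, "ddct": ddct, "rq": rq}, names=["quantity"]
        )
        .stack()
        .rename("value")
        .reset_index()
        .pivot_table(index=[sample_col, gene_col], columns="quantity", values="value")
        .reset_index()
    )
    out.columns.name = None
    return out
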