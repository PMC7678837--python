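"""Joining the methylome and expression layers.

Per-gene correlation of region-average promoter mCG with expression across
paired subjects (Bonferroni-controlled over the number of genes tested),
a marker-hypomethylation concordance report with an exact sign test, and
the stable-isotope fraction-new-DNA product/precursor ratio.

Pairing across layers is strictly by subject id: TRAP RNA from one
hemisphere and captured nuclei from the other of the same animal; no
cross-subject pairing is permitted.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def methylation_expression_correlation(
    observations: pd.DataFrame,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
    gene_col: str = "gene",
    meth_col: str = "meth",
    expr_col: str = "expr",
) -> pd.DataFrame:
    """Per-gene Pearson correlation of region mCG with expression.

    ``observations`` is long-form with one row per (gene, subject) pair;
    both measurements must come from the same subject.  Genes need ≥3
    paired observations (else NaN).  The significance flag tests
    p < alpha / n_comparisons, with n_comparisons defaulting to the number
    of genes tested.
    """
    genes = sorted(observations[gene_col].unique())
    if n_comparisons is None:
        n_comparisons = len(genes)
    threshold = alpha / n_comparisons
    rows = []
    for gene in genes:
        sub = observations[observations[gene_col] == gene]
        x = sub[meth_col].to_numpy(dtype=float)
        y = sub[expr_col].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((gene, len(x), np.nan, np.nan, False))
            continue
        res = sps.pearsonr(x, y)
        rows.append((gene, len(x), float(res.statistic), float(res.pvalue),
                     bool(res.pvalue < threshold)))
    out = pd.DataFrame(rows, columns=[gene_col, "n", "r", "p", "significant"])
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_comparisons"] = n_comparisons
    return out


def concordance_report(
    marker_sets: Mapping[str, Sequence[str]],
    region_means: pd.DataFrame,
    positive_col_for: Mapping[str, str],
    input_col: str = "input",
) -> pd.DataFrame:
    """Own-marker promoter hypomethylation: positive fraction versus input.

    ``region_means`` is gene-indexed with one column per fraction holding
    the gene's region-average mCG; ``positive_col_for`` maps each cell
    type to its positive-fraction column.  Per cell type, Δ = positive −
    input over that type's markers; the report gives the fraction of
    markers with Δ < 0 and an exact two-sided binomial sign-test p against
    0.5 (Δ = 0 genes are excluded from the test; genes missing a layer are
    excluded and counted).
    """
    rows = []
    for ct, genes in marker_sets.items():
        pos_col = positive_col_for[ct]
        sub = region_means.reindex(list(genes))[[pos_col, input_col]]
        missing = int(sub.isna().any(axis=1).sum())
        sub = sub.dropna()
        delta = sub[pos_col] - sub[input_col]
        nonzero = delta[delta != 0]
        n_hypo = int((nonzero < 0).sum())
        n_test = len(nonzero)
        if n_test:
            p = sps.binomtest(n_hypo, n_test, 0.5).pvalue
            frac = n_hypo / n_test
        else:
            p, frac = np.nan, np.nan
        rows.append((ct, len(genes), missing, n_test, n_hypo, frac, p))
    return pd.DataFrame(
        rows,
        columns=["cell_type", "n_markers", "n_missing", "n_tested",
                 "n_hypomethylated", "fraction_hypomethylated", "sign_test_p"],
    )


def fraction_new_dna(product_enrichment: float, precursor_enrichment: float) -> float:
    """Fraction of newly synthesised DNA from the product/precursor relation.

    Deuterium enrichment of DNA deoxyribose over the precursor-pool
    enrichment.  Ratios above 1 are reported with a warning, not clipped.
    """
    if precursor_enrichment <= 0:
        raise ValueError("precursor enrichment must be positive")
    ratio = product_enrichment / precursor_enrichment
    if ratio > 1:
        warnings.warn(f"fraction new DNA {ratio:.3f} exceeds 1; check enrichments")
    return ratio
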