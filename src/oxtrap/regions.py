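"""Strand-aware metagene binning, CpG-island context, and repeat-class levels.

A gene's neighbourhood is laid out in transcription orientation as 67
ordered bins: 20 × 200 bp upstream flank bins (4 kb, most distal first),
27 equal-width gene-body bins, and 20 × 200 bp downstream flank bins.
Metagene profiles average per-bin site means with genes weighted equally,
so long genes do not dominate.  CpG-island context classifies every
position as island, shore (within 2 kb of an island), shelf (2–4 kb) or
open sea, with island > shore > shelf precedence when neighbouring
islands' derived intervals collide.  Region-level group comparisons use a
two-way ANOVA with Sidak-adjusted pairwise contrasts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from oxtrap.stats import sidak_adjust, twoway_anova

logger = logging.getLogger(__name__)

REGION_OF_BIN = {"upstream": range(0, 20), "body": range(20, 47),
                 "downstream": range(47, 67)}


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic footprint; start/end are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("gene body length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class BinScheme:
    """The 20 / 27 / 20 bin layout: 4 kb flanks in 200 bp bins."""

    flank_bp: int = 4000
    flank_bins: int = 20
    body_bins: int = 27

    def __post_init__(self):
        if self.flank_bp != self.flank_bins * 200:
            raise ValueError("flank_bp must equal flank_bins * 200")

    @property
    def total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def bin_index_for_site(gene: GeneModel, scheme: BinScheme, pos: int) -> int | None:
    """Bin index (0 .. total_bins − 1) of a position, or None outside.

    Upstream flank bins come first in transcription sense (bin 0 most
    distal, bin flank_bins − 1 abutting the TSS), body bins use
    floor(body_bins × offset / body_length), and minus-strand genes are
    mirrored.  Intervals are half-open: a site belongs to a bin iff
    position ∈ [start, end).
    """
    fb, bb, fl = scheme.flank_bins, scheme.body_bins, scheme.flank_bp
    L = gene.end - gene.start
    if gene.strand == "+":
        if gene.start - fl <= pos < gene.start:
            return (pos - (gene.start - fl)) // 200
        if gene.start <= pos < gene.end:
            return fb + (bb * (pos - gene.start)) // L
        if gene.end <= pos < gene.end + fl:
            return fb + bb + (pos - gene.end) // 200
        return None
    # minus strand: transcription runs end -> start
    if gene.end <= pos < gene.end + fl:
        return fb - 1 - (pos - gene.end) // 200
    if gene.start <= pos < gene.end:
        return fb + (bb * (gene.end - 1 - pos)) // L
    if gene.start - fl <= pos < gene.start:
        return fb + bb + (gene.start - 1 - pos) // 200
    return None


def genes_from_frame(genes: pd.DataFrame) -> list[GeneModel]:
    """GeneModel list from a gene table (gene_id, chrom, start, end, strand)."""
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in genes.itertuples(index=False)
    ]


@dataclass
class MetageneProfile:
    """Gene-list metagene summary: per-bin means plus region aggregates."""

    bin_means: np.ndarray           # (total_bins,) mean level per bin, NaN if empty
    n_sites: np.ndarray             # sites contributing per bin
    n_genes: np.ndarray             # genes contributing per bin
    region_means: dict[str, float]  # upstream / body / downstream
    per_gene: pd.DataFrame          # gene_id x (upstream, body, downstream)
    excluded_genes: list[str] = field(default_factory=list)


def metagene_profile(
    paired: pd.DataFrame,
    genes: list[GeneModel] | pd.DataFrame,
    scheme: BinScheme = BinScheme(),
    level_col: str = "mC_pct",
) -> MetageneProfile:
    """Average a per-site level over the 67-bin metagene layout.

    Per bin, the mean over genes of that gene's per-bin site mean (genes
    weighted equally); region aggregates are the mean of the gene-level
    region values.  Genes whose body is shorter than ``body_bins`` bp are
    excluded and logged.
    """
    if isinstance(genes, pd.DataFrame):
        genes = genes_from_frame(genes)
    if not genes:
        raise ValueError("empty gene list")
    usable = [g for g in genes if g.end - g.start >= scheme.body_bins]
    excluded = [g.gene_id for g in genes if g.end - g.start < scheme.body_bins]
    if excluded:
        logger.info("metagene_profile: %d gene(s) shorter than %d bp excluded",
                    len(excluded), scheme.body_bins)
    if not usable:
        raise ValueError("no gene survives the body-length filter")

    nb = scheme.total_bins
    sums = np.zeros(nb)
    gene_counts = np.zeros(nb, dtype=int)
    site_counts = np.zeros(nb, dtype=int)
    per_gene_rows = []
    by_chrom = {c: sub for c, sub in paired.groupby("chrom")}
    for g in usable:
        sub = by_chrom.get(g.chrom)
        row = {"gene_id": g.gene_id, "upstream": np.nan, "body": np.nan,
               "downstream": np.nan}
        if sub is not None:
            lo, hi = g.start - scheme.flank_bp, g.end + scheme.flank_bp
            pos = sub["pos"].to_numpy()
            mask = (pos >= lo) & (pos < hi)
            if mask.any():
                sel_pos = pos[mask]
                levels = sub[level_col].to_numpy()[mask]
                bins = np.array(
                    [bin_index_for_site(g, scheme, p) for p in sel_pos], dtype=float
                )
                ok = ~np.isnan(bins) & ~np.isnan(levels)
                bins = bins[ok].astype(int)
                levels = levels[ok]
                if len(bins):
                    bin_sum = np.bincount(bins, weights=levels, minlength=nb)
                    bin_n = np.bincount(bins, minlength=nb)
                    has = bin_n > 0
                    gmeans = np.full(nb, np.nan)
                    gmeans[has] = bin_sum[has] / bin_n[has]
                    sums[has] += gmeans[has]
                    gene_counts[has] += 1
                    site_counts += bin_n
                    for region, rng in REGION_OF_BIN.items():
                        idx = np.fromiter(rng, dtype=int)
                        in_region = np.isin(bins, idx)
                        if in_region.any():
                            row[region] = float(levels[in_region].mean())
        per_gene_rows.append(row)

    bin_means = np.full(nb, np.nan)
    nonzero = gene_counts > 0
    bin_means[nonzero] = sums[nonzero] / gene_counts[nonzero]
    per_gene = pd.DataFrame(per_gene_rows).set_index("gene_id")
    region_means = {
        region: float(np.nanmean(per_gene[region])) if per_gene[region].notna().any()
        else float("nan")
        for region in REGION_OF_BIN
    }
    return MetageneProfile(
        bin_means=bin_means,
        n_sites=site_counts,
        n_genes=gene_counts,
        region_means=region_means,
        per_gene=per_gene,
        excluded_genes=excluded,
    )


def region_group_comparison(values: pd.DataFrame) -> dict:
    """Two-way ANOVA (group × region) with Sidak-adjusted group contrasts.

    ``values`` is long-form with columns sample, group, region, value —
    one region-average per sample.  Pairwise group differences are tested
    within each region with pooled-error t statistics and Sidak-corrected
    over the number of pairwise tests, p_adj = 1 − (1 − p)^m.
    """
    required = {"sample", "group", "region", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(required)}")
    groups = sorted(values["group"].unique())
    regions = sorted(values["region"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    counts = values.groupby(["group", "region"])["value"].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per group x region cell")
    if values.groupby(["group", "region"])["value"].var().fillna(0).sum() == 0:
        warnings.warn("zero within-group variance everywhere; p-values undefined")
        return {"anova": None, "pairwise": None}

    anova = twoway_anova(values, "value", "group", "region",
                         interaction=len(regions) > 1)
    resid_row = anova.loc["Residual"]
    mse = resid_row["sum_sq"] / resid_row["df"]
    dfe = int(resid_row["df"])

    rows = []
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs) * len(regions)
    for region in regions:
        sub = values[values["region"] == region]
        for a, b in pairs:
            va = sub.loc[sub["group"] == a, "value"]
            vb = sub.loc[sub["group"] == b, "value"]
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            diff = va.mean() - vb.mean()
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / se
                p = 2 * float(sps.t.sf(abs(t), dfe))
            rows.append((region, a, b, float(diff), p))
    pw = pd.DataFrame(rows, columns=["region", "group_a", "group_b", "diff", "p_raw"])
    pw["p_sidak"] = np.minimum(1.0, sidak_adjust(pw["p_raw"].to_numpy(), m))
    return {"anova": anova, "pairwise": pw, "n_comparisons": m}


def assign_sites_to_genes(
    sites: pd.DataFrame, genes: list[GeneModel] | pd.DataFrame,
    scheme: BinScheme = BinScheme(),
) -> pd.DataFrame:
    """Static site → (gene, bin, region) assignment table.

    Maps each (chrom, pos) row of ``sites`` to every gene whose 67-bin
    layout contains it.  Computing this once lets per-sample tables be
    summarised by a plain merge + groupby instead of re-binning.
    """
    if isinstance(genes, pd.DataFrame):
        genes = genes_from_frame(genes)
    region_lookup = np.empty(BinScheme().total_bins, dtype=object)
    for region, rng in REGION_OF_BIN.items():
        for b in rng:
            region_lookup[b] = region
    rows = []
    by_chrom = {c: np.unique(grp["pos"].to_numpy()) for c, grp in sites.groupby("chrom")}
    for g in genes:
        if g.end - g.start < scheme.body_bins:
            continue
        pos = by_chrom.get(g.chrom)
        if pos is None:
            continue
        lo, hi = g.start - scheme.flank_bp, g.end + scheme.flank_bp
        window = pos[(pos >= lo) & (pos < hi)]
        for p in window:
            b = bin_index_for_site(g, scheme, int(p))
            if b is not None:
                rows.append((g.chrom, int(p), g.gene_id, b, region_lookup[b]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "bin", "region"])


# ---------------------------------------------------------------------------
# CpG island context


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals (n × 2, sorted output)."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def island_context_classify(
    positions, islands: np.ndarray, shore_bp: int = 2000, shelf_bp: int = 2000
):
    """Classify positions as island / shore / shelf / open_sea.

    ``islands`` is an n × 2 array of half-open intervals on one chromosome
    (merged internally).  Shores are the 2 kb flanks of islands, shelves
    the next 2 kb; the distance to the nearest island decides the class,
    which realises the island > shore > shelf precedence when neighbouring
    islands' derived intervals collide.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    islands = merge_intervals(np.asarray(islands, dtype=np.int64).reshape(-1, 2))
    labels = np.full(pos.shape, "open_sea", dtype=object)
    if len(islands):
        starts, ends = islands[:, 0], islands[:, 1]
        # nearest interval via searchsorted on starts
        idx = np.searchsorted(starts, pos, side="right") - 1
        dist = np.full(pos.shape, np.iinfo(np.int64).max)
        has_left = idx >= 0
        li = np.clip(idx, 0, None)
        inside = has_left & (pos < ends[li])
        dist_left = np.where(has_left, np.maximum(0, pos - (ends[li] - 1)), dist)
        ri = np.clip(idx + 1, None, len(starts) - 1)
        has_right = idx + 1 < len(starts)
        dist_right = np.where(has_right, np.maximum(0, starts[ri] - pos), dist)
        dist = np.minimum(dist_left, dist_right)
        labels[inside] = "island"
        shore = ~inside & (dist <= shore_bp)
        shelf = ~inside & ~shore & (dist <= shore_bp + shelf_bp)
        labels[shore] = "shore"
        labels[shelf] = "shelf"
    if np.isscalar(positions) or np.ndim(positions) == 0:
        return labels[0]
    return labels


def island_context_levels(
    paired: pd.DataFrame, islands: pd.DataFrame, level_cols=("mC_pct", "hmC_pct")
) -> pd.DataFrame:
    """Mean levels per island context (island/shore/shelf/open_sea), CG sites."""
    sub = paired[paired["context"] == "CG"].copy()
    labels = np.full(len(sub), "open_sea", dtype=object)
    for chrom, grp in sub.groupby("chrom"):
        iv = islands.loc[islands["chrom"] == chrom, ["start", "end"]].to_numpy()
        idx = sub.index.get_indexer(grp.index)
        labels[idx] = island_context_classify(grp["pos"].to_numpy(), iv)
    sub["island_context"] = labels
    return sub.groupby("island_context")[list(level_cols)].mean()


# ---------------------------------------------------------------------------
# repeat classes


def _sites_in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of positions falling in any merged half-open interval."""
    if len(intervals) == 0:
        return np.zeros(len(pos), dtype=bool)
    merged = merge_intervals(intervals)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < merged[np.clip(idx[ok], 0, None), 1]
    return res


def repeat_class_levels(
    paired: pd.DataFrame,
    repeats: pd.DataFrame,
    level_map={"mCG": ("CG", "mC_pct"), "hmCG": ("CG", "hmC_pct"),
               "mCH": ("CH", "mC_pct")},
) -> pd.DataFrame:
    """Mean modification levels per repeat class plus the non-repeat rest.

    A site overlapping intervals of several classes counts once in each
    class; ``non_repeat`` covers sites outside every repeat interval.
    Classes with no covered site give NaN.
    """
    classes = sorted(repeats["repeat_class"].unique()) if len(repeats) else []
    masks: dict[str, np.ndarray] = {}
    any_repeat = np.zeros(len(paired), dtype=bool)
    pos_by_chrom = {c: grp for c, grp in paired.groupby("chrom")}
    for cls in classes:
        mask = np.zeros(len(paired), dtype=bool)
        cls_rep = repeats[repeats["repeat_class"] == cls]
        for chrom, grp in pos_by_chrom.items():
            iv = cls_rep.loc[cls_rep["chrom"] == chrom, ["start", "end"]].to_numpy()
            idx = paired.index.get_indexer(grp.index)
            mask[idx] = _sites_in_intervals(grp["pos"].to_numpy(), iv)
        masks[cls] = mask
        any_repeat |= mask
    masks["non_repeat"] = ~any_repeat

    rows = {}
    ctx = paired["context"].to_numpy()
    for name, mask in masks.items():
        row = {}
        for level, (context, col) in level_map.items():
            sel = mask & (ctx == context)
            vals = paired.loc[sel, col]
            row[level] = float(vals.mean()) if vals.notna().any() else float("nan")
        rows[name] = row
    out = pd.DataFrame(rows).T
    out.index.name = "repeat_class"
    return out
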