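"""Synthetic data generator for the paired transcriptome/methylome analysis.

Generates, from one :class:`~oxtrap.config.SimConfig`, everything the
pipeline consumes — gene models, CpG-island and repeat annotations, a
per-cell-type truth methylome, BS/oxBS cytosine call tables for input,
negative and affinity-purified positive fractions, spike-in conversion
controls, negative-binomial TRAP count matrices with planted marker genes,
bisulfite amplicon read sets, and qPCR Ct tables — together with the truth
objects that recovery tests compare against.

The statistical structure emulated:

* a tissue mixture of four cell types; the positive fraction of a target
  type contains that type at ``purity`` with the complementary mixture
  making up the rest, and the negative fraction is the mixture depleted of
  the target proportionally;
* each cell type's own marker-gene promoters (−4 kb .. TSS) are
  hypomethylated relative to the genome-wide mCG baseline;
* hmCG level differs by cell type (lowest in the microglia-like type),
  mCH is low with a sparse high-mCH minority, and hmCH is identically 0;
* BS libraries read mC+hmC as methylated, oxBS libraries read only mC,
  each with configurable conversion errors;
* TRAP counts are negative-binomial with planted positive/input marker
  enrichment and recorded per-sample size factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from oxtrap._seeding import rng_for
from oxtrap.config import SimConfig

logger = logging.getLogger(__name__)

FLANK_BP = 4000

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


@dataclass
class Annotation:
    """Gene models plus CpG-island and repeat intervals (0-based half-open)."""

    genes: pd.DataFrame      # gene_id, chrom, start, end, strand
    islands: pd.DataFrame    # chrom, start, end
    repeats: pd.DataFrame    # chrom, start, end, repeat_class


@dataclass
class TruthSet:
    """Ground-truth methylome and mixture structure behind the call tables."""

    marker_sets: dict[str, list[str]]
    sites: pd.DataFrame  # chrom, pos, strand, context + mC_<ct>, hmC_<ct> columns
    expected_fraction_mixtures: dict[str, dict[str, float]]

    def mixture_modification(self, fraction: str) -> tuple[np.ndarray, np.ndarray]:
        """Effective (mC, hmC) truth fractions per site for a named fraction."""
        weights = self.expected_fraction_mixtures[fraction]
        mC = np.zeros(len(self.sites))
        hmC = np.zeros(len(self.sites))
        for ct, w in weights.items():
            mC += w * self.sites[f"mC_{ct}"].to_numpy()
            hmC += w * self.sites[f"hmC_{ct}"].to_numpy()
        return mC, hmC


@dataclass
class CallTables:
    """BS/oxBS cytosine call tables per fraction and replicate, plus spike-ins.

    ``tables[(fraction, replicate, library)]`` is a site-call DataFrame with
    columns chrom, pos, strand, context, meth_count, total_count.  Fractions
    are named ``input``, ``positive:<cell_type>``, ``negative:<cell_type>``;
    libraries are ``BS`` and ``oxBS``.
    """

    tables: dict[tuple[str, int, str], pd.DataFrame]
    spikein: pd.DataFrame  # site_id, true_class, library, meth_count, total_count
    spikein_truth: pd.DataFrame = field(default=None)  # site_id, true_class


def fraction_mixtures(config: SimConfig) -> dict[str, dict[str, float]]:
    """Effective cell-type composition of every simulated fraction."""
    cts = list(config.cell_types)
    props = dict(zip(cts, config.mixture_proportions))
    mixtures = {"input": dict(props)}
    for target in cts:
        others = {ct: p for ct, p in props.items() if ct != target}
        other_total = sum(others.values())
        pos = {ct: (1.0 - config.purity) * p / other_total for ct, p in others.items()}
        pos[target] = config.purity
        mixtures[f"positive:{target}"] = pos
        neg = dict(props)
        neg[target] = props[target] * (1.0 - config.purity)
        s = sum(neg.values())
        mixtures[f"negative:{target}"] = {ct: p / s for ct, p in neg.items()}
    return mixtures


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> Annotation:
    """Pack non-overlapping gene models onto chromosomes; add islands/repeats.

    Gene bodies are 2–6 kb, separated by their 4 kb flanks plus a random
    gap, so promoters never collide.  CpG islands sit on a random subset of
    promoters (plus a few intergenic ones); repeats are random intervals
    labelled LINE/SINE/LTR/simple.
    """
    rng = rng_for(config.seed, "annotation")
    body_range, gap_range = config.gene_body_range, config.gene_gap_range
    footprint = 2 * FLANK_BP + body_range[1] + gap_range[1]
    per_chrom = -(-config.n_genes // config.n_chromosomes) if config.n_genes else 0
    if per_chrom * footprint > config.chrom_length_bp:
        raise ValueError(
            f"cannot pack {per_chrom} genes of max footprint {footprint} bp "
            f"onto a {config.chrom_length_bp} bp chromosome; increase "
            "chrom_length_bp or n_chromosomes, or reduce n_genes"
        )
    records = []
    for gi in range(config.n_genes):
        chrom_i = gi % config.n_chromosomes
        records.append((gi, f"chr{chrom_i + 1}"))
    genes = []
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    for gi, chrom in records:
        gap = int(rng.integers(*gap_range))
        body = int(rng.integers(*body_range))
        start = cursors[chrom] + gap + FLANK_BP
        end = start + body
        cursors[chrom] = end + FLANK_BP
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"g{gi:04d}", chrom, start, end, strand))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])

    # islands: ~40% of promoters carry one, plus sparse intergenic islands
    islands = []
    for _, g in genes_df.iterrows():
        if rng.random() < 0.4:
            tss = g.start if g.strand == "+" else g.end - 1
            islands.append((g.chrom, max(0, tss - 500), tss + 500))
    for i in range(config.n_chromosomes):
        for _ in range(5):
            s = int(rng.integers(0, max(1, config.chrom_length_bp - 1000)))
            islands.append((f"chr{i + 1}", s, s + int(rng.integers(300, 1000))))
    islands_df = (
        pd.DataFrame(islands, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    repeats = []
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        for cls, n in (("LINE", 40), ("SINE", 60), ("LTR", 30), ("simple", 30)):
            starts = rng.integers(0, config.chrom_length_bp - 1000, size=n)
            lengths = rng.integers(200, 1000, size=n)
            for s, L in zip(starts, lengths):
                repeats.append((chrom, int(s), int(s + L), cls))
    repeats_df = (
        pd.DataFrame(repeats, columns=["chrom", "start", "end", "repeat_class"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    return Annotation(genes=genes_df, islands=islands_df, repeats=repeats_df)


# ---------------------------------------------------------------------------
# methylome truth


def _beta_around(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    """Beta draws with given mean and concentration, tolerant of 0/1 means."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-6, 1 - 1e-6)
    return rng.beta(mean * conc, (1 - mean) * conc)


def simulate_methylome_truth(config: SimConfig, annotation: Annotation) -> TruthSet:
    """Per-site, per-cell-type (mC, hmC) truth fractions.

    CG sites: promoter sites of a cell type's own markers centre on
    ``marker_promoter_mCG`` for that type, island sites on ``island_mCG``,
    all others on ``baseline_mCG``; hmCG centres on the type's entry in
    ``hmCG_by_type`` (clipped so mC + hmC ≤ 1).  CH sites centre on
    ``mCH_baseline`` except a ``high_mCH_site_rate`` minority drawn
    uniformly in ``high_mCH_range``; hmCH is identically zero.
    """
    rng = rng_for(config.seed, "methylome_truth")
    genes = annotation.genes
    cts = list(config.cell_types)

    marker_sets: dict[str, list[str]] = {}
    gene_ids = genes["gene_id"].tolist()
    order = rng.permutation(len(gene_ids))
    k = config.n_markers_per_type
    if k * len(cts) > len(gene_ids):
        raise ValueError("n_genes too small for requested markers per type")
    for i, ct in enumerate(cts):
        marker_sets[ct] = sorted(gene_ids[j] for j in order[i * k:(i + 1) * k])
    marker_of = {g: ct for ct, gs in marker_sets.items() for g in gs}

    chroms, positions, strands, contexts = [], [], [], []
    owner_ct = []  # cell type whose marker promoter hosts the site, else ""
    in_island_flag = []

    island_by_chrom = {
        c: sub[["start", "end"]].to_numpy()
        for c, sub in annotation.islands.groupby("chrom")
    }

    def in_island(chrom: str, pos_arr: np.ndarray) -> np.ndarray:
        iv = island_by_chrom.get(chrom)
        if iv is None or not len(iv):
            return np.zeros(len(pos_arr), dtype=bool)
        hit = np.zeros(len(pos_arr), dtype=bool)
        for s, e in iv:
            hit |= (pos_arr >= s) & (pos_arr < e)
        return hit

    for _, g in genes.iterrows():
        if g.strand == "+":
            prom_lo, prom_hi = g.start - FLANK_BP, g.start
        else:
            prom_lo, prom_hi = g.end, g.end + FLANK_BP
        prom = np.sort(rng.integers(prom_lo, prom_hi, size=config.promoter_cg_sites))
        body = np.sort(rng.integers(g.start, g.end, size=config.body_cg_sites))
        for arr, owner in ((prom, marker_of.get(g.gene_id, "")), (body, "")):
            n = len(arr)
            chroms.extend([g.chrom] * n)
            positions.extend(arr.tolist())
            strands.extend(rng.choice(["+", "-"], size=n).tolist())
            contexts.extend(["CG"] * n)
            owner_ct.extend([owner] * n)
            in_island_flag.extend(in_island(g.chrom, arr).tolist())

    n_chrom = config.n_chromosomes
    for kind, total, ctx in (("cg", config.n_intergenic_cg, "CG"),
                             ("ch", config.n_ch_sites, "CH")):
        for i in range(n_chrom):
            chrom = f"chr{i + 1}"
            n = total // n_chrom
            arr = np.sort(rng.integers(0, config.chrom_length_bp, size=n))
            chroms.extend([chrom] * n)
            positions.extend(arr.tolist())
            strands.extend(rng.choice(["+", "-"], size=n).tolist())
            contexts.extend([ctx] * n)
            owner_ct.extend([""] * n)
            in_island_flag.extend(in_island(chrom, arr).tolist())

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strands,
            "context": contexts,
            "_owner": owner_ct,
            "_island": in_island_flag,
        }
    )
    sites = sites.drop_duplicates(["chrom", "pos", "strand"]).reset_index(drop=True)

    is_cg = (sites["context"] == "CG").to_numpy()
    is_island = sites["_island"].to_numpy() & is_cg
    n_sites = len(sites)

    # CH high-mCH minority, shared across cell types (site-level feature)
    is_ch = ~is_cg
    high_ch = is_ch & (rng.random(n_sites) < config.high_mCH_site_rate)
    lo, hi = config.high_mCH_range
    high_vals = rng.uniform(lo, hi, size=n_sites)

    for ct in cts:
        mean = np.full(n_sites, config.baseline_mCG)
        own = (sites["_owner"] == ct).to_numpy()
        mean[own] = config.marker_promoter_mCG
        # islands are hypomethylated in every cell type and take precedence
        mean[is_island] = config.island_mCG
        mean[is_ch] = config.mCH_baseline
        mC = _beta_around(rng, mean, 50.0)
        mC[high_ch] = high_vals[high_ch]
        hmC = np.zeros(n_sites)
        hm_mean = config.hmCG_by_type[ct]
        if hm_mean > 0:
            hmC[is_cg] = _beta_around(rng, np.full(is_cg.sum(), hm_mean), 50.0)
        hmC = np.minimum(hmC, 1.0 - mC)  # conservation: mC + hmC <= 1
        sites[f"mC_{ct}"] = mC
        sites[f"hmC_{ct}"] = hmC

    sites = sites.drop(columns=["_owner", "_island"])
    return TruthSet(
        marker_sets=marker_sets,
        sites=sites,
        expected_fraction_mixtures=fraction_mixtures(config),
    )


# ---------------------------------------------------------------------------
# call tables


def _apparent_probs(
    f_mC: np.ndarray, f_hmC: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent methylated-call probabilities in the BS and oxBS libraries.

    BS reads mC and hmC as methylated (each retained with eff_mC); oxBS
    converts hmC with eff_hmC so only mC is read as methylated.  An
    unmethylated C escapes conversion with 1 - eff_C in either library.
    """
    f_C = 1.0 - f_mC - f_hmC
    p_bs = (f_mC + f_hmC) * config.conversion_eff_mC + f_C * (1 - config.conversion_eff_C)
    p_ox = (
        f_mC * config.conversion_eff_mC
        + f_hmC * (1 - config.conversion_eff_hmC)
        + f_C * (1 - config.conversion_eff_C)
    )
    return np.clip(p_bs, 0, 1), np.clip(p_ox, 0, 1)


def simulate_call_tables(truth: TruthSet, config: SimConfig) -> CallTables:
    """BS and oxBS site-call tables for every fraction and replicate.

    Per site and replicate, total_count ~ Poisson(coverage_mean) and the
    methylated count is Binomial(total, p) with p the conversion-adjusted
    apparent probability of the library.  Sites with zero coverage are
    dropped (uncovered cytosines do not appear in call reports).  Spike-in
    controls carry pure C / mC / hmC sites with known truth.
    """
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    base = truth.sites[["chrom", "pos", "strand", "context"]]
    n_sites = len(base)
    tables: dict[tuple[str, int, str], pd.DataFrame] = {}
    for fraction in truth.expected_fraction_mixtures:
        f_mC, f_hmC = truth.mixture_modification(fraction)
        p_bs, p_ox = _apparent_probs(f_mC, f_hmC, config)
        for rep in range(1, config.n_methylome_replicates + 1):
            for lib, p in (("BS", p_bs), ("oxBS", p_ox)):
                rng = rng_for(config.seed, f"calls:{fraction}:{rep}:{lib}")
                total = rng.poisson(config.coverage_mean, size=n_sites)
                meth = rng.binomial(total, p)
                df = base.copy()
                df["meth_count"] = meth
                df["total_count"] = total
                df = df[df["total_count"] > 0].reset_index(drop=True)
                tables[(fraction, rep, lib)] = df

    spike_truth = {"C": (0.0, 0.0), "mC": (1.0, 0.0), "hmC": (0.0, 1.0)}
    rng = rng_for(config.seed, "spikein")
    rows = []
    truth_rows = []
    for cls, (f_mC, f_hmC) in spike_truth.items():
        for i in range(config.n_spikein_per_class):
            site_id = f"spike_{cls}_{i:03d}"
            truth_rows.append((site_id, cls))
            p_bs, p_ox = _apparent_probs(np.array([f_mC]), np.array([f_hmC]), config)
            for lib, p in (("BS", p_bs[0]), ("oxBS", p_ox[0])):
                total = int(rng.poisson(config.spikein_coverage))
                meth = int(rng.binomial(total, p)) if total else 0
                rows.append((site_id, cls, lib, meth, total))
    spike = pd.DataFrame(
        rows, columns=["site_id", "true_class", "library", "meth_count", "total_count"]
    )
    spike_truth_df = pd.DataFrame(truth_rows, columns=["site_id", "true_class"])
    return CallTables(tables=tables, spikein=spike, spikein_truth=spike_truth_df)


# ---------------------------------------------------------------------------
# TRAP counts


@dataclass
class TrapTruth:
    """Planted structure behind a simulated TRAP count matrix."""

    target: str
    marker_sets: dict[str, list[str]]
    size_factors: pd.Series
    expected_fc: pd.Series  # expected positive/input ratio per gene


def simulate_trap_counts(
    config: SimConfig,
    target: str | None = None,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    study: str = "nutrap",
    treatment: str = "none",
):
    """Negative-binomial gene × sample counts for one affinity-purified model.

    ``target`` names the cell type captured in the positive fraction
    (default: first configured type).  The planted expected positive/input
    ratio is ``marker_enrichment_fc`` for the target's own markers,
    ``1/fc`` for other types' markers and 1 for background genes; the
    negative fraction has input-like means.  Per-sample library size
    factors are drawn log-normally and recorded in the truth.

    Returns ``(CountMatrix, TrapTruth)``; :class:`CountMatrix` is defined
    in :mod:`oxtrap.expression`.
    """
    from oxtrap.expression import CountMatrix

    if config.n_samples_per_group < 2:
        raise ValueError("n_samples_per_group must be >= 2 for downstream statistics")
    cts = list(config.cell_types)
    if target is None:
        target = cts[0]
    if target not in cts:
        raise ValueError(f"unknown target cell type {target!r}")

    rng = rng_for(config.seed, f"trap:{study}:{target}:{treatment}")
    if marker_sets is None:
        pool = [f"g{gi:04d}" for gi in range(config.n_genes)]
        k = config.n_markers_per_type
        order = rng.permutation(len(pool))
        marker_sets = {
            ct: sorted(pool[j] for j in order[i * k:(i + 1) * k])
            for i, ct in enumerate(cts)
        }
        gene_ids = pool
    else:
        marker_sets = {ct: list(gs) for ct, gs in marker_sets.items()}
        gene_ids = sorted({g for gs in marker_sets.values() for g in gs})
    # background genes pad the universe to transcriptome scale so that the
    # median-of-ratios assumption (most genes unchanged) holds
    n_bg = max(0, config.n_rna_genes - len(gene_ids))
    gene_ids = gene_ids + [f"bg{gi:04d}" for gi in range(n_bg)]

    genes = sorted(gene_ids)
    marker_of = {g: ct for ct, gs in marker_sets.items() for g in gs}
    fc = config.marker_enrichment_fc
    effect = np.ones(len(genes))
    for i, g in enumerate(genes):
        ct = marker_of.get(g)
        if ct == target:
            effect[i] = fc
        elif ct is not None:
            effect[i] = 1.0 / fc

    base = np.exp(rng.normal(np.log(150.0), 1.0, size=len(genes)))
    base = np.maximum(base, 5.0)

    n = config.n_samples_per_group
    samples, fractions, subjects = [], [], []
    for frac in ("input", "negative", "positive"):
        for i in range(1, n + 1):
            samples.append(f"{study}_{target}_{frac}_{i}")
            fractions.append(frac)
            subjects.append(f"{study}_{target}_s{i}")
    sf = pd.Series(
        np.exp(rng.normal(0.0, 0.3, size=len(samples))), index=samples, name="size_factor"
    )

    disp = config.nb_dispersion
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, (smp, frac) in enumerate(zip(samples, fractions)):
        mu = base * (effect if frac == "positive" else 1.0) * sf[smp]
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "fraction": fractions,
            "treatment": treatment,
            "study": study,
            "subject": subjects,
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(counts=counts_df, meta=meta)
    truth = TrapTruth(
        target=target,
        marker_sets={ct: list(gs) for ct, gs in marker_sets.items()},
        size_factors=sf,
        expected_fc=pd.Series(effect, index=genes, name="expected_fc"),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# amplicon reads


def simulate_amplicon_reads(
    reference: str,
    site_probs: Mapping[int, float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Bisulfite images of an amplicon reference.

    Each read converts every reference C to T unless that position is
    methylated, which happens independently per read with the site's truth
    probability (``site_probs``; positions absent from the mapping are
    unmethylated).  Non-C positions acquire substitution errors at
    ``error_rate``.
    """
    if not 50 <= len(reference) <= 1000:
        raise ValueError("reference length must be in [50, 1000]")
    bad = [o for o in site_probs if reference[o].upper() != "C"]
    if bad:
        raise ValueError(f"site offsets not at a reference C: {bad}")
    if n_reads == 0:
        return []
    rng = rng_for(seed, "amplicon_reads")
    ref = np.frombuffer(reference.upper().encode(), dtype="S1")
    L = len(ref)
    c_mask = ref == b"C"
    probs = np.zeros(L)
    for o, p in site_probs.items():
        probs[o] = p
    others = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

    reads = []
    for _ in range(n_reads):
        out = ref.copy()
        meth = rng.random(L) < probs
        out[c_mask & ~meth] = b"T"
        # retained (methylated) C stays C
        if error_rate > 0:
            err = (~c_mask) & (rng.random(L) < error_rate)
            for idx in np.nonzero(err)[0]:
                choices = others[others != ref[idx]]
                out[idx] = rng.choice(choices)
        reads.append(out.tobytes().decode())
    return reads


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr_cts(
    config: SimConfig,
    genes: Sequence[str],
    log2_effects: Mapping[str, Mapping[str, float]],
    control_gene: str = "Hprt",
    groups: Sequence[str] = ("input", "negative", "positive"),
    sd: float = 0.15,
    seed_label: str = "qpcr",
) -> pd.DataFrame:
    """Ct tables with planted log2 expression effects per gene and group.

    ``log2_effects[gene][group]`` is the planted log2 expression relative
    to the calibrator; Ct decreases by one cycle per doubling.  The control
    gene is flat across groups.  Returns a long table (sample, group, gene,
    ct).
    """
    rng = rng_for(config.seed, seed_label)
    rows = []
    for group in groups:
        for i in range(1, config.n_samples_per_group + 1):
            sample = f"{group}_{i}"
            rows.append((sample, group, control_gene, rng.normal(20.0, sd)))
            for gene in genes:
                eff = log2_effects.get(gene, {}).get(group, 0.0)
                rows.append((sample, group, gene, rng.normal(25.0 - eff, sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
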