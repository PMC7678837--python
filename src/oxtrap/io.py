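"""Format readers/writers and end-to-end pipeline orchestration.

Table dialects are plain TSV.  The cytosine call dialect is
(chrom, pos, strand, context, meth_count, total_count) with 1-based
positions on disk and 0-based half-open coordinates in memory; a
``bismark_cov`` mapping flag accepts bismark coverage-style columns
(chrom, start, end, percentage, meth, unmeth).  Every file written
carries a header comment naming the producing version and seed.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import oxtrap
from oxtrap import bsas, expression, integrate, methylome, regions, simulate
from oxtrap._seeding import rng_for
from oxtrap.config import RunConfig, SimConfig

logger = logging.getLogger(__name__)

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


def _header(seed) -> str:
    return f"# oxtrap={oxtrap.__version__} seed={seed}\n"


def write_table(df: pd.DataFrame, path, seed="NA", index: bool = False) -> Path:
    """Write a TSV with the version/seed provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, float_format="%.6g")
    path.write_text(_header(seed) + buf.getvalue())
    return path


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# cytosine call tables


def write_cytosine_table(df: pd.DataFrame, path, seed="NA") -> Path:
    """Write site calls with 1-based positions (the call-report convention)."""
    out = df[CYTOSINE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    return write_table(out, path, seed=seed)


def read_cytosine_table(path, dialect: str = "oxtrap") -> pd.DataFrame:
    """Read a per-cytosine call table into the internal 0-based dialect.

    ``dialect='oxtrap'``: chrom, pos(1-based), strand, context, meth_count,
    total_count.  ``dialect='bismark_cov'``: chrom, start(1-based), end,
    percentage, meth, unmeth — strand defaults to '+' and context to CG.
    Malformed rows (meth > total, negative counts) are rejected and logged
    with their line numbers.
    """
    if dialect == "oxtrap":
        df = read_table(path)
        missing = set(CYTOSINE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
    elif dialect == "bismark_cov":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "end", "pct", "meth_count", "unmeth"],
        )
        df["total_count"] = df["meth_count"] + df["unmeth"]
        df["strand"] = "+"
        df["context"] = "CG"
        df = df[CYTOSINE_COLUMNS]
    else:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: 'oxtrap', 'bismark_cov'"
        )
    if df.empty:
        logger.warning("read_cytosine_table: %s is empty", path)
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    bad = (
        (df["meth_count"] > df["total_count"])
        | (df["meth_count"] < 0)
        | (df["total_count"] < 0)
        | ~df["strand"].isin(["+", "-"])
    )
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based incl. header
        logger.warning("read_cytosine_table: rejected %d malformed row(s) "
                       "at line(s) %s", int(bad.sum()), lines[:20])
        df = df[~bad]
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED


def write_bed(df: pd.DataFrame, path, seed="NA") -> Path:
    """Write BED (half-open, 0-based) with name/score/strand when present."""
    cols = ["chrom", "start", "end"]
    out = df.copy()
    if "name" not in out.columns:
        for alt in ("gene_id", "repeat_class"):
            if alt in out.columns:
                out["name"] = out[alt]
                break
    if "name" in out.columns:
        cols.append("name")
        if "score" not in out.columns:
            out["score"] = 0
        cols.append("score")
        if "strand" in out.columns:
            cols.append("strand")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    out[cols].to_csv(buf, sep="\t", index=False, header=False)
    path.write_text(_header(seed) + buf.getvalue())
    return path


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a sorted half-open interval table.

    Strand defaults to '+' when absent; rows with end ≤ start are rejected
    and logged.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    for col in ("name", "score", "strand"):
        if col not in df.columns:
            df[col] = {"name": ".", "score": 0, "strand": "+"}[col]
    bad = df["end"] <= df["start"]
    if bad.any():
        logger.warning("read_bed: rejected %d row(s) with end <= start", int(bad.sum()))
        df = df[~bad]
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# counts + metadata


def write_count_matrix(cm: expression.CountMatrix, counts_path, meta_path, seed="NA"):
    write_table(cm.counts, counts_path, seed=seed, index=True)
    write_table(cm.meta.reset_index(), meta_path, seed=seed)


def read_count_matrix(counts_path, meta_path) -> expression.CountMatrix:
    counts = read_table(counts_path, index_col=0)
    meta = read_table(meta_path).set_index("sample")
    return expression.CountMatrix(counts=counts, meta=meta)


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None and line.strip():
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# full pipeline


def _pool_replicates(paired_by_rep: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-site levels over replicates (site-wise mean of percents)."""
    cat = pd.concat(paired_by_rep, ignore_index=True)
    return (
        cat.groupby(["chrom", "pos", "strand", "context"], as_index=False)
        .agg(mC_pct=("mC_pct", "mean"), hmC_pct=("hmC_pct", "mean"),
             bs_cov=("bs_cov", "sum"), oxbs_cov=("oxbs_cov", "sum"))
    )


def _synthetic_amplicon(rng: np.random.Generator, n_cg: int = 8, length: int = 300) -> str:
    """Random amplicon reference carrying ``n_cg`` CG dinucleotides."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    seq[seq == "C"] = "A"  # clear incidental C, then plant CGs
    pos = np.linspace(10, length - 12, n_cg).astype(int)
    for p in pos:
        seq[p], seq[p + 1] = "C", "G"
    return "".join(seq)


def run_full_pipeline(config: RunConfig) -> dict:
    """Generate → analyse → compare against truth; return the summary bundle.

    Synthetic mode runs every analysis arm on one generated dataset:
    per-fraction genome-wide modification levels and spike-in conversion
    efficiencies, metagene/region methylation with group comparison,
    island-context and repeat-class levels, TRAP marker recovery
    (sensitivity/precision against the planted lists), a BSAS amplicon
    fraction comparison, qPCR relative quantification, and the
    methylation–expression integration with Bonferroni control.  All
    randomness derives from ``config.seed``; repeated runs are identical.
    """
    if config.mode != "synthetic":
        return _run_real_pipeline(config)
    sim = config.sim or SimConfig(seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = sim.seed

    ann = simulate.simulate_annotation(sim)
    truth = simulate.simulate_methylome_truth(sim, ann)
    calls = simulate.simulate_call_tables(truth, sim)
    cts = list(sim.cell_types)

    write_bed(ann.genes, outdir / "genes.bed", seed)
    write_bed(ann.islands, outdir / "cpg_islands.bed", seed)
    write_bed(ann.repeats, outdir / "repeats.bed", seed)

    # --- methylome arm -----------------------------------------------------
    fractions = list(truth.expected_fraction_mixtures)
    paired: dict[tuple[str, int], pd.DataFrame] = {}
    for fraction in fractions:
        for rep in range(1, sim.n_methylome_replicates + 1):
            paired[(fraction, rep)] = methylome.pair_call_tables(
                calls.tables[(fraction, rep, "BS")],
                calls.tables[(fraction, rep, "oxBS")],
            )
    write_cytosine_table(calls.tables[("input", 1, "BS")],
                         outdir / "calls_input_rep1_BS.tsv", seed)
    write_cytosine_table(calls.tables[("input", 1, "oxBS")],
                         outdir / "calls_input_rep1_oxBS.tsv", seed)

    levels_rows = []
    for fraction in fractions:
        per_rep = [
            methylome.genome_wide_levels(paired[(fraction, rep)],
                                         min_coverage=config.min_coverage)
            for rep in range(1, sim.n_methylome_replicates + 1)
        ]
        mean_levels = {k: float(np.mean([r[k] for r in per_rep])) for k in per_rep[0]}
        levels_rows.append({"fraction": fraction, **mean_levels})
    genome_levels = pd.DataFrame(levels_rows).set_index("fraction")
    write_table(genome_levels.reset_index(), outdir / "genome_levels.tsv", seed)

    conv = methylome.conversion_efficiency(calls.spikein)

    # --- region arm --------------------------------------------------------
    site_map = regions.assign_sites_to_genes(
        truth.sites[truth.sites["context"] == "CG"], ann.genes
    )
    region_values = {}  # (fraction, rep) -> gene x region mean mCG
    for (fraction, rep), table in paired.items():
        cg = table[(table["context"] == "CG")
                   & (table["bs_cov"] >= config.min_coverage)
                   & (table["oxbs_cov"] >= config.min_coverage)]
        merged = cg.merge(site_map, on=["chrom", "pos"])
        region_values[(fraction, rep)] = (
            merged.groupby(["gene_id", "region"])["mC_pct"].mean().unstack()
        )

    pooled_input = _pool_replicates(
        [paired[("input", r)] for r in range(1, sim.n_methylome_replicates + 1)]
    )
    gene_frame = ann.genes.set_index("gene_id")
    profiles = {}
    region_comparisons = {}
    for ct in cts:
        marker_genes = regions.genes_from_frame(
            gene_frame.loc[truth.marker_sets[ct]].reset_index()
        )
        pooled_pos = _pool_replicates(
            [paired[(f"positive:{ct}", r)]
             for r in range(1, sim.n_methylome_replicates + 1)]
        )
        profiles[ct] = {
            "positive": regions.metagene_profile(
                pooled_pos[pooled_pos["context"] == "CG"], marker_genes
            ),
            "input": regions.metagene_profile(
                pooled_input[pooled_input["context"] == "CG"], marker_genes
            ),
        }
        rows = []
        for fraction in ("input", f"positive:{ct}", f"negative:{ct}"):
            for rep in range(1, sim.n_methylome_replicates + 1):
                rv = region_values[(fraction, rep)].reindex(truth.marker_sets[ct])
                for region in ("upstream", "body", "downstream"):
                    if region in rv.columns:
                        rows.append((f"{fraction}:{rep}", fraction, region,
                                     float(rv[region].mean())))
        vals = pd.DataFrame(rows, columns=["sample", "group", "region", "value"])
        region_comparisons[ct] = regions.region_group_comparison(vals)
        write_table(vals, outdir / f"region_values_{ct}.tsv", seed)

    profile_rows = []
    for ct in cts:
        for frac, prof in profiles[ct].items():
            for b, v in enumerate(prof.bin_means):
                profile_rows.append((ct, frac, b, v))
    write_table(
        pd.DataFrame(profile_rows, columns=["cell_type", "fraction", "bin", "mCG"]),
        outdir / "metagene_profiles.tsv", seed,
    )

    island_levels = regions.island_context_levels(pooled_input, ann.islands)
    repeat_levels = regions.repeat_class_levels(pooled_input, ann.repeats)
    write_table(island_levels.reset_index(), outdir / "island_context_levels.tsv", seed)
    write_table(repeat_levels.reset_index(), outdir / "repeat_class_levels.tsv", seed)

    # --- expression arm ----------------------------------------------------
    expr_summary = {}
    norm_by_ct = {}
    for ct in cts:
        cm, trap_truth = simulate.simulate_trap_counts(
            sim, target=ct, marker_sets=truth.marker_sets
        )
        sf = expression.size_factors(cm.counts)
        norm = expression.normalize_counts(cm.counts, sf)
        kept = expression.filter_expressed(
            norm, cm.meta["fraction"], threshold=config.expression_filter
        )
        de = expression.differential_expression(
            norm.loc[kept], cm.meta, factor="fraction"
        )
        markers = expression.define_marker_genes(
            de, ct, fc_cutoff=config.fc_cutoff_marker, q_cutoff=config.q_cutoff
        )
        planted = set(truth.marker_sets[ct])
        found = set(markers.genes)
        tp = len(found & planted)
        expr_summary[ct] = {
            "n_genes_total": int(len(cm.counts)),
            "n_genes_expressed": int(len(kept)),
            "n_markers_found": len(found),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(found) if found else float("nan"),
        }
        norm_by_ct[ct] = (norm, cm.meta)
        write_count_matrix(cm, outdir / f"counts_{ct}.tsv",
                           outdir / f"samples_{ct}.tsv", seed)
        write_table(de.table.reset_index(names="gene_id"),
                    outdir / f"de_{ct}.tsv", seed)
        write_table(pd.DataFrame({"gene_id": markers.genes}),
                    outdir / f"markers_{ct}.tsv", seed)

    # --- integration arm ---------------------------------------------------
    n_rep = sim.n_methylome_replicates
    pos_col_for = {ct: f"positive:{ct}" for ct in cts}
    upstream_means = pd.DataFrame({
        fraction: pd.concat(
            [region_values[(fraction, r)]["upstream"] for r in range(1, n_rep + 1)],
            axis=1,
        ).mean(axis=1)
        for fraction in fractions
    })
    concordance = integrate.concordance_report(
        truth.marker_sets, upstream_means, pos_col_for
    )
    write_table(concordance, outdir / "concordance.tsv", seed)

    correlation_summary = {}
    for ct in cts:
        norm, meta = norm_by_ct[ct]
        obs_rows = []
        genes_tested = [g for gs in truth.marker_sets.values() for g in gs]
        # input and positive fractions only: the correlation design pairs the
        # pre-capture homogenate with the captured fraction per subject
        for fraction, meth_fraction in (("input", "input"),
                                        ("positive", f"positive:{ct}")):
            rna_samples = meta.index[meta["fraction"] == fraction]
            for rep in range(1, n_rep + 1):
                if rep - 1 >= len(rna_samples):
                    break
                smp = rna_samples[rep - 1]
                rv = region_values[(meth_fraction, rep)]
                for gene in genes_tested:
                    if gene in rv.index and gene in norm.index:
                        meth_v = rv.loc[gene].get("upstream", np.nan)
                        obs_rows.append(
                            (gene, f"{fraction}:{rep}", meth_v,
                             float(np.log2(norm.loc[gene, smp] + 1)))
                        )
        obs = pd.DataFrame(obs_rows, columns=["gene", "subject", "meth", "expr"])
        # each model's panel is corrected over its own gene count, the way a
        # targeted panel is analysed
        own_obs = obs[obs["gene"].isin(truth.marker_sets[ct])]
        other_obs = obs[~obs["gene"].isin(truth.marker_sets[ct])]
        corr_own = integrate.methylation_expression_correlation(own_obs)
        corr_other = integrate.methylation_expression_correlation(other_obs)
        neg_sig = corr_own[(corr_own["r"] < 0) & corr_own["significant"]]
        correlation_summary[ct] = {
            "n_own_markers": int(len(corr_own)),
            "own_mean_r": float(corr_own["r"].mean()),
            "own_negative_significant_fraction":
                float(len(neg_sig) / len(corr_own)) if len(corr_own) else float("nan"),
            "other_flagged_fraction":
                float(corr_other["significant"].mean()) if len(corr_other) else float("nan"),
            "bonferroni_threshold": float(corr_own.attrs["bonferroni_threshold"]),
        }
        write_table(corr_own, outdir / f"meth_expr_correlation_{ct}.tsv", seed)

    # --- BSAS arm ----------------------------------------------------------
    rng = rng_for(seed, "pipeline:bsas")
    ref = bsas.AmpliconRef("amp1", _synthetic_amplicon(rng))
    truth_by_fraction = {"input": 0.65, "negative": 0.70, "positive": 0.35}
    n_animals = max(3, sim.n_samples_per_group)
    site_rows = []
    for animal in range(1, n_animals + 1):
        for fraction, level in truth_by_fraction.items():
            probs = {
                o: float(np.clip(level + rng.normal(0, 0.03), 0, 1))
                for o in ref.c_offsets
            }
            reads = simulate.simulate_amplicon_reads(
                ref.sequence, probs, n_reads=300,
                seed=int(rng.integers(2**31)),
            )
            called = bsas.call_amplicon_methylation(reads, ref)
            cg = called[called["context"] == "CG"]
            site_rows.append((f"a{animal}", fraction, float(cg["pct"].mean())))
    bsas_values = pd.DataFrame(site_rows, columns=["subject", "fraction", "value"])
    bsas_cmp = bsas.compare_amplicon_fractions(bsas_values)
    pos_vs_input = next(
        c for c in bsas_cmp["tukey"]
        if {c.level_a, c.level_b} == {"positive", "input"}
    )
    write_table(bsas_values, outdir / "bsas_region_means.tsv", seed)

    # --- qPCR arm ----------------------------------------------------------
    qpcr_genes = truth.marker_sets[cts[0]][:3]
    log2fc = float(np.log2(sim.marker_enrichment_fc))
    ct_table = simulate.simulate_qpcr_cts(
        sim, qpcr_genes, {g: {"positive": log2fc} for g in qpcr_genes}
    )
    cal = ct_table.loc[ct_table["group"] == "input", "sample"].unique()
    rq = expression.relative_quantification(ct_table, "Hprt", list(cal))
    pos_samples = ct_table.loc[ct_table["group"] == "positive", "sample"].unique()
    rq_pos = rq[rq["sample"].isin(pos_samples)]
    qpcr_recovered_fc = float(np.exp(np.log(rq_pos["rq"]).mean()))
    write_table(rq, outdir / "qpcr_rq.tsv", seed)

    summary = {
        "version": oxtrap.__version__,
        "seed": seed,
        "genome_levels": {
            f: {k: genome_levels.loc[f, k] for k in genome_levels.columns}
            for f in genome_levels.index
        },
        "conversion": {"eff_C": conv.eff_C, "eff_mC": conv.eff_mC,
                       "eff_hmC": conv.eff_hmC},
        "expression": expr_summary,
        "concordance": {
            r.cell_type: {
                "fraction_hypomethylated": r.fraction_hypomethylated,
                "sign_test_p": r.sign_test_p,
                "n_tested": int(r.n_tested),
            }
            for r in concordance.itertuples()
        },
        "correlation": correlation_summary,
        "region_sidak_min_p": {
            ct: float(region_comparisons[ct]["pairwise"]["p_sidak"].min())
            for ct in cts
        },
        "bsas": {"F": bsas_cmp["F"], "p": bsas_cmp["p"],
                 "tukey_positive_vs_input_p": pos_vs_input.p},
        "qpcr_recovered_fc": qpcr_recovered_fc,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _run_real_pipeline(config: RunConfig) -> dict:
    """Real-data mode: read user tables and run the analysis arms present."""
    paths = {k: Path(v) for k, v in config.paths.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bs = read_cytosine_table(paths["cytosine_bs"])
    ox = read_cytosine_table(paths["cytosine_oxbs"])
    paired = methylome.pair_call_tables(bs, ox)
    levels = methylome.genome_wide_levels(paired, min_coverage=config.min_coverage)

    genes_bed = read_bed(paths["genes_bed"])
    genes_bed = genes_bed.rename(columns={"name": "gene_id"})
    profile = regions.metagene_profile(
        paired[paired["context"] == "CG"], genes_bed
    )

    cm = read_count_matrix(paths["counts"], paths["metadata"])
    sf = expression.size_factors(cm.counts)
    norm = expression.normalize_counts(cm.counts, sf)
    kept = expression.filter_expressed(
        norm, cm.meta["fraction"], threshold=config.expression_filter
    )
    de = expression.differential_expression(norm.loc[kept], cm.meta)
    markers = expression.define_marker_genes(
        de, "target", fc_cutoff=config.fc_cutoff_marker, q_cutoff=config.q_cutoff
    )
    write_table(de.table.reset_index(names="gene_id"), outdir / "de.tsv", config.seed)
    summary = {
        "version": oxtrap.__version__,
        "seed": config.seed,
        "genome_levels": levels,
        "region_means": profile.region_means,
        "n_genes_expressed": int(len(kept)),
        "n_markers": len(markers.genes),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
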