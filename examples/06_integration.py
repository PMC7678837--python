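"""Join the layers: promoter methylation vs expression, end to end.

Runs the full synthetic pipeline (generate -> analyse -> compare against
truth) and prints the integrated results: marker recovery, promoter
hypomethylation concordance with its exact sign test, and the per-gene
methylation-expression Pearson correlations under Bonferroni control.
Also shows the qPCR 2^-ddCt and isotope product/precursor arithmetic.
"""

from oxtrap.config import RunConfig, SimConfig
from oxtrap.integrate import fraction_new_dna
from oxtrap.io import run_full_pipeline

cfg = RunConfig(mode="synthetic", seed=1, outdir="scratch/example_run",
                sim=SimConfig(seed=1))
summary = run_full_pipeline(cfg)

print("genome-wide levels (%):")
for fraction in ("input", "positive:astrocyte", "positive:microglia"):
    lv = summary["genome_levels"][fraction]
    print(f"  {fraction:22s} mCG={lv['mCG']:.1f} hmCG={lv['hmCG']:.1f} "
          f"mCH={lv['mCH']:.2f} hmCH={lv['hmCH']:.2f}")
print("marker recovery / concordance / correlation per cell type:")
for ct in ("astrocyte", "microglia", "neuron", "oligodendrocyte"):
    e = summary["expression"][ct]
    c = summary["concordance"][ct]
    r = summary["correlation"][ct]
    print(f"  {ct:16s} sens={e['sensitivity']:.2f} prec={e['precision']:.2f} "
          f"hypo-frac={c['fraction_hypomethylated']:.2f} "
          f"own r̄={r['own_mean_r']:+.2f} "
          f"flagged={r['own_negative_significant_fraction']:.2f}")
print(f"qPCR recovered fold change: {summary['qpcr_recovered_fc']:.2f} "
      f"(planted {cfg.sim.marker_enrichment_fc})")
print(f"fraction new DNA (product 0.021, precursor 0.042): "
      f"{fraction_new_dna(0.021, 0.042):.2f}")
# Every cell type's own markers are hypomethylated in its positive
# fraction (sign test over 100 genes), methylation anti-correlates with
# expression most strongly for the minority glial types, and the planted
# 8-fold qPCR enrichment is recovered.
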