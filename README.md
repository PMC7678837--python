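# oxtrap

Paired cell-type-specific transcriptome and DNA-modification analysis for
tagged-cell experiments.

## The problem

Epigenetic regulation is cell-type specific, but bulk brain tissue mixes
neurons, astrocytes, microglia and oligodendrocytes. Transgenic tagging
lets one animal yield both layers: TRAP (translating ribosome affinity
purification) captures a cell type's actively translated mRNA, and INTACT
captures its tagged nuclei and hence DNA. Paired bisulfite (BS) and
oxidative-bisulfite (oxBS) libraries on that DNA separate methylation from
hydroxymethylation: BS reads mC + hmC as methylated, oxBS reads only mC,
so per site

```
mC  = oxBS methylated / total            (as a percentage)
hmC = max(0, BS% − oxBS%)                (clamped per-site difference)
```

`oxtrap` implements the desk-side analysis stack for such experiments:

- **methylome**: per-cytosine mC/hmC calling from paired call tables,
  genome-wide context-stratified levels (mCG, hmCG, mCH, hmCH), spike-in
  conversion efficiencies;
- **regions**: strand-aware metagene profiles (20 × 200 bp flank bins,
  27 equal gene-body bins, 67 bins total), CpG-island / shore (2 kb) /
  shelf (2 kb) classification, repeat-class levels, two-way ANOVA with
  Sidak-corrected region contrasts;
- **bsas**: bisulfite amplicon sequencing — wildcard-C ungapped read
  mapping, site-level CG/CH percentages, repeated-measures ANOVA with
  Tukey post-hoc across input/negative/positive fractions;
- **expression**: median-of-ratios normalization, the >20-in-every-sample
  expression filter, per-gene ANOVA with Benjamini–Hochberg correction
  and SNK/Tukey post-hocs, fold-change cutoffs (|1.25| for DE; markers at
  positive/input FC > 5, q < 0.05), enrichment-score lists (≥ 3.5 +
  cross-type uniqueness), ≥ 2-study consensus, cross-study fold-change
  correlation, and 2^−ΔΔCt qPCR quantification;
- **integrate**: per-gene Pearson correlation of promoter mCG with
  expression under Bonferroni control, marker-hypomethylation concordance
  with an exact sign test, and the isotope-labeling product/precursor
  fraction-new-DNA ratio;
- **simulate**: a first-class generator that emulates the study
  conditions — a four-cell-type mixture, 90 %-pure positive fractions,
  planted 8× marker enrichment, ~70 % baseline mCG with own-marker
  promoter hypomethylation, cell-type-dependent hmCG (lowest in the
  microglia-like type), sparse 2–60 % high-mCH sites, hmCH ≡ 0 — plus
  the truth objects recovery tests compare against.

## Worked example

```python
from oxtrap.config import RunConfig, SimConfig
from oxtrap.io import run_full_pipeline

summary = run_full_pipeline(RunConfig(mode="synthetic", seed=1,
                                      outdir="scratch/demo",
                                      sim=SimConfig(seed=1)))
```

Running `python examples/06_integration.py` (which does the above) prints:

```
genome-wide levels (%):
  input                  mCG=65.1 hmCG=10.5 mCH=1.23 hmCH=0.02
  positive:astrocyte     mCG=65.0 hmCG=10.1 mCH=1.24 hmCH=0.03
  positive:microglia     mCG=65.1 hmCG=3.8 mCH=1.26 hmCH=0.02
marker recovery / concordance / correlation per cell type:
  astrocyte        sens=1.00 prec=1.00 hypo-frac=1.00 own r̄=-0.96 flagged=0.83
  microglia        sens=1.00 prec=1.00 hypo-frac=1.00 own r̄=-0.96 flagged=0.87
  neuron           sens=1.00 prec=1.00 hypo-frac=1.00 own r̄=-0.91 flagged=0.25
  oligodendrocyte  sens=1.00 prec=1.00 hypo-frac=1.00 own r̄=-0.95 flagged=0.76
qPCR recovered fold change: 8.06 (planted 8.0)
fraction new DNA (product 0.021, precursor 0.042): 0.50
```

Reading the numbers: the microglia-like positive fraction shows the planted
hmCG deficit (3.8 % vs ~10.5 %) while hmCH stays at ~0; every cell type's
100 planted markers are recovered exactly from the TRAP counts
(sensitivity = precision = 1.0); all own markers are promoter-hypomethylated
in their own positive fraction (sign-test concordance 1.0); and promoter
methylation anti-correlates with expression (mean Pearson r ≈ −0.95), with
Bonferroni-significant flags concentrated in the minority glial types whose
capture contrast against input is largest.

The other `examples/` scripts each demonstrate one capability (simulation,
hmC arithmetic, metagene profiles, BSAS, marker consensus). A thin CLI
mirrors the library: `oxtrap simulate | methylome | profile | bsas |
expression | integrate | run-all`.

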