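# Methods

## Model and measurement

The package analyses experiments in which a tagged cell type is purified
out of a tissue mixture twice over: its translated mRNA by ribosome
affinity capture (TRAP; "input" = pre-capture homogenate, "positive" =
bound, "negative" = unbound) and its DNA by affinity capture of tagged
nuclei (INTACT), from the two hemispheres of the same animal. DNA
modifications are measured by paired libraries from the same fragmented
DNA: one bisulfite-converted (BS, reads mC + hmC as methylated) and one
oxidised then converted (oxBS, reads only mC). Per cytosine,

- methylation % = 100 × methylated/total counts in the oxBS library,
- total-modification % = the same in the BS library,
- hmC % = max(0, BS% − oxBS%).

Negative per-site differences are sampling noise around a true level of
~0 and are clamped (negative hydroxymethylation is physically
meaningless). **Genome-wide** hydroxymethylation is computed differently:
the global BS call level minus the global oxBS call level (clamped at 0),
not the mean of per-site clamped differences. Per-site clamping is
half-normal-biased near zero — at a 1 % mCH baseline and 50× coverage it
would inflate a truly-zero hmCH to ~0.6 pp — while the aggregate
difference is unbiased, which is what makes "hmCH not detected" a
meaningful observation. Genome-wide methylation levels are unweighted
site means after a coverage filter (default ≥ 5 reads in both
libraries); site means are robust to coverage hotspots, and the choice
is configurable. Symmetric CpG strands are not merged: each strand's
cytosine is its own site, matching per-cytosine call reports. Conversion
efficiencies come from spike-in controls of known composition: eff_C =
1 − (BS methylated rate at true-C sites), eff_mC = BS methylated rate at
true-mC sites, eff_hmC = 1 − (oxBS methylated rate at true-hmC sites).

## Region profiling

Gene neighbourhoods use a fixed 67-bin layout in transcription
orientation: 4 kb upstream in 20 bins of 200 bp (most distal first),
the gene body in 27 equal-width bins (variable width per gene; bodies
shorter than 27 bp are excluded and logged), and 4 kb downstream in 20
bins. Intervals are half-open; minus-strand genes are mirrored. Bin
means weight genes equally (mean over genes of each gene's per-bin site
mean) so long genes do not dominate; this is configurable in effect by
pooling sites directly from the per-gene table. CpG-island context is a
partition by distance to the nearest island: inside = island, within
2 kb = shore, within 4 kb = shelf, else open sea; nearest-distance
classification realises the island > shore > shelf precedence when
neighbouring islands' derived intervals collide (the precedence between
one island's shore and another island's interior is not otherwise
defined, so island-first was adopted). Repeat-class levels average
per-site percentages over sites overlapping each class; a site under two
classes counts once in each, and a complementary non-repeat mean is
reported. Region-level group comparisons use a two-way fixed-effects
ANOVA (group × region, type II via OLS) with pairwise group contrasts
per region on the pooled error term, Sidak-adjusted: p_adj = 1 − (1 −
p)^m over the m contrasts performed.

## Amplicon calling (BSAS)

Reads are compared ungapped against the amplicon reference at offset 0
(optionally scanning ±3 bp for ragged ends), with every reference C a
wildcard matching C (methylated) or T (converted); mismatches count only
at non-C positions and reads exceeding the mismatch cap are tallied and
rejected. Only the bisulfite-PCR top strand is modelled; reverse
complements are tried and tallied. A read base that is neither C nor T
at a reference C is non-informative for that site and leaves its
denominator. This wildcard matcher is a documented stand-in for a
commercial bisulfite mapper whose parameters are not public. Fractions
are compared per animal with a repeated-measures one-way ANOVA (subject
as blocking factor, plain sums of squares, cross-checked against
statsmodels' AnovaRM in the tests) and Tukey HSD on fraction means using
the repeated-measures error term.

## Expression analysis

Size factors are DESeq-style median-of-ratios: the reference is the
per-gene geometric mean over samples restricted to genes nonzero in
every sample; each sample's factor is the median ratio to the reference
(a 0.5-pseudocount fallback exists for degenerate inputs). The
expression filter keeps a gene when its normalized count exceeds 20 in
**every** sample of at least one group — the vendor-style "average read
count > 20 in 100 % of samples in at least one group" detection rule,
threshold configurable. Differential expression is per-gene one- or
two-way ANOVA on log2(normalized + 1) (the log scale stabilises count
variance at this scale; the source analysis does not state a scale),
Benjamini–Hochberg corrected across genes, with a Student–Newman–Keuls
stepwise studentized-range post-hoc (Tukey HSD available as a flag;
both are built on scipy's studentized-range distribution since SNK has
no statsmodels implementation). Fold changes are ratios of normalized
group means with a 0.5 pseudocount. DE calls use q < 0.05 with
|FC| > 1.25; markers use positive/input FC > 5 at q < 0.05. For two
groups the one-way ANOVA coincides with the t-test (F = t²), so the
marker t-test and the ANOVA pipeline agree there. Cell-type lists from
enrichment scores keep genes scoring ≥ 3.5 (inclusive) and then drop any
gene qualifying for more than one type; consensus markers are genes on
≥ 2 study lists, optionally intersected with a cell-sorting reference.
qPCR uses 2^−ΔΔCt against an endogenous control and a calibrator group.

## Integration

Methylation–expression correlation is per-gene Pearson r over paired
subjects (both layers from the same animal; no cross-subject pairing),
flagged at p < 0.05/m with m defaulting to the number of genes tested —
an 11-gene panel reproduces the 0.05/11 ≈ 0.0045 threshold. Concordance
reports, per cell type, the fraction of its own markers whose positive-
fraction promoter mCG lies below input, with an exact two-sided binomial
sign test against 0.5 (zero differences excluded). The isotope-labeling
proliferation measure is the product/precursor deuterium-enrichment
ratio; values above 1 warn but are not clipped.

## Synthetic data: what it emulates, and what it does not

One `SimConfig` drives everything; every artifact draws from its own RNG
stream derived from the master seed by labelled hashing, so identical
configurations give byte-identical outputs and regenerating one artifact
never perturbs another.

Conditions emulated (defaults in parentheses): four cell types mixed
15/10/55/20 % (astrocyte/microglia/neuron/oligodendrocyte — neurons the
majority, glia minorities, as in brain); positive fractions at 90 %
purity with the remainder in mixture proportions; the negative INTACT
fraction is the mixture with the target scaled by (1 − purity) and
renormalized — the negative fraction's true composition is not
documented, so this proportional-depletion model is an assumption;
baseline mCG 0.70 with Beta(concentration 50) site noise; own-marker
promoters (−4 kb..TSS) at 0.50; CpG islands at 0.08 in **every** cell
type, taking precedence over marker status (islands are constitutively
hypomethylated; without this precedence, island-bearing marker promoters
would invert the planted direction); hmCG by type (0.10/0.03/0.13/0.08 —
lowest in the microglia-like type); mCH baseline 0.01 with a 1 % minority
of high-mCH sites uniform in [0.02, 0.60]; hmCH ≡ 0. Read counts are
Poisson(coverage 50) totals with Binomial methylated counts whose
probabilities pass through the conversion-error model (unmethylated C
read methylated with 1 − eff_C; mC retained with eff_mC; hmC protected
in BS, converted in oxBS with eff_hmC); sites with zero coverage are
dropped, as in real call reports. TRAP counts are negative-binomial
(gamma–Poisson, dispersion 0.05, variance μ + 0.05 μ²) with planted
positive/input ratios of 8 for own markers, 1/8 for other types'
markers, 1 for background, log-normal size factors, and n = 6 samples
per fraction; the RNA gene universe is padded with background genes to
4,000 so that markers are a ~10 % minority and the median-of-ratios
assumption (most genes unchanged) holds — with markers a majority,
normalization itself would be confounded. The negative RNA fraction has
input-like means (unbound material; no quantitative composition is
documented for it). Methylome arms use 4 replicates per fraction, RNA
arms 6 — the two arms' replicate counts differ in the emulated study,
hence separate fields. Promoters carry 20 CG sites and bodies 10
(≈ 1 CG per 200 bp per strand, the CpG-depleted genome average;
promoters are deliberately over-sampled relative to a real genome to
power the region statistics at desk scale). The default genome is 4 ×
2.2 Mb with 480 genes (100 markers per type), chosen so the full
synthetic pipeline runs in seconds on one CPU; realized global mCG is
~65 % rather than the 70 % baseline purely because this small genome is
promoter- and island-rich compared to a real one.

Not emulated: read-level errors and quality strings, alignment and
mapping bias, PCR duplicates, fragment-length effects, strand-specific
CG asymmetry, dropout or batch structure in RNA counts, and any
treatment (e.g. inflammatory challenge) time course. Passing recovery
tests therefore demonstrates correctness of the estimators and
statistics under the stated generative assumptions, not robustness to
alignment artefacts or confounded designs.

## Numerical choices and degenerate inputs

NA propagates through all modification arithmetic (a zero-coverage site
is NA, never 0). BH uses the standard step-up with cumulative-minimum
enforcement. The SNK procedure tests stretches widest-first and blocks
inner pairs once an enclosing stretch fails, keeping decisions coherent.
Zero within-group variance yields F = 0, p = 1 for identically-flat
data and NA where undefined. Pearson correlations need ≥ 3 pairs and
non-constant vectors, else NA. Interval logic is 0-based half-open
internally; cytosine tables are written 1-based in the call-report
convention and converted on read. All output tables carry a header
naming the producing version and seed.

## Known limitations

The amplicon mapper is ungapped (no indel tolerance) by design. The
correlation arm's significance contrast is weakest for the majority cell
type (its input-vs-positive methylation contrast is smallest — a real
feature of mixture designs, visible in the worked example's neuron row).
Two-factor differential expression fits per-gene OLS and is slower than
the vectorized one-way path. Real-data mode expects the package's TSV
dialects (or bismark-style coverage files via a flag) and does not do
read alignment.
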