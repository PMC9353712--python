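# Methods

## Scope and data model

The pipeline reduces every omics layer to a `TimeCourseMatrix` (features ×
samples, each column labelled with its Zeitgeber hour). The default
sampling design is 8 timepoints every 3 h across one 24 h light–dark cycle
with one sample per timepoint; replicates are supported (they enter the
rank test as tied reference values, which the exact nulls handle natively).
Internal genomic coordinates are 0-based half-open on a 10 Mb toy
chromosome (`chrT`) in synthetic mode; GTF is converted at the boundary
from its native 1-based closed convention, BED and bedGraph pass through.

## Layer quantification

**Nascent transcription.** Gene-body signal is summed on the gene's strand
over a window that skips the first 2 kb downstream of the TSS (promoter-
proximal pausing) and extends to +12 kb, the TES, or the whole body for
genes over 12 kb, between 2 and 12 kb, or under 2 kb respectively. A gene of
exactly 12 kb uses the +2 kb→TES branch; a gene of exactly 2 kb is treated
as short, because a +2 kb window on a 2 kb body is empty. Densities are
RPKTM = count / (kb) / (mapped reads / 10⁷).

**Enhancer RNA.** Candidate peaks (an external caller's output, read as
BED6 + FDR + fold-change columns) are kept iff FDR < 0.001, fold change >
3, and the center is more than 300 bp from every annotated TSS; signal is
RPKTM over ±500 bp around the center, on the peak's strand.

**Mature RNA / footprints.** Exonic RPKM. **Translation rate** is
footprint RPKM / mRNA RPKM per gene and timepoint, computed on the shared
ZT labels of the two matrices (no interpolation; the Ribo-seq grid may be
denser than the RNA-seq grid). Ratios where the mRNA density is below a
floor (default 0.1 RPKM) are left missing rather than unstable; genes with
more than 25 % missing timepoints are flagged unusable. Both cut-offs are
config parameters.

**Protein detection.** Only proteins whose mean abundance exceeds a
detection floor in *all* independent proteome datasets (three in the
synthetic default) enter protein-layer comparisons.

## Rhythm detection

For each series the Jonckheere–Terpstra/Kendall-τ concordance `S` is
computed against cosine templates evaluated at the actual sample times.
Pairs tied in either vector contribute zero; missing samples drop out of
both the statistic and the null.

**Exact nulls.** Conditional on the tie patterns of the template and of
the data, the permutation distribution of `S` is computed exactly: with
untied data it is the Gaussian q-multinomial generating function over the
template's tie groups (integer arithmetic, so probabilities are exact to
float rounding); when both vectors carry ties, a dynamic program over
remaining group capacities enumerates weighted placements. Beyond a
configurable size (default n = 25, or an intractable tie DP) a
continuity-corrected normal approximation with the standard tied-variance
formula is used and flagged. The distributions are symmetric for
palindromic tie patterns (cosine templates always are); they are not
symmetric in general, only mean-zero.

**Template grid.** Periods span 20–28 h. The default grid keeps periods
that are integer multiples of the sampling interval (21/24/27 h for 3 h
sampling): with 8 samples, a rank statistic cannot distinguish an off-grid
period from its on-grid neighbour — the two produce identical sample
orderings — so finer period grids only enlarge the correction family
without adding resolvable alternatives. Phase lags step by half the
sampling interval for the same reason. Both grids are parameters, and
templates with identical rank patterns are deduplicated (keeping the
longest period, then the smallest lag, which also fixes the tie-break for
the reported best period/phase).

**Multiple templates.** The reported `raw_p` is the minimum one-sided
upper-tail exact p over templates. The default familywise adjustment is the
exact permutation distribution of that minimum: for n ≤ 9 all n!
arrangements are enumerated once per (template set, tie pattern) and
cached; larger designs use seeded Monte Carlo (20 000 permutations,
deterministic for a fixed `perm_seed`). This correction accounts for the
heavy overlap between neighbouring cosine templates and is exactly
calibrated (measured type-I 0.044–0.052 at the 0.05 threshold over 2 000
null series). Classic Bonferroni over the distinct templates
(`adj_p = min(1, raw_p × n_templates)`) is available via
`adjust="bonferroni"`; it is markedly conservative here because an 8-point
exact null is discrete — its smallest achievable p times any realistic
template count leaves almost no rejection region. An optional further
Bonferroni factor across features exists but is off by default, matching
the convention of correcting per feature across its template family only.

**One-sided testing.** Antiphase alternatives are covered by the lag grid
(a sign flip maps a series to the template lagged by half a period), so the
upper tail alone is tested; two-sidedness would double-count.

**Estimates.** The best (period, lag) is the argmin-p template; amplitude
is the least-squares cosinor coefficient at that template. Constant series,
series with fewer than 4 finite values, and templates constant on the
observed subset are reported non-rhythmic with p = 1.

**Thresholds.** Rhythmic means adj-p strictly below the layer threshold:
0.05 for transcription, mature RNA, eRNA and translation rate; 0.1 for
protein and DBP activity (proteome time courses are noisier and shorter on
effective dynamic range).

## Cross-layer integration

Adjacent layers (transcription → mature RNA → protein → DBP activity) are
compared per gene among genes detected in both: rhythmic/rhythmic =
conserved, rhythmic/flat = disrupted, flat/rhythmic = enhanced. The
conserved fraction is |conserved| / (|conserved| + |disrupted|), i.e. the
share of upstream-rhythmic genes keeping their rhythm; alternative
denominators would mix in downstream-only genes and are not used.
Orientation is downstream-relative throughout ("disrupted in mature RNA
compared with transcription").

Mechanism attribution: protein-specific (enhanced) genes are translation-
rate dependent when their TE series is itself rhythmic at adj-p < 0.05 (the
RNA-layer convention; a config parameter); DBP-specific genes are
phosphorylation-dependent when they carry at least one detected phosphosite
— binary presence, not rhythmic phosphorylation, though a stricter rhythmic-
phospho mode can be had by scanning the phospho matrix and intersecting.
Translation-rate *variability* between conserved and disrupted genes is
compared as per-gene CV (sd/mean over timepoints) with a two-sided
equal-variance Student's t-test. Regulatory triads are emitted where a DBP
with rhythmic binding activity links (via a supplied pairing map) to a
rhythmic enhancer RNA that links to a gene with rhythmic transcription; for
real data the default enhancer→gene pairing is nearest TSS within 100 kb.
Dangling ids in pairing maps are rejected rather than silently dropped.

## Synthetic data generator

Every feature is a truncated-Gaussian cosinor. Layers are coupled through
a planted cascade: mature RNA inherits the transcription phase plus a
configurable processing delay (default 0 h); protein is generated from the
*realized* mature RNA × translation-rate series rescaled to the protein
baseline (so rhythmic protein can arise from rhythmic RNA or from rhythmic
translation alone, and noise propagates down the cascade the way abundances
do); DBP activity inherits the protein phase. Planted per-pair category
counts are exact by construction, which requires the flow constraint that
genes rhythmic downstream of pair *i* equal those rhythmic upstream of pair
*i + 1*.

Defaults plant the regime the pipeline is meant to resolve: 500 genes,
baseline 10, amplitude 3, noise SD 1 (amplitude/noise = 3), per-pair
(conserved, disrupted, enhanced) counts of (180, 120, 70), (140, 110, 60),
(60, 140, 40) — conserved fractions 0.60, 0.56, 0.30 — 45 % of
protein-specific genes driven by rhythmic translation (TE amplitude 0.3 on
baseline 1), 62.5 % of DBP-specific genes phosphorylated (background
phosphorylation rate 0.3 elsewhere), 40 enhancers with 12 fully wired
rhythmic triads plus linked-but-flat and rhythmic-but-unlinked decoys.
Translation-rate CVs are planted low (0.05) for genes whose rhythm survives
into protein and high (0.5) for genes whose rhythm is lost there, with 0.1
elsewhere. GRO-seq-style coverage is emitted as strand-separated bedGraph
per timepoint by placing `round(expression × 100)` reads uniformly over
each feature's quantification window, together with a GTF, a peak BED
(including decoys failing each eRNA filter rule), and true library totals.

What the generator does **not** emulate: read-level sampling noise (counts
are deterministic given expression), alignment artifacts, isoform
structure, batch effects between the three protein datasets beyond additive
jitter, peptide-level missingness, or phase dispersion within a layer.
Passing tests on these bundles therefore demonstrate correctness of the
statistics and plumbing under the planted model, not robustness to every
real-data pathology.

## Calibration, power, and known limitations

With 8 samples the exact null of `S` is strongly discrete, which caps the
power of any familywise-valid rank test. Measured on the default design at
amplitude/noise = 3: an oracle single-template test at raw p < 0.05 detects
≈ 98 % of planted cosinors, the default exact permutation adjustment
detects ≈ 84–86 % (phase within one sampling interval), and strict
Bonferroni over the template family detects ≈ 40–46 %. Downstream, every
cross-layer estimate inherits this per-layer detection rate π: the
recovered conserved fraction concentrates near planted × π (measured ≈ 0.59
vs 0.667 planted), and attribution fractions are diluted by genes that leak
into the wrong category when one layer's call is missed (measured TE-
dependent ≈ 0.30 vs 0.45 planted at these conditions). These are
properties of rank tests on 8-point series, not of the implementation: the
per-template nulls match exhaustive enumeration to 10⁻¹⁰ and the type-I
rate is at the nominal level. Designs with more timepoints or replicates
relax the ceiling quickly (the nulls and the permutation adjustment handle
replicates as reference ties; above n = 9 the adjustment switches to seeded
Monte Carlo).

Numerical choices: tie detection after rounding to 9 decimals; p-value
lookups by suffix-summed exact tables; amplitude by 2-parameter linear
least squares; PCA sanity reports standardise features before projecting
samples and score the fraction of temporally adjacent sample pairs that
remain neighbours in the circular (angular) order of the 2-D projection —
1.0 means the unsupervised projection recovers the clock order exactly.
Degenerate inputs (rank-deficient or duplicated samples) are flagged rather
than scored. All pipeline outputs are written with fixed float formatting
and hashed into a manifest; a rerun with the same config and seed is
byte-identical.
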