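# Methods

## Model and procedure

The package analyzes the consequences of whole-chromosome loss (monosomy)
in otherwise diploid human cells through five connected quantifications.

**Copy number from binned coverage.** Low-pass sequencing coverage is
summarized per fixed-size genomic bin (0-based half-open intervals, BED
convention). A bin is assigned to a gene when their intervals overlap by at
least one base; genes with no overlapping bin are dropped. Each gene is
summarized by the median of log2(coverage + pseudocount) over its bins
(pseudocount 1 keeps zero-coverage bins finite), and the genome-wide median
is subtracted so the disomic population centers on 0. A chromosome whose
per-gene median falls below −0.5 is called a loss; above +0.42 ≈
log2(3/2)/2-midpoint, a gain. These cutoffs are the midpoints between the
expected log2 ratios of adjacent integer copy states (copy 1 → −1, copy 2
→ 0, copy 3 → +0.585). Chromosomes with fewer than 20 measured genes are
flagged uncallable rather than guessed. Centering is idempotent and removes
any global sequencing-depth scale, so calls are depth-invariant. Note that
the centering median is global: if a very large fraction of the genome is
monosomic (⅓ in a toy genome), the global median is dragged toward the
lost chromosome and the centered values compress; with a realistic
monosome fraction (≲10% of genes) the bias is negligible.

**Dosage response.** Replicate log2 intensity matrices (default 3
replicates) for a monosomic line and its parental control are normalized by
shifting every replicate additively so that its median over the
*non-monosomic* genes equals the grand median of those per-replicate
medians; monosomic genes are shifted by the same per-replicate constant, so
a genuine chromosome-wide deficit survives normalization. The monosomic and
parental matrices are anchored *jointly* (all replicates to one common
median): normalizing them separately would leave an arbitrary offset
between the two lines that propagates into every fold change and visibly
shifts the disomic fold-change median away from 0. The fold change per gene
is the sample replicate-median minus the parental replicate-median. Genes
quantified in both modalities ("matched") are classified at a −0.5 log2FC
cutoff into up;up / down;up / down;down / up;down; equality at the cutoff
goes to the "down" side, which is conservative for buffering claims
(configurable). Pooling across cell lines is record-level (a gene monosomic
in two lines counts twice), excluding chromosome X, whose loss is masked by
X inactivation. Density summaries use a fixed histogram grid (width 0.1
over [−3, 3]) so they reproduce exactly across runs. Shared extreme
proteins use strict inequalities (|log2FC| > 1.5) and require the same
direction in at least two cell lines.

**2D annotation enrichment.** With genes ranked separately by mRNA and by
protein fold change (average ranks for ties), each term's score per
dimension is s = 2·(mean rank of members − mean rank of non-members)/n,
bounded in [−1, 1] and invariant under monotone transforms of the values.
Each dimension gets a two-sided Mann–Whitney p-value; the term's p-value is
min(1, 2·min(p_x, p_y)) (Bonferroni over the two dimensions), followed by
Benjamini–Hochberg FDR across terms (default threshold 0.02, minimum term
size 10 after intersecting with the measured universe). The per-dimension
Mann–Whitney with Bonferroni combination is a deliberate, documented
approximation of multivariate rank-enrichment tests; it is conservative for
terms deregulated in both dimensions.

**ssGSEA.** For one sample, genes are sorted by expression descending (ties
broken by gene id, so scoring is deterministic); the score is the sum over
rank positions of the difference between the weighted in-set ECDF (weights
|expression|^α, normalized; α = 0.75 by default) and the uniform
out-of-set ECDF. The sum-based statistic (not the running-sum maximum) is
used. Lower scores mean the set's genes are under-expressed in that sample
relative to the rest of the transcriptome. Optional normalization divides
each term's scores by their range across samples. Zero-variance samples
are rejected; if every member's expression is exactly zero, in-set weights
fall back to uniform.

**Polysome profiles.** Raw (position, absorbance) traces are smoothed with
a Savitzky–Golay filter, window 57 points (midpoint of 51–61) and cubic
polynomial; the filter is linear and exact on polynomials up to its order,
and edges are handled by evaluating the edge-window polynomial fit.
Unevenly sampled traces are linearly resampled to a uniform grid first.
40S/60S/80S peaks are the global maxima of the smoothed trace within
user-supplied search windows (ordered, non-overlapping); a window whose
maximum does not rise above the trace baseline + ε is flagged
not-detected. Profiles are overlaid by multiplying a sample trace by
(reference 80S height / sample 80S height), so both agree at the 80S peak;
within-profile ratios (60S/40S, 80S/40S, 80S/60S) are invariant to this
scaling. Optional linear baseline subtraction from the trace ends is off
by default.

**Cohort stratification.** WGD-filtered tumor samples are classified by
ABSOLUTE-style ploidy: Monosomy below 1.80, Polysomy above 2.19, Disomy in
between; boundary equality goes to Disomy (ploidy exactly 2 must be
disomic). Because the ploidy distribution has no clean minima, both
thresholds are swept (1.66–1.90 × 2.0–2.27, 5×5 grid by default) and a
result is called "robust" only if significant at every grid point.
TP53-alteration enrichment in Monosomy uses the one-sided exact
hypergeometric test. The default is the **mid-p** variant,
P(X > a) + P(X = a)/2: the classic Fisher tail P(X ≥ a) is conditionally
exact but conservative — under realistic null cohorts its realized type-I
error measured ≈ 0.039–0.041 at nominal 0.05 — while mid-p keeps the
realized level at ≈ 0.048–0.054 without anti-conservative pathologies at
these table sizes. Classic Fisher remains available (`method="fisher"`)
and is the variant checked against exhaustive hypergeometric enumeration.
Per-cancer-type comparisons of a score column (e.g. the TP53 classifier
score, a consumed input in [0, 1]) use one-sided Wilcoxon rank-sum tests,
exact by enumeration when both groups have ≤ 12 samples and no ties,
normal approximation with continuity correction otherwise; types with
fewer than 3 samples in either group are reported "untested". Counts of
significant types are reported uncorrected across types (a BH option
exists but is off by default). The aneuploidy-score summary contrasts
SCNA burden (median/IQR per class, Monosomy-vs-Polysomy rank-sum) with the
alteration-rate difference to show the TP53 enrichment is not an SCNA
artifact.

## Synthetic data: what it emulates, and what it does not

Every generator emits its ground truth (category labels, strata, true peak
heights) next to the data, so recovery tests never parse logs.

- *Coverage*: negative binomial counts per bin with mean
  depth × copy/2 and variance m + φ·m² (Poisson at φ = 0; noise-free
  expectation with φ = None). Default φ = 0.05 gives realistic ~25%
  overdispersion CV at depth 100. No GC waves, mappability structure or
  segmental artifacts are simulated, so passing tests show correct
  normalization arithmetic, not robustness to alignment biases.
- *Expression*: per-gene baselines N(10, 1.5²) log2 units; monosomic genes
  draw a category from the four-component mixture, default (0.30, 0.45,
  0.20, 0.05) with means −1 ("down") and 0 ("up"); gene-level scatter
  σ_gene = 0.2, replicate noise σ_rep = 0.1, and a global per-replicate
  shift (σ = 0.3) that the median-shift normalization must remove. Real
  data additionally carry intensity-dependent variance, missing protein
  values and TMT ratio compression, none of which is modeled; the
  generator shows the estimators recover their own model, not that the
  model captures mass-spectrometry artifacts.
- *Polysome traces*: baseline + Gaussian peaks (defaults at positions
  20/32/45/65 with the 80S peak tallest) + white noise; sampled so the
  57-point smoothing window spans roughly one peak width (≈1000 points
  over 100 units), which is where windowed-maximum localization is
  reliable to ±2 sampling points at noise σ = 0.005. Real traces have
  sloping sucrose baselines and asymmetric peaks.
- *Cohorts*: ploidy normal per stratum, defaults (1.70, 2.00, 2.26) with
  sd (0.05, 0.06, 0.04) — wide enough that the monosomy stratum has mass
  below the 1.66 sweep edge, as real ABSOLUTE ploidies do, while keeping
  default-threshold classification ≈99% accurate; TP53 alteration
  Bernoulli per stratum (default 0.60/0.25/0.25); TP53 classifier score a
  logistic transform of a stratum-shifted unit normal; aneuploidy score
  Poisson with equal means in Monosomy and Polysomy (the designed
  confound structure); pathway genes shifted by −0.5 log2 units in
  monosomic samples.

## Numerical choices and test design

- One top-level seed fans out to per-stage seeds by BLAKE2 hashing of
  "seed:stage", keeping all derived seeds below 2³¹; identical seed +
  config gives byte-identical outputs (floats are written with a fixed
  `%.6g` format).
- Buffering-fraction recovery is judged against the *flip-corrected*
  multinomial expectation: under the generator's noise a gene's fold
  change crosses the −0.5 cutoff with probability
  q = Φ(−0.5/σ_FC), σ_FC² = σ_gene² + 2·(0.6699·σ_rep)², which reshuffles
  the observable fractions by up to 0.4·q (≈0.005 at defaults). Comparing
  to the raw mixture probabilities would conflate this predictable
  classification noise with estimator error.
- Calibration checks run 2000 null cohorts of 400 samples; the rank-sum
  part uses 3 cancer types so per-type groups are in the asymptotic
  regime. Problem sizes throughout (10³–2×10³ genes, ≤2000 replicates)
  were chosen so each check completes in seconds on one core while
  keeping Monte Carlo error well inside the stated tolerances.
- Exact rank-sum and Fisher paths are verified against brute-force
  enumeration (all group assignments up to 8 per group; all 2×2 tables up
  to n = 20).

## Known limitations

- No segmentation: arm-level events are handled by annotating arms as
  separate "chromosome" labels, not inferred.
- The 2D enrichment p-value is a per-dimension combination, not a joint
  two-dimensional test.
- ssGSEA scores are sensitive to the α weighting for α > 0 (documented,
  not removed); only α = 0 is rank-invariant.
- Peak localization needs user-supplied search windows; there is no
  automatic sedimentation calibration.
- The deposited-data and cohort-download reproductions (pooled medians
  −0.25/−0.59, 5/13 shared extreme proteins, 48/349 CCLE lines, 13/15 and
  3/15 significant cancer types) require the study's external tables and
  run only when those are provided under `data/external/`.
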