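# Methods

This note documents the models, the defaults and why they were chosen,
what the synthetic data does and does not emulate, and the package's known
limitations.

## Genome model

The genome is an abstract ordered partition: chromosomes tiled by
contiguous unit-width bins in 0-based half-open coordinates (5000 bins
over 22 chromosomes by default, mirroring low-pass whole-genome binning).
All coordinates in the package are bin indices; physical (bp) coordinates
are deliberately out of scope, since every computation downstream of
alignment operates on bins. `make_genome` draws chromosome sizes from a
Dirichlet-multinomial with concentration 5, which gives karyotype-like
size variation — the largest chromosomes comfortably hold ≥ 200-bin
(arm-scale) events — while summing exactly to the requested bin count.

## Noise model of the synthetic data

Per-bin counts are independent negative binomials with mean
`depth × true_ratio` and size (dispersion) parameter r, so the variance is
μ + μ²/r. Defaults: depth 50 and r = 10 for single cells — deliberately
heavy-tailed to stand in for whole-genome-amplification distortion — and
depth 100, r = 50 for cfDNA libraries, which are markedly cleaner. cfDNA
is the mixture (1−f)·1 + f·Σ w_c·ratio_c of neutral background and clone
profiles at tumor fraction f; the expected per-bin ratio is available
analytically (`cfdna_expected_ratio`) and is checked bin-by-bin in the
tests before any sampling.

What the generators do **not** emulate: GC and mappability bias, waviness,
correlated (smoothly varying) amplification artifacts, supercoiled cfDNA
fragment-length structure, and real karyotype coordinates. Passing the
simulation studies therefore demonstrates correctness of the algorithms
under idealized independent-count noise, not performance on raw sequencing
data, which would additionally need bias correction upstream.

Clones are defined by explicit event lists (chrom, start, end, ratio),
later events overwriting earlier ones — reproducibility is preferred over
stochastic karyotype realism. Draw-series templates ("flat",
"best_responder", "average_responder", "poor_responder") fix the CTCs/ml
arc and the variant acquisition/loss schedule; the generator enforces the
arc's defining property against count rounding (monotone increase for the
poor responder, clearance below 1.5 CTCs/ml for the best responder).

## Normalization and segmentation

Counts are divided by the median over nonzero bins, making profiles
scale-invariant with median ratio 1. Median rather than mean was chosen
for robustness against aberrant segments; zero bins are floored at 1e-6
before logs.

Segmentation is a circular-binary-segmentation scheme on log2 ratios.
For a segment of length n, the candidate split is the arc [i, j)
maximizing the pooled-variance two-sample t versus its complement.
Because a permutation keeps the segment's value multiset (hence its total
sum of squares), |t| is a strictly monotone function of the weighted
centered-partial-sum statistic u = |z_j − z_i|·√(n/(k(n−k))) — so the
exhaustive search and the permutation test both operate on u, which needs
only one cumulative sum and a cached weight matrix per evaluation. The
split is accepted when its permutation p-value (+1-corrected) is below
alpha, and the procedure recurses into the resulting pieces.

Sequential early stopping: permutations run in blocks; testing stops as
soon as the exceedance count already forces the final p above alpha
(reject the split), or once at least 300 shuffles with zero exceedances
make the corrected p-estimate fall below alpha (accept). Decisions are
identical to the full run except for splits whose p sits essentially at
the threshold. Ties in the arc search resolve to the leftmost (smallest
i, then j) pair.

Defaults and rationale:

* `alpha = 0.01`, `n_perm = 1000` — conventional CBS settings.
* `min_width = 20` bins. At 5000-bin resolution, 20 bins ≈ one-hundredth
  of the genome; shorter events are below the arm-scale resolution this
  score targets. With the very heavy single-cell dispersion, a smaller
  minimum width lets genuine 5–10-bin runs of low counts become segments,
  which contaminates the copy-neutral GI band; 20 bins restores the
  neutral-band property while leaving ≥ 200-bin event detection untouched.
* Outlier smoothing (on by default): bins more than 4 estimated noise SDs
  from their ±5-bin local median are capped to 2 SDs from it before
  boundary detection, as in the canonical CBS workflow. Segment means are
  always computed from the *unsmoothed* ratios, so the per-chromosome mean
  of the segmented values equals the normalized input mean exactly.
* Undo pass: adjacent segments whose log2 means differ by less than
  `undo_sd = 1` estimated per-bin noise SD are re-merged (smallest
  difference first). The noise SD is the median absolute successive
  difference of log2 ratios divided by 0.6745·√2.
* Chromosomes shorter than 2·min_width become a single segment, silently.

Segment means are reported on the ratio scale; SEG export writes log2
means at 6 decimals and round-trips through the matching reader.

## GI score

GI = Σ_bins [tanh(3·|ln RM_i| − 2) + tanh(2)], computed on the segmented
per-bin values with RM recomputed from that vector (so its median is
exactly 1). The natural log is used; the gain/loss symmetry holds in any
base, and a base change only rescales what the constants 3 and 2 mean in
ratio units. GI is computed after segmentation because the copy-neutral
band (≤ 30) is attainable only once bin-level noise has been suppressed;
raw-ratio GI at single-cell dispersion is in the thousands. Bands:
neutral ≤ 30 (inclusive), aberrant > 100 (exclusive), intermediate
between. Alteration limits are inclusive: mean ≥ 1.25 is a gain, ≤ 0.75 a
loss.

## Clonality and clustering

"Sharing an alteration" is operationalized as two same-direction calls
with reciprocal bin overlap ≥ 50% (configurable); each call matches at
most once, pairs taken greedily by overlap with leftmost tie-break — on
small instances this greedy matching equals the exhaustive maximum
matching, which the tests verify. Cells sharing ≥ 2 alterations are
joined by an edge; clones are connected components with ≥ 2 members
(transitive closure of the pairwise rule), every other cell is
"unclonal". Alterations are counted per segment, not per arm. Profile
clustering uses Ward linkage on Euclidean distances between per-bin log2
segmented values, with inputs sorted by sample id so leaf order is
deterministic; the heatmap encodes loss/neutral/gain per bin at the call
limits.

## Tumor-fraction estimation

The reference is a clonal CTC profile (a ground-truth clone or a
segmented consensus — when several reference cells exist, combine them
upstream into one consensus, e.g. a per-clone median profile; the
estimator accepts exactly one reference). Informative segments deviate
from diploid by ≥ 0.25, aligning informativeness with the call limits.
For each, f_s = (r_cf − 1)/(r_ref − 1), where r_cf is the mean of the
cfDNA profile's *bin-level* values across the segment's bins — averaging
bins directly (a NormalizedProfile is accepted) avoids diluting small
fractions through the granularity of a separate cfDNA segmentation. The
point estimate is the median of the f_s clamped to [0, 1] (median over
mean for outlier robustness; negative f_s are retained in the
per-segment table for diagnostics), with a percentile bootstrap over
segments for the CI. Estimates below 0.05 carry a `below_floor` flag —
the method's stated confidence floor — but are never suppressed. The
noiseless identity (the estimator returns f exactly on an analytic
mixture) holds for any f and any reference with at least one informative
segment.

## CTC analytics

Analyzed blood volume = slide nucleated count / WBC concentration;
CTCs/ml = CTC count / volume, each cluster member counted as a cell.
Positivity is inclusive (≥ 1.0 CTC/ml); stability is strict
(|Δ| < 5 CTCs/ml), matching the printed wording of both rules. SDOM is
formalized as the signed z-score (I_cell − mean(I_bg))/sd(I_bg) against
the 50 WBCs nearest in frame coordinates (Euclidean; ties by cell id;
sample SD, ddof 1); with fewer than 50 WBCs all are used and the result is
flagged; a zero-SD background raises an explicit error. Variant "absent"
means not reported by the assay — never VAF 0 — and trajectory status
follows the presence pattern: present at first and last analyzed draw →
persistent; absent first, present last → acquired; present first, absent
last → lost; interior only → transient; single draw → persistent by
convention. Nuclear area and eccentricity units are carried as opaque
labels.

## Simulation studies and problem sizes

The bundled studies (also run by `scripts/acceptance.py`) use 20 seeds of
5000-bin, 22-chromosome genomes for the GI band experiments, and a
0–10% × 20-replicate grid for the detection-floor scan against a 4-event
arm-scale reference. These sizes give stable medians and extremes while a
full study completes in well under a minute; the detection criterion
(median within 2 percentage points of truth and above the 95th percentile
of zero-fraction estimates) is deliberately two-sided against both bias
and false detection.

## Known limitations

* No GC/mappability correction, ploidy/purity-aware integer copy-number
  calling, or allele-specific analysis.
* One consensus reference clone for fraction estimation; simultaneous
  multi-clone deconvolution is out of scope.
* The dendrogram is a linkage tree, not a phylogeny; event ordering is
  not inferred.
* Sub-20-bin events are invisible at default segmentation settings by
  design; lower `min_width` (and expect a noisier neutral band) to chase
  focal events.
* The permutation test's early-stopping decisions can differ from the
  full run for splits whose p-value lies essentially at alpha.
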