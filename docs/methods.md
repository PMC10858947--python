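# Methods

This note documents the models and procedures implemented in `loopshift`,
the defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical corner cases.

## Contact-map model and conventions

All coordinates are 0-based half-open; bin `b` of a map with bin size `s`
spans `[b·s, (b+1)·s)`. A contact-map cell is *missing* (NaN) iff either bin
has zero marginal coverage, and *zero* otherwise — the distinction feeds the
imputation stage. Maps are symmetric per-chromosome cis matrices; trans
contacts are out of scope.

### O/E normalization

The expected value at bin distance d is the mean of defined cells on
diagonal d. Diagonals with fewer than 10 defined cells are pooled with the
next farther diagonals until the pool reaches 10 (a trailing short pool
merges into its predecessor). Consequences worth knowing: on an n-bin map
the farthest diagonals are always pooled, so a matrix constructed with
constant per-diagonal values has O/E exactly 1 only on unpooled diagonals.
Cells on diagonals whose pooled expectation is 0 become missing.

### Smoothing and imputation

The fragment-level imputation used in the source data processing (a Markov
random field over neighboring fragments) is represented here by a masked
Gaussian kernel: K(i,j) is the Gaussian-weighted mean (sd `sigma`, default
1.0 bin) of defined cells within Chebyshev radius 2; missing cells take K,
defined cells take `alpha·obs + (1−alpha)·K` with `alpha` default 0.5. Cells
with no defined neighbor stay missing. The defaults were chosen as the
mildest smoothing that visibly stabilizes loop scores on the synthetic maps;
because both the peak and its background are smoothed identically, the
*calibration* of downstream score statistics is essentially insensitive to
these parameters (see "Calibration" below).

## Loop scoring and calling

`score(i,j) = P / max(D, H, V, BL)` with peak half-width `p = 1` and outer
half-width `w = 5` bins: P is the mean O/E over offsets with
max(|Δa|,|Δb|) ≤ p; H (horizontal stripe): |Δa| ≤ p, p < |Δb| ≤ w; V
(vertical): mirrored; BL (lower-left quadrant, toward the diagonal):
0 < Δa ≤ w, 0 < −Δb ≤ w excluding the peak; D (donut): everything else
within the outer window. BL overlaps D and the near parts of H/V by
construction. A candidate is valid only if every component has ≥ `m_min = 3`
defined cells and the background maximum exceeds 1e-9; candidates whose
outer window leaves the matrix are flagged invalid rather than raised.

Calling scans the distance band `d_min = 3` to `d_max = 200` bins, keeps
valid scores ≥ `score_min = 2.0`, and applies greedy non-maximum suppression
(descending score, ties by ascending (i,j), Chebyshev exclusion radius p).

A ratio threshold alone is not a sufficient loop definition at realistic
depth: where the expected count per cell is below ~1 (far diagonals), O/E
ratio noise is effectively unbounded and a score cutoff of 2 admits hundreds
of false pixels per chromosome. Calling therefore also requires, whenever
the raw observed map is provided, that the observed peak-window count exceed
a Poisson background with rate (local background O/E) × (expected count sum
over the peak window), BH-corrected at FDR 0.1 across in-band candidates.
This joint enrichment + count-significance rule is standard in the
donut-filter tradition; with it, loop-free synthetic maps yield zero calls
at the default thresholds while planted 5-fold loops are recovered at ≥ 90%
per replicate.

## Differential loops

Per-sample scores are computed over the union of all samples' loop calls;
candidates invalid in any sample are dropped. Within each sample, scores are
z-normalized across candidates using the population (n-denominator)
standard deviation — this is a normalization, not an inference step.
Difference scores DS are control-minus-treatment z differences over the full
replicate cross product (`all_combinations`, k = R₁·R₂; a `matched_pairs`
mode pairs replicates positionally and is provided for the alternative
reading). The meta-statistic is Stouffer's Z = ΣDS/√k with two-sided normal
p-values; P < 0.05 defines significance, Z > 0 is a loss in treatment,
Z < 0 a gain. No multiple-testing correction is applied across candidates
(significance is a raw-P threshold by design).

### Calibration

The DS share replicates and are treated as independent, so the statistic is
exactly calibrated only when a candidate's score is reproducible across
samples. Two regimes matter:

* **Structure-dominated candidates** (real loops — the statistic's use
  case): the shared locus effect cancels in DS and the residual variance is
  small; on the standard synthetic experiment all planted condition-specific
  loops are detected with the correct direction and none of the planted
  shared loops reaches significance.
* **Noise-dominated candidates** (loop-free maps): each sample's z at a
  fixed candidate is approximately an independent unit-variance draw, which
  makes Var(Z) ≈ 6 in 3v3 all-combinations mode (≈ 2 for matched pairs)
  rather than 1. The permutation-null significant fraction at P < 0.05 is
  then ~0.3, not 0.05, and is invariant to smoothing strength because
  z-normalization makes the noise-to-structure ratio scale-free. The test
  suite asserts this anticonservative behavior explicitly. Interpreting Z
  p-values for candidates without reproducible structure is not supported.

## Compartments

PC1 is the leading eigenvector of the Pearson correlation matrix of the O/E
map restricted to valid bins (rare missing cells on zero-expectation pooled
diagonals are set to the neutral O/E of 1 first). A constant O/E column is
degenerate and raises. The eigenvector sign is fixed in two steps: a
deterministic gauge (largest-|v| entry positive), then TSS orientation — the
sign class with the higher mean TSS count per bin becomes '+'; an exact tie
leaves the track unflipped and flags it ambiguous.

Saddle analysis (per chromosome): drop the ⌈1%⌉ lowest-coverage usable bins
(coverage = marginal sum of the raw map), rank the rest by PC1 descending,
partition into 100 contiguous rank groups (remainder spread over leading
groups; chromosomes with fewer than 100 usable bins are skipped), and
average O/E over group pairs; chromosome matrices are averaged unweighted.
AA/BB/AB are the means of the top-left/bottom-right/top-right 25×25 corner
blocks (the top/bottom 25% of PC1). The differential saddle is the
element-wise log2 ratio, undefined where either side is missing or ≤ 0. The
switching fraction is the share of common valid bins with opposite oriented
PC1 signs (exact zeros excluded).

At desk scale the differential saddle between two simulations of the same
truth has mean |log2FC| around 0.4 — percentile blocks of 4 bins are noisy —
so only the corner aggregates (AA/BB/AB) and the switching fraction are
treated as stable summaries.

## Coverage normalization

Chain: size-filter fragments (strictly < 120 bp for TF experiments, < 150 bp
for ATAC, no filter for histone marks/ChIP) → pool all samples → call
enriched regions → derive flanks → count → size factors → thin.

* **Peak calling**: fixed windows (default 500 bp) against a uniform
  background; per-window Poisson upper tail P(X ≥ c), BH at alpha, merge
  significant windows separated by ≤ 1 window; region p = min member raw p.
  Fragments are assigned to windows by midpoint.
* **Flanks**: default 5,000 bp each side of each peak, clipped to the
  chromosome, with any overlap with any peak subtracted. Flanks of nearby
  peaks may duplicate the inter-peak gap; counting is consistent so the
  size-factor estimate is unaffected.
* **Size factors**: median-of-ratios — sf_j = median over regions of
  counts[i,j]/geomean_i, over regions with positive geometric mean.
* **Thinning**: subsampling "at the scale-factor rate" is ill-posed when
  sf > 1, so the retention rate is r_j = min(sf)/sf_j ∈ (0,1] — the deepest
  samples are thinned down to the shallowest — applied as independent
  Bernoulli retention. On synthetic samples with depth factors 0.5–2, flank
  size factors recomputed after thinning sit within 5% of 1; the residual
  is estimator noise of the median-of-ratios on ~90 desk-scale flank
  regions, not bias.

## Differential binding

On the common catalog (peaks of the pooled fragments), per-region normalized
counts q = count/sf feed an NB Wald test: Δ = log2((q̄₂+0.5)/(q̄₁+0.5)) with
pseudocount 0.5; SE² = (1/ln2)²·Σ_g v_g/(n_g·max(q̄_g,0.5)²) with
v_g = q̄_g + α̂·q̄_g²; two-sided normal p; BH across the catalog; direction
gated on padj < 0.05 (a flag gates on raw p instead).

Dispersion α̂ is estimated from *within-condition* moments — per region, the
mean over groups of (s²_g − q̄_g)/q̄_g² — and then shrunk to a mean-dispersion
trend a₀ + a₁/μ fitted across regions by least squares on trimmed estimates;
the trend value is used (strong shrinkage). Rationale: with 3 replicates per
group a per-region variance gives the Wald statistic t-like tails (~10%
type-I at |W| > 1.96), and pooling across groups would absorb true fold
changes into the dispersion; the trend estimator is the moment-method
analogue of how replicated count frameworks share dispersion information
across features. Simulation at the standard conditions (NB, μ = 50,
dispersion 0.1, 1,000 regions, 3v3): type-I fraction 0.047 at raw p < 0.05,
98% recovery of 4-fold changes at observed FDR 3%. The log2 fold changes
agree with an independent NB-GLM reference implementation (r > 0.95) on a
planted fixture.

## Integration statistics

* **Peak-to-gene scores**: each differential peak contributes
  (1/n)·(−10·log₁₀ p) — base 10, raw p — to every gene whose TSS lies within
  25 kb (inclusive) of the peak midpoint; p = 0 is capped at the p = 1e-300
  equivalent. Scores are additive over peak lists.
* **Overlap tests**: one-sided hypergeometric on catalog-index subsets
  (region-level universe, so draws are exchangeable), BH across a batch.
* **Anchor annotation**: promoter iff the anchor bin intersects a
  TSS ± 2 kb window (precedence), else enhancer iff it intersects an
  active-mark peak; differential flags by intersection with named
  direction-filtered region sets.
* **Gain/loss bias**: per category, the ratio g/l of significant gained to
  lost loops with ≥ 1 qualifying anchor (undefined when l = 0, never
  infinity). Category pairs are compared by a one-sided Wilcoxon rank-sum on
  per-anchor net change (gained − lost per anchor), normal approximation
  with tie correction, BH across the requested comparisons. Per-anchor (not
  per-loop) aggregation is a design choice: it prevents a single promiscuous
  anchor from being counted once per loop.
* **Locus enrichment**: Welch's unequal-variance t comparing per-locus
  rearrangement counts (significant-loop anchors within ± 5 kb of the locus
  center) between a subset and all loci; zero variance in both groups is an
  error, not ±∞.

## Synthetic data: what it emulates, and what it does not

The Hi-C generator draws Poisson counts around
E[i,j] = depth·C·(1+|i−j|)^−γ · (1±s) · f, i.e. power-law distance decay
(γ = 1), a compartment checkerboard (alternating 25-bin blocks, strength
s = 0.3), planted 3×3 loop windows (f = 5), per-replicate depth factors
(log-uniform 0.7–1.4), and 2% low-coverage bins (expectations × 0.05). The
standard experiment is one 2 Mb chromosome at 5 kb bins (400 bins) with
C = 50 — chosen so near-diagonal cells hold tens of counts, comparable per
unit length to a few hundred million reads genome-wide. TSS positions are
drawn 3:1 denser in A blocks so sign orientation is testable. The fragment
generator emits per-region Poisson counts (background 0.01 fragments/bp on a
1 Mb genome, 40 peaks of 1 kb, 4-fold planted changes) with a two-component
normal length mixture (80 ± 15 and 200 ± 30 bp, weights 0.6/0.4).

Not emulated: restriction-fragment spacing (uniform bins stand in for
fragment resolution), trans contacts, copy-number structure, overdispersion
beyond depth variation (Hi-C cells are Poisson; the NB behavior of the
binding test is exercised with directly simulated NB counts), GC/mappability
bias, and duplicate reads. Passing tests therefore demonstrate the
correctness and calibration of the statistics under these idealized
conditions, not robustness to every artifact of real libraries.

## Numerical choices and degenerate inputs

Ties in loop-call NMS break by ascending (i,j); z-scores use population sd
and a zero-variance score vector is an error naming the sample; the
hypergeometric and rank-sum tests use exact set arithmetic and
tie-corrected normal approximation respectively; BH is the standard step-up.
Empty unions, empty catalogs, all-missing maps, grid mismatches, and
fewer-than-two loci per enrichment group raise errors rather than returning
NaN. The pipeline derives per-stage seeds from one global seed via
`SeedSequence.spawn`, so stages are individually reproducible.

## Known limitations

* The Stouffer p-values are nominal only for structure-dominated candidates
  (see Calibration); a permutation-based calibration would be needed for
  noise-regime inference and is deliberately not applied, to keep the
  published formula intact.
* The Wald dispersion trend assumes dispersions vary smoothly with the mean;
  strongly region-specific overdispersion would be under-served by the
  trend-only shrinkage.
* The smoothing stand-in is validated against planted truth only; it is not
  a reimplementation of the fragment-level MRF imputation it replaces.
* Saddle percentile blocks are noisy at desk scale (4 bins per percentile);
  only corner aggregates are quantitative.
* The analysis scales comfortably to a few thousand bins per chromosome;
  the dense-matrix representation is not intended for genome-wide
  fragment-resolution maps.
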