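# Methods

## Problem and model

Cellular radiosensitivity is commonly summarised by the surviving fraction
at 2 Gy (SF2): the proportion of cells that retain colony-forming ability
after a 2 Gy dose, obtained by fitting clonogenic-survival data to the
linear-quadratic model `SF = exp(-αD - βD²)` and evaluating it at D = 2 Gy
(`lq_surviving_fraction`).  Genome-wide copy-number variation is measured
per marker as the fold change `FC = log2(sample/reference)`; positive FC
indicates a copy-number gain, negative a loss.

radioseg treats SF2 as a continuous dependent variable and models it as a
*piecewise* multivariate linear function of marker fold changes: samples
are sorted by SF2 and partitioned into K contiguous segments, and within
segment k

    SF2_i = a_k + Σ_m b_{k,m} · FC_{i,m} + ε_i ,

with a separate, independently selected marker set per segment.  The
piecewise form encodes the working hypothesis that different genomic
factors drive response in sensitive and resistant cells, so that the
FC–SF2 relation is only locally linear.

## Pipeline

1. **Screening** (`screen`).  Per marker, Pearson and Spearman correlation
   of FC with SF2; two-sided p-values from the t distribution with n−2
   degrees of freedom (Spearman: exact permutation enumeration for n ≤ 9,
   t approximation above — the approximation is routine beyond n = 20 and
   is also used for 10 ≤ n ≤ 20).  Benjamini–Hochberg adjustment is
   applied separately to the Pearson and Spearman families.  The
   *candidate pool* for all regression models in a run is the set of
   markers with unadjusted Pearson p < 10⁻⁵ on the training set, ordered
   by ascending p; only Pearson is used here because the regression is
   linear.  Zero-variance markers are flagged undefined and excluded from
   adjustment.

2. **Forward selection** (`regression`).  Each model starts from the
   intercept; at every step the unused candidate with the highest Bayes
   factor over the current model is added.  The Bayes factor uses the BIC
   approximation (unit-information prior), `BF = exp((BIC_cur −
   BIC_cand)/2)` with `BIC = n·ln(RSS/n) + k·ln(n)`; an addition is
   accepted while BF ≥ 10 ("strong evidence") and the model respects the
   sample-to-feature rule of at least 10 observations per independent
   variable (`max_features = ⌊n/10⌋`; the intercept is not counted, so
   116 training samples allow 11 features).  BF ties are broken by the
   candidate-pool order (ascending screening p), which makes selection
   deterministic.  Model quality is the mean relative error, `RE_i =
   |SF2_pred − SF2_obs| / |SF2_obs|`; RE is preferred over squared error
   because a fixed absolute miss on a sensitive (low-SF2) sample matters
   more than the same miss on a resistant one.

3. **Segmentation** (`segmentation`).  For a window of SF2-sorted samples,
   the segment cost is the RE sum of its own forward-selected local model
   (feature cap from the window's own size).  Dynamic programming over
   last-cut positions, `D[k][j] = min_i D[k−1][i] + cost(i, j)`, yields
   the exactly cost-minimal K-segmentation under a minimum batch size of
   10 (the 10-observations-per-variable rule again).  The overall
   weighted MRE satisfies the identity `Σ_k MRE_k·n_k/N = Σ_i RE_i/N`.
   The breakpoint of a segment is the highest SF2 among its members.  K
   is chosen by *utmost-border stabilisation*: the smallest K ≥ 3 whose
   lowest and highest breakpoints coincide exactly (as realized sample
   values) with those at K+1; if none stabilises, the scan returns K_max
   with a flag.  The lowest-SF2 segment is labelled radio-sensitive (RS),
   the highest radio-resistant (RR), the rest normally-sensitive (NS).
   A fixed 2-segmentation at the training-mean SF2 (`mean_split_baseline`,
   strictly-below-mean on the lower side) serves as the non-optimised
   baseline; DP's 2-segment solution can never be worse on training data.
   Validation samples are assigned to segments by observed SF2 against
   the breakpoints (lower-exclusive / upper-inclusive); samples outside
   the training SF2 range fall to the nearest utmost segment and are
   flagged.

4. **Group comparison** (`compare`).  RS and RR groups — either the
   utmost DP segments or the samples at/beyond the SF2 quartiles
   (linear-interpolation quantiles, boundary-inclusive) — are compared
   marker-by-marker with the Mann–Whitney U test (midranks; exact
   enumeration of rank assignments when the pooled sample is ≤ 12 and
   tie-free, normal approximation with tie and continuity correction
   otherwise) and the Glass rank-biserial correlation `r = 2·(meanrank_A −
   meanrank_B)/n`, algebraically equal to `2U_A/(n_A n_B) − 1`.  Effects
   are categorised by |r| at 0.1/0.3/0.5/0.7 (negligible/small/medium/
   large/very large).  Sign convention: r is computed as RR minus RS, so
   positive r means copy number is higher in the resistant group.

## Synthetic cohorts

`simulate.generate` produces cohorts with the exact structure the method
assumes, plus full ground truth for recovery testing.  SF2 is drawn
uniform or truncated-normal on a configurable range; the study-scale
default (`default_study_spec`) uses 129 samples with truncated-normal
SF2 (mean 0.3273, SD 0.0868, range [0.1384, 0.4860]), five regimes with
1/2/3/3/1 informative markers (intercepts descending 0.4412…0.1713 with
coefficient magnitudes ~0.07–0.18, matching the scale of fitted segment
models), and 10,000 null markers (`FC ~ N(0, 0.2)`).

Key construction choices, and why:

- **Inverted link.**  Informative FC is solved from SF2 (not drawn first)
  so the planted within-segment linearity is exact.  For a support of m
  markers, the first m−1 get the shared trend `(SF2−a)/(m·b)` plus small
  independent scatter (`fc_within_sd = 0.02`, small relative to the
  within-segment trend so each marker individually tracks SF2 inside its
  own segment), and the last marker closes the identity exactly.  This
  keeps partial-fit residuals inside the support's own span — random
  per-sample signal splits were rejected because they leave residual
  structure that either invites spurious selections or makes support
  columns nearly collinear.
- **Carryover trend.**  Outside its own regime a marker keeps the same
  mean linear trend plus large scatter (`fc_carryover_sd = 0.6`).  Real
  segment-associated markers must survive a genome-wide correlation
  screen; a marker informative in only ~20 of 129 samples and pure noise
  elsewhere has global |r| ≈ 0.1 and would never reach p < 10⁻⁵.  The
  carryover keeps global |r| high (≈0.6–0.9) while foreign markers still
  explain little variance inside other segments, which is the contrast
  the DP exploits.
- **Regime boundaries.**  The default boundaries (0.2300/0.2835/0.3613/
  0.4100) are placed so that every regime's expected occupancy under the
  truncated normal comfortably exceeds the minimum batch size of 10;
  boundaries pushed into the distribution tails would make the lowest
  segment unrecoverable by construction.
- **Noise.**  `noise_sd = 0.005` SF2 units of regression noise — small
  against segment widths (~0.05–0.08) so planted boundaries are
  identifiable, non-zero so fits are never degenerate.

What the generator does *not* emulate: probe-level microarray noise,
genomic contiguity of CNV segments (gains/losses spanning neighbouring
markers), linkage between markers, or covariate structure among samples.
Passing recovery tests therefore demonstrates correctness of the
screening → selection → segmentation machinery under the model's own
assumptions, not performance on real microarray data.

## Numerical choices

- The DP inner loop evaluates thousands of candidate windows, so window
  models are fitted from prefix-summed cross-product (Gram) matrices:
  each window Gram is O(d²) to form and each candidate model a Cholesky
  solve of a ≤(cap+2)-dimensional system.  Gram-based RSS is computed by
  subtraction and carries cancellation noise of order machine-eps×TSS;
  an RSS below 10⁻¹² of the total sum of squares is treated as a perfect
  fit (BF = +∞, selection stops).  Final reported models are refit with
  ordinary lstsq for accurate coefficients and t-test p-values.
- A candidate whose addition makes the window Gram non-positive-definite
  (collinearity) is skipped inside forward selection; the public
  `fit_ols` raises an error naming the collinear markers.
- DP ties are broken toward the earliest cut; BF ties toward the earliest
  candidate in screening order; SF2 sorting is stable, so equal SF2
  values keep input order.  All of this makes every pipeline stage
  deterministic given a seed.
- Quartile groups use inclusive boundaries (≤ Q1, ≥ Q3) so that tied
  samples are never silently dropped and groups cannot be empty on
  real-valued data.

## Problem sizes in the test suite

Unit and property tests run on cohorts of 6–130 samples and up to 10⁴
markers.  DP-vs-enumeration checks use N ≤ 30, minimum batch 5, K ≤ 3,
where exhaustive enumeration is cheap; breakpoint-recovery checks use 25
study-scale cohorts (129 × 10,010) and the null-calibration check 50
pure-null cohorts (129 × 10,000).  These sizes keep the full suite and
the reproduction script to a few minutes on one CPU while exercising the
method at the scale it was designed for.

## Known limitations

- The Bayes factor is the BIC approximation; other formulations (g-prior,
  JZS) would change selection paths.  The threshold semantics ("≥ 10 is
  strong evidence") are those of the standard evidence rubric.
- Greedy forward selection is not guaranteed to find the best subset; the
  DP is exact only over cut positions given the per-window greedy models.
- Exact Mann–Whitney inference is limited to pooled n ≤ 12 without ties;
  beyond that the tie-corrected normal approximation is used.
- The stabilisation rule compares breakpoints by exact value equality,
  which is meaningful because breakpoints are realized sample values; on
  data with duplicated SF2 values segment membership at a tie is decided
  by stable sort order and flagged by the equality of breakpoints across
  the cut.
- Screening, selection, and segmentation all share one candidate pool
  computed on the training set; validation data never influence feature
  selection, but the pool is re-used across every segment rather than
  re-screened within segments.
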