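# Methods

This note documents the models, defaults and numerical choices behind
`glycoseq`, and what the synthetic data does and does not establish.

## Read layout and barcode decoding

A barcode read is modeled as
`[trimmed prefix][5' flank][middle barcode][3' flank][filler]`.
The published protocol fixes the read length (26 bp) and the trim (first 3
bases) but not the exact flank/middle partition, so the layout is fully
configurable; the defaults (trim 3, 6 nt flanks, 8 nt middle) fill the
26 bp read. Matching is substitution-only: a read is assigned to the probe
minimizing middle-barcode mismatches, ties broken by fewer flank
mismatches, and accepted only when middle mismatches ≤ 1 and total flank
mismatches (5' + 3' combined) ≤ 2 — both maxima inclusive. The
two-mismatch flank budget is interpreted as shared across both flanks
(`per_flank=True` applies it per flank instead). Ambiguous reads —
equal-cost ties between distinct probes — are discarded; on a panel
satisfying the distance-≥ 3 invariant such ties can only arise at
mismatch counts ≥ 2, so no validly assignable read is ever ambiguous.
Indels are not modeled: the rule is stated in mismatch counts, and at 26 bp
an indel model would be speculative. There is no UMI collapsing; counts are
read counts. Cell indexes (i5, i7) resolve by exact match.

Conservation holds by construction:
assigned + unassigned (by reason) + unindexed + malformed = total reads,
and the decoder is verified read-for-read against an exhaustive
Hamming-distance oracle in the tests.

## QC thresholding

Otsu's method is applied to the 1-D sample of per-cell totals without
binning: candidate thresholds are the sorted unique totals, the
between-class variance w₀w₁(μ₀−μ₁)² is maximized exactly, ties prefer the
smaller threshold, and the threshold is reported as the largest low-class
value. Cells are kept iff total > threshold (strict, matching the
"higher than" phrasing of the published cut-offs). A binned mode
(`bins=n`) reproduces classic histogram Otsu for comparison with
histogram-based cut-offs.

Limitation: on strongly right-skewed totals with partially overlapping
modes, raw-scale Otsu biases the threshold into the high mode's lower tail
(we measured ~5% of high-mode cells lost at lognormal σ = 0.35 with a
12.5× mode ratio; ≤ 1% at σ = 0.25). The method is intended for clearly
bimodal totals, which is how it is exercised in the tests; log-transforming
totals before thresholding is a sensible alternative for marginal cases.

## Normalizations

- Percent: 100·count/total per cell. The default denominator is **all 41
  probes** (controls included) because the equimolar-mix average of
  100/41 ≈ 2.439% then matches the printed 2.43%; `lectins_only` is
  available.
- CLR: the log1p-centered form y = ln(x+1) − mean(ln(x+1)), continuous at
  zero counts. Default margin is per-probe (across cells), the tag-data
  convention; exact mean-zero along the margin is the testable contract —
  the pure log-ratio scaling invariance holds only asymptotically for the
  (+1) form and is not asserted.
- RNA: y = ln(1 + s·x/colsum), s = 10,000.

## Brunner–Munzel test

Implemented from the midrank formulas: effect estimate
p̂ = (mean pooled midrank of sample 2 − (n₂+1)/2)/n₁, within-sample rank
variances S², statistic n₁n₂(R̄₂−R̄₁)/(N√(n₁S₁²+n₂S₂²)), two-sided p from a
t distribution with Satterthwaite-type degrees of freedom. Degenerate
inputs (zero pooled rank variance, e.g. complete separation) are flagged
and report p = NaN rather than an invented closed form; callers decide how
to treat them (the CLI fills 1.0 before correction, the conservative
choice). The implementation is cross-checked against an independent
reference implementation and a pairwise-enumeration oracle; its empirical
null size at α = 0.05 is 0.048–0.054 over 10⁴ repeats at n = m = 30.

Bonferroni takes the family size m as a parameter (the published analyses
correct over a small family of pairwise comparisons); BH is the standard
step-up. PCA is mean-centered SVD with no variance scaling and a
deterministic sign convention (largest-magnitude loading positive). The
adjusted Rand index delegates to scikit-learn behind the module surface
and is tested against explicit pair counting.

## PLS

NIPALS with both blocks centered and unit-variance scaled by default
(`scale=False` gives pure centering). Per component: deterministic start
from the Y-residual column of largest variance; iterate
w ∝ X'u, t = Xw, c ∝ Y't, u = Yc to 1e-10 on w (max 500 iterations);
sign fixed by the largest-magnitude gene weight. Deflation is
**canonical**: X loses t·p' with p = X't/t't, and Y loses u·q' with
q = Y'u/u'u. This makes both decomposition identities
X = TP′ + E and Y = UQ′ + F hold exactly on the stored matrices — the
reason canonical deflation was chosen over regression-mode deflation,
which leaves the Y identity only approximate. T columns are mutually
orthogonal; U columns are not guaranteed orthogonal.

The component-1 pair (w, c) equals the leading singular-vector pair of the
processed cross-covariance X'Y (verified to machine precision). The
gene–lectin association matrix is A = Σₖ pₖqₖ′ over selected components.
The quantity that decreases across components is the score covariance
|t′u| the algorithm greedily maximizes; per-component explained Y variance
is non-increasing when the data's low-rank signal dominates, but can
fluctuate at noise level for trailing components — both behaviors are
pinned down in the tests. Default components: 10. The default gene
pre-filter is "nonzero variance" (zero-variance columns are an error when
scaling).

## Pseudotime dynamics

The Gaussian identity-link additive fit is realized as fixed-df cubic
B-spline regression: df basis columns (intercept excluded), interior knots
at pseudotime quantiles, default df 4. The spline model is compared to the
intercept-only model with an exact F-test — deterministic, with exactly
uniform null p-values (empirical size 0.04–0.06 at α = 0.05 over 10⁴ null
features), at the cost of not selecting the smoothing parameter from data.
p-values below 1e-300 are floored; perfect fits report p at the floor.
BH correction runs across all tested features. An optional
highly-variable-feature pre-filter keeps the top fraction (default when
enabled: 20%) by variance of log1p signal.

The direction label is a heuristic endpoint comparison of the fitted
curve: increasing/decreasing when the endpoint change covers at least half
the fitted range, non-monotone otherwise. Noisy mid-range wiggles can
demote a genuine monotone trend to "non-monotone"; the significance call
is unaffected.

LOESS smoothing is local linear regression with tricube weights over the
span-fraction nearest neighbors, evaluated on a 100-point grid, no
robustness iterations; exact for linear data.

## Synthetic data

The read-level generator emulates the assay's evaluation conditions: a
41-probe panel (39 lectins + 2 IgG controls) with rejection-sampled 8-mer
barcodes at pairwise distance ≥ 3, 26 bp reads, multinomial molecule
counts per cell, and deterministic per-probe PCR bias (1+e)^20 cycles,
mean-normalized (per-probe efficiency, not per-molecule branching — enough
to reproduce the fold-range phenomenology at desk scale). The default
efficiency spread U(0.875, 1.0) keeps every probe's fold deviation from
the mean percentage within two cycles of amplification at the mean
efficiency, i.e. inside [0.25, 4], bracketing the published 0.26–1.58
range; substitutions are iid per base; read 2 is reverse-complement
filler with constant "I" qualities.

The matrix-level generator produces two populations of 48 cells laid out
along a pseudotime in [0, 1]: a marker probe elevated 2 log-units in the
early population, planted dynamic lectins (sigmoid/linear trends with full
swing 2× the 0.35 log-scale noise SD), and planted gene–lectin association
blocks driven by shared standard-normal latent factors, each planted
feature carrying its factor at the block's per-feature SNR (default 2).
RNA counts are negative-binomial (dispersion 0.2) at depth 50,000 over 200
genes; glycan counts are multinomial at depth 10,000 over 41 probes. A
Gaussian benchmark (`simulate_association_gaussian`, n = 96, 50 genes, 10
lectins) isolates the association-recovery question from count noise.

What the simulations do **not** capture: ambient barcodes, doublets, index
hopping, sequencing-chemistry error profiles, gene–gene correlation
structure beyond the planted factors, and realistic transcriptome sparsity.
Passing tests therefore establish the correctness and calibration of the
algorithms under their stated models, not performance on real libraries.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as representative:
10⁴–8·10⁴ simulated reads, 96-cell matrices (matching the study's
plate size), 200-gene transcriptomes, 10⁴ repeats for null-calibration
estimates. The acceptance script reports the dynamics screen's recall and
false-discovery proportion averaged over 10 replicate screens, since a
single 200-feature screen yields only ~21 discoveries and its realized FDP
is dominated by 2–3 read-outs of Poisson noise.
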