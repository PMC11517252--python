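# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `eep-mpra` pipeline, in the order data flows through it.

## Quantification model

A barcode's activity in one replicate is the ratio of its
counts-per-million in the cDNA table to its counts-per-million in the
plasmid (pDNA) table. The normalisation scale is arbitrary — any constant
cancels in the cDNA:pDNA ratio and again in boost indices — and CPM is used
purely for interpretability. Three quality rules shape the estimates:

* **Ambiguity filter.** A barcode observed with more than one insert
  identity (promoter, fragment pair, orientations) is removed outright;
  exact duplicate rows are first collapsed (set semantics), so only genuine
  identity conflicts are discarded.
* **pDNA floor.** A barcode enters a replicate only with ≥ 8 *raw* pDNA
  counts; below that, the plasmid abundance estimate in the denominator is
  too unstable. The raw-count reading (rather than normalised) is
  deliberate: the rule exists to bound Poisson counting error.
* **Barcode minimum.** A combination is quantified in a replicate only from
  ≥ 5 barcodes (arithmetic mean of barcode activities). The minimum is
  enforced *per replicate*, so one deeply sequenced replicate cannot mask
  sparse coverage in the others.

Replicate means are combined with a geometric mean, the natural average for
a ratio-scale quantity. Zero-expression barcodes keep activity 0 (no
pseudocount — the ratio formula is applied as stated; an optional CPM
pseudocount exists but is off by default), and a combination with a zero
replicate mean is excluded from the geometric-mean step and counted in the
QC report. Combinations surviving in a single replicate are flagged
`low_replicate` rather than dropped.

## Baselines, boost indices, activation calls

The baseline of a promoter is the *median* combined activity over its
control–control (CC) combinations; the median resists the occasional
scrambled control with residual activity. The sample SD over the same CC
set is retained for error propagation. A warning is logged when fewer than
30 CC combinations support a baseline (sparse libraries make noticeably
noisier baselines). Boost indices are log2(activity / baseline); aggregation
over orientations and positions is an arithmetic mean in log2 space, which
equals the log of a geometric mean of activity ratios. CC boost indices are
referenced to the per-promoter CC median by default (so their median is 0
per promoter); referencing to the global control median is available via
`cc_boost_indices(..., per_promoter=False)`.

Enhancer activation is tested per (enhancer, promoter) by a two-sided
Wilcoxon rank-sum comparison of the enhancer's EC/CE boost records against
the promoter's CC boost distribution, with Benjamini–Hochberg control at 1%
FDR across all tests of a run.

## Additivity analysis

Single-enhancer activities are estimated per position: `A_E1CP` is the
median over all combinations with the enhancer at position 1 and a control
at position 2 (both orientations pooled), `A_CE2P` the converse. Expected
activities are computed in **linear space** per position-resolved enhancer
pair, after averaging observed activities over orientation variants:

* additive: `A_E1CP + A_CE2P − A_CCP`
* multiplicative: `A_E1CP · A_CE2P / A_CCP`

The SD of the additive expectation is propagated as the square root of the
summed variances of the three inputs, where each variance is the sample
variance across the combination set behind the corresponding median — the
only spread estimate available at that aggregation level. The variance of
the baseline term is included by default; `include_baseline_variance=False`
gives the two-term variant. Classification (supra / sub / within) applies
the ±1 SD band in linear space, because the propagation formula lives
there; a log-space band is available behind `log_space_band=True` for
sensitivity analysis. Records whose additive expectation is non-positive
(possible when the baseline exceeds both single estimates) or whose SD is
undefined (a single-enhancer median resting on one combination) are flagged
invalid, excluded from classified outputs, and counted in the QC log.

Model preference restricts to records where the two expectations differ by
more than 0.5 log2 units — below that gap, measurement noise decides which
model "wins" — and compares absolute log-space distances. No SD is defined
for the multiplicative expectation, so this comparison carries no error
bars. Note the algebraic ordering: whenever both single activities are at
or above baseline, `(a−b)(c−b) ≥ 0` forces the multiplicative expectation
to be ≥ the additive one, so multiplicative overestimation grows with
enhancer strength.

Per-enhancer summaries average log2(observed/expected-additive) over all
pairs containing the enhancer (either position; self-pairs once); an
enhancer is "consistently supra-additive" in a promoter context when that
mean exceeds 0.5 log2. Cluster comparison collapses ordered records to
unordered pairs per promoter (each pair in exactly one group), pools across
promoters, and compares same-cluster vs different-cluster pairs with the
rank-sum test.

## Promoter selectivity

Per-promoter populations of a single enhancer's boost records have visibly
unequal variances (weak promoters produce wider boost distributions), so
selectivity uses Welch's heteroscedastic one-way F (Welch 1951): weights
`n_i/s_i²`, the `h`-based denominator correction, and an F reference with
`df1 = k−1`, `df2 = (k²−1)/(3h)`. Groups need n ≥ 2 and non-zero variance;
enhancers with fewer than two usable groups are reported "not testable".
Populations are screened with Shapiro–Wilk at 1% FDR; the screen is
reported but does not gate the F-test.

## Promoter scaling

For every enhancer pair present in all promoter libraries
(position/orientation-averaged boost indices), the cross-promoter mean
boost defines a common x-axis; each promoter's observed boosts are
regressed on it by ordinary least squares (intercept included; a
no-intercept variant is exposed). Because every fit shares the same x, the
unweighted mean of slopes over a fixed shared key set is exactly 1 — a
useful internal consistency check, asserted in the tests. The
slope–baseline relation reports Pearson R of slope against log2 baseline
(and against raw baseline); promoters without a CC-derived baseline are
excluded with a warning. The same machinery runs on single-enhancer (EC)
keys. Slopes are *relative* to the cross-promoter average: absolute
power-law exponents are not identifiable because there is no absolute unit
of enhancer strength.

## Statistical primitives

* **Wilcoxon rank-sum**: for `min(n, m) ≤ 8` (and a tractable number of
  assignments) the two-sided p is exact, by enumerating all `C(n+m, n)`
  assignments of the pooled midranks — valid in the presence of ties, and
  p is then a multiple of `1/C(n+m, n)`. Larger samples use a normal
  approximation with tie-corrected variance, continuity correction, and a
  one-term Edgeworth refinement using the null excess kurtosis
  `−(6/5)(n²+m²+nm+n+m)/(nm(N+1))` (Fix–Hodges). The refinement matters:
  the plain continuity-corrected normal deviates from the exact two-sided p
  by up to 0.011 at n=m=8, the Edgeworth-corrected form by ≤ 0.0006, so the
  two routes agree to well within 0.01 at the hand-over size.
* **BH-FDR** (statsmodels), **Shapiro–Wilk**, **Pearson r**, **OLS**
  (scipy) are thin wrappers with input validation. Note that BH adjusted
  p-values are *not* idempotent under re-adjustment (e.g. [0.25, 1.0] →
  [0.5, 1.0] → [1.0, 1.0]); downstream code treats q-values as final.

## The simulator

The generator emulates the assay that motivates the pipeline: 8 promoter
libraries × (59 enhancers + 20 scrambled controls)², three biological
replicates, ten barcodes per combination — 49,928 combinations, or 199,712
counting the four orientation/position variants.

Ground truth: promoter baseline `b_P`, enhancer contribution `c_E ≥ 0`
(exactly 0 for controls), raw combined signal `R` (additive
`b_P + c1 + c2`, optionally plus a supra-additive bonus `2^δ · min(c1, c2)`
for designated pairs; or multiplicative `b_P(1 + c1/b_P)(1 + c2/b_P)`), and
a promoter power law `A = b_P (R/b_P)^γ_P`. CC combinations therefore sit
exactly at `b_P` for any γ. Counts follow a log-normal/Poisson hierarchy:
per-clone representation weight `w ~ LogNormal(0, 0.5)` shared across
replicates, expression noise `ε ~ LogNormal(0, 0.15)` fresh per clone and
replicate, pDNA counts `Poisson(depth · w/Σw)` and cDNA counts
`Poisson(depth · wAε/Σ(wAε))`, drawn **per promoter library** — each
library is transfected and sequenced separately, so depths (default 10⁷)
are per library and replicate. A configurable fraction (default 2%) of
barcodes is re-used for a second identity in the same library, giving the
ambiguity filter a realistic target. All randomness derives from one seed
split into per-stage substreams, so catalogs, truth, assignments and counts
are each reproducible in isolation.

Default parameters were calibrated once, at design time, so the synthetic
assay lands in the regime the real assay reports: baselines
`2^linspace(2, −2, 8)` (a 16-fold promoter-strength ladder) and
`c_E ~ LogNormal(−0.5, 1)` give median single-enhancer boosts ≈ 0.7 log2
with a tail to ≈ 5 log2, and — under exactly additive truth — ≈ 73% of
enhancer-pair activities within one propagated SD of the additive
expectation and ≈ 96% within two. The per-combination measurement SD at
these settings is ≈ 0.055 log2 for raw position-resolved records and
≈ 0.04 log2 for the position/orientation-averaged boost indices the
analyses consume.

What the simulator deliberately does **not** model: orientation effects
(orientation labels are carried but all clones are '+'/'+'; real assays
show little orientation dependence, and the pipeline treats orientation as
a pass-through grouping key), barcode sequence errors (count tables are
assumed already clustered), partial library coverage (every combination is
represented; real libraries cover ~70%), residual activity of scrambled
controls, enhancer–enhancer distance or chromatin context, and replicate-
level batch effects (replicates share clone weights but are otherwise
exchangeable, which makes simulated replicate correlations, R ≈ 0.99,
higher than typical experimental values). Consequently, passing recovery
tests demonstrates the estimators are unbiased and correctly calibrated
under the stated noise model — not that the pipeline is robust to every
artefact of real libraries.

One structural observation the simulator makes vivid: with exactly linear
(γ = 1) additive promoters, scaling slopes still spread far from 1 and
anti-correlate with baseline, because a fixed linear increment is a larger
*fold* change on a weak promoter. Noise-driven supra- and sub-additive
calls likewise both become more frequent as baselines fall (the SD band
narrows relative to the signal). In the simulator these two tails grow
symmetrically; an asymmetric excess of supra-additive calls on weak
promoters — as real data show — is therefore a genuine biological signal,
not an artefact of the classification rule.

## Problem sizes used in validation

The test suite validates small configurations (2–3 promoters, 14–18
fragments) for speed, plus three design-scale runs (full 8×79×79 additive,
the same with δ = 1 injected into 40 enhancer pairs, and a 5-promoter run
with γ ∈ {0.4, 0.7, 1.0, 1.3, 1.6} against baselines {4, 2, 1, 0.5, 0.25})
— the same three runs `scripts/acceptance.py` performs. Each design-scale
run takes ≈ 15 s.
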