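# Methods

This note records the statistical model, the numerical conventions, and the
design choices behind `tsmr`, in the spirit of a package vignette. It states
nothing that the test suite or `scripts/acceptance.py` does not itself
compute.

## Two-sample MR and its assumptions

The package estimates the causal effect of an exposure on an outcome from
two non-overlapping GWAS. A genetic variant is a valid instrument when it
(1) is associated with the exposure, (2) shares no common cause with the
outcome, and (3) affects the outcome only through the exposure. Assumptions
(2) and (3) are jointly "independence from pleiotropy"; the estimator suite
is designed around the fact that with many instruments some will violate
them:

* **IVW** assumes all instruments valid. We use the fixed-effect form:
  weights w_j = β̂²_Xj/σ²_Yj (first-order delta method, exposure-side
  sampling error ignored), β̂ = Σw_jθ̂_j/Σw_j, SE = (Σw_j)^(−1/2), normal
  reference. A random-effects or heterogeneity-corrected variant
  (Cochran's Q, I²) is deliberately out of scope.
* **Weighted median** tolerates up to (but not including) half of the
  weight on invalid instruments. With ratio estimates ordered
  θ_(1) ≤ … ≤ θ_(m) and normalized weights w′, the standardized cumulative
  weight is s_j = Σ_{k≤j} w′_k − w′_j/2 and the estimate linearly
  interpolates the bracketing pair around s = 0.5 (boundary θ when s₁ ≥ 0.5
  or s_m ≤ 0.5). The SE is the standard deviation of the estimate over
  parametric-bootstrap replicates (β̂_X, β̂_Y redrawn from normal(β̂, σ)),
  default 1,000, mandatory seed; below 100 replicates the function warns.
* **MR-Egger** regresses β̂_Y on β̂_X with an unconstrained intercept,
  weights 1/σ²_Yj, after orienting each instrument so β̂_X ≥ 0 (the
  intercept is otherwise uninterpretable). The intercept estimates mean
  directional pleiotropy under InSIDE (pleiotropic effects independent of
  instrument strength); the slope is a pleiotropy-corrected causal
  estimate. Coefficient covariance is scaled by the residual dispersion
  floored at 1 — never deflated below the fixed-effect level — and
  inference uses t(m−2). This requires ≥ 3 instruments and at least two
  distinct β̂_X values.

All 95% intervals use the exact 0.975 quantile of the reference
distribution, not 1.96. IVW and weighted-median p-values use the normal
reference; published MR tables do not always state their conventions, so
p-values computed here need not reproduce any particular table's p-values
even when the estimate and CI match.

## Instrument selection and harmonization

* Genome-wide filter: strictly p < 5×10⁻⁸ (configurable).
* LD pruning: greedy, visiting variants in ascending (p-value, variant id)
  order; a variant is kept iff its known r² with every kept variant is
  ≤ 0.05. Unknown r² is treated as independence, because LD tables
  typically enumerate linked pairs only; `strict=True` turns an unknown
  pair into an error. The tie-break on equal p-values (lexicographic id)
  makes the output a function of the set, not the row order.
* Proxy substitution: an instrument missing from the outcome study is
  replaced by the variant with maximal known r² to it, strictly > 0.8,
  drawn from the exposure∩outcome intersection (a proxy is useless without
  both effect estimates); ties break on smaller exposure p, then id. The
  pairwise-r² guarantee of pruning is asserted at pruning time; a proxy
  stands in for an instrument that satisfied it and is not re-checked
  against the other instruments.
* Exclusion lists re-run the full estimator suite on a reduced instrument
  set (the classic "drop variants with known secondary trait associations"
  sensitivity analysis).
* Harmonization expresses every outcome record on the exposure's effect
  allele: label swap → negate β̂_Y and complement the frequency; strand
  complement → relabel only; both → both. Palindromic variants (A/T, C/G)
  cannot be resolved from labels; the default policy drops them, and an
  optional `infer-by-eaf` policy aligns on frequency when both studies are
  on the same side of 0.5 by more than a tolerance (default 0.08), dropping
  otherwise. Harmonization never touches a standard error, never silently
  repairs a value, and logs every action to a per-variant audit.

The Bonferroni threshold reported for each exposure-outcome pair is
α / (final post-harmonization instrument count). The pre-selection and
post-harmonization counts can differ (proxies dropped, palindromes removed),
and published analyses are not always explicit about which count they
divide by; the choice here is logged with both counts so a reader can form
either threshold.

## The synthetic-data generator

`simulate_two_sample` emulates the summary statistics of a large
anthropometric exposure GWAS paired with an early-growth outcome GWAS:
per SNP, a true exposure effect γ_j ~ Uniform(0.04, 0.16) SD/allele, a
pleiotropic outcome effect α_j (zero; N(0, τ²) balanced; or N(μ, τ²) on a
chosen fraction of SNPs, drawn independently of γ_j so InSIDE holds), and
observed effects β̂_Xj ~ N(γ_j, σ²_Xj), β̂_Yj ~ N(βγ_j + α_j, σ²_Yj).

Default SEs are σ_X = 0.0033 — the sampling error implied by a
standardized-trait GWAS of n ≈ 224,000 at minor-allele frequency ≈ 0.3,
via σ ≈ 1/√(2p(1−p)n) — and σ_Y ~ Uniform(0.01, 0.03), spanning outcome
GWAS of roughly 10,000–150,000 individuals. With these defaults the
smallest true effect has expected |z| = 12, so every instrument clears the
genome-wide filter by construction, and regression dilution from
exposure-side error is negligible (reliability ≈ 0.99), which keeps the
Egger intercept an essentially unbiased estimate of μ at the replicate
counts the tests use. γ_j is drawn positive; sign heterogeneity enters
through allele coding, not effect direction, which keeps the truth record
simple.

The generator also emits block LD (all within-block pairs at a stated r²),
assigns palindromic allele pairs to a stated fraction of SNPs, and corrupts
a stated fraction of the *outcome* table's allele codes with random swaps
and strand flips (recorded in the truth record), so harmonization can be
tested as exact inversion of a known corruption. One global seed drives
six per-purpose streams (effects, exposure noise, outcome noise,
pleiotropy, alleles, corruption), so toggling one feature never perturbs
the draws of another.

What the generator does **not** emulate — and therefore what passing tests
do not certify about real data: realistic allele-frequency spectra and
frequency-dependent effect sizes, winner's curse in the discovery GWAS,
cross-block LD and MAF-correlated LD, sample overlap between the two
studies, and pleiotropy correlated with instrument strength (InSIDE
violations). Estimator behaviour under those features must be argued
separately.

## Numerical conventions and degenerate inputs

* p-values are clamped to the smallest positive double rather than
  underflowing to 0, preserving the (0, 1] invariant.
* β̂_X = 0 makes a ratio undefined and raises a degenerate-instrument
  error; all-equal β̂_X raises a singular-design error in MR-Egger.
* Result tables print 3 significant figures with CIs as "low to high"; the
  JSON mirror carries full precision. Reading a summary-statistics file
  drops (and counts) rows violating the record invariants — positive SE,
  p ∈ (0, 1], single-nucleotide A/C/G/T alleles, frequency in [0, 1] —
  and never edits a value.
* Weighted-median bootstrap replicates may redraw β̂_X through zero; the
  resulting extreme ratios are legitimate bootstrap mass, not errors.
* Per-pair bootstrap seeds are derived from the global seed and the pair
  index via a seed sequence, so grids are reproducible pair-by-pair and
  the JSON mirror is byte-identical across reruns.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use 1,000 replicates of 25–30-instrument scenarios
(parameter recovery, CI coverage, Egger type-I error and directional
recovery, weighted-median robustness with 40% invalid weight), 100 random
3–50-instrument sets for the weighted-least-squares oracle comparisons
(agreement to 1e-10 relative; statsmodels is the independent oracle, never
the implementation), and a hand-traced 5-SNP fixture covering every
selection and harmonization branch. These sizes give Monte-Carlo standard
errors comfortably below the tolerances they are checked against.

## Known limitations

* Fixed-effect IVW only; no heterogeneity statistics, no MR-PRESSO-style
  outlier removal, no multivariable MR, no leave-one-out scans.
* LD must be supplied as a pairwise table; there is no reference-panel
  computation and no distance-window clumping.
* No multi-allelic variants or indels; no strand resolution against a
  reference genome beyond the frequency heuristic for palindromes.
* The weighted-median SE is a bootstrap quantity: its value (and hence the
  CI and p) depends on the seed and replicate count, though the point
  estimate does not.
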