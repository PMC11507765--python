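# Methods

## Rank normalization and pooling

Each DMS assay measures variant effects on its own scale, so scores are
only comparable within an assay. Records are first restricted to single,
non-synonymous substitutions between the 20 standard amino acids
(multi-mutant strings, synonymous rows, stop gains and malformed tokens
are dropped, with per-reason tallies logged). Scores are then converted to
percentile ranks *within each assay*: quantile = (average rank)/n, with
ties broken by rank averaging. This yields values in (0, 1], never exactly
0 — the convention is documented because the modeled support is [0, 1].
An explicit `higher_is_fitter` flag per assay fixes score polarity
(ranking is performed on negated scores when false), so quantile 1 is
always the fittest variant. Replicate rows for the same variant are kept
and ranked independently; ranking handles them naturally.

Quantiles are pooled across assays by ordered replacement type (from,
to), giving up to 380 type-specific samples. By construction the pooled
quantiles over *all* types within one assay are uniform; a type-specific
departure from uniformity is exactly the information the analysis
extracts. Because ranking is invariant to monotone transformations of raw
scores, the choice of raw-score scale is irrelevant to everything
downstream.

## The truncated exponential family

The maximum-entropy distribution on [0, 1] with a fixed mean is
p(x) = c·e^{−λx}, c = λ/(1 − e^{−λ}), with λ real: positive λ means the
type is deleterious-leaning (mean < 0.5). Mean and variance are

    μ(λ) = 1/λ − 1/(e^λ − 1),       σ²(λ) = 1/λ² − e^λ/(e^λ − 1)²,

with limits 1/2 and 1/12 at λ = 0. Both are evaluated via `expm1`/`sinh`
forms, with Taylor branches (μ: |λ| < 1e−6; σ²: |λ| < 1e−4) to avoid 0/0;
the thresholds keep the series truncation error below 1e−12. The
mean–variance curve traced by (μ(λ), σ²(λ)) is an inverted U, symmetric
about μ = 0.5 and peaking at (0.5, 1/12); empirical (mean, variance)
points landing on this curve is the diagnostic that justifies
constraining only the first moment.

λ is recovered from a sample mean by safeguarded Newton iteration, using
the exponential-family identity dμ/dλ = −σ² for the derivative,
initialized at λ₀ = 12(0.5 − μ) (the linearization of μ about 0),
tolerance 1e−10 on μ, at most 100 iterations, with bisection fallback on
the bracket [−500, 500] whenever a Newton step would leave it. Means of
exactly 0 or 1 (possible on degenerate samples) raise rather than
returning ±∞; means outside (μ(500), μ(−500)) ≈ (0.002, 0.998) raise a
convergence error. Transfer to another measurement scale composes the
family's inverse CDF with a monotone map F⁻¹ (the overall inverse CDF on
the target scale); the induced distribution minimizes KL divergence from
the overall target-scale distribution subject to the exceedance
constraint.

## The test battery

Per ordered type: a one-sample KS test against the uniform CDF (is the
type distinguishable from the background DFE at all?); a split-half
goodness-of-fit test — a random half of the sample (the larger half when n
is odd) estimates the mean and hence λ, and the held-out half is KS-tested
against the fitted CDF, avoiding the bias of testing against a
distribution fitted on the same data; and a monotonicity score, the
absolute Spearman correlation between bin index and bin count over 15
equal-width right-closed bins (values exactly 1.0 fall in the last bin;
a perfectly flat histogram scores 0). Per unordered pair with both
directions present: a two-sample KS test for forward/reverse asymmetry.

KS p-values are asymptotic (per-type n runs to the hundreds or
thousands; scipy's `ks_1samp`/`ks_2samp` with `method="asymp"` implement
exactly the sup-gap statistics used here). Bonferroni families are fixed
at 380 for per-type tests and 190 for asymmetry tests, the full
enumeration of types and unordered pairs, regardless of how many are
present in a given dataset; corrected p-values are capped at 1.
Significance (corrected p < 0.05) is what *asymmetric* and *rejected*
mean throughout. Split-half assignment is uniformly random; each type's
split derives a child seed from the battery seed in sorted pair order, so
whole-battery runs are deterministic.

## The selection model

Stringency q ∈ [0, 1): replacements with fitness quantile below q are
rejected. The normalized substitution rate for a type with parameter λ is

    K_λ/K_s(q) = (1 − e^{−2(1−q)(−λ)}) / (1 − e^{−2(−λ)}),

implemented exactly in this form (an overflow-safe e^{a−b} factorization
is used for λ > 0). It equals 1 at q = 0, (1 − q) at λ = 0, and is
strictly decreasing in both arguments. Note the exponent carries 2λ, not
λ: the expression coincides with the Kimura fixation probability at
scaled coefficient −2λ and initial frequency 1 − q, and differs by a
factor of 2 in the exponent from the survival probability obtained by
naively truncating the density itself. The form is kept as stated; the
Monte-Carlo check of threshold semantics therefore asserts only rank
agreement between simulated sharp-truncation acceptance frequencies and
the analytic rate, not numerical equality. The q → 1 limit of
K_λ/K_s ÷ (1 − q) is 2(−λ)/(1 − e^{2λ}); "q → 1" is operationalized as
q = 1 − 1e−6 by default, which agrees with the limit to ~1e−6 relative.

Exchangeability prediction covers the 75 unordered pairs of amino acids
whose codons differ at exactly one position under the standard genetic
code (NCBI table 1, enumerated from Biopython's table; stop-adjacent
paths contribute nothing; alternative code tables can be supplied). In
the underlying codon model Q_ij ∝ μ_ij·U_ij·π_j, the mutational bias and
stationary frequencies cancel in U_ij ∝ 2/((1/Q_ij) + (1/Q_ji)), so only
the cancelled harmonic-mean form is implemented: each pair's raw value is
the harmonic mean of the forward and reverse K_λ/K_s, and the 75 values
are divided by their mean so the prediction averages 1, matching the
published scaling convention of the U index. The predicted dynamic range
(max/min) is non-decreasing in q.

## Synthetic data

The generator emulates the study conditions the pipeline is meant for:
380 ground-truth λ* drawn by sampling target means uniformly on
[0.22, 0.71] (the span of real mean quantiles, a ~3-fold dynamic range)
and inverting the mean function; 20 assays × 19,000 mutations = 380,000
records by default, giving ~1000 observations per type under uniform
composition — matching the per-type depth of the large aggregated DMS
compilations (which average ~940 per type across 87 assays; fewer, larger
assays are generated here because ranking is within-assay either way and
generation is faster). Latent quantiles are drawn by inverse-CDF sampling
from each type's truncated exponential; raw scores push the latent
quantile through a heavy-left-tailed monotone map (log by default — most
mutations deleterious), which rank-based inference then inverts exactly.

The "stability" regime designates a random ~1/5 of types to draw instead
from unimodal interior-mode Beta distributions (mode uniform in
[0.3, 0.7], concentration 12), emulating thermostability-like measures
where the exponential law genuinely fails; it exists to verify the
split-half test *rejects* where it should. A noisy observed-U generator
multiplies predictions by independent lognormal noise of a given
coefficient of variation (mean-1 parameterization) and re-centers, for
end-to-end comparison tests.

What the synthetic data does not emulate: real protein sequences or
structures, per-assay composition biases tied to actual amino-acid
frequencies, assay-specific noise floors, or epistasis. One real-data
feature it does reproduce and the tests account for: because the pooled
within-assay score distribution mixes all types, re-ranked quantiles are
a slightly distorted (monotone) image of the latent ones, so recovery
tolerances carry a small slack beyond pure sampling error. Passing tests
demonstrate correctness of the machinery under the stated generative
model, not that any particular real dataset follows the exponential law.

## Balanced resampling

To probe composition effects, per-assay representation of the 380 types
can be equalized by up-sampling every type with replacement to the
assay's maximum per-type count, or down-sampling without replacement to
the minimum. This requires assays that cover all 380 types; fitted λ
values should move by less than sampling error (the delta-method standard
error of λ̂ is 1/√(n·σ²(λ)), since dμ/dλ = −σ²).

## Sizes and determinism

Default test and acceptance runs use the full 380-type scenarios
(~380,000 records each for the recovery, null and stability batteries);
a complete pipeline pass takes a few seconds. Every stochastic step takes
an explicit seed, all derived seeds stay below 2³¹, and identical config
plus seed reproduces byte-identical TSV/JSON outputs.

## Known limitations

- Asymptotic KS p-values are inaccurate below n ≈ 50; per-type counts in
  the intended use are far larger.
- Means outside ≈ (0.002, 0.998) are not invertible within the λ bracket;
  such degenerate types should be pooled further instead.
- The threshold model describes conservatism under purifying selection;
  it says nothing about adaptive (beneficial-mutation) regimes.
- Bonferroni family sizes assume the full 380/190 enumeration; analyses
  of partial type sets inherit conservative corrections.
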