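# Methods

## Scope and quantities

`pairscreen` analyses *single-dose* combination screens. Every measurement
is a viability g: the fraction of cells surviving a treatment relative to
untreated control, at one fixed dose per drug. Throughout the package g is
survival, not kill fraction — this is the convention under which the
embedded reference table's printed interaction scores reproduce (e.g. for
the H1299 CPT+CisPt pair, ln(1 + 0.67 − 0.77·0.82) = 0.038 → 0.04 as
printed; a kill-fraction or base-10/base-2 reading does not reproduce the
table). Viabilities slightly above 1 are allowed (assay noise); values
above 2.0 are rejected as probable unit errors (percent vs fraction).

Predictions only apply at the doses at which the pairs were measured; dose
interpolation and response-surface fitting are out of scope.

## Prediction models

All models map single viabilities gᵢ and/or pair viabilities g_ij to an
M-drug cocktail viability:

* **Bliss** g = ∏gᵢ; **pairs** g = (∏g_ij)^(1/(M−1)); **regression**
  g = ∏g_ij·(∏gᵢ)^−(M−2); **log-linear family**
  g = (∏g_ij)^α(∏gᵢ)^β with β = 1 − (M−1)α, which contains the first three
  at α = 0, 1/(M−1), 1 and is Bliss-conserving for every α.
* **Isserlis** (maximum-entropy pairing): triplet
  g₁g₂₃ + g₂g₁₃ + g₃g₁₂ − 2g₁g₂g₃; quadruplet the sum over the three
  perfect pairings minus twice the product of singles. It is implemented
  for M ∈ {3, 4} only: no pairing formula for M ≥ 5 is established, and any
  extension would be a guess, so higher orders raise `UnsupportedOrderError`
  and appear in skip lists. The formula is not positivity-preserving;
  negative outputs are clamped to 0 with a `clamped` flag (viability is
  non-negative by definition), never silently.

Numerical guards: formulas with negative single exponents raise
`DegenerateInputError` when any single ≤ 1e−9 (a division blow-up must be
visible, not clamped); 0^positive = 0 is allowed in the pair part. Missing
inputs raise `MissingInputError` naming the absent measurements — at the
dataset level these become per-cocktail skip-list entries rather than
failures, which is exactly how cocktails containing an unmeasured pair are
excluded from evaluation.

`predict_dataset` iterates the cocktails appearing anywhere in the dataset
(union over cell lines) and predicts them for the requested cell line when
inputs allow. Evaluation (`evaluate_models`) scores only cocktails that
also have an observed record, pooling cell lines, by
R² = 1 − SSres/SStot — unclipped, so badly mis-scaled models show
meaningfully negative values. The default `min_order=3` excludes pairs from
evaluation: they are model inputs, and scoring them would trivially inflate
any pair-based fit.

## Interaction score and bootstrap

I = ln(1 + g_observed − ∏gᵢ), natural log; I < 0 synergy, I > 0
antagonism. The log argument must be positive, otherwise the score is
undefined and a `DomainError` is raised (fail fast — repeats are never
dropped silently).

Confidence intervals: per-repeat scores I_r = ln(1 + g_r − ∏ singles) use
the *mean* single-drug viabilities (singles are fixed, not jointly
resampled — the per-repeat variation of the cocktail measurement is the
quantity bootstrapped). The I_r are resampled with replacement n_boot
(default 10,000, minimum 1,000) times; the reported I is the mean of the
resample means and the CI their plain 5th/95th percentiles (no BCa). Fully
reproducible given a seed.

Classification is strict: **antagonistic** iff I > 0 *and* the 5th
percentile > 0; **synergistic** iff I < 0 *and* the 95th percentile < 0;
otherwise **additive**. The extra condition on the sign of I itself makes
the three labels exhaustive and mutually exclusive even for degenerate
intervals.

On the embedded reference screen, where raw repeats are not published, the
consistency analysis uses the printed I and CI columns directly. One known
limit of working from a printed table: two of its H1299 CI bounds are
printed as exactly 0.00, so their true (unrounded) sign is unrecoverable
and the strict rule classifies those two cocktails additive — the H1299
antagonistic/synergistic counts from the printed columns are 6 and 21
(19 with a same-sign pair; both exceptions triplets), slightly below the
counts obtained from unrounded repeat-level data (7 and 22, 3 exceptions).
The HeLa counts (16/16 and 10/10) reproduce exactly.

## Noise amplification

Under independent multiplicative noise exp(σZ), Z ~ N(0,1), on every input
measurement, a model (∏pairs)^a(∏singles)^b has log-prediction standard
deviation σ·√(a²·M(M−1)/2 + b²·M). Hence Bliss → √M, regression →
√(M(M−1)/2 + M(M−2)²), pairs → √(M/2(M−1)); for triplets √3 ≈ 1.73,
√6 ≈ 2.45, √(3/4) ≈ 0.87. For every M the ordering pairs < Bliss <
regression holds — the pairs model's 1/(M−1) exponents shrink noise below
even a single measurement's. The Monte-Carlo estimator
(`noise_amplification_mc`) checks the closed forms by actually perturbing a
Bliss-consistent ground truth and evaluating the formula in linear space
(default 10⁵ simulations, σ ≤ 0.2; the factor is σ-independent because the
family is exactly log-linear).

## Ranking accuracy

For prioritization, `ranking_accuracy` measures the overlap between the
top-k most *effective* (lowest-viability) cocktails by observation and by
prediction, k = floor(top_fraction·n), ties broken by canonical cocktail
name for determinism. A random predictor scores k/n in expectation
(hypergeometric mean), the baseline the sanity tests assert.

## Synthetic screens

`generate_screen` emulates a fully factorial single-dose screen with known
structure: true singles ~ Uniform(single_range); true pairs
g_ij = gᵢg_j·exp(δ_ij), δ_ij ~ N(0, pair_interaction_sd); true higher
orders from the log-linear family at a known exponent `true_alpha`
(optionally plus a per-cocktail log deviation `high_order_sd` to emulate
genuine third-order interactions); observed repeats multiply the truth by
exp(noise_sigma·Z) independently. Defaults (6 drugs, single_range
(0.6, 0.9), pair_interaction_sd 0.1, noise_sigma 0.05, 6 repeats) describe
a realistic high-survival (LD20-style) cytotoxicity screen: ~80% survival
doses, pair interactions of roughly ±10% on the log scale (the spread seen
in real pair screens), 5% multiplicative assay noise, six biological
repeats. Multiplicative log-normal noise is a modelling choice — real
assays also have additive background and plate effects the generator does
not emulate, so passing recovery tests demonstrate correctness of the
machinery under the stated noise model, not robustness to every real-world
artifact.

`recover_alpha` closes the loop: it requires a screen whose order-≥3
cocktails share a single order M (the optimum 1/(M−1) is order-specific)
and returns the alpha-scan argmax. Alpha-scan ties resolve to the smallest
α — the lower-variance model — which also makes the degenerate case
(exactly Bliss-consistent data, where the R² curve is flat) deterministic.

## Problem sizes and determinism

Defaults throughout: bootstrap 10⁴ resamples, noise Monte-Carlo 10⁵
simulations, ranking baseline 10³ repetitions of n = 10³, alpha grids of
21 (step 0.05) or 41 (step 0.025) points. Every stochastic routine takes an
explicit seed and is bit-reproducible for a fixed seed; CLI outputs embed a
provenance header (version, subcommand, parameters, seed) and contain no
timestamps, so identical invocations produce byte-identical files.

## Known limitations

* The pairs model predicts only at the measured doses; no extrapolation.
* Isserlis predictions are unavailable for M ≥ 5 (by design, see above).
* Printed-table inputs carry 2-decimal rounding; interaction scores
  recomputed from printed means match printed I columns to about ±0.02,
  and significance calls at a rounded-to-zero CI bound are conservative.
* The fixture carries means/ste/CI but not raw repeats, so bootstrap
  machinery is exercised on synthetic repeats.
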