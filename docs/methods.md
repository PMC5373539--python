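# Methods

This note documents the models, conventions and design choices behind
`thermotrait`, in the order the pipeline applies them.

## Growth-curve model and fitting

OD₅₉₀ trajectories are averaged across replicate wells per
(isolate, substrate, temperature) and fit by nonlinear least squares to the
modified Gompertz sigmoid in the Zwietering parameterization,

    y(t) = A · exp{ −exp[ μmax·e/A · (λ − t) + 1 ] } + y₀ ,

chosen because its parameters are directly interpretable: μmax (OD/day) is
exactly the maximum slope of the curve, λ (days) is the x-intercept of the
inflection tangent, A (OD) the asymptotic rise and y₀ the inoculation
density. The max-slope identity is verified numerically in the test suite
(dense finite differencing of fitted curves agrees with μmax to < 1 %).

Starting values are heuristic — y₀ = first OD, A = rise above it, μmax =
steepest two-point slope, λ = first time the OD exceeds y₀ + 0.05 A — and
all parameters are bounded below by zero with A capped at twice the maximum
observed OD so that flat curves cannot drive A to a degenerate optimum.
Curves with fewer than 5 time points are rejected; an exactly constant
curve returns a zero-rate fit flagged `degenerate`; optimizer
non-convergence is reported through a flag (with the residual sum of
squares at the last iterate), never as an exception.

Identifiability caveat: with daily sampling, a culture that saturates
before the first post-inoculation read leaves μmax and λ unconstrained even
though the fitted curve reproduces the data perfectly. Tests therefore
assert parameter recovery only where the sampling grid resolves the
exponential rise (at least two observations between 5 % and 95 % of the
rise) and assert curve equality elsewhere.

## Substrate-use calls and functional traits

A substrate is utilized if the replicate-mean OD₅₉₀ at day 10 is ≥ 0.30
(inclusive), a threshold that exceeds the carbon-free control wells; no
blank subtraction is applied before thresholding (available as an option).
If day 10 is missing the last observed day is used and the call flagged.
Gompertz fits are performed only for utilized combinations; μmax of an
unused combination is missing, not zero. One isolate (by default
*Sanguibacter sp.*) is excluded from all plate analyses at load time
because pigment formation in its control wells invalidates the OD
threshold. Substrate richness counts substrates used at any temperature by
default; counting by the across-temperature mean OD is available
(`richness_aggregation="mean_od"`) since either aggregation is defensible.
Per-isolate plate traits average first across utilized substrates within a
temperature, then across temperatures; missing values propagate as missing.

## Q₁₀ conventions

All Q₁₀ statistics use the warm-over-cold rate orientation,

    Q10 = (rate_warm / rate_cold)^(10 / (t_warm − t_cold)) ,

so faster-when-warmer gives Q₁₀ > 1; with rates inversely proportional to
times-to-threshold this is identical to `(t_cold / t_warm)^(10/Δt)`, the
form used for litter decomposition. Only the extreme temperatures (18 and
26 °C by default) enter a Q₁₀; the intermediate 22 °C treatment is carried
through summaries. Degenerate inputs are flagged rather than silently
propagated: activity at the warm temperature only produces an unbounded,
non-comparable ratio (`undefined-at-cold`, invalid); activity at the cold
temperature only gives a valid Q₁₀ of 0 flagged `warm-inactive`; no
activity at either extreme is invalid (`no-activity`). Invalid Q₁₀s are
excluded from the phylogenetic tests by default.

Microcosms are vented to ambient between samplings, so cumulative CO₂ is
the running sum of above-ambient headspace readings, with each increment
clamped at zero (a reading at or below the 400 ppm default baseline
contributes nothing). This clamped running sum is a declared convention:
the bookkeeping between venting events admits alternatives, and the
baseline is configurable because instrument-specific ambient values vary.
Time to the 5000 ppm threshold is found by linear interpolation between
bracketing sampling days, anchored at (day 0, 0 ppm); series that never
reach the threshold are flagged `not-reached` and never extrapolated.
`ppm_to_percent_litter_c` converts a mixing ratio to percent of litter
carbon respired by the ideal gas law at 1 atm; headspace volume, litter
mass and litter carbon fraction are explicit arguments because published
summaries typically omit one or more of them.

## Phylogenetic signal

Blomberg's K is computed from first principles. With V the tip
variance-covariance matrix of the (implicitly pruned) tree, x the trait
vector and n tips:

    â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1),
    MSE0 = (x−â1)ᵀ(x−â1)/(n−1),   MSE = (x−â1)ᵀV⁻¹(x−â1)/(n−1),
    K = (MSE0/MSE) / { [tr(V) − n/(1ᵀV⁻¹1)] / (n−1) }.

The implementation was verified against R's `picante::Kcalc` on a worked
3-tip example (both give K = 1.234375; the value is frozen in the test
suite) and satisfies the analytic identities: K ≡ 1 on equal-branch star
trees, invariance to affine trait transforms and to uniform branch-length
rescaling. Missing-trait tips are dropped by subsetting V, which equals
pruning the tree. Zero-length pendant edges receive a configurable ε
(default 1e-8) on the diagonal to keep V invertible.

The permutation test shuffles trait values across tips and uses the
MSE0/MSE ratio as the test statistic — equivalent to permuting K itself,
because the expectation term is permutation-invariant. The test is
one-tailed for signal, ties count as exceedances (conservative), and p
follows the add-one rule (1 + count)/(1 + n_perm), so p is never 0. Note
that picante's own randomization uses the variance of phylogenetically
independent contrasts; the MSE-ratio null here is a declared convention
and can produce slightly different p-values.

The Mantel test correlates lower triangles of two distance matrices
(Pearson), permuting rows and columns of one matrix simultaneously;
one-tailed positive, add-one p. For small n an exhaustive mode enumerates
all n! permutations and returns the exact fraction. The statistic is
cross-checked against scikit-bio's implementation at test time.

Distance matrices for the Mantel comparisons are built per substrate:
activity profiles (binary use, final OD₅₉₀, μmax) fill unused combinations
with zero — no use is zero measurable activity, and pairwise deletion
would leave isolate pairs with disjoint substrate repertoires incomparable
— while Q₁₀ profiles keep undefined entries missing (a temperature
sensitivity of an unused substrate is not zero) and use pairwise deletion.

## Synthetic data generator

The generator reproduces the statistical structure of the emulated study,
with every draw a pure function of (configuration, seed):

* **Tree**: pure-birth (Yule) with 16 extant tips, birth rate 1. The
  process stops at the n-th birth, which leaves the newest pendant edges
  with zero length, so all pendant edges are extended by the Exp(nλ)
  waiting time to the next speciation event — branch lengths become
  strictly positive and the tree stays ultrametric. A Yule tree is the
  simplest ultrametric stand-in for a small 16S ML tree; K's null behavior
  depends only on shape and branch lengths, not on how a tree was inferred.
* **Trait architectures**: the per-isolate log growth-rate factor is either
  Brownian motion on the tree (heritable) or i.i.d. normal with matched
  marginal variance (non-heritable). σ²(BM) defaults to 0.3, which on a
  unit-depth tree spans roughly 10-fold rate differences between extreme
  isolates — the spread seen between fast and slow litter bacteria.
  Substrate use follows a thresholded per-substrate liability with the same
  architecture, so in BM mode use profiles are heritable too (as observed
  in real litter communities); the threshold is set so each substrate is
  usable by ~40 % of isolates.
* **Temperature scaling**: rates scale as `q10^((T − 18)/10)` with a
  per-isolate Q₁₀ drawn around `true_q10 = 2` with log-scale spread 0.2
  (~2-fold differences in sensitivity between isolates), non-heritable by
  default. An optional per-temperature multiplier table overrides the
  monotone Q₁₀ scaling to model mid-temperature activity peaks.
* **Plates**: OD₅₉₀ is the forward Gompertz curve plus additive Gaussian
  noise (SD 0.02 OD, truncated at zero — plate readers report nonnegative
  densities); within-replicate OD variance is not reported in published
  summaries, so this is a package choice. Control wells are baseline noise
  only and stay below the 0.30 threshold by construction. OD₇₅₀ is carried
  through the schema as a turbidity proxy but not modeled further.
* **CO₂**: each measurement is ambient + rate × interval with 5 % relative
  noise on increments; cumulating above-ambient parts yields nondecreasing
  series, and with noise switched off the decomposition-Q₁₀ recovery is
  exact because the cumulative series is piecewise linear.

What the generator does **not** emulate: substrate-specific chemistry
(substrate effects are exchangeable lognormal factors), growth on litter as
a mechanistic decay process, diauxie or death phases in the growth curves,
plate edge/position effects, and measurement-noise autocorrelation. Passing
recovery tests therefore demonstrate correctness of the estimators under
the declared generative model, not robustness to every artifact of real
plate data.

## Pipeline and numerics

The end-to-end run is deterministic given inputs and one seed: a single
seeded stream is fanned out to named per-stage substreams (CRC32-keyed
`SeedSequence` spawn keys), so stage-level reruns reproduce independently.
All tables are written as TSV with fixed float formatting; the manifest
records configuration, seed, per-stage record counts, machine-readable
warnings and SHA-256 hashes of every output file. Two runs with identical
configuration produce byte-identical outputs (asserted in the tests).

Problem sizes used in the test suite and acceptance script were chosen to
give stable statistics at interactive runtimes: 200 noisy curves for
fitting recovery, 1000 Brownian-motion simulations for the K expectation,
500 simulations each for permutation type-I error, power and the Mantel
null, and 100 seeded runs for the heritable-vs-non-heritable contrast;
end-to-end pipeline checks use 8–16 taxa and 6–12 substrates.

## Known limitations

* K permutation power depends strongly on tree shape: pectinate 16-tip
  trees give ~0.5 power under pure Brownian motion where Yule trees give
  ~0.95+. Power figures quoted here are for the Yule tree model the
  generator uses.
* K is sensitive to non-phylogenetic noise on trees containing very short
  sister splits: small i.i.d. perturbations (e.g. the non-heritable Q₁₀
  factor folded into a temperature-averaged rate trait) can dominate the
  GLS error term and mask otherwise strong signal. This is a property of
  the statistic, and it is why composite traits averaged across
  temperatures test less reliably than the underlying architecture.
* The mixed-model ANOVA of isolate x temperature effects reported alongside
  analyses of this kind is deliberately out of scope; statsmodels or R
  lme4 fit such models directly from the pipeline's TSV outputs.
* consenTRAIT-style depth-of-conservation metrics, partial Mantel tests and
  phylogenetic GLS are not implemented.
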