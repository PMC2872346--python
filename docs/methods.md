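# Methods

## Model and sampling assumptions

All machinery targets the normal linear model `y = Xβ + u` with
homoscedastic independent errors `u ~ N(0, σ²I)`. A candidate set of `p`
covariates defines `2^p` submodels, all containing the intercept; the
model space is enumerated exhaustively (hard cap p ≤ 20; beyond that a
stochastic search would be needed, which is out of scope). Errors in the
two-equation cost-effectiveness model may be correlated across equations,
but never across patients, and costs are modelled on the natural scale —
skewed-cost families (log-normal, gamma) are not supported.

## The conjugate layer

The normal-inverse-gamma (NIG) prior
`π(β, σ²) ∝ (σ²)^{−(d+k+2)/2} exp(−[(β−β₀)′V⁻¹(β−β₀) + a]/(2σ²))`
updates in closed form to an NIG posterior with

```
V* = (V⁻¹ + X′X)⁻¹
β* = V*(V⁻¹β₀ + X′y)
a* = a + β₀′V⁻¹β₀ + y′y − β*′(V*)⁻¹β*
```

and marginal Student t for β (d + n degrees of freedom, scale matrix
`a*/(d+n)·V*`). Note the quadratic form in `a*` uses the *posterior*
precision `(V*)⁻¹`; a variant with the prior precision circulates in the
applied literature but is inconsistent with the conjugate algebra — the
implementation was validated against brute-force numeric integration of
`∫∫ likelihood × prior dβ dσ²` on a small fixture (tests), which settles
the orientation.

Because the NIG hyperparameters are rarely elicited in applications, the
*reporting* prior for coefficient estimates of a chosen model is the
reference prior `π ∝ σ⁻²`: posterior mean = least squares, marginal
Student t with `n − k` degrees of freedom and squared scale
`rss/(n−k)·(X′X)⁻¹ᵢᵢ`. A proper NIG can be supplied instead.

## The four objective scores

Improper priors cannot be used for model comparison directly (their
arbitrary normalising constants do not cancel between models of different
dimension); each method repairs this differently.

**BIC.** `log B_ji = (n/2)(log rss_i − log rss_j) + ((k_i−k_j)/2) log n`.
Exact antisymmetry and transitivity; scale and location invariant.

**Reference-prior factor and arithmetic-mean IBF.** Under `π ∝ σ⁻²` the
formal Bayes factor is

```
B_ji^N = π^{(k_j−k_i)/2} · Γ((n−k_j)/2)/Γ((n−k_i)/2)
         · (|X_i′X_i|/|X_j′X_j|)^{1/2} · rss_i^{(n−k_i)/2}/rss_j^{(n−k_j)/2}
```

which drifts by `α^{k_j−k_i}` under `y → αy` (asserted in a test). The
IBF removes the drift by averaging training-sample corrections:
`B_ji^mean = B_ji^N · (1/L) Σ_l B_ij^N(l)`, the inner factors evaluated on
minimal training samples of size `m` (n → m throughout). Design choices:

* `m = k_max + 1`, where `k_max` is the larger column count of the pair —
  nonsingularity needs `m ≥ k_max` and a strictly positive gamma argument
  `(m − k)/2` needs one more observation;
* `L = min(C(n, m), 200)` subsets, drawn uniformly without replacement by
  rejection (cap 1000·L draws), each validated for full rank and positive
  rss; when there are at most L subsets in total, all valid ones are
  enumerated. Deterministic given the seed;
* for whole-space posteriors one shared training set with `m = k_full + 1`
  is drawn once against the full design and reused for every pair —
  validating the largest model suffices because a submodel's rss on a
  subset bounds the full model's from above;
* every model is paired against the intercept-only base `M_1` (nested in
  all models). The arithmetic-mean IBF is not transitive, so the base
  matters; fixing `M_1` follows the posterior-probability convention used
  with intrinsic priors and is documented rather than configurable.

**FBF.** For the linear model,

```
log FBF_ji = lgΓ((nb−k_i)/2) − lgΓ((nb−k_j)/2) + lgΓ((n−k_j)/2) − lgΓ((n−k_i)/2)
             + (n(1−b)/2)(log rss_i − log rss_j)
```

with `b = m/n` by default. The orientation of the second gamma ratio is
the "corrected" variant: at equal rss it penalises the extra parameter and
it vanishes at b = 1. A "printed" variant with the opposite orientation —
which rewards complexity at equal fit — is retained behind a flag for
fidelity studies only.

**Intrinsic-prior Bayes factor.** For a model with `j` regressors beyond
the intercept,

```
B_j1 = (2(j+1)^{(j−1)/2}/π) ∫₀^{π/2} (sin φ)^{j−1}
       [n + (j+1)sin²φ]^{(n−j)/2} / [nB_j + (j+1)sin²φ]^{(n−1)/2} dφ
```

with `B_j = rss_j / Σ(y−ȳ)² ∈ [0, 1]` (the divisor-n sample variance makes
`B_j` the unexplained-variance fraction and pins `B_j = 1` for the
intercept-only model — this requirement fixes the dimension convention,
there being no printed worked example to check against). The integrand is
evaluated in log space with max-subtraction over a 513-point scouting
grid; adaptive quadrature (scipy's Gauss–Kronrod, relative tolerance
1e-10, limit 200 intervals) then integrates the rescaled integrand, so the
factor stays finite for n up to 1e5 and extreme rss ratios. `j = 0`
returns log B = 0 by convention. A noteworthy boundary: at `j = 1`,
`B_j = 1` the integrand is identically 1 and the Bayes factor is exactly 1
— a single useless regressor is not penalised until `B_j` or `j` moves;
penalisation holds for `j ≥ 2`.

Degenerate inputs: any model with numerically zero rss (relative to
`max(1, y′y)` at 1e-12) is a "perfect fit" and is rejected from scoring —
all four methods divide by rss powers. Rank deficiency is detected by QR
with relative tolerance 1e-10 and rejected, never silently repaired.

## Posteriors, inclusion and averaging

Scores `log B_j1` are combined with the model prior (uniform by default)
through a max-subtracted softmax; exponentiation happens only here.
Inclusion probabilities are sums over including models; forced-in
covariates (e.g. the treatment indicator for final reporting) appear in
every enumerated model and are reported separately with probability 1 by
construction.

BMA of a coefficient uses the reference-prior per-model posteriors and
Leamer's decomposition
`V = Σ_j V_j P(M_j) + Σ_j (E_j − E)² P(M_j)`. The default `all_models`
mode treats the coefficient as exactly 0 when excluded; `conditional`
renormalises over including models. Models with posterior weight below
1e-12 are skipped without fitting (their reference posterior may not exist
when `n − k ≤ 2`); the floor is far below any reportable probability.

## Cost-effectiveness applications

*Selection* runs per equation with the error correlation set to zero —
with a bivariate error law the marginal likelihoods have no closed form —
and the treatment indicator is an ordinary candidate so that its inclusion
probability (the evidence that the treatment moves the outcome) is
estimated. *Final models* are the modal model of a designated method
(default BIC) augmented with the treatment indicator; incremental
effectiveness and cost are its reference-prior posterior (mean, sd,
equal-tailed 95% t interval). The final pair can be re-estimated jointly
by a Gibbs sampler for the seemingly-unrelated-regressions model: flat
coefficient prior, `|Σ|^{−3/2}` prior on the 2×2 error covariance,
alternating a joint-normal draw of the stacked coefficients with an
inverse-Wishart draw (df = n, scale = residual cross-product). With equal
design matrices the coefficient posterior collapses to equation-wise least
squares, which the tests exploit as a correctness check, along with
coverage of a known error correlation.

*Subgroup screening* appends the `modifier × T` column to both equations'
candidates and reports its inclusion probability; a modifier constant
within an arm makes the interaction collinear and is rejected.
*Net-benefit regression* repeats selection on `z = R·e − c` over a
willingness-to-pay grid with identical seed and options per R; at R = 0
the outcome is `−c` and sign invariance of all four methods makes the
table bit-identical to the cost equation's (asserted exactly), while large
R recovers the effectiveness table by scale invariance.

## Synthetic data

`simulate_table1` draws the six-covariate benchmark: x1 ~ N(10, 3²),
x2 ~ N(5, 1), x3 ~ N(0, 3²), x4 ~ Bernoulli(0.7), x5 ~ Bernoulli(0.2),
x6 ~ Poisson(4), independent, and
`y = 5 + 3·x2 + 7·x4 − 4·x6 + N(0, 8²)` (the noise parameter is a
standard deviation, consistent with the N(μ, σ) convention of the
covariate laws and the implied response variance 147.29). Discrete
covariates can be constant at tiny n; the generator re-checks the full
design's rank and redraws (logged) up to 100 times. Replicate seeds derive
from the master seed through a counter-based SeedSequence so any subset of
replicates is independently reproducible.

`simulate_cea_trial` emulates a two-arm HIV-trial shape: age ~ N(35, 7²),
gender and cc1 ~ Bernoulli(0.28), cc2 ~ Bernoulli(0.10), start ~ N(79,
95²) truncated at 0; effectiveness on the QALY scale (intercept 0.011,
error sd 0.037, cc2 effect 0.02 by default) and cost in euros (intercept
7100, error sd 1600), with bivariate normal errors of configurable
correlation and configurable treatment effects (null by default). These
scales mirror a published trial's summary statistics; what the generator
does *not* emulate is right-skewed costs, informative covariate–treatment
imbalance, missingness, or clustering — so passing tests demonstrate
correct inference under the stated normal model, not robustness to those
real-data features.

## Problem sizes and numerical choices

The replication harness defaults to 50 replicates (200 for the small-n
band check, where each replicate costs only 64 least-squares fits) and to
n ∈ {30, 100, 300}; the heavier checks — IBF posteriors (12,800 small QR
fits per dataset at L=200) and the Gibbs sampler (5,000 sweeps) — run in
seconds each, and the sizes were chosen so the statistical assertions have
comfortable margins. Ties in model ranking break by the deterministic
space order (subset size, then lexicographic), so reports are reproducible
bit-for-bit from their embedded configuration.

## Known limitations

* Exhaustive enumeration only; no MC3/stochastic search, so p ≤ 20.
* The arithmetic-mean IBF's base-model sensitivity is fixed, not explored.
* Selection ignores the cost–effectiveness error correlation (joint
  estimation is a separate step), matching standard practice but not a
  fully joint analysis.
* No generalized linear models, heteroscedasticity, or regularisation.
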