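# bvscea — objective Bayesian variable selection for cost-effectiveness analysis

Regression models in health economics explain a treatment's cost and
effectiveness from patient covariates (age, gender, comorbidities, time
since diagnosis, …) plus a 0/1 treatment indicator whose coefficients are
the *incremental effectiveness* and *incremental cost*. Most applied
analyses fit a single model — usually the full one — and so ignore model
uncertainty. `bvscea` instead enumerates every intercept-containing
submodel of a normal linear regression and scores each with objective
Bayes factors, turning the question "which covariates belong in the
model?" into posterior probabilities.

## The methods

For submodels `M_j` of `y = Xβ + u`, `u ~ N(0, σ²I)`, each model is scored
against the intercept-only base `M_1` by a pairwise log Bayes factor
`log B_j1`, computed by one of four objective methods (none requires a
subjective prior per submodel):

* **BIC** — Schwarz's approximation,
  `B_ji = (rss_i / rss_j)^{n/2} · n^{(k_i − k_j)/2}`;
* **IBF** — the arithmetic-mean intrinsic Bayes factor,
  `B_ji^mean = B_ji^N · (1/L) Σ_l B_ij^N(l)`, which corrects the
  reference-prior factor `B^N` with minimal training samples `x(l)` of size
  `m = k_max + 1`;
* **FBF** — O'Hagan's fractional Bayes factor, spending a fraction
  `b = m/n` of the likelihood as implicit training;
* **intrinsic** — the Bayes factor under intrinsic priors, a
  one-dimensional integral in the unexplained-variance fraction
  `B_j = rss_j / Σ(y − ȳ)²`.

Posterior model probabilities follow by normalisation,
`P(M_j | y) = B_j1 π(M_j) / Σ_i B_i1 π(M_i)`; a covariate's *inclusion
probability* is the summed probability of the models containing it, and
coefficients can be model-averaged with Leamer's variance decomposition
(`bma`). Applications for two-arm trials: equation-wise selection for cost
and effectiveness with a joint (SUR) Gibbs re-estimation of the final
models, subgroup screening via the `modifier × treatment` interaction, and
net-benefit regression `z = R·e − c` over a willingness-to-pay grid.

## Worked example

```python
from bvscea import BayesianVariableSelector, simulate_table1, Table1Config

data = simulate_table1(Table1Config(n=300, seed=1))   # benchmark design
X = data.frame[[f"x{i}" for i in range(1, 7)]]
sel = BayesianVariableSelector(method="bic").fit(X, data.frame["y"])
print(sel.inclusion_probabilities_.round(5))
for model, p in sel.top_models(3):
    print(f"{str(model):24s} {p:.4f}")
```

prints

```
(intercept)    1.00000
x1             0.06219
x2             1.00000
x3             0.08433
x4             1.00000
x5             0.05813
x6             1.00000
{x2, x4, x6}             0.8091
{x2, x3, x4, x6}         0.0742
{x1, x2, x4, x6}         0.0533
```

The benchmark generator draws six independent covariates (three normal,
two Bernoulli, one Poisson) and `y = 5 + 3·x2 + 7·x4 − 4·x6 + N(0, 8²)`.
At n=300 the three true covariates receive inclusion probability 1.00000
at five decimals, the three noise covariates stay below 0.1, and the true
model `{x2, x4, x6}` is modal with probability 0.81 — selection has
essentially converged at this sample size.

The same machinery runs from a shell:

```sh
bvscea simulate --preset table1 --n 300 --seed 1 --reps 50 --method all --out sim.json
bvscea cea --data trial.csv --effectiveness eff --cost cost --treatment T \
      --covariates age,gender,cc1,cc2,start --method all --seed 17 --out report.json
bvscea subgroup --modifier gender --data trial.csv ... --out subgroup.json
bvscea netbenefit --wtp 0,50000,100000 --method intrinsic --data trial.csv ... --out nb.json
```

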