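"""Seeded synthetic-data generators and the inclusion-probability experiment.

Two generators:

* :func:`simulate_table1` — the six-covariate benchmark design used to
  validate the selection methods: three normal covariates, two Bernoulli,
  one Poisson, and ``y = 5 + 3 x2 + 7 x4 - 4 x6 + N(0, sd 8)`` (so x1, x3,
  x5 are pure noise covariates);
* :func:`simulate_cea_trial` — a two-arm, two-equation cost-effectiveness
  trial with QALY-scale effectiveness, euro-scale cost, correlated bivariate
  normal errors and covariate laws shaped like an HIV-trial baseline table.

:func:`run_inclusion_experiment` replicates the benchmark across seeds and
aggregates inclusion probabilities per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import model_space as ms
from .regression_core import Dataset, InputError, ModelSpec, build_design_matrix

__all__ = [
    "Table1Config",
    "CEASimConfig",
    "ExperimentReport",
    "simulate_table1",
    "run_inclusion_experiment",
    "simulate_cea_trial",
    "derive_seed",
]

logger = logging.getLogger(__name__)

TABLE1_CANDIDATES = ("x1", "x2", "x3", "x4", "x5", "x6")
TABLE1_COEFFICIENTS = {"x2": 3.0, "x4": 7.0, "x6": -4.0}
TABLE1_INTERCEPT = 5.0
TABLE1_NOISE_SD = 8.0


def derive_seed(master: int, *indices: int) -> int:
    """Counter-based child seed: reproducible independently per replicate."""
    ss = np.random.SeedSequence([int(master), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class Table1Config:
    """Benchmark data-generating process.

    ``x1 ~ N(10, sd 3), x2 ~ N(5, 1), x3 ~ N(0, 3), x4 ~ Bernoulli(0.7),
    x5 ~ Bernoulli(0.2), x6 ~ Poisson(4)``, all independent;
    ``y = 5 + 3 x2 + 7 x4 - 4 x6 + N(0, sd 8)``.
    """

    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("n must be >= 1")


def simulate_table1(cfg: Table1Config) -> Dataset:
    """Draw one benchmark dataset; deterministic given the seed.

    The Poisson and Bernoulli covariates can be constant at tiny n; the full
    design's rank is checked and the draw repeated (logged) up to 100 times.
    """
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(100):
        cols = {
            "x1": rng.normal(10.0, 3.0, cfg.n),
            "x2": rng.normal(5.0, 1.0, cfg.n),
            "x3": rng.normal(0.0, 3.0, cfg.n),
            "x4": rng.binomial(1, 0.7, cfg.n).astype(float),
            "x5": rng.binomial(1, 0.2, cfg.n).astype(float),
            "x6": rng.poisson(4.0, cfg.n).astype(float),
        }
        noise = rng.normal(0.0, TABLE1_NOISE_SD, cfg.n)
        y = TABLE1_INTERCEPT + sum(
            coef * cols[name] for name, coef in TABLE1_COEFFICIENTS.items()
        ) + noise
        cols["y"] = y
        data = Dataset(pd.DataFrame(cols))
        if cfg.n < len(TABLE1_CANDIDATES) + 1:
            return data  # too few rows for the full design; caller's problem
        X = build_design_matrix(data, ModelSpec(TABLE1_CANDIDATES))
        if np.linalg.matrix_rank(X.values) == X.k:
            return data
        logger.warning("degenerate design on attempt %d; redrawing", attempt + 1)
    raise RuntimeError("could not draw a full-rank benchmark design in 100 attempts")


@dataclass(frozen=True)
class ExperimentReport:
    """Aggregated inclusion probabilities over replicate datasets."""

    n: int
    reps: int
    methods: tuple[str, ...]
    mean_inclusion: pd.DataFrame  # rows: covariates, columns: methods
    sd_inclusion: pd.DataFrame
    modal_models: dict[str, tuple[ModelSpec, ...]]  # per method, one per replicate
    replicate_seeds: tuple[int, ...]
    failed_replicates: int = 0


def run_inclusion_experiment(
    n: int,
    methods: tuple[str, ...] = ms.METHODS,
    reps: int = 50,
    seed: int = 0,
    ibf_L: int | None = None,
) -> ExperimentReport:
    """Replicate the benchmark: per replicate, draw a fresh dataset, score
    all 64 models per method, and record inclusion probabilities and the
    modal model.  Replicate seeds derive deterministically from the master
    seed, so subsets of replicates are independently reproducible.  Failed
    replicates (degenerate fits) are logged and excluded from the means.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    for method in methods:
        if method not in ms.METHODS:
            raise InputError(f"unknown method {method!r}")
    rep_seeds = tuple(derive_seed(seed, r) for r in range(reps))
    tables: dict[str, list[pd.Series]] = {m: [] for m in methods}
    modal: dict[str, list[ModelSpec]] = {m: [] for m in methods}
    failed = 0
    space = ms.enumerate_models(TABLE1_CANDIDATES)
    for rep_seed in rep_seeds:
        data = simulate_table1(Table1Config(n=n, seed=rep_seed))
        try:
            for method in methods:
                mp = ms.model_posterior_probabilities(
                    space, data, "y", method, seed=rep_seed, ibf_L=ibf_L
                )
                inc = ms.inclusion_probabilities(mp)
                tables[method].append(pd.Series(inc.probability))
                modal[method].append(ms.top_models(mp, 1)[0][0])
        except Exception:
            logger.exception("replicate with seed %d failed; excluded", rep_seed)
            failed += 1
    mean = pd.DataFrame({m: pd.concat(v, axis=1).mean(axis=1) for m, v in tables.items()})
    sd = pd.DataFrame({m: pd.concat(v, axis=1).std(axis=1, ddof=1) if len(v) > 1
                       else pd.concat(v, axis=1).iloc[:, 0] * 0.0
                       for m, v in tables.items()})
    return ExperimentReport(
        n=n, reps=reps, methods=tuple(methods),
        mean_inclusion=mean, sd_inclusion=sd,
        modal_models={m: tuple(v) for m, v in modal.items()},
        replicate_seeds=rep_seeds, failed_replicates=failed,
    )


@dataclass(frozen=True)
class CEASimConfig:
    """Two-arm CEA trial generator.

    Covariate laws default to the shape of an HIV-trial baseline table:
    age ~ N(35, sd 7); gender, cc1 ~ Bernoulli(0.28); cc2 ~ Bernoulli(0.10);
    start (months since diagnosis) ~ N(79, sd 95) truncated at 0.  The two
    outcome equations share the covariates:

    ``e = b0 + b'x + bT T + u`` (QALYs), ``c = d0 + d'x + dT T + v`` (euros),
    with (u, v) bivariate normal, sds ``eff_sd``/``cost_sd`` and correlation
    ``error_corr``.  Default effect sizes are null (no treatment effect, only
    cc2 moving effectiveness), with outcome scales matching the baseline
    table: eff intercept 0.011, sd 0.037; cost intercept 7100, sd 1600.
    """

    n_per_arm: int = 150
    seed: int = 0
    eff_intercept: float = 0.011
    eff_coefficients: dict[str, float] = field(
        default_factory=lambda: {"cc2": 0.02}
    )
    eff_treatment: float = 0.0
    eff_sd: float = 0.037
    cost_intercept: float = 7100.0
    cost_coefficients: dict[str, float] = field(default_factory=dict)
    cost_treatment: float = 0.0
    cost_sd: float = 1600.0
    error_corr: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.error_corr < 1.0:
            raise InputError("error correlation must lie in (-1, 1)")
        if self.eff_sd <= 0 or self.cost_sd <= 0:
            raise InputError("error sds must be positive")
        if self.n_per_arm < 2:
            raise InputError("need at least 2 patients per arm")


CEA_COVARIATES = ("age", "gender", "cc1", "cc2", "start")


def simulate_cea_trial(cfg: CEASimConfig):
    """Draw one synthetic CEA trial; deterministic given the seed.

    Returns a :class:`bvscea.cea.CEATrial` with columns
    eff, cost, T, age, gender, cc1, cc2, start.
    """
    from .cea import CEATrial  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_arm
    T = np.repeat([0.0, 1.0], cfg.n_per_arm)
    cols = {
        "age": rng.normal(35.0, 7.0, n),
        "gender": rng.binomial(1, 0.28, n).astype(float),
        "cc1": rng.binomial(1, 0.28, n).astype(float),
        "cc2": rng.binomial(1, 0.10, n).astype(float),
        "start": stats.truncnorm.rvs(
            (0.0 - 79.0) / 95.0, np.inf, loc=79.0, scale=95.0, size=n,
            random_state=rng,
        ),
    }
    cov = cfg.error_corr * cfg.eff_sd * cfg.cost_sd
    sigma = np.array([[cfg.eff_sd**2, cov], [cov, cfg.cost_sd**2]])
    errors = rng.multivariate_normal([0.0, 0.0], sigma, size=n)
    eff = cfg.eff_intercept + cfg.eff_treatment * T + errors[:, 0]
    cost = cfg.cost_intercept + cfg.cost_treatment * T + errors[:, 1]
    for name, coef in cfg.eff_coefficients.items():
        eff = eff + coef * cols[name]
    for name, coef in cfg.cost_coefficients.items():
        cost = cost + coef * cols[name]
    frame = pd.DataFrame({"eff": eff, "cost": cost, "T": T, **cols})
    return CEATrial(
        data=Dataset(frame),
        effectiveness="eff",
        cost="cost",
        treatment="T",
        covariates=CEA_COVARIATES,
    )
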