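"""Cost-effectiveness applications of Bayesian variable selection.

A two-arm trial records per patient an effectiveness outcome e (e.g. QALYs),
a cost outcome c, a 0/1 treatment indicator T and candidate control
covariates.  The full model per equation regresses the outcome on all
controls plus T; the treatment coefficients are the incremental
effectiveness and incremental cost.

Selection is run on each equation separately, treating the error
correlation between equations as zero (model selection with a bivariate
error law has no closed-form evidence); the chosen final pair of models can
then be re-estimated jointly with a seemingly-unrelated-regressions (SUR)
Gibbs sampler that does model the correlation.

Two further applications: subgroup screening via the inclusion probability
of a modifier x T interaction, and net-benefit regression, which repeats
selection on ``z = R e - c`` over a grid of willingness-to-pay values R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import model_space as ms
from .regression_core import (
    Dataset,
    InputError,
    ModelSpec,
    build_design_matrix,
    ols_fit,
    reference_coefficient_posterior,
)

__all__ = [
    "CEATrial",
    "CEAResult",
    "NetBenefitResult",
    "SURPosterior",
    "run_cea_selection",
    "estimate_joint_sur",
    "subgroup_interaction_analysis",
    "net_benefit_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CEATrial:
    """Two-arm trial data: effectiveness, cost, 0/1 treatment, covariates."""

    data: Dataset
    effectiveness: str
    cost: str
    treatment: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        t = self.data.column(self.treatment)
        if not np.isin(t, (0.0, 1.0)).all():
            raise InputError(f"treatment column {self.treatment!r} must be 0/1")
        if t.min() == t.max():
            raise InputError("single-arm data: both treatment arms must be nonempty")
        for name in (self.effectiveness, self.cost, *self.covariates):
            self.data.column(name)  # existence check

    @property
    def candidates(self) -> tuple[str, ...]:
        """Candidate covariates for selection: controls plus treatment."""
        return (*self.covariates, self.treatment)


@dataclass(frozen=True)
class CEAResult:
    inclusion_eff: dict[str, ms.InclusionTable]   # per method
    inclusion_cost: dict[str, ms.InclusionTable]
    final_model_eff: ModelSpec
    final_model_cost: ModelSpec
    incremental_effectiveness: tuple[float, float, tuple[float, float]]
    incremental_cost: tuple[float, float, tuple[float, float]]
    correlation_note: float  # sample correlation of the final-model residuals
    posteriors_eff: dict[str, ms.ModelPosterior] | None = None
    posteriors_cost: dict[str, ms.ModelPosterior] | None = None


@dataclass(frozen=True)
class NetBenefitResult:
    wtp_grid: tuple[float, ...]
    tables: dict[float, ms.InclusionTable]
    method: str


@dataclass(frozen=True)
class SURPosterior:
    """Posterior draws of the joint two-equation model."""

    draws_eff: np.ndarray    # (S, k_eff)
    draws_cost: np.ndarray   # (S, k_cost)
    draws_sigma: np.ndarray  # (S, 2, 2)
    labels_eff: tuple[str, ...]
    labels_cost: tuple[str, ...]
    burn_in: int
    thin: int
    seed: int

    @property
    def correlation_draws(self) -> np.ndarray:
        s = self.draws_sigma
        return s[:, 0, 1] / np.sqrt(s[:, 0, 0] * s[:, 1, 1])


def _select_one_equation(
    trial: CEATrial, y_name: str, methods: Sequence[str], seed: int, **options
) -> tuple[dict[str, ms.InclusionTable], dict[str, ms.ModelPosterior]]:
    space = ms.enumerate_models(trial.candidates)
    tables, posteriors = {}, {}
    for method in methods:
        mp = ms.model_posterior_probabilities(
            space, trial.data, y_name, method, seed=seed, **options
        )
        tables[method] = ms.inclusion_probabilities(mp)
        posteriors[method] = mp
    return tables, posteriors


def run_cea_selection(
    trial: CEATrial,
    methods: Sequence[str] = ms.METHODS,
    seed: int = 0,
    final_method: str = "bic",
    **options,
) -> CEAResult:
    """Equation-wise selection and final-model incremental estimates.

    Selection runs independently on the effectiveness and cost equations
    (error correlation set to zero for scoring), with the treatment indicator
    an ordinary candidate so its inclusion probability is reported.  The
    final model per equation is the ``final_method`` modal model augmented
    with the treatment indicator, whose reference-prior posterior gives the
    incremental effectiveness and cost (mean, posterior sd, equal-tailed
    95% interval).
    """
    if final_method not in methods:
        raise InputError("final_method must be one of the requested methods")
    inc_eff, post_eff = _select_one_equation(
        trial, trial.effectiveness, methods, seed, **options)
    inc_cost, post_cost = _select_one_equation(
        trial, trial.cost, methods, seed, **options)

    def finalize(posteriors: Mapping[str, ms.ModelPosterior]) -> ModelSpec:
        modal = ms.top_models(posteriors[final_method], 1)[0][0]
        if trial.treatment in modal:
            return modal
        return ModelSpec((*modal.included, trial.treatment))

    final_eff = finalize(post_eff)
    final_cost = finalize(post_cost)
    m_e, s_e, _, ci_e = reference_coefficient_posterior(
        trial.data, final_eff, trial.effectiveness, trial.treatment)
    m_c, s_c, _, ci_c = reference_coefficient_posterior(
        trial.data, final_cost, trial.cost, trial.treatment)

    resid_e = _residuals(trial.data, final_eff, trial.effectiveness)
    resid_c = _residuals(trial.data, final_cost, trial.cost)
    corr = float(np.corrcoef(resid_e, resid_c)[0, 1])
    return CEAResult(
        inclusion_eff=inc_eff, inclusion_cost=inc_cost,
        final_model_eff=final_eff, final_model_cost=final_cost,
        incremental_effectiveness=(m_e, s_e, ci_e),
        incremental_cost=(m_c, s_c, ci_c),
        correlation_note=corr,
        posteriors_eff=post_eff, posteriors_cost=post_cost,
    )


def _residuals(data: Dataset, model: ModelSpec, y_name: str) -> np.ndarray:
    y = data.column(y_name)
    X = build_design_matrix(data, model)
    fit = ols_fit(X, y)
    return y - X.values @ fit.coefficients


def estimate_joint_sur(
    trial: CEATrial,
    model_eff: ModelSpec,
    model_cost: ModelSpec,
    iters: int = 5000,
    burn_in: int = 1000,
    thin: int = 1,
    seed: int = 0,
) -> SURPosterior:
    """Gibbs sampler for the bivariate-error (SUR) final model.

    Alternates the joint-normal full conditional of the stacked coefficients
    given the 2x2 error covariance with the inverse-Wishart full conditional
    of the covariance given the coefficients, under a flat coefficient prior
    and the Jeffreys-type |Sigma|^(-3/2) prior.  With identical design
    matrices in both equations the coefficient posterior collapses to
    equation-wise least squares.
    """
    if iters <= burn_in:
        raise InputError("iters must exceed burn_in")
    rng = np.random.default_rng(seed)
    e = trial.data.column(trial.effectiveness)
    c = trial.data.column(trial.cost)
    X_e = build_design_matrix(trial.data, model_eff)
    X_c = build_design_matrix(trial.data, model_cost)
    n = trial.data.n
    k_e, k_c = X_e.k, X_c.k
    fit_e = ols_fit(X_e, e)
    fit_c = ols_fit(X_c, c)
    u = e - X_e.values @ fit_e.coefficients
    v = c - X_c.values @ fit_c.coefficients
    sigma = np.cov(np.vstack([u, v]), ddof=1)
    sigma += 1e-12 * np.eye(2) * max(1.0, sigma[0, 0], sigma[1, 1])

    A_e, A_c = X_e.values, X_c.values
    XtX_ee = A_e.T @ A_e
    XtX_cc = A_c.T @ A_c
    XtX_ec = A_e.T @ A_c
    Xte_e, Xte_c = A_e.T @ e, A_c.T @ e
    Xtc_e, Xtc_c = A_e.T @ c, A_c.T @ c

    keep = (iters - burn_in) // thin
    draws_eff = np.empty((keep, k_e))
    draws_cost = np.empty((keep, k_c))
    draws_sigma = np.empty((keep, 2, 2))
    kept = 0
    for it in range(iters):
        W = np.linalg.inv(sigma)
        P = np.block([
            [W[0, 0] * XtX_ee, W[0, 1] * XtX_ec],
            [W[0, 1] * XtX_ec.T, W[1, 1] * XtX_cc],
        ])
        b = np.concatenate([
            W[0, 0] * Xte_e + W[0, 1] * Xtc_e,
            W[0, 1] * Xte_c + W[1, 1] * Xtc_c,
        ])
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("divergent chain: non-SPD precision draw") from exc
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        z = rng.standard_normal(k_e + k_c)
        theta = mean + np.linalg.solve(L.T, z)
        beta, delta = theta[:k_e], theta[k_e:]
        ru = e - A_e @ beta
        rv = c - A_c @ delta
        S = np.array([[ru @ ru, ru @ rv], [ru @ rv, rv @ rv]])
        sigma = stats.invwishart.rvs(df=n, scale=S, random_state=rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            draws_eff[kept] = beta
            draws_cost[kept] = delta
            draws_sigma[kept] = sigma
            kept += 1
    return SURPosterior(
        draws_eff=draws_eff[:kept], draws_cost=draws_cost[:kept],
        draws_sigma=draws_sigma[:kept],
        labels_eff=X_e.labels, labels_cost=X_c.labels,
        burn_in=burn_in, thin=thin, seed=seed,
    )


def subgroup_interaction_analysis(
    trial: CEATrial,
    modifier: str,
    methods: Sequence[str] = ms.METHODS,
    seed: int = 0,
    **options,
) -> dict[str, dict[str, float]]:
    """Inclusion probability of the modifier x treatment interaction.

    The interaction column is appended to the candidate set of both
    equations; a subgroup effect shows up as a high inclusion probability.
    Returns ``{"effectiveness": {method: prob}, "cost": {method: prob}}``.
    """
    mod = trial.data.column(modifier)
    t = trial.data.column(trial.treatment)
    for arm in (0.0, 1.0):
        if np.unique(mod[t == arm]).size < 2:
            raise InputError(
                f"modifier {modifier!r} is constant within arm T={int(arm)}; "
                "the interaction is degenerate"
            )
    inter_name = f"{modifier}:{trial.treatment}"
    frame = trial.data.frame.copy()
    frame[inter_name] = mod * t
    augmented = CEATrial(
        data=Dataset(frame),
        effectiveness=trial.effectiveness,
        cost=trial.cost,
        treatment=trial.treatment,
        covariates=(*trial.covariates, inter_name),
    )
    out: dict[str, dict[str, float]] = {"effectiveness": {}, "cost": {}}
    for key, y_name in (("effectiveness", trial.effectiveness),
                        ("cost", trial.cost)):
        tables, _ = _select_one_equation(augmented, y_name, methods, seed, **options)
        for method, table in tables.items():
            out[key][method] = table.probability[inter_name]
    return out


def net_benefit_sweep(
    trial: CEATrial,
    wtp_grid: Sequence[float],
    method: str = "intrinsic",
    seed: int = 0,
    **options,
) -> NetBenefitResult:
    """Selection on the net monetary benefit ``z = R e - c`` over a grid of
    willingness-to-pay values R, with identical seed/options per R.

    At R = 0 the outcome is -c, and every method is invariant to the sign
    flip, so the table coincides exactly with the cost equation's; as R grows
    the table approaches the effectiveness equation's.
    """
    tables: dict[float, ms.InclusionTable] = {}
    space = ms.enumerate_models(trial.candidates)
    e = trial.data.column(trial.effectiveness)
    c = trial.data.column(trial.cost)
    for R in wtp_grid:
        if R < 0:
            raise InputError("willingness-to-pay values must be nonnegative")
        frame = trial.data.frame.copy()
        frame["__net_benefit__"] = R * e - c
        data = Dataset(frame)
        mp = ms.model_posterior_probabilities(
            space, data, "__net_benefit__", method, seed=seed, **options
        )
        tables[float(R)] = ms.inclusion_probabilities(mp)
    return NetBenefitResult(
        wtp_grid=tuple(float(R) for R in wtp_grid), tables=tables, method=method
    )
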