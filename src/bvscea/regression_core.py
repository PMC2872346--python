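"""Conjugate Bayesian normal linear regression primitives.

The sampling model is ``y = X beta + u`` with ``u ~ N(0, sigma^2 I)``.  A
submodel is a subset of candidate covariates; the intercept is always
included.  Two priors are supported:

* the conjugate normal-inverse-gamma (NIG) prior
  ``pi(beta, sigma^2) ~ (sigma^2)^{-(d+k+2)/2}
  exp(-[(beta-beta0)' V^{-1} (beta-beta0) + a] / (2 sigma^2))``,
  under which the posterior is again NIG and pairwise Bayes factors are
  available in closed form;
* the improper reference prior ``pi(beta, sigma^2) ~ sigma^{-2}``, used for
  reporting coefficient posteriors of a chosen model (its posterior mean is
  the least-squares estimate and the marginal for each coefficient is a
  Student t with n - k degrees of freedom).

Improper priors cannot be used for model comparison directly — the arbitrary
normalising constants do not cancel — which is what the training-sample and
fractional corrections in :mod:`bvscea.bayes_factors` repair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dataset",
    "ModelSpec",
    "DesignMatrix",
    "OLSFit",
    "NIGPrior",
    "NIGPosterior",
    "LogBayesFactor",
    "InputError",
    "DegenerateModelError",
    "SingularDesignError",
    "PerfectFitError",
    "ImproperPriorError",
    "build_design_matrix",
    "ols_fit",
    "nig_update",
    "marginal_coefficient_distribution",
    "conjugate_log_bf",
    "reference_coefficient_posterior",
]

logger = logging.getLogger(__name__)

INTERCEPT = "(intercept)"

#: relative tolerance for QR-based rank detection
RANK_RTOL = 1e-10


class InputError(ValueError):
    """Malformed user input (unknown column, bad coding, bad shape)."""


class DegenerateModelError(ValueError):
    """Model cannot be fit: more parameters than observations."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient at the working tolerance."""


class PerfectFitError(ValueError):
    """Residual sum of squares is numerically zero; all four Bayes-factor
    methods divide by powers of the rss, so such a model cannot be scored."""


class ImproperPriorError(ValueError):
    """An improper (singular-V) prior was supplied where model comparison
    requires proper priors."""


@dataclass(frozen=True)
class Dataset:
    """Numeric columns of equal length, by name.

    Thin, validated wrapper around a column mapping.  All values must be
    finite; column names must be unique and non-empty.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise InputError("duplicate column names in dataset")
        if self.frame.shape[0] == 0:
            raise InputError("dataset has no rows")
        values = self.frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError("dataset contains non-finite values")

    @classmethod
    def from_columns(cls, columns: Mapping[str, Sequence[float]]) -> "Dataset":
        return cls(pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()}))

    @property
    def n(self) -> int:
        return int(self.frame.shape[0])

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise InputError(f"unknown column {name!r}")
        return self.frame[name].to_numpy(dtype=float)


@dataclass(frozen=True, order=True)
class ModelSpec:
    """A submodel: the ordered covariate subset it includes.

    The intercept is implicit and always present; the empty spec is the
    intercept-only model.
    """

    included: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.included)) != len(self.included):
            raise InputError("duplicate covariates in model spec")

    @classmethod
    def of(cls, *names: str) -> "ModelSpec":
        return cls(tuple(names))

    def __contains__(self, name: str) -> bool:
        return name in self.included

    @property
    def size(self) -> int:
        """Number of regressors beyond the intercept."""
        return len(self.included)

    def __str__(self) -> str:
        return "{" + ", ".join(self.included) + "}" if self.included else "{intercept}"


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray  # (n, k), first column all ones
    labels: tuple[str, ...]  # k labels, INTERCEPT first

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class OLSFit:
    coefficients: np.ndarray
    rss: float
    k: int
    n: int
    rank: int
    perfect_fit: bool
    xtx_logdet: float  # log |X'X|, reused by the reference-prior Bayes factor
    labels: tuple[str, ...] = ()
    xtx_inv: np.ndarray | None = None


@dataclass(frozen=True)
class NIGPrior:
    beta0: np.ndarray
    V: np.ndarray
    a: float
    d: float

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise InputError("V must be a square matrix")
        if not np.allclose(V, V.T, rtol=1e-10, atol=1e-12):
            raise InputError("V must be symmetric")
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise ImproperPriorError(
                "prior covariance V is not positive definite; improper priors "
                "are not usable for model comparison"
            ) from exc
        if self.a <= 0:
            raise InputError("prior scale a must be positive")


@dataclass(frozen=True)
class NIGPosterior:
    beta_star: np.ndarray
    V_star: np.ndarray
    a_star: float
    dof: float  # d + n
    conditional_B: float  # d + k + n

    def conditional_A(self, beta: np.ndarray) -> float:
        """Scale of the inverse-gamma conditional of sigma^2 given beta."""
        diff = np.asarray(beta, dtype=float) - self.beta_star
        return float(diff @ np.linalg.solve(self.V_star, diff) + self.a_star)


@dataclass(frozen=True)
class LogBayesFactor:
    """Pairwise evidence ratio log B_{ji} (model j over model i), log scale."""

    log_value: float
    method: str
    model_j: ModelSpec
    model_i: ModelSpec

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_value):
            raise ValueError("log Bayes factor must be finite")


def build_design_matrix(data: Dataset, model: ModelSpec) -> DesignMatrix:
    """Assemble the n x (1 + |model|) design matrix with a leading ones column."""
    cols = [np.ones(data.n)]
    for name in model.included:
        cols.append(data.column(name))
    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1]:
        raise DegenerateModelError(
            f"model with k={X.shape[1]} columns cannot be fit on n={X.shape[0]} rows"
        )
    return DesignMatrix(values=X, labels=(INTERCEPT, *model.included))


def ols_fit(X: DesignMatrix, y: np.ndarray, *, need_xtx_inv: bool = False) -> OLSFit:
    """Least-squares fit with QR rank detection.

    Raises :class:`SingularDesignError` if the design is rank deficient at
    relative tolerance 1e-10.  A numerically zero rss with n > k is flagged
    (``perfect_fit=True``); callers scoring models must reject such fits.
    """
    y = np.asarray(y, dtype=float)
    A = X.values
    n, k = A.shape
    if y.shape != (n,):
        raise InputError(f"y has length {y.shape}, expected ({n},)")
    Q, R = np.linalg.qr(A)
    rdiag = np.abs(np.diag(R))
    tol = RANK_RTOL * rdiag.max() if rdiag.size else 0.0
    rank = int((rdiag > tol).sum())
    if rank < k:
        raise SingularDesignError(
            f"design matrix rank {rank} < {k} columns (labels {X.labels})"
        )
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - A @ coef
    rss = float(resid @ resid)
    scale = max(1.0, float(y @ y))
    perfect = n > k and rss <= 1e-12 * scale
    if perfect:
        logger.warning("perfect fit (rss ~ 0) for design %s; model will be "
                       "excluded from Bayes-factor scoring", X.labels)
        rss = 0.0
    # log|X'X| = 2 sum log |r_ii|
    xtx_logdet = float(2.0 * np.log(rdiag).sum())
    xtx_inv = None
    if need_xtx_inv:
        Rinv = np.linalg.inv(R)
        xtx_inv = Rinv @ Rinv.T
    return OLSFit(coefficients=coef, rss=rss, k=k, n=n, rank=rank,
                  perfect_fit=perfect, xtx_logdet=xtx_logdet, labels=X.labels,
                  xtx_inv=xtx_inv)


def nig_update(X: DesignMatrix, y: np.ndarray, prior: NIGPrior) -> NIGPosterior:
    """Conjugate update of the normal-inverse-gamma prior.

    ``V* = (V^-1 + X'X)^-1``, ``beta* = V* (V^-1 beta0 + X'y)``,
    ``a* = a + beta0' V^-1 beta0 + y'y - beta*' (V*)^-1 beta*``.
    """
    y = np.asarray(y, dtype=float)
    A = X.values
    n, k = A.shape
    beta0 = np.asarray(prior.beta0, dtype=float)
    if beta0.shape != (k,) or prior.V.shape != (k, k):
        raise InputError("prior dimension does not match design matrix")
    Vinv = np.linalg.inv(np.asarray(prior.V, dtype=float))
    precision_star = Vinv + A.T @ A
    V_star = np.linalg.inv(precision_star)
    V_star = 0.5 * (V_star + V_star.T)
    beta_star = V_star @ (Vinv @ beta0 + A.T @ y)
    a_star = float(prior.a + beta0 @ Vinv @ beta0 + y @ y
                   - beta_star @ precision_star @ beta_star)
    if a_star <= 0:
        raise ValueError(f"posterior scale a* = {a_star} is not positive; "
                         "numerically inconsistent update")
    return NIGPosterior(beta_star=beta_star, V_star=V_star, a_star=a_star,
                        dof=prior.d + n, conditional_B=prior.d + k + n)


def marginal_coefficient_distribution(
    post: NIGPosterior, index: int, level: float = 0.95
) -> tuple[float, float, float, tuple[float, float]]:
    """Marginal Student-t summary of one coefficient.

    Returns ``(mean, scale, dof, (lo, hi))`` where the marginal is
    ``t_dof(mean, scale^2)`` with ``scale^2 = a*/dof * V*[i,i]`` and the
    interval is the equal-tailed central interval at ``level``.  The variance
    ``a*/(dof-2) * V*[i,i]`` exists only for dof > 2.
    """
    dof = post.dof
    if dof <= 2:
        raise ValueError(f"marginal variance undefined for dof = {dof} <= 2")
    mean = float(post.beta_star[index])
    scale = math.sqrt(post.a_star / dof * post.V_star[index, index])
    alpha = 1.0 - level
    q = stats.t.ppf(1.0 - alpha / 2.0, df=dof)
    return mean, scale, dof, (mean - q * scale, mean + q * scale)


def conjugate_log_bf(
    model_i: ModelSpec,
    model_j: ModelSpec,
    data: Dataset,
    y_name: str,
    priors: Mapping[ModelSpec, NIGPrior],
) -> LogBayesFactor:
    """Closed-form log Bayes factor B_{ji} under proper NIG priors.

    ``log B_ji = 1/2 (log|V_i| + log|V_j*| - log|V_j| - log|V_i*|)
    + (d+n)/2 (log a_i* - log a_j*)``; both priors must share d.
    """
    y = data.column(y_name)
    entries = {}
    for m in (model_i, model_j):
        if m not in priors:
            raise InputError(f"no prior supplied for model {m}")
        prior = priors[m]
        X = build_design_matrix(data, m)
        fit = ols_fit(X, y)
        if fit.perfect_fit:
            raise PerfectFitError(f"model {m} fits the data perfectly")
        post = nig_update(X, y, prior)
        sign, logdet_V = np.linalg.slogdet(prior.V)
        sign_s, logdet_Vs = np.linalg.slogdet(post.V_star)
        if sign <= 0 or sign_s <= 0:
            raise ImproperPriorError("non-positive-definite prior or posterior V")
        entries[m] = (logdet_V, logdet_Vs, post.a_star, prior.d)
    ldV_i, ldVs_i, a_i, d_i = entries[model_i]
    ldV_j, ldVs_j, a_j, d_j = entries[model_j]
    if d_i != d_j:
        raise InputError("priors must share the degrees-of-freedom parameter d")
    n = data.n
    log_bf = 0.5 * (ldV_i + ldVs_j - ldV_j - ldVs_i) \
        + (d_i + n) / 2.0 * (math.log(a_i) - math.log(a_j))
    return LogBayesFactor(log_value=log_bf, method="conjugate",
                          model_j=model_j, model_i=model_i)


def reference_coefficient_posterior(
    data: Dataset, model: ModelSpec, y_name: str, coefficient: str,
    level: float = 0.95,
) -> tuple[float, float, float, tuple[float, float]]:
    """Coefficient posterior under the reference prior pi ~ sigma^-2.

    The marginal of each coefficient is Student t with n - k degrees of
    freedom, location the least-squares estimate and squared scale
    ``rss/(n-k) * (X'X)^-1_{ii}``.  Returns ``(mean, sd, dof, (lo, hi))``
    with sd the posterior standard deviation (requires n - k > 2).
    """
    y = data.column(y_name)
    X = build_design_matrix(data, model)
    if coefficient not in X.labels:
        raise InputError(f"{coefficient!r} is not a column of model {model}")
    fit = ols_fit(X, y, need_xtx_inv=True)
    dof = fit.n - fit.k
    if dof <= 2:
        raise ValueError("reference posterior sd needs n - k > 2")
    if fit.perfect_fit:
        raise PerfectFitError("perfect fit: reference posterior degenerate")
    idx = X.labels.index(coefficient)
    assert fit.xtx_inv is not None
    scale = math.sqrt(fit.rss / dof * fit.xtx_inv[idx, idx])
    mean = float(fit.coefficients[idx])
    sd = scale * math.sqrt(dof / (dof - 2.0))
    alpha = 1.0 - level
    q = stats.t.ppf(1.0 - alpha / 2.0, df=dof)
    return mean, sd, dof, (mean - q * scale, mean + q * scale)


def drop_incomplete_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Complete-case filter with a logged count of dropped rows."""
    kept = frame.dropna()
    dropped = len(frame) - len(kept)
    if dropped:
        logger.warning("dropped %d incomplete rows (complete-case analysis)", dropped)
    return kept
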