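"""The four objective model-comparison scores, each as a pairwise log Bayes factor.

All four avoid eliciting a subjective prior per submodel:

* **BIC** — Schwarz's asymptotic approximation to the Bayes factor;
* **IBF** — the arithmetic-mean intrinsic Bayes factor, which corrects the
  reference-prior (improper) Bayes factor with minimal training samples;
* **FBF** — O'Hagan's fractional Bayes factor, which spends a fraction ``b``
  of the likelihood as implicit training;
* **intrinsic** — the Bayes factor under intrinsic priors, a one-dimensional
  integral comparing a model with ``j`` regressors against the intercept-only
  model.

Everything is computed on the log scale; exponentiation happens only when
normalising posterior model probabilities.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.special import gammaln, logsumexp

from .regression_core import (
    Dataset,
    DesignMatrix,
    LogBayesFactor,
    ModelSpec,
    OLSFit,
    PerfectFitError,
    build_design_matrix,
    ols_fit,
)

__all__ = [
    "TrainingSampleSet",
    "FBFConfig",
    "IntrinsicStat",
    "NoValidTrainingSampleError",
    "bic_log_bf",
    "reference_log_bf",
    "draw_training_samples",
    "arithmetic_ibf",
    "fractional_bf",
    "intrinsic_prior_log_bf",
    "intrinsic_stat",
]

logger = logging.getLogger(__name__)

LOG_PI = math.log(math.pi)


class NoValidTrainingSampleError(RuntimeError):
    """Rejection sampling failed to find enough valid minimal training
    samples; signals near-degenerate covariates."""


@dataclass(frozen=True)
class TrainingSampleSet:
    """Minimal training samples: ``L`` index subsets of size ``m``.

    Each subset is validated to give full-rank designs and strictly positive
    residual sums of squares for the models under comparison.
    """

    indices: tuple[tuple[int, ...], ...]
    m: int
    L: int
    seed: int


@dataclass(frozen=True)
class FBFConfig:
    """Fraction ``b`` of the likelihood used as implicit training.

    ``variant`` selects the orientation of the small-sample gamma-ratio
    correction: ``"corrected"`` (default) penalises complexity at equal fit;
    ``"printed"`` reproduces the alternative orientation for fidelity studies.
    """

    b: float
    variant: str = "corrected"

    def __post_init__(self) -> None:
        if not 0.0 < self.b <= 1.0:
            raise ValueError(f"fraction b must be in (0, 1], got {self.b}")
        if self.variant not in ("printed", "corrected"):
            raise ValueError(f"unknown FBF variant {self.variant!r}")


@dataclass(frozen=True)
class IntrinsicStat:
    """Sufficient statistic for the intrinsic-prior Bayes factor.

    ``j`` regressors beyond the intercept; ``Bj = rss_j / (n s_y^2)`` with
    ``s_y^2`` the (divisor-n) sample variance of y, so ``Bj`` is the
    unexplained variance fraction, in [0, 1], and equals 1 for the
    intercept-only model.
    """

    j: int
    n: int
    Bj: float

    def __post_init__(self) -> None:
        if self.j < 0:
            raise ValueError("j must be nonnegative")
        if not 0.0 <= self.Bj <= 1.0:
            raise ValueError(f"Bj = {self.Bj} outside [0, 1]")


def _require_positive_rss(fit: OLSFit) -> None:
    if fit.perfect_fit or fit.rss <= 0.0:
        raise PerfectFitError(
            "residual sum of squares is numerically zero; Bayes-factor "
            "methods divide by rss powers"
        )


def bic_log_bf(fit_i: OLSFit, fit_j: OLSFit) -> LogBayesFactor:
    """Schwarz approximation:
    ``log B_ji = n/2 (log rss_i - log rss_j) + (k_i - k_j)/2 log n``."""
    if fit_i.n != fit_j.n:
        raise ValueError("fits have different sample sizes")
    _require_positive_rss(fit_i)
    _require_positive_rss(fit_j)
    n = fit_i.n
    log_bf = 0.5 * n * (math.log(fit_i.rss) - math.log(fit_j.rss)) \
        + 0.5 * (fit_i.k - fit_j.k) * math.log(n)
    return LogBayesFactor(log_bf, "bic",
                          ModelSpec(fit_j.labels[1:]), ModelSpec(fit_i.labels[1:]))


def _reference_log_bf_from_fits(fit_i: OLSFit, fit_j: OLSFit, n: int) -> float:
    """log B_ji^N for the improper reference prior pi ~ sigma^-2 (both models
    fit on the same n observations)."""
    k_i, k_j = fit_i.k, fit_j.k
    if n <= max(k_i, k_j):
        raise ValueError(f"n = {n} leaves no residual degrees of freedom")
    _require_positive_rss(fit_i)
    _require_positive_rss(fit_j)
    return (
        0.5 * (k_j - k_i) * LOG_PI
        + gammaln(0.5 * (n - k_j)) - gammaln(0.5 * (n - k_i))
        + 0.5 * (fit_i.xtx_logdet - fit_j.xtx_logdet)
        + 0.5 * (n - k_i) * math.log(fit_i.rss)
        - 0.5 * (n - k_j) * math.log(fit_j.rss)
    )


def reference_log_bf(
    model_i: ModelSpec, model_j: ModelSpec, data: Dataset, y_name: str
) -> LogBayesFactor:
    """Improper-reference-prior Bayes factor for the full data.

    Well defined as a formula but carries the arbitrary normalising constants
    of the improper priors — it is not scale invariant (``y -> c y`` shifts it
    by ``(k_j - k_i) log c``) and must be corrected by training samples (IBF)
    or a likelihood fraction (FBF) before use in selection.
    """
    y = data.column(y_name)
    fit_i = ols_fit(build_design_matrix(data, model_i), y)
    fit_j = ols_fit(build_design_matrix(data, model_j), y)
    value = _reference_log_bf_from_fits(fit_i, fit_j, data.n)
    return LogBayesFactor(value, "reference", model_j, model_i)


def _subsample_design(X: DesignMatrix, idx: Sequence[int]) -> DesignMatrix:
    return DesignMatrix(values=X.values[np.asarray(idx)], labels=X.labels)


def _subset_valid(X: DesignMatrix, y: np.ndarray, idx: tuple[int, ...]) -> bool:
    sub = _subsample_design(X, idx)
    try:
        fit = ols_fit(sub, y[np.asarray(idx)])
    except Exception:
        return False
    return not (fit.perfect_fit or fit.rss <= 0.0)


def draw_training_samples(
    X_union: DesignMatrix,
    y: np.ndarray,
    m: int,
    L: int,
    seed: int,
    models: Sequence[DesignMatrix] | None = None,
) -> TrainingSampleSet:
    """Draw ``L`` valid minimal training samples of size ``m``.

    Validity: every design in ``models`` (default: just ``X_union``)
    restricted to the subset is full rank with strictly positive rss.
    Validating the *largest* design suffices for all its submodels, because a
    submodel's rss on the subset is at least the larger model's.

    Subsets are sampled uniformly without replacement by rejection; if the
    total number of size-``m`` subsets does not exceed ``L``, all valid
    subsets are enumerated instead.  Deterministic given ``seed``.
    """
    n = X_union.n
    k_max = max((d.k for d in models), default=X_union.k) if models else X_union.k
    if m < k_max + 1:
        raise ValueError(
            f"minimal training sample needs m >= k_max + 1 = {k_max + 1}, got {m}"
        )
    if m > n:
        raise ValueError(f"training sample size m = {m} exceeds n = {n}")
    if L < 1:
        raise ValueError("L must be >= 1")
    designs = list(models) if models else [X_union]
    y = np.asarray(y, dtype=float)

    def valid(idx: tuple[int, ...]) -> bool:
        return all(_subset_valid(d, y, idx) for d in designs)

    total = math.comb(n, m)
    if total <= L:
        subsets = tuple(idx for idx in itertools.combinations(range(n), m) if valid(idx))
        if not subsets:
            raise NoValidTrainingSampleError("no valid training samples exist")
        return TrainingSampleSet(subsets, m, len(subsets), seed)

    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    cap = 1000 * L
    draws = 0
    while len(chosen) < L:
        if draws >= cap:
            raise NoValidTrainingSampleError(
                f"exceeded {cap} rejection draws; covariates may be near-degenerate"
            )
        idx = tuple(sorted(rng.choice(n, size=m, replace=False).tolist()))
        draws += 1
        if idx in seen:
            continue
        seen.add(idx)
        if valid(idx):
            chosen.append(idx)
    return TrainingSampleSet(tuple(chosen), m, L, seed)


def arithmetic_ibf(
    model_i: ModelSpec,
    model_j: ModelSpec,
    data: Dataset,
    y_name: str,
    ts: TrainingSampleSet,
) -> LogBayesFactor:
    """Arithmetic-mean intrinsic Bayes factor.

    ``log B_ji^mean = log B_ji^N + log[(1/L) sum_l B_ij^N(l)]`` where the
    inner reference Bayes factors are evaluated on the training subsamples
    (n -> m) and averaged with log-sum-exp.
    """
    y = data.column(y_name)
    X_i = build_design_matrix(data, model_i)
    X_j = build_design_matrix(data, model_j)
    fit_i = ols_fit(X_i, y)
    fit_j = ols_fit(X_j, y)
    full = _reference_log_bf_from_fits(fit_i, fit_j, data.n)
    inner = np.empty(len(ts.indices))
    for pos, idx in enumerate(ts.indices):
        sel = np.asarray(idx)
        sub_fit_i = ols_fit(_subsample_design(X_i, sel), y[sel])
        sub_fit_j = ols_fit(_subsample_design(X_j, sel), y[sel])
        # B_ij^N(l): roles swapped relative to the full-data factor
        inner[pos] = _reference_log_bf_from_fits(sub_fit_j, sub_fit_i, ts.m)
    correction = logsumexp(inner) - math.log(len(inner))
    return LogBayesFactor(full + correction, "ibf", model_j, model_i)


def fractional_bf(fit_i: OLSFit, fit_j: OLSFit, cfg: FBFConfig) -> LogBayesFactor:
    """Fractional Bayes factor for the normal linear model.

    corrected (default):
    ``log FBF_ji = lgamma((nb-k_i)/2) - lgamma((nb-k_j)/2)
    + lgamma((n-k_j)/2) - lgamma((n-k_i)/2)
    + n(1-b)/2 (log rss_i - log rss_j)``;
    the printed variant flips the second gamma ratio.
    """
    if fit_i.n != fit_j.n:
        raise ValueError("fits have different sample sizes")
    _require_positive_rss(fit_i)
    _require_positive_rss(fit_j)
    n = fit_i.n
    k_i, k_j = fit_i.k, fit_j.k
    nb = n * cfg.b
    if nb <= max(k_i, k_j):
        raise ValueError(f"n b = {nb} leaves no residual degrees of freedom")
    small = gammaln(0.5 * (nb - k_i)) - gammaln(0.5 * (nb - k_j))
    if cfg.variant == "corrected":
        large = gammaln(0.5 * (n - k_j)) - gammaln(0.5 * (n - k_i))
    else:  # printed
        large = gammaln(0.5 * (n - k_i)) - gammaln(0.5 * (n - k_j))
    log_bf = small + large + 0.5 * n * (1.0 - cfg.b) * (
        math.log(fit_i.rss) - math.log(fit_j.rss)
    )
    return LogBayesFactor(log_bf, "fbf",
                          ModelSpec(fit_j.labels[1:]), ModelSpec(fit_i.labels[1:]))


def intrinsic_stat(data: Dataset, model: ModelSpec, y_name: str) -> IntrinsicStat:
    """Compute (j, n, Bj) for a model: Bj = rss_j / total sum of squares."""
    y = data.column(y_name)
    fit = ols_fit(build_design_matrix(data, model), y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        raise PerfectFitError("response is constant; total sum of squares is zero")
    if fit.perfect_fit or fit.rss <= 0.0:
        raise PerfectFitError("perfect fit: intrinsic-prior integrand singular")
    Bj = fit.rss / tss
    if Bj > 1.0:
        if Bj > 1.0 + 1e-10:
            raise ValueError(f"Bj = {Bj} exceeds 1 beyond round-off")
        logger.warning("Bj = %.17g marginally above 1; clipped", Bj)
        Bj = 1.0
    return IntrinsicStat(j=model.size, n=data.n, Bj=Bj)


def _intrinsic_log_integrand(phi: np.ndarray, j: int, n: int, Bj: float) -> np.ndarray:
    s2 = np.sin(phi) ** 2
    if j == 1:
        t = np.zeros_like(phi)
    else:
        with np.errstate(divide="ignore"):
            t = (j - 1) * np.log(np.sin(phi))
    return (
        t
        + 0.5 * (n - j) * np.log(n + (j + 1) * s2)
        - 0.5 * (n - 1) * np.log(n * Bj + (j + 1) * s2)
    )


def intrinsic_prior_log_bf(stat: IntrinsicStat) -> LogBayesFactor:
    """Intrinsic-prior Bayes factor of a j-regressor model against the
    intercept-only model:

    ``B_j1 = (2 (j+1)^{(j-1)/2} / pi)
    int_0^{pi/2} (sin phi)^{j-1} [n + (j+1) sin^2 phi]^{(n-j)/2}
    / [n Bj + (j+1) sin^2 phi]^{(n-1)/2} dphi``.

    The integrand is evaluated in log space with max-subtraction and
    integrated by adaptive quadrature to relative tolerance 1e-8.  ``j = 0``
    returns 0 (the model is the base itself).
    """
    j, n, Bj = stat.j, stat.n, stat.Bj
    if j == 0:
        return LogBayesFactor(0.0, "intrinsic", ModelSpec(), ModelSpec())
    if n <= j + 1:
        raise ValueError(f"need n > j + 1, got n = {n}, j = {j}")
    if Bj == 0.0:
        raise PerfectFitError("Bj = 0 (perfect fit): integrand singular")
    grid = np.linspace(1e-12, math.pi / 2.0, 513)
    M = float(np.max(_intrinsic_log_integrand(grid, j, n, Bj)))

    def f(phi: float) -> float:
        return float(np.exp(_intrinsic_log_integrand(np.asarray([phi]), j, n, Bj) - M)[0])

    val, _ = integrate.quad(f, 0.0, math.pi / 2.0, epsrel=1e-10, epsabs=0.0, limit=200)
    log_bf = math.log(2.0 / math.pi) + 0.5 * (j - 1) * math.log(j + 1) + M + math.log(val)
    return LogBayesFactor(log_bf, "intrinsic", ModelSpec(), ModelSpec())
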