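"""Model-space enumeration and posterior model / inclusion probabilities.

All intercept-containing submodels of the candidate set are enumerated
(2^p of them), each is scored against the intercept-only base model by the
requested pairwise Bayes-factor method, and the scores are normalised into
posterior model probabilities:

``P(M_j | x) = B_j1 pi(M_j) / sum_i B_i1 pi(M_i)``

(with B_11 = 1).  The inclusion probability of a covariate is the sum of the
probabilities of the models containing it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from . import bayes_factors as bf
from .regression_core import (
    INTERCEPT,
    Dataset,
    InputError,
    ModelSpec,
    build_design_matrix,
    ols_fit,
)

__all__ = [
    "ModelSpace",
    "ModelPosterior",
    "InclusionTable",
    "METHODS",
    "enumerate_models",
    "model_posterior_probabilities",
    "inclusion_probabilities",
    "top_models",
]

logger = logging.getLogger(__name__)

METHODS = ("bic", "ibf", "fbf", "intrinsic")

#: hard cap on the number of candidates; 2^p models are enumerated
MAX_CANDIDATES = 20


@dataclass(frozen=True)
class ModelSpace:
    """All 2^p intercept-containing submodels, in a deterministic order:
    by subset size, then lexicographically in candidate order.  Covariates in
    ``forced`` appear in every model (and are excluded from ``candidates``)."""

    candidates: tuple[str, ...]
    models: tuple[ModelSpec, ...]
    forced: tuple[str, ...] = ()

    @property
    def p(self) -> int:
        return len(self.candidates)

    def index(self, model: ModelSpec) -> int:
        return self.models.index(model)


@dataclass(frozen=True)
class ModelPosterior:
    """Normalised posterior probabilities over a model space."""

    space: ModelSpace
    probs: np.ndarray
    log_evidence: np.ndarray  # log B_j1 vs the intercept-only base
    method: str
    prior: np.ndarray
    base_model: int = 0

    def __post_init__(self) -> None:
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("posterior probabilities do not sum to 1")
        if (self.probs < 0).any():
            raise ValueError("negative posterior probability")


@dataclass(frozen=True)
class InclusionTable:
    """Per-covariate posterior inclusion probabilities; intercept fixed at 1.
    Forced-in covariates (probability 1 by construction) are listed
    separately from the data-driven candidates."""

    probability: dict[str, float]
    forced: tuple[str, ...] = ()


def enumerate_models(
    candidates: Sequence[str], forced: Sequence[str] = ()
) -> ModelSpace:
    """Enumerate the 2^p submodels over the free candidates.

    Every model implicitly contains the intercept; covariates in ``forced``
    are prepended to each model's inclusion list.
    """
    candidates = tuple(candidates)
    forced = tuple(forced)
    if len(set(candidates)) != len(candidates):
        raise InputError("duplicate candidate names")
    if set(candidates) & set(forced):
        raise InputError("a covariate cannot be both free and forced")
    if len(candidates) > MAX_CANDIDATES:
        raise InputError(
            f"{len(candidates)} candidates would enumerate 2^{len(candidates)} "
            "models; use a stochastic model-space search instead"
        )
    models = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(range(len(candidates)), size):
            names = tuple(candidates[i] for i in subset)
            models.append(ModelSpec(forced + names))
    return ModelSpace(candidates=candidates, models=tuple(models), forced=forced)


def _log_evidence_bic(space, data, y, fits, n):
    base = fits[0]
    return np.array([bf.bic_log_bf(base, f).log_value for f in fits])


def _log_evidence_fbf(space, data, y, fits, n, b, variant):
    k_max = max(f.k for f in fits)
    if b == "auto" or b is None:
        b = (k_max + 1) / n
    cfg = bf.FBFConfig(b=float(b), variant=variant)
    base = fits[0]
    return np.array([bf.fractional_bf(base, f, cfg).log_value for f in fits])


def _log_evidence_intrinsic(space, data, y, fits, n):
    tss = float(np.sum((y - y.mean()) ** 2))
    out = np.empty(len(fits))
    for idx, (model, fit) in enumerate(zip(space.models, fits)):
        stat = bf.IntrinsicStat(j=model.size, n=n, Bj=min(fit.rss / tss, 1.0))
        out[idx] = bf.intrinsic_prior_log_bf(stat).log_value
    return out


def _log_evidence_ibf(space, data, y_name, fits, n, L, seed):
    full_model = space.models[-1]
    X_full = build_design_matrix(data, full_model)
    m = X_full.k + 1
    if L is None:
        L = min(math.comb(n, m), 200)
    ts = bf.draw_training_samples(X_full, data.column(y_name), m=m, L=L, seed=seed)
    base = ModelSpec(())  # intercept-only, nested in every model
    out = np.empty(len(space.models))
    for idx, model in enumerate(space.models):
        if model == base:
            out[idx] = 0.0
        else:
            out[idx] = bf.arithmetic_ibf(base, model, data, y_name, ts).log_value
    return out


def model_posterior_probabilities(
    space: ModelSpace,
    data: Dataset,
    y_name: str,
    method: str,
    *,
    model_prior: np.ndarray | None = None,
    seed: int = 0,
    ibf_L: int | None = None,
    fbf_b: float | str = "auto",
    fbf_variant: str = "corrected",
) -> ModelPosterior:
    """Posterior model probabilities under one of the four methods.

    Every model is scored against the intercept-only base (log B_j1) and the
    scores are softmax-normalised together with the model prior (uniform by
    default).  For the IBF one shared training-sample set with
    ``m = k_full + 1`` is drawn once (seeded) and reused for every pair.
    """
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}; choose from {METHODS}")
    y = data.column(y_name)
    n = data.n
    fits = [ols_fit(build_design_matrix(data, m), y) for m in space.models]
    k_max = max(f.k for f in fits)
    if n <= k_max + 1:
        raise InputError(f"need n > k_max + 1 = {k_max + 1}, got n = {n}")
    for model, fit in zip(space.models, fits):
        if fit.perfect_fit:
            raise bf.PerfectFitError(f"model {model} fits perfectly; cannot score")

    if method == "bic":
        log_ev = _log_evidence_bic(space, data, y, fits, n)
    elif method == "fbf":
        log_ev = _log_evidence_fbf(space, data, y, fits, n, fbf_b, fbf_variant)
    elif method == "intrinsic":
        log_ev = _log_evidence_intrinsic(space, data, y, fits, n)
    else:  # ibf
        log_ev = _log_evidence_ibf(space, data, y_name, fits, n, ibf_L, seed)

    if model_prior is None:
        prior = np.full(len(space.models), 1.0 / len(space.models))
    else:
        prior = np.asarray(model_prior, dtype=float)
        if prior.shape != (len(space.models),) or (prior < 0).any():
            raise InputError("model prior must be a nonnegative vector over the space")
        prior = prior / prior.sum()
    with np.errstate(divide="ignore"):
        scores = log_ev + np.log(prior)
    probs = np.exp(scores - logsumexp(scores))
    probs = probs / probs.sum()
    return ModelPosterior(space=space, probs=probs, log_evidence=log_ev,
                          method=method, prior=prior)


def inclusion_probabilities(mp: ModelPosterior) -> InclusionTable:
    """Sum posterior probabilities of the models containing each covariate."""
    table: dict[str, float] = {INTERCEPT: 1.0}
    for name in mp.space.candidates:
        table[name] = float(sum(
            p for model, p in zip(mp.space.models, mp.probs) if name in model
        ))
    return InclusionTable(probability=table, forced=mp.space.forced)


def top_models(mp: ModelPosterior, m: int) -> list[tuple[ModelSpec, float]]:
    """The ``m`` most probable models, descending; ties broken by the
    deterministic model-space order."""
    if m < 1:
        raise InputError("m must be >= 1")
    order = sorted(range(len(mp.probs)), key=lambda i: (-mp.probs[i], i))
    return [(mp.space.models[i], float(mp.probs[i])) for i in order[:m]]
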