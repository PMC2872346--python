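"""Bayesian model averaging of regression coefficients.

The model-averaged posterior mean of a coefficient is the probability-weighted
sum of its per-model posterior means; the averaged variance is Leamer's
decomposition

``V = sum_j V_j P(M_j) + sum_j (E_j - E)^2 P(M_j)``

(within-model uncertainty plus between-model spread).  Per-model posteriors
use the reference prior, under which the posterior mean is the least-squares
estimate and the marginal is a Student t with n - k degrees of freedom.

Two averaging modes: ``all_models`` treats the coefficient as exactly zero in
models that exclude it (the sum runs over all q models); ``conditional``
restricts to including models with renormalised weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_space import ModelPosterior, ModelSpace
from .regression_core import (
    INTERCEPT,
    Dataset,
    InputError,
    ModelSpec,
    reference_coefficient_posterior,
)

__all__ = ["BMAEstimate", "bma_coefficient"]


@dataclass(frozen=True)
class BMAEstimate:
    coefficient: str
    mean: float
    variance: float
    mode: str
    per_model: tuple[tuple[ModelSpec, float, float, float], ...]
    # each entry: (model, weight, within-model mean, within-model variance)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def bma_coefficient(
    space: ModelSpace,
    mp: ModelPosterior,
    data: Dataset,
    y_name: str,
    coefficient: str,
    mode: str = "all_models",
    weight_floor: float = 1e-12,
) -> BMAEstimate:
    """Model-averaged posterior mean and Leamer variance of a coefficient.

    Models with posterior weight below ``weight_floor`` contribute nothing
    and are not fit (their reference posterior may not even exist when
    n - k <= 2); the floor is far below any reportable probability.
    """
    if mode not in ("all_models", "conditional"):
        raise InputError(f"unknown BMA mode {mode!r}")
    if coefficient != INTERCEPT and coefficient not in (*space.candidates, *space.forced):
        raise InputError(f"{coefficient!r} is not a candidate covariate")

    rows: list[tuple[ModelSpec, float, float, float]] = []
    for model, weight in zip(space.models, mp.probs):
        includes = coefficient == INTERCEPT or coefficient in model
        if mode == "conditional" and not includes:
            continue
        if weight <= weight_floor:
            rows.append((model, float(weight), 0.0, 0.0))
            continue
        if includes:
            mean, sd, _, _ = reference_coefficient_posterior(
                data, model, y_name, coefficient
            )
            rows.append((model, float(weight), mean, sd * sd))
        else:
            rows.append((model, float(weight), 0.0, 0.0))

    weights = np.array([r[1] for r in rows])
    total = weights.sum()
    if mode == "conditional":
        if total <= weight_floor:
            raise InputError(
                f"{coefficient!r} has no posterior mass in any including model"
            )
        weights = weights / total
    means = np.array([r[2] for r in rows])
    variances = np.array([r[3] for r in rows])
    mean = float(weights @ means)
    within = float(weights @ variances)
    between = float(weights @ (means - mean) ** 2)
    return BMAEstimate(
        coefficient=coefficient,
        mean=mean,
        variance=within + between,
        mode=mode,
        per_model=tuple((m, w, mu, v) for (m, _, mu, v), w in zip(rows, weights)),
    )
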