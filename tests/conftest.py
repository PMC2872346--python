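import math

import numpy as np
import pytest

from bvscea.regression_core import Dataset, ModelSpec


@pytest.fixture
def line_data() -> Dataset:
    """n=5 fixture with one covariate, y roughly linear in x."""
    return Dataset.from_columns(
        {"x": [1.0, 2.0, 3.0, 4.0, 5.0], "y": [1.2, 1.9, 3.2, 3.8, 5.1]}
    )


@pytest.fixture
def six_row_data() -> Dataset:
    """n=6 fixture with one covariate and a generic integer-ish response."""
    return Dataset.from_columns(
        {"x": [0.0, 1.0, 2.0, 3.0, 5.0, 8.0], "y": [2.0, 3.0, 5.0, 4.0, 9.0, 12.0]}
    )


@pytest.fixture
def intercept_only() -> ModelSpec:
    return ModelSpec(())


@pytest.fixture
def one_covariate() -> ModelSpec:
    return ModelSpec(("x",))


def simpson_log_marginal(X, y, log_weight, log_s2_grid, precision_extra=None,
                         shift=None, n_points=201, half_width=12.0):
    """Brute-force marginal likelihood by nested Simpson integration.

    Integrates ``exp(loglik(beta, s2) + log_weight(beta, s2))`` over the
    coefficients and sigma^2 (the latter on a log grid, Jacobian included).
    For each sigma^2 slice the coefficient grid is centred on the ridge
    solution ``(X'X + P)^-1 (X'y + s)`` with half-width ``half_width``
    conditional standard deviations, so heavy sigma^2 tails never truncate
    the coefficient integral.  ``P``/``s`` default to zero (flat coefficient
    weight); pass the prior precision and precision-weighted prior mean for
    a Gaussian coefficient weight.  Independent of the closed forms under
    test.
    """
    from scipy.integrate import simpson
    from scipy.special import logsumexp

    n, k = X.shape
    P = X.T @ X + (precision_extra if precision_extra is not None else 0.0)
    s = X.T @ y + (shift if shift is not None else 0.0)
    center = np.linalg.solve(P, s)
    cond_sd = np.sqrt(np.diag(np.linalg.inv(P)))
    log_slices = np.empty(len(log_s2_grid))
    for pos, t in enumerate(log_s2_grid):
        sig = math.exp(0.5 * t)
        grids = [np.linspace(center[i] - half_width * sig * cond_sd[i],
                             center[i] + half_width * sig * cond_sd[i],
                             n_points) for i in range(k)]
        mesh = np.meshgrid(*grids, indexing="ij")
        B = np.stack([m.ravel() for m in mesh], axis=1)
        S2 = np.full(B.shape[0], math.exp(t))
        R = y[None, :] - B @ X.T
        rss = np.einsum("ij,ij->i", R, R)
        logf = (-0.5 * n * np.log(2.0 * np.pi * S2) - rss / (2.0 * S2)
                + log_weight(B, S2))
        M = float(np.max(logf))
        vals = np.exp(logf - M).reshape([n_points] * k)
        for g in reversed(grids):
            vals = simpson(vals, x=g, axis=-1)
        log_slices[pos] = M + math.log(vals) + t  # + t: d(sigma^2) = s2 dt
    M = float(np.max(log_slices))
    outer = simpson(np.exp(log_slices - M), x=log_s2_grid)
    return float(M + math.log(outer))
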