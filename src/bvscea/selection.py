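"""scikit-learn style front end for Bayesian variable selection.

:class:`BayesianVariableSelector` enumerates all intercept-containing
submodels of the supplied covariates, scores them with one of the four
objective Bayes-factor methods and exposes posterior model probabilities,
per-covariate inclusion probabilities and model-averaged coefficients as
fitted attributes.  It composes with sklearn pipelines and cloning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import bma as bma_mod
from . import model_space as ms
from .regression_core import Dataset, InputError, ModelSpec

__all__ = ["BayesianVariableSelector"]


class BayesianVariableSelector(BaseEstimator):
    """Exhaustive objective-Bayes variable selection for normal linear models.

    Parameters
    ----------
    method : {"bic", "ibf", "fbf", "intrinsic"}, default "bic"
        Pairwise Bayes-factor method used to score submodels against the
        intercept-only base model.
    model_prior : array-like of shape (2^p,) or None
        Prior over the enumerated model space; None means uniform.
    forced : sequence of str, default ()
        Covariates forced into every model (inclusion probability 1 by
        construction; reported separately).
    ibf_L : int or None
        Number of minimal training samples for the arithmetic-mean IBF;
        None means min(C(n, m), 200) with m = k_full + 1.
    fbf_b : float or "auto"
        Fraction of the likelihood used as implicit training by the FBF;
        "auto" means (k_max + 1)/n, the minimal-training-sample ratio.
    fbf_variant : {"corrected", "printed"}
        Orientation of the FBF's small-sample gamma correction.
    random_state : int, default 0
        Seed for the IBF training-sample draw.

    Attributes
    ----------
    model_space_ : ModelSpace
        The 2^p enumerated submodels.
    posterior_ : ModelPosterior
        Normalised posterior model probabilities.
    posterior_probabilities_ : ndarray of shape (2^p,)
    log_evidence_ : ndarray of shape (2^p,)
        log Bayes factor of each model against the intercept-only model.
    inclusion_probabilities_ : pandas.Series
        Posterior inclusion probability per covariate (intercept = 1).
    feature_names_in_ : ndarray of str

    Examples
    --------
    >>> from bvscea.simulation import simulate_table1, Table1Config
    >>> data = simulate_table1(Table1Config(n=300, seed=1))
    >>> sel = BayesianVariableSelector(method="bic").fit(
    ...     data.frame[["x1", "x2", "x3", "x4", "x5", "x6"]], data.frame["y"])
    >>> sel.top_models(1)[0][0]  # doctest: +SKIP
    ModelSpec(included=('x2', 'x4', 'x6'))
    """

    def __init__(
        self,
        method: str = "bic",
        model_prior=None,
        forced: tuple[str, ...] = (),
        ibf_L: int | None = None,
        fbf_b: float | str = "auto",
        fbf_variant: str = "corrected",
        random_state: int = 0,
    ):
        self.method = method
        self.model_prior = model_prior
        self.forced = forced
        self.ibf_L = ibf_L
        self.fbf_b = fbf_b
        self.fbf_variant = fbf_variant
        self.random_state = random_state

    def _as_dataset(self, X, y) -> tuple[Dataset, str, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            frame = X.astype(float).copy()
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise InputError("X must be two-dimensional")
            names = [f"x{i + 1}" for i in range(X.shape[1])]
            frame = pd.DataFrame(X, columns=names)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != frame.shape[0]:
            raise InputError("X and y have inconsistent lengths")
        y_name = "__response__"
        frame = frame.reset_index(drop=True)
        frame[y_name] = y
        return Dataset(frame), y_name, names

    def fit(self, X, y):
        """Enumerate and score all submodels of the columns of X."""
        data, y_name, names = self._as_dataset(X, y)
        forced = tuple(self.forced)
        candidates = [c for c in names if c not in forced]
        space = ms.enumerate_models(candidates, forced=forced)
        posterior = ms.model_posterior_probabilities(
            space, data, y_name, self.method,
            model_prior=self.model_prior,
            seed=self.random_state,
            ibf_L=self.ibf_L,
            fbf_b=self.fbf_b,
            fbf_variant=self.fbf_variant,
        )
        table = ms.inclusion_probabilities(posterior)
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.model_space_ = space
        self.posterior_ = posterior
        self.posterior_probabilities_ = posterior.probs
        self.log_evidence_ = posterior.log_evidence
        self.inclusion_probabilities_ = pd.Series(table.probability)
        self._data = data
        self._y_name = y_name
        return self

    def top_models(self, m: int = 5) -> list[tuple[ModelSpec, float]]:
        """The m most probable models, descending."""
        check_is_fitted(self, "posterior_")
        return ms.top_models(self.posterior_, m)

    def modal_model(self) -> ModelSpec:
        """The single most probable model."""
        return self.top_models(1)[0][0]

    def bma_coefficient(self, coefficient: str, mode: str = "all_models"):
        """Model-averaged posterior mean and variance of one coefficient."""
        check_is_fitted(self, "posterior_")
        return bma_mod.bma_coefficient(
            self.model_space_, self.posterior_, self._data, self._y_name,
            coefficient, mode=mode,
        )
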