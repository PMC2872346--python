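"""The four pairwise model-comparison scores and their invariances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import simpson
from scipy.special import gammaln

from bvscea.bayes_factors import (
    FBFConfig,
    IntrinsicStat,
    NoValidTrainingSampleError,
    TrainingSampleSet,
    arithmetic_ibf,
    bic_log_bf,
    draw_training_samples,
    fractional_bf,
    intrinsic_prior_log_bf,
    intrinsic_stat,
    reference_log_bf,
)
from bvscea.regression_core import (
    Dataset,
    ModelSpec,
    OLSFit,
    PerfectFitError,
    build_design_matrix,
    ols_fit,
)

from conftest import simpson_log_marginal


def make_fit(rss: float, k: int, n: int, xtx_logdet: float = 0.0,
             labels=None) -> OLSFit:
    labels = labels or ("(intercept)", *[f"c{i}" for i in range(k - 1)])
    return OLSFit(coefficients=np.zeros(k), rss=rss, k=k, n=n, rank=k,
                  perfect_fit=False, xtx_logdet=xtx_logdet, labels=tuple(labels))


class TestBIC:
    def test_equal_fits_give_even_odds(self):
        f = make_fit(10.0, 2, 20)
        assert bic_log_bf(f, f).log_value == 0.0

    def test_direct_evaluation(self):
        # rss_i=100, rss_j=50, n=20, k_i=2, k_j=3: BF = 2^10 * 20^(-1/2)
        f_i = make_fit(100.0, 2, 20)
        f_j = make_fit(50.0, 3, 20)
        expected = 10.0 * math.log(2.0) - 0.5 * math.log(20.0)
        bf = bic_log_bf(f_i, f_j)
        assert bf.log_value == pytest.approx(expected, rel=1e-12)
        assert math.exp(bf.log_value) == pytest.approx(1024.0 / math.sqrt(20.0))

    def test_perfect_fit_rejected(self):
        with pytest.raises(PerfectFitError):
            bic_log_bf(make_fit(0.0, 2, 20), make_fit(1.0, 2, 20))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_and_transitivity(self, seed):
        rng = np.random.default_rng(seed)
        rss = rng.uniform(0.5, 50.0, 3)
        ks = rng.integers(1, 6, 3)
        n = int(rng.integers(10, 500))
        f1, f2, f3 = (make_fit(r, int(k), n) for r, k in zip(rss, ks))
        b21 = bic_log_bf(f1, f2).log_value
        b12 = bic_log_bf(f2, f1).log_value
        assert b21 == pytest.approx(-b12, abs=1e-10)
        b13 = bic_log_bf(f3, f1).log_value
        b23 = bic_log_bf(f3, f2).log_value
        assert b21 + b13 == pytest.approx(b23, abs=1e-10)


class TestReferenceBF:
    def test_identity(self, six_row_data):
        m = ModelSpec(("x",))
        assert reference_log_bf(m, m, six_row_data, "y").log_value == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_numeric_integration_oracle(self, six_row_data):
        """The closed form equals the ratio of improper-reference-prior
        marginals ``int N(y|Xb, s2) s^-2 db ds2`` computed on a grid."""
        y = six_row_data.column("y")
        # generous sigma^2 range: the base model's scale posterior has only
        # 2.5 tail degrees of freedom, so truncation bites slowly
        ts = np.linspace(-6.0, 14.0, 481)

        def ref_weight(B, S2):
            return -np.log(S2)

        lm_base = simpson_log_marginal(np.ones((6, 1)), y, ref_weight, ts)
        X = np.column_stack([np.ones(6), six_row_data.column("x")])
        lm_full = simpson_log_marginal(X, y, ref_weight, ts)
        impl = reference_log_bf(
            ModelSpec(()), ModelSpec(("x",)), six_row_data, "y").log_value
        assert impl == pytest.approx(lm_full - lm_base, rel=1e-5)

    def test_known_scale_drift(self, six_row_data):
        """y -> 2y shifts the improper-prior factor by (k_j - k_i) log 2 —
        the defect the training-sample corrections remove."""
        mi, mj = ModelSpec(()), ModelSpec(("x",))
        base = reference_log_bf(mi, mj, six_row_data, "y").log_value
        scaled_data = Dataset.from_columns(
            {"x": six_row_data.column("x"), "y": 2.0 * six_row_data.column("y")})
        scaled = reference_log_bf(mi, mj, scaled_data, "y").log_value
        assert scaled - base == pytest.approx((2 - 1) * math.log(2.0), abs=1e-9)


class TestTrainingSamples:
    @pytest.fixture
    def design(self, six_row_data):
        return build_design_matrix(six_row_data, ModelSpec(("x",)))

    def test_full_set_when_m_equals_n(self, design, six_row_data):
        ts = draw_training_samples(design, six_row_data.column("y"), m=6, L=1, seed=0)
        assert ts.indices == ((0, 1, 2, 3, 4, 5),)

    def test_deterministic_and_valid(self):
        rng = np.random.default_rng(3)
        data = Dataset.from_columns({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        X = build_design_matrix(data, ModelSpec(("x",)))
        y = data.column("y")
        ts1 = draw_training_samples(X, y, m=8, L=3, seed=5)
        ts2 = draw_training_samples(X, y, m=8, L=3, seed=5)
        assert ts1.indices == ts2.indices
        assert len(set(ts1.indices)) == 3
        # exhaustive validity oracle: every subset full rank with rss > 0
        for idx in ts1.indices:
            sub = X.values[np.asarray(idx)]
            assert np.linalg.matrix_rank(sub) == 2
            beta = np.linalg.lstsq(sub, y[np.asarray(idx)], rcond=None)[0]
            assert np.sum((y[np.asarray(idx)] - sub @ beta) ** 2) > 0

    def test_m_below_minimum_rejected(self, design, six_row_data):
        with pytest.raises(ValueError):
            draw_training_samples(design, six_row_data.column("y"), m=2, L=1, seed=0)

    def test_degenerate_covariate_filtered(self):
        # x constant except one row: only subsets containing row 0 are valid
        data = Dataset.from_columns(
            {"x": [1.0] + [0.0] * 7, "y": [0.1, 1.0, 2.0, 3.0, 1.5, 2.5, 0.5, 1.2]})
        X = build_design_matrix(data, ModelSpec(("x",)))
        ts = draw_training_samples(X, data.column("y"), m=3, L=5, seed=1)
        for idx in ts.indices:
            assert 0 in idx


class TestArithmeticIBF:
    def test_identity(self, six_row_data):
        X = build_design_matrix(six_row_data, ModelSpec(("x",)))
        ts = draw_training_samples(X, six_row_data.column("y"), m=3, L=50, seed=0)
        m = ModelSpec(("x",))
        assert arithmetic_ibf(m, m, six_row_data, "y", ts).log_value == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, six_row_data):
        """Against brute-force evaluation over all C(6,3) training subsets
        with plain-float arithmetic (no log-sum-exp)."""
        mi, mj = ModelSpec(()), ModelSpec(("x",))
        X_j = build_design_matrix(six_row_data, mj)
        y = six_row_data.column("y")
        ts = draw_training_samples(X_j, y, m=3, L=100, seed=0)
        assert len(ts.indices) == 20  # all subsets valid on this fixture

        def ref_bf(Xi, Xj, yy, nn):
            def piece(X, k):
                b = np.linalg.lstsq(X, yy, rcond=None)[0]
                rss = float(np.sum((yy - X @ b) ** 2))
                det = float(np.linalg.det(X.T @ X))
                return rss, det
            rss_i, det_i = piece(Xi, Xi.shape[1])
            rss_j, det_j = piece(Xj, Xj.shape[1])
            k_i, k_j = Xi.shape[1], Xj.shape[1]
            return (math.pi ** (0.5 * (k_j - k_i))
                    * math.gamma(0.5 * (nn - k_j)) / math.gamma(0.5 * (nn - k_i))
                    * math.sqrt(det_i / det_j)
                    * rss_i ** (0.5 * (nn - k_i)) / rss_j ** (0.5 * (nn - k_j)))

        Xi = np.ones((6, 1))
        Xj = X_j.values
        full = ref_bf(Xi, Xj, y, 6)
        # B_ij^N(l): model roles swapped on the subsample
        inner = [ref_bf(Xj[list(idx)], Xi[list(idx)], y[list(idx)], 3)
                 for idx in ts.indices]
        expected = math.log(full * np.mean(inner))
        impl = arithmetic_ibf(mi, mj, six_row_data, "y", ts).log_value
        assert impl == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance(self, six_row_data):
        mi, mj = ModelSpec(()), ModelSpec(("x",))
        X_j = build_design_matrix(six_row_data, mj)
        y = six_row_data.column("y")
        ts = draw_training_samples(X_j, y, m=3, L=100, seed=0)
        base = arithmetic_ibf(mi, mj, six_row_data, "y", ts).log_value
        scaled = Dataset.from_columns(
            {"x": six_row_data.column("x"), "y": 2.0 * y})
        assert arithmetic_ibf(mi, mj, scaled, "y", ts).log_value == pytest.approx(
            base, abs=1e-9)


class TestFractionalBF:
    def test_full_fraction_is_even_odds(self):
        f_i, f_j = make_fit(30.0, 2, 20), make_fit(10.0, 4, 20)
        cfg = FBFConfig(b=1.0, variant="corrected")
        assert fractional_bf(f_i, f_j, cfg).log_value == pytest.approx(0.0, abs=1e-12)

    def test_direct_log_gamma_evaluation(self):
        f_i, f_j = make_fit(100.0, 2, 20), make_fit(50.0, 3, 20)
        cfg = FBFConfig(b=0.2, variant="corrected")
        expected = (gammaln(1.0) - gammaln(0.5)
                    + gammaln(8.5) - gammaln(9.0)
                    + 8.0 * math.log(2.0))
        assert fractional_bf(f_i, f_j, cfg).log_value == pytest.approx(
            expected, rel=1e-12)

    def test_complexity_penalty_orientation(self):
        """At equal rss the corrected variant penalises the extra parameter;
        the printed orientation rewards it."""
        f_i, f_j = make_fit(50.0, 2, 20), make_fit(50.0, 3, 20)
        b = (3 + 1) / 20
        corrected = fractional_bf(f_i, f_j, FBFConfig(b=b, variant="corrected"))
        printed = fractional_bf(f_i, f_j, FBFConfig(b=b, variant="printed"))
        assert corrected.log_value < 0
        assert printed.log_value > 0

    def test_insufficient_fraction_rejected(self):
        with pytest.raises(ValueError):
            fractional_bf(make_fit(1.0, 2, 20), make_fit(1.0, 3, 20),
                          FBFConfig(b=0.1))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_and_transitivity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 300))
        fits = [make_fit(float(r), int(k), n)
                for r, k in zip(rng.uniform(0.5, 50.0, 3), rng.integers(1, 6, 3))]
        cfg = FBFConfig(b=0.5)
        b21 = fractional_bf(fits[0], fits[1], cfg).log_value
        b12 = fractional_bf(fits[1], fits[0], cfg).log_value
        assert b21 == pytest.approx(-b12, abs=1e-10)
        b13 = fractional_bf(fits[2], fits[0], cfg).log_value
        b23 = fractional_bf(fits[2], fits[1], cfg).log_value
        assert b21 + b13 == pytest.approx(b23, abs=1e-10)


def simpson_intrinsic_oracle(j: int, n: int, Bj: float, panels: int = 10**6) -> float:
    """Fixed-grid Simpson evaluation of the intrinsic-prior integral in log
    space with max-subtraction."""
    phi = np.linspace(0.0, math.pi / 2.0, panels + 1)
    s2 = np.sin(phi) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = ((j - 1) * np.log(np.sin(phi))
                + 0.5 * (n - j) * np.log(n + (j + 1) * s2)
                - 0.5 * (n - 1) * np.log(n * Bj + (j + 1) * s2))
    if j == 1:
        logf[0] = (0.5 * (n - j) * math.log(n) - 0.5 * (n - 1) * math.log(n * Bj))
    M = float(np.max(logf[np.isfinite(logf)]))
    vals = np.exp(logf - M)
    vals[~np.isfinite(logf)] = 0.0
    integral = simpson(vals, x=phi)
    return math.log(2.0 / math.pi) + 0.5 * (j - 1) * math.log(j + 1) + M \
        + math.log(integral)


class TestIntrinsicPriorBF:
    def test_base_model_identity(self):
        assert intrinsic_prior_log_bf(IntrinsicStat(0, 20, 1.0)).log_value == 0.0

    @pytest.mark.parametrize("j,n,Bj", [(1, 20, 0.5), (2, 50, 0.3), (3, 30, 0.9)])
    def test_matches_simpson_oracle(self, j, n, Bj):
        impl = intrinsic_prior_log_bf(IntrinsicStat(j, n, Bj)).log_value
        oracle = simpson_intrinsic_oracle(j, n, Bj)
        assert impl == pytest.approx(oracle, rel=1e-8)

    def test_useless_regressor_not_favoured(self):
        """A regressor that explains nothing (Bj = 1) never gains evidence:
        for one regressor the integrand is identically 1 and the Bayes factor
        is exactly 1; from two regressors on, complexity is penalised."""
        val1 = intrinsic_prior_log_bf(IntrinsicStat(1, 20, 1.0)).log_value
        assert val1 == pytest.approx(0.0, abs=1e-10)
        val2 = intrinsic_prior_log_bf(IntrinsicStat(2, 20, 1.0)).log_value
        assert val2 < 0
        assert val2 == pytest.approx(simpson_intrinsic_oracle(2, 20, 1.0), rel=1e-8)

    def test_monotone_in_unexplained_fraction(self):
        values = [intrinsic_prior_log_bf(IntrinsicStat(2, 40, b)).log_value
                  for b in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_perfect_fit_rejected(self):
        with pytest.raises(PerfectFitError):
            intrinsic_prior_log_bf(IntrinsicStat(1, 20, 0.0))

    def test_no_overflow_at_large_n(self):
        val = intrinsic_prior_log_bf(IntrinsicStat(3, 10**5, 0.2)).log_value
        assert math.isfinite(val)

    def test_stat_from_data(self, six_row_data):
        stat = intrinsic_stat(six_row_data, ModelSpec(("x",)), "y")
        assert stat.j == 1 and stat.n == 6
        assert 0.0 < stat.Bj < 1.0
        base = intrinsic_stat(six_row_data, ModelSpec(()), "y")
        assert base.Bj == pytest.approx(1.0, abs=1e-12)


class TestScaleLocationInvariance:
    """bic, fbf, ibf and intrinsic scores are invariant under y -> a y + c."""

    @pytest.mark.parametrize("alpha,c", [(2.0, 0.0), (-1.0, 0.0), (0.5, 7.0),
                                         (3.0, -40.0)])
    def test_all_methods(self, six_row_data, alpha, c):
        y = six_row_data.column("y")
        data2 = Dataset.from_columns(
            {"x": six_row_data.column("x"), "y": alpha * y + c})
        mi, mj = ModelSpec(()), ModelSpec(("x",))

        def fits(d):
            return (ols_fit(build_design_matrix(d, mi), d.column("y")),
                    ols_fit(build_design_matrix(d, mj), d.column("y")))

        f1 = fits(six_row_data)
        f2 = fits(data2)
        assert bic_log_bf(*f1).log_value == pytest.approx(
            bic_log_bf(*f2).log_value, abs=1e-8)
        cfg = FBFConfig(b=0.5)
        assert fractional_bf(*f1, cfg).log_value == pytest.approx(
            fractional_bf(*f2, cfg).log_value, abs=1e-8)
        s1 = intrinsic_stat(six_row_data, mj, "y")
        s2 = intrinsic_stat(data2, mj, "y")
        assert intrinsic_prior_log_bf(s1).log_value == pytest.approx(
            intrinsic_prior_log_bf(s2).log_value, abs=1e-8)
        X_j = build_design_matrix(six_row_data, mj)
        ts = draw_training_samples(X_j, y, m=3, L=100, seed=0)
        assert arithmetic_ibf(mi, mj, six_row_data, "y", ts).log_value == \
            pytest.approx(arithmetic_ibf(mi, mj, data2, "y", ts).log_value, abs=1e-8)
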