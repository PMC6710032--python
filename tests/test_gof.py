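"""Corrected W*/A* statistics, information criteria, KS test, Hessian SEs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from adequacy.gof import (
    anderson_darling,
    compute_u,
    cramer_von_mises,
    information_criteria,
    ks_test,
    numerical_hessian,
    standard_errors,
)


def w2_bruteforce(u):
    """n * int_0^1 (U_n(t) - t)^2 dt by exact piecewise integration.

    U_n is the empirical cdf of the transformed sample u; on each interval
    between consecutive break points U_n is the constant c = i/n, and
    int (c - t)^2 dt has the closed antiderivative -(c - t)^3 / 3.
    """
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    knots = np.concatenate(([0.0], u, [1.0]))
    total = 0.0
    for i in range(n + 1):
        c = i / n
        a, b = knots[i], knots[i + 1]
        total += ((c - a) ** 3 - (c - b) ** 3) / 3.0
    return n * total


class TestComputeU:
    def test_two_point_example(self):
        # v = (0.3, 0.7): y = -/+0.52440, ybar = 0, s_y = 0.74161,
        # u = Phi(-/+0.70711)
        gin = compute_u(
            np.array([1.0, 2.0]), lambda x: np.where(x < 1.5, 0.3, 0.7)
        )
        assert np.allclose(gin.normal_scores, [-0.5244005, 0.5244005], atol=1e-6)
        assert np.allclose(gin.u_values, [0.2397501, 0.7602499], atol=1e-6)

    def test_symmetric_v_gives_symmetric_u(self):
        v = np.array([0.1, 0.35, 0.65, 0.9])
        gin = compute_u(np.arange(4.0), lambda x: v)
        assert np.allclose(gin.u_values + gin.u_values[::-1], 1.0, atol=1e-12)

    def test_clamping_warns(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            gin = compute_u(np.array([1.0, 2.0, 3.0]), lambda x: np.array([0.0, 0.5, 1.0]))
        assert np.all((gin.cdf_values > 0) & (gin.cdf_values < 1))

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            compute_u(np.array([1.0]), lambda x: np.array([0.5]))

    def test_degenerate_equal_v_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_u(np.array([1.0, 2.0]), lambda x: np.array([0.5, 0.5]))


class TestCramerVonMises:
    def test_null_spacing_gives_minimum(self):
        # u_i = (2i-1)/(2n) zeroes the sum, leaving W^2 = 1/(12n)
        n = 5
        u = (2 * np.arange(1, n + 1) - 1) / (2 * n)
        W2, W_star = cramer_von_mises(u)
        assert W2 == pytest.approx(1.0 / 60.0, abs=1e-15)
        assert W_star == pytest.approx(1.1 / 60.0, abs=1e-15)

    def test_lower_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = rng.uniform(size=rng.integers(2, 30))
            W2, _ = cramer_von_mises(u)
            assert W2 >= 1.0 / (12.0 * u.size) - 1e-15

    def test_matches_empirical_process_integral(self):
        # Eq-style sum equals the brute-force integral of the empirical
        # process, for 100 random small samples
        rng = np.random.default_rng(12345)
        for _ in range(100):
            u = rng.uniform(size=int(rng.integers(2, 11)))
            W2, _ = cramer_von_mises(u)
            assert W2 == pytest.approx(w2_bruteforce(u), abs=1e-10)


class TestAndersonDarling:
    def test_single_point_closed_form(self):
        A2, A_star = anderson_darling(np.array([0.5]))
        assert A2 == pytest.approx(-1.0 - 2.0 * np.log(0.5), rel=1e-12)
        assert A2 == pytest.approx(0.3862944, abs=1e-6)
        assert A_star == pytest.approx(A2 * 4.0, rel=1e-12)

    def test_reflection_symmetry(self):
        rng = np.random.default_rng(4)
        u = np.sort(rng.uniform(size=15))
        A2, _ = anderson_darling(u)
        A2_reflected, _ = anderson_darling(1.0 - u)
        assert A2 == pytest.approx(A2_reflected, rel=1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            anderson_darling(np.array([0.0, 0.5]))


class TestInformationCriteria:
    def test_flood_quartet(self):
        ic = information_criteria(-16.35941, k=4, n=20)
        assert ic.aic == pytest.approx(-24.71882, abs=1e-4)
        assert ic.caic == pytest.approx(-22.05215, abs=1e-4)
        assert ic.bic == pytest.approx(-20.73589, abs=1e-4)
        assert ic.hqic == pytest.approx(-23.94131, abs=1e-4)

    def test_carbon_quartet(self):
        ic = information_criteria(141.332, k=3, n=100)
        assert ic.aic == pytest.approx(288.664, abs=1e-3)
        assert ic.caic == pytest.approx(288.914, abs=1e-3)
        assert ic.bic == pytest.approx(296.4796, abs=1e-3)
        assert ic.hqic == pytest.approx(291.8272, abs=1e-3)

    def test_zero_parameters(self):
        assert information_criteria(0.0, k=0, n=10).aic == 0.0

    @pytest.mark.parametrize("k,n", [(4, 20), (3, 100), (2, 7)])
    def test_caic_aic_gap_identity(self, k, n):
        ic = information_criteria(-5.0, k=k, n=n)
        assert ic.caic - ic.aic == pytest.approx(
            2.0 * k * (k + 1.0) / (n - k - 1.0), rel=1e-12
        )

    def test_caic_undefined_small_n(self):
        with pytest.warns(RuntimeWarning):
            ic = information_criteria(1.0, k=4, n=5)
        assert np.isnan(ic.caic)
        assert np.isfinite(ic.aic)


class TestKsTest:
    def test_midpoint_spacing_statistic(self):
        # v_(i) = (i - 0.5)/n for all i gives D = 0.5/n
        n = 8
        data = np.arange(1.0, n + 1)
        D, _ = ks_test(data, lambda x: (x - 0.5) / n)
        assert D == pytest.approx(0.5 / n, abs=1e-12)

    def test_true_cdf_large_sample(self):
        rng = np.random.default_rng(2)
        data = rng.exponential(size=5000)
        D, p = ks_test(data, stats.expon.cdf)
        assert D < 0.05
        assert 0.0 <= p <= 1.0

    def test_ties_warn(self):
        with pytest.warns(RuntimeWarning, match="ties"):
            ks_test(np.array([1.0, 1.0, 2.0]), stats.expon.cdf)


class TestStandardErrors:
    def test_unit_curvature(self):
        se = standard_errors(lambda th: 0.5 * float(th[0] ** 2), np.array([0.0]))
        assert se[0] == pytest.approx(1.0, rel=1e-4)

    def test_diagonal_quadratic(self):
        f = lambda th: 2.0 * float(np.sum(np.asarray(th) ** 2))
        se = standard_errors(f, np.array([0.3, -0.2, 1.0]))
        assert np.allclose(se, 0.5, rtol=1e-4)

    def test_hessian_cross_terms(self):
        f = lambda th: float(th[0] ** 2 + 3.0 * th[0] * th[1] + 2.0 * th[1] ** 2)
        H = numerical_hessian(f, np.array([0.5, 0.5]))
        assert np.allclose(H, [[2.0, 3.0], [3.0, 4.0]], atol=1e-4)

    def test_indefinite_hessian_flagged(self):
        f = lambda th: float(th[0] ** 2 - th[1] ** 2)
        with pytest.warns(RuntimeWarning):
            se = standard_errors(f, np.array([0.0, 0.0]))
        assert np.isnan(se[1])


@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_statistics_invariant_to_units(scale, seed):
    """W* and A* depend only on v_i = F(x_i), so rescaling data and cdf
    together changes nothing."""
    rng = np.random.default_rng(seed)
    data = rng.exponential(size=12) + 0.01
    base_cdf = stats.expon.cdf
    gin1 = compute_u(data, base_cdf)
    gin2 = compute_u(scale * data, lambda x: base_cdf(x / scale))
    assert cramer_von_mises(gin1.u_values)[1] == pytest.approx(
        cramer_von_mises(gin2.u_values)[1], rel=1e-9
    )
    assert anderson_darling(gin1.u_values)[1] == pytest.approx(
        anderson_darling(gin2.u_values)[1], rel=1e-9
    )
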