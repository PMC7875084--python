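"""Wishart core: SPD validation, multivariate gamma, log-density, sampling.

The density implementation is checked three independent ways: against
closed univariate forms (chi-squared / gamma), against a naive
term-by-term implementation with explicit inverses and determinants,
and against scipy.stats.wishart.
"""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from wisdom.exceptions import (
    AsymmetricError,
    DegreesOfFreedomError,
    DimensionMismatchError,
    DomainError,
    NonSquareError,
    NotPositiveDefiniteError,
    SingularScaleError,
)
from wisdom.wishart import (
    WishartParams,
    log_multivariate_gamma,
    sample_wishart,
    validate_spd,
    wishart_log_pdf,
)

from conftest import random_spd


def naive_wishart_log_pdf(m: np.ndarray, n: int, sigma: np.ndarray) -> float:
    """Independent oracle: explicit inverse, explicit determinant,
    product-form multivariate gamma."""
    p = m.shape[0]
    log_gamma_p = p * (p - 1) / 4.0 * np.log(np.pi) + sum(
        gammaln((n / 2.0) + (1 - i) / 2.0) for i in range(1, p + 1)
    )
    return (
        -(n * p / 2.0) * np.log(2.0)
        - log_gamma_p
        - (n / 2.0) * np.log(np.linalg.det(sigma))
        + ((n - p - 1) / 2.0) * np.log(np.linalg.det(m))
        - 0.5 * np.trace(np.linalg.inv(sigma) @ m)
    )


class TestValidateSpd:
    def test_identity_is_valid(self):
        spd = validate_spd(np.eye(2))
        assert spd.p == 2
        assert spd.is_correlation
        np.testing.assert_allclose(spd.values, np.eye(2))

    def test_indefinite_matrix_rejected(self):
        with pytest.raises(NotPositiveDefiniteError):
            validate_spd(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_near_symmetric_is_symmetrized(self):
        a = np.array([[1.0, 0.5], [0.49999999, 1.0]])
        spd = validate_spd(a, sym_tol=1e-6)
        np.testing.assert_allclose(spd.values, spd.values.T)
        assert spd.values[0, 1] == pytest.approx(0.499999995)

    def test_gross_asymmetry_rejected(self):
        with pytest.raises(AsymmetricError):
            validate_spd(np.array([[1.0, 0.9], [0.1, 1.0]]))

    def test_non_square_rejected(self):
        with pytest.raises(NonSquareError):
            validate_spd(np.ones((2, 3)))

    def test_ridge_rescues_singular_matrix(self):
        singular = np.ones((2, 2))  # rank one
        with pytest.raises(NotPositiveDefiniteError):
            validate_spd(singular)
        spd = validate_spd(singular, ridge=1e-6)
        assert spd.p == 2

    def test_cached_cholesky_reconstructs(self, rng):
        a = random_spd(rng, 4)
        spd = validate_spd(a)
        np.testing.assert_allclose(spd.chol @ spd.chol.T, spd.values, atol=1e-12)


class TestLogMultivariateGamma:
    def test_p1_is_univariate(self):
        assert log_multivariate_gamma(1, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert log_multivariate_gamma(1, 5.5) == pytest.approx(gammaln(5.5))

    def test_p2_closed_form(self):
        # Gamma_2(2) = pi^{1/2} * Gamma(2) * Gamma(3/2), expanded by hand
        expected = 0.5 * np.log(np.pi) + np.log(np.sqrt(np.pi) / 2.0)
        assert log_multivariate_gamma(2, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_p3_matches_product_oracle(self):
        a = 5.0
        expected = 3 * 2 / 4.0 * np.log(np.pi) + sum(
            gammaln((2 * a + 1 - i) / 2.0) for i in (1, 2, 3)
        )
        assert log_multivariate_gamma(3, a) == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            log_multivariate_gamma(4, 1.0)  # 2a+1-p = -1


class TestWishartLogPdf:
    def test_p1_equals_chi_squared(self):
        params = WishartParams(scale=validate_spd(np.array([[1.0]])), dof=3)
        got = wishart_log_pdf(np.array([[1.0]]), params)
        assert got == pytest.approx(stats.chi2(3).logpdf(1.0), abs=1e-12)

    @pytest.mark.parametrize("n", range(2, 11))
    @pytest.mark.parametrize("s2", [0.5, 1.0, 2.0])
    def test_p1_equals_gamma_density(self, n, s2):
        """W_1(n, sigma^2) is gamma(shape n/2, scale 2 sigma^2)."""
        params = WishartParams(scale=validate_spd(np.array([[s2]])), dof=n)
        xs = np.linspace(0.1, 20.0, 20)
        ours = np.array([wishart_log_pdf(np.array([[x]]), params) for x in xs])
        ref = stats.gamma(a=n / 2.0, scale=2.0 * s2).logpdf(xs)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_non_spd_gives_neg_inf(self):
        params = WishartParams(scale=validate_spd(np.eye(2)), dof=5)
        assert wishart_log_pdf(np.array([[1.0, 2.0], [2.0, 1.0]]), params) == -np.inf

    def test_p2_identity_direct_substitution(self):
        # -(np/2)log2 - logGamma_2(5/2) + 0 + 0 - (1/2)tr(I) with n=5, p=2
        params = WishartParams(scale=validate_spd(np.eye(2)), dof=5)
        expected = -5.0 * np.log(2.0) - log_multivariate_gamma(2, 2.5) - 1.0
        assert wishart_log_pdf(np.eye(2), params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 5])
    def test_matches_naive_oracle(self, p, rng):
        for _ in range(17):
            m = random_spd(rng, p)
            sigma = random_spd(rng, p)
            n = p + int(rng.integers(0, 20))
            params = WishartParams(scale=validate_spd(sigma), dof=n)
            got = wishart_log_pdf(m, params)
            want = naive_wishart_log_pdf(m, n, sigma)
            assert got == pytest.approx(want, rel=1e-9)

    def test_matches_scipy(self, rng):
        m = random_spd(rng, 4)
        sigma = random_spd(rng, 4)
        params = WishartParams(scale=validate_spd(sigma), dof=9)
        ref = stats.wishart(df=9, scale=sigma).logpdf(m)
        assert wishart_log_pdf(m, params) == pytest.approx(ref, rel=1e-9)

    def test_normalization_p1(self):
        for n in (2, 5, 10):
            params = WishartParams(scale=validate_spd(np.array([[1.0]])), dof=n)
            total, _ = integrate.quad(
                lambda x: np.exp(wishart_log_pdf(np.array([[x]]), params)),
                0.0, np.inf, limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_equivariance(self, c, rng):
        """log f(cM, n, cSigma) - log f(M, n, Sigma) equals the analytic
        Jacobian term ((n-p-1)/2 - n/2) * p * log c."""
        p, n = 3, 8
        m = random_spd(rng, p)
        sigma = random_spd(rng, p)
        base = wishart_log_pdf(m, WishartParams(scale=validate_spd(sigma), dof=n))
        scaled = wishart_log_pdf(
            c * m, WishartParams(scale=validate_spd(c * sigma), dof=n)
        )
        expected = ((n - p - 1) / 2.0 - n / 2.0) * p * np.log(c)
        assert scaled - base == pytest.approx(expected, rel=1e-9)

    def test_dimension_mismatch(self):
        params = WishartParams(scale=validate_spd(np.eye(3)), dof=5)
        with pytest.raises(DimensionMismatchError):
            wishart_log_pdf(np.eye(2), params)

    def test_dof_below_p_rejected(self):
        with pytest.raises(DegreesOfFreedomError):
            WishartParams(scale=validate_spd(np.eye(3)), dof=2)

    def test_non_integer_dof_rejected(self):
        with pytest.raises(DegreesOfFreedomError):
            WishartParams(scale=validate_spd(np.eye(2)), dof=2.5)

    def test_singular_scale_from_arrays(self):
        with pytest.raises(SingularScaleError):
            WishartParams.from_arrays(np.ones((2, 2)), dof=5)


class TestSampleWishart:
    def test_zero_draws(self):
        params = WishartParams(scale=validate_spd(np.eye(2)), dof=5)
        assert sample_wishart(params, 0, seed=0) == []

    def test_mean_matches_n_sigma(self):
        """E(M) = n * Sigma, within 3 Monte-Carlo standard errors."""
        params = WishartParams(scale=validate_spd(np.eye(2)), dof=10)
        draws = sample_wishart(params, 20_000, seed=1)
        stack = np.stack([d.values for d in draws])
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - 10.0 * np.eye(2)) <= 3.0 * se)

    def test_scalar_mean(self):
        params = WishartParams(scale=validate_spd(np.array([[2.0]])), dof=4)
        draws = sample_wishart(params, 50_000, seed=2)
        vals = np.array([d.values[0, 0] for d in draws])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(8.0, abs=3.0 * se)

    def test_draws_are_spd_and_reproducible(self):
        params = WishartParams(scale=validate_spd(np.eye(3)), dof=6)
        a = sample_wishart(params, 5, seed=3)
        b = sample_wishart(params, 5, seed=3)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.values, db.values)
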