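"""Core distribution functions: cdf/pdf/quantile/generation and their identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import naptplx as nx
from naptplx import ParameterVector

from conftest import integrate_pdf, random_valid_params


class TestBaselinePowerLomax:
    def test_cdf_anchors(self):
        p = ParameterVector(theta=2.0695, beta=1.4277, lam=34.858, alpha=1.0)
        assert nx.plx_cdf(0.0, p) == 0.0
        # at x**beta = lam the cdf is 1 - 2**(-theta)
        x = p.lam ** (1.0 / p.beta)
        assert nx.plx_cdf(x, p) == pytest.approx(1.0 - 2.0 ** (-p.theta), rel=1e-12)
        grid = np.linspace(0.0, 50.0, 200)
        assert np.all(np.diff(nx.plx_cdf(grid, p)) >= 0)

    def test_pdf_integrates_to_cdf(self):
        p = ParameterVector(theta=2.0695, beta=1.4277, lam=34.858, alpha=1.0)
        for x in (0.5, 3.0, 12.0):
            q, _ = integrate.quad(lambda t: nx.plx_pdf(t, p), 0, x)
            assert q == pytest.approx(nx.plx_cdf(x, p), abs=1e-8)

    def test_pdf_normalizes(self):
        p = ParameterVector(theta=2.0695, beta=1.4277, lam=34.858, alpha=1.0)
        q, _ = integrate.quad(lambda t: nx.plx_pdf(t, p), 0, np.inf, limit=200)
        assert q == pytest.approx(1.0, abs=1e-8)

    def test_negative_x_rejected(self):
        p = ParameterVector(theta=1.0, beta=1.0, lam=1.0)
        with pytest.raises(ValueError):
            nx.plx_cdf(-0.5, p)


class TestTransformedCdf:
    def test_median_anchor(self):
        p = ParameterVector(theta=0.5, beta=0.5, lam=0.5, alpha=0.5)
        assert nx.cdf(0.302408, p) == pytest.approx(0.5, abs=1e-6)

    def test_limits_and_monotonicity(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        assert nx.cdf(0.0, p) == 0.0
        assert nx.cdf(1e9, p) == pytest.approx(1.0, abs=1e-10)
        grid = np.linspace(0, 10, 500)
        assert np.all(np.diff(nx.cdf(grid, p)) >= 0)

    def test_alpha_one_reduces_to_baseline(self):
        p = ParameterVector(theta=1.4, beta=2.1, lam=3.0, alpha=1.0)
        grid = np.linspace(0.01, 8, 50)
        np.testing.assert_allclose(nx.cdf(grid, p), nx.plx_cdf(grid, p), rtol=0, atol=0)
        np.testing.assert_allclose(nx.pdf(grid, p), nx.plx_pdf(grid, p), rtol=0, atol=0)
        np.testing.assert_allclose(
            nx.quantile(np.array([0.2, 0.5, 0.9]), p), nx.plx_quantile(np.array([0.2, 0.5, 0.9]), p)
        )

    def test_cdf_nonincreasing_in_alpha(self):
        """dF/dalpha = G(G-1)alpha**(G-2) <= 0, so F falls and quantiles rise with alpha."""
        base = dict(theta=1.5, beta=3.0, lam=5.0)
        alphas = [0.5, 1.0, 1.5, 2.5, 10.0, 100.0]
        grid = np.linspace(0.1, 6, 40)
        F = np.array([nx.cdf(grid, ParameterVector(alpha=a, **base)) for a in alphas])
        assert np.all(np.diff(F, axis=0) <= 1e-12)
        q = np.array([nx.quantile(0.5, ParameterVector(alpha=a, **base)) for a in alphas])
        assert np.all(np.diff(q) >= -1e-12)

    def test_cdf_agrees_with_pdf_quadrature(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        for x in (0.5, 1.5, 3.0):
            q, _ = integrate.quad(lambda t: nx.pdf(t, p), 0, x)
            assert q == pytest.approx(nx.cdf(x, p), abs=1e-8)

    def test_cdf_derivative_matches_pdf(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        h = 1e-6
        for x in (0.4, 1.0, 2.2, 4.0):
            fd = (nx.cdf(x + h, p) - nx.cdf(x - h, p)) / (2 * h)
            assert fd == pytest.approx(nx.pdf(x, p), rel=1e-6)


class TestPdf:
    @pytest.mark.parametrize(
        "p",
        [
            ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5),
            ParameterVector(theta=2.0695, beta=1.4277, lam=34.858, alpha=1.0),
            ParameterVector(theta=0.8781, beta=2.8773, lam=60.317, alpha=1564.3),
        ],
    )
    def test_normalization(self, p):
        med = nx.quantile(0.5, p)
        q1, _ = integrate.quad(lambda t: nx.pdf(t, p), 0, med, limit=200)
        q2, _ = integrate.quad(lambda t: nx.pdf(t, p), med, np.inf, limit=200)
        assert q1 + q2 == pytest.approx(1.0, abs=1e-8)

    def test_limit_at_origin_by_beta_regime(self):
        assert nx.pdf(0.0, ParameterVector(theta=2.0, beta=0.7, lam=1.0, alpha=2.0)) == math.inf
        p1 = ParameterVector(theta=2.0, beta=1.0, lam=3.0, alpha=2.0)
        assert nx.pdf(0.0, p1) == pytest.approx(p1.theta / (p1.lam * p1.alpha))
        assert nx.pdf(1e-9, p1) == pytest.approx(p1.theta / (p1.lam * p1.alpha), rel=1e-6)
        assert nx.pdf(0.0, ParameterVector(theta=2.0, beta=1.5, lam=1.0, alpha=2.0)) == 0.0

    def test_logpdf_safe_for_huge_alpha(self):
        p = ParameterVector(theta=0.8781, beta=2.8773, lam=60.317, alpha=1564.3)
        lp = nx.logpdf(np.array([4.1, 10.8, 39.2]), p)
        assert np.all(np.isfinite(lp))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_normalization_property_random_params(self, idx):
        """pdf integrates to one for any strictly valid parameter vector."""
        r = np.random.default_rng(idx)
        (p,) = random_valid_params(r, 1)
        assert integrate_pdf(p) == pytest.approx(1.0, abs=1e-7)


class TestSeriesPdf:
    def test_converges_to_closed_form(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        assert nx.series_pdf(1.0, p, K=40) == pytest.approx(nx.pdf(1.0, p), abs=1e-10)

    def test_k0_alpha1_is_baseline_exactly(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.0)
        x = np.array([0.3, 1.0, 2.5])
        np.testing.assert_array_equal(nx.series_pdf(x, p, K=0), nx.plx_pdf(x, p))

    def test_partial_sums_alternate_for_alpha_above_one(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=3.0)
        x = 0.8
        limit = nx.pdf(x, p)
        signs = [np.sign(nx.series_pdf(x, p, K=k) - limit) for k in range(6)]
        assert all(signs[i] != signs[i + 1] for i in range(5))

    def test_negative_truncation_rejected(self):
        p = ParameterVector(theta=1.0, beta=1.0, lam=1.0, alpha=2.0)
        with pytest.raises(ValueError):
            nx.series_pdf(1.0, p, K=-1)


class TestReliabilityFunctions:
    def test_pointwise_identities(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        grid = np.linspace(0.05, 6.0, 60)
        S, F, f = nx.survival(grid, p), nx.cdf(grid, p), nx.pdf(grid, p)
        np.testing.assert_allclose(S + F, 1.0, atol=1e-14)
        np.testing.assert_allclose(nx.cumulative_hazard(grid, p), -np.log(S), atol=1e-10)
        np.testing.assert_allclose(nx.hazard(grid, p) * S, f, atol=1e-10)
        np.testing.assert_allclose(nx.reverse_hazard(grid, p) * F, f, atol=1e-10)

    def test_hazard_shape_by_beta(self):
        # beta < 1: L-shaped, monotone decreasing
        p = ParameterVector(theta=1.5, beta=0.6, lam=2.0, alpha=1.5)
        grid = np.linspace(0.05, 10, 100)
        assert np.all(np.diff(nx.hazard(grid, p)) < 0)
        # beta > 1: starts from zero at the origin
        p2 = ParameterVector(theta=1.5, beta=2.0, lam=2.0, alpha=1.5)
        assert nx.hazard(1e-8, p2) < 1e-6

    def test_reverse_hazard_flagged_at_origin(self):
        p = ParameterVector(theta=1.5, beta=2.0, lam=2.0, alpha=1.5)
        assert nx.reverse_hazard(0.0, p) == math.inf


class TestQuantile:
    @pytest.mark.parametrize(
        "params,prob,expected",
        [
            ((0.5, 0.5, 0.5, 0.5), 0.25, 0.029628),
            ((0.5, 0.5, 0.5, 0.5), 0.50, 0.302408),
            ((0.5, 0.5, 0.5, 0.5), 0.75, 3.810631),
            ((1.0, 2.0, 0.5, 20.0), 0.50, 1.565673),
        ],
    )
    def test_published_quartiles(self, params, prob, expected):
        th, be, lam, al = params
        p = ParameterVector(theta=th, beta=be, lam=lam, alpha=al)
        assert nx.quantile(prob, p) == pytest.approx(expected, abs=1e-4)

    def test_roundtrip(self):
        for p in (
            ParameterVector(theta=0.5, beta=0.5, lam=0.5, alpha=0.5),
            ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5),
            ParameterVector(theta=0.8781, beta=2.8773, lam=60.317, alpha=1564.3),
        ):
            probs = np.linspace(0.001, 0.999, 21)
            back = nx.cdf(nx.quantile(probs, p), p)
            np.testing.assert_allclose(back, probs, atol=1e-9)

    def test_small_prob_limit(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        assert nx.quantile(1e-12, p) < 1e-3

    def test_domain_errors(self):
        p = ParameterVector(theta=1.0, beta=1.0, lam=1.0, alpha=2.0)
        with pytest.raises(ValueError):
            nx.quantile(0.0, p)
        with pytest.raises(ValueError):
            nx.quantile(1.0, p)
        with pytest.raises(nx.InvalidFamilyError):
            nx.quantile(0.5, ParameterVector(theta=1.0, beta=1.0, lam=1.0, alpha=0.2))


class TestRandomSample:
    def test_distributional_ks(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        x = nx.random_sample(5000, p, seed=7)
        d = stats.kstest(x, lambda t: nx.cdf(t, p)).statistic
        assert d < 1.36 / math.sqrt(5000)

    def test_mean_matches_theory(self, p_std):
        x = nx.random_sample(10_000, p_std, seed=11)
        mean, sd = 1.76758, 0.96342
        assert abs(x.mean() - mean) < 3 * sd / math.sqrt(10_000)

    def test_reproducible_and_errors(self):
        p = ParameterVector(theta=1.5, beta=3.0, lam=5.0, alpha=1.5)
        np.testing.assert_array_equal(nx.random_sample(50, p, seed=3), nx.random_sample(50, p, seed=3))
        with pytest.raises(ValueError):
            nx.random_sample(0, p, seed=3)
        with pytest.raises(nx.InvalidFamilyError):
            nx.random_sample(5, ParameterVector(theta=0.5, beta=0.5, lam=0.1, alpha=0.1), seed=3)
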