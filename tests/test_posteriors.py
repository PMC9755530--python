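"""Truncated-normal surrogate posterior: constraint transform, densities,
analytic moments, and reparameterized sampling."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from varmerge import autodiff as ad
from varmerge.posteriors import (AmplitudePosterior, constrain,
                                 constrain_inverse, tn_log_density,
                                 tn_moments, tn_rsample, tn_rsample_t)


class TestConstraint:
    def test_exp_and_softplus_reference_points(self):
        assert constrain(0.0, "exp") == pytest.approx(1.0)
        assert constrain(0.0, "softplus") == pytest.approx(math.log(2.0))

    @pytest.mark.parametrize("transform", ["exp", "softplus"])
    def test_monotone_positive_and_invertible(self, transform):
        rng = np.random.default_rng(0)
        raw = np.sort(rng.normal(scale=3.0, size=100))
        out = constrain(raw, transform)
        assert np.all(out > 0)
        assert np.all(np.diff(out) > 0)
        np.testing.assert_allclose(
            constrain_inverse(out, transform), raw, rtol=1e-9, atol=1e-9)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            constrain(0.0, "sigmoid")


class TestLogDensity:
    def test_unconstrained_normal_limit(self):
        # loc far above the truncation point: plain normal value at mode
        val = tn_log_density(10.0, 10.0, 1.0)
        assert val == pytest.approx(-0.5 * math.log(2.0 * math.pi), abs=1e-6)

    def test_negative_argument_outside_support(self):
        assert tn_log_density(-1.0, 0.5, 1.0) == -np.inf

    @pytest.mark.parametrize("loc,scale", [(0.5, 1.0), (2.0, 0.5), (-1.0, 1.0)])
    def test_normalizes_to_one(self, loc, scale):
        val, _ = integrate.quad(
            lambda F: np.exp(tn_log_density(F, loc, scale)), 0.0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestMoments:
    def test_unconstrained_normal_closed_forms(self):
        mean, var, m4 = tn_moments(20.0, 1.0)
        assert mean == pytest.approx(20.0, rel=1e-6)
        assert var == pytest.approx(1.0, rel=1e-6)
        assert m4 == pytest.approx(20.0 ** 4 + 6 * 20.0 ** 2 + 3.0, rel=1e-6)

    def test_halfnormal_limit(self):
        mean, var, _ = tn_moments(0.0, 1.0)
        assert mean == pytest.approx(math.sqrt(2.0 / math.pi))
        assert var == pytest.approx(1.0 - 2.0 / math.pi)

    def test_matches_quadrature_over_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            loc = rng.uniform(-2.0, 4.0)
            scale = rng.uniform(0.2, 2.0)
            mean, var, m4 = tn_moments(loc, scale)
            Z = stats.norm.cdf(loc / scale)
            pdf = lambda x: stats.norm.pdf(x, loc, scale) / Z
            hi = loc + 40 * scale
            q1 = integrate.quad(lambda x: x * pdf(x), 0, hi)[0]
            q2 = integrate.quad(lambda x: x * x * pdf(x), 0, hi)[0]
            q4 = integrate.quad(lambda x: x ** 4 * pdf(x), 0, hi)[0]
            assert mean == pytest.approx(q1, rel=1e-8)
            assert var == pytest.approx(q2 - q1 ** 2, rel=1e-7)
            assert m4 == pytest.approx(q4, rel=1e-8)

    def test_cross_check_against_scipy_truncnorm(self):
        loc, scale = 1.3, 0.8
        a = (0.0 - loc) / scale
        ref = stats.truncnorm(a, np.inf, loc=loc, scale=scale)
        mean, var, m4 = tn_moments(loc, scale)
        assert mean == pytest.approx(ref.mean(), rel=1e-10)
        assert var == pytest.approx(ref.var(), rel=1e-10)
        assert m4 == pytest.approx(ref.moment(4), rel=1e-8)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            tn_moments(1.0, 0.0)


class TestRsample:
    def test_degenerate_scale_collapses_to_loc(self):
        s = tn_rsample(np.full(100, 5.0), np.full(100, 1e-6), seed=0)
        np.testing.assert_allclose(s, 5.0, atol=1e-4)

    def test_empirical_mean_matches_analytic(self):
        loc, scale = 1.0, 1.0
        s = tn_rsample(np.full(100_000, loc), np.full(100_000, scale), seed=1)
        mean, var, _ = tn_moments(loc, scale)
        se = math.sqrt(var / len(s))
        assert abs(s.mean() - mean) < 3 * se
        assert np.all(s > 0)

    def test_same_seed_reproduces(self):
        a = tn_rsample(np.ones(5), np.ones(5), seed=3)
        b = tn_rsample(np.ones(5), np.ones(5), seed=3)
        np.testing.assert_array_equal(a, b)

    def test_pathwise_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(size=2000)
        loc0, scale0 = 0.8, 0.6

        def mean_at(l, s):
            from varmerge.posteriors import _tn_transform_np
            return _tn_transform_np(np.full_like(u, l), np.full_like(u, s),
                                    u).mean()

        loc = ad.Tensor(np.full_like(u, loc0), requires_grad=True)
        scale = ad.Tensor(np.full_like(u, scale0), requires_grad=True)
        ad.mul(ad.tsum(tn_rsample_t(loc, scale, u)), 1.0 / len(u)).backward()
        eps = 1e-5
        fd_loc = (mean_at(loc0 + eps, scale0) - mean_at(loc0 - eps, scale0)) / (2 * eps)
        fd_scale = (mean_at(loc0, scale0 + eps) - mean_at(loc0, scale0 - eps)) / (2 * eps)
        assert loc.grad.sum() == pytest.approx(fd_loc, abs=1e-3)
        assert scale.grad.sum() == pytest.approx(fd_scale, abs=1e-3)


class TestAmplitudePosterior:
    def test_initialization_is_wilson_anchored(self):
        rng = np.random.default_rng(2)
        mean_I = rng.uniform(0.1, 5.0, size=50)
        eps = np.ones(50)
        post = AmplitudePosterior.from_data(mean_I, epsilon=eps)
        loc = post.loc
        assert np.mean(loc ** 2 / eps) == pytest.approx(1.0, rel=1e-10)
        np.testing.assert_allclose(post.scale / loc, 0.1, rtol=1e-10)

    def test_kl_to_matched_centric_prior_is_near_zero(self):
        # the centric Wilson branch IS a zero-truncated normal, so a
        # surrogate with loc->0-, scale=sqrt(eps) matches it exactly and
        # the sampled KL estimate must vanish within Monte-Carlo error
        from varmerge.priors import WilsonPrior
        n = 10_000
        eps = 2.0
        post = AmplitudePosterior(
            np.full(n, -12.0), np.full(n, 0.5 * math.log(eps)), "exp")
        prior = WilsonPrior(np.full(n, eps), np.ones(n, dtype=bool))
        rng = np.random.default_rng(0)
        F = post.rsample_t(rng.uniform(size=n))
        kl_terms = post.log_prob_t(F).data - prior.log_prob_t(F).data
        se = kl_terms.std() / math.sqrt(n)
        assert abs(kl_terms.mean()) < max(3 * se, 1e-4)

    def test_kl_to_mismatched_prior_is_positive(self):
        from varmerge.priors import WilsonPrior
        n = 20_000
        post = AmplitudePosterior(np.full(n, 1.0), np.full(n, -1.0), "exp")
        prior = WilsonPrior(np.ones(n), np.zeros(n, dtype=bool))
        rng = np.random.default_rng(1)
        F = post.rsample_t(rng.uniform(size=n))
        kl = (post.log_prob_t(F).data - prior.log_prob_t(F).data).mean()
        assert kl > 0

    def test_interval_brackets_the_mean(self):
        post = AmplitudePosterior(np.log(np.array([1.0, 2.0])),
                                  np.log(np.array([0.2, 0.1])))
        lo, hi = post.interval(0.95)
        assert np.all(lo < post.mean) and np.all(post.mean < hi)
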