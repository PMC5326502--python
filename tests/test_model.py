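"""Unit and property tests for the beta-binomial allelic-imbalance model."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from asbcall.model import (
    ALT_BIASED,
    NO_ASB,
    REF_BIASED,
    ImproperPriorError,
    MCMCSettings,
    ModelHyperParams,
    SNPModelInput,
    betabin_logpmf,
    call_asb,
    dtheta_deta,
    hpd_interval,
    log_posterior_eta,
    log_prior_eta,
    mean_precision_to_shapes,
    prior_shapes,
    sample_posterior,
    sample_posterior_batch,
    theta_of_eta,
)
from conftest import brute_force_hpd, grid_posterior_summary

interior = st.floats(min_value=0.01, max_value=0.99)
# mu values keeping the prior proper at lambda=0.05 (mu*(1-mu) > 0.05)
feasible_mu = st.floats(min_value=0.1, max_value=0.9)


class TestShapes:
    @pytest.mark.parametrize(
        "theta,precision,expected",
        [(0.5, 1000, (500, 500)), (0.3, 1000, (300, 700))],
    )
    def test_mean_precision_reparameterization(self, theta, precision, expected):
        assert mean_precision_to_shapes(theta, precision) == pytest.approx(expected)

    def test_extreme_mean_keeps_shapes_positive(self):
        alpha, beta = mean_precision_to_shapes(0.999999, 1000)
        assert alpha == pytest.approx(1000, rel=1e-5)
        assert beta == pytest.approx(0.001, rel=1e-6)
        assert alpha > 0 and beta > 0

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.1, 1.1])
    def test_mean_outside_open_interval_rejected(self, theta):
        with pytest.raises(ValueError):
            mean_precision_to_shapes(theta, 1000)

    @given(theta=interior, precision=st.floats(min_value=1, max_value=1e4))
    def test_shapes_sum_to_precision(self, theta, precision):
        alpha, beta = mean_precision_to_shapes(theta, precision)
        assert alpha + beta == pytest.approx(precision)


class TestBetaBinomial:
    def test_empty_experiment_has_probability_one(self):
        assert betabin_logpmf(0, 0, 2.0, 5.0) == pytest.approx(0.0)

    def test_uniform_case(self):
        # BetaBin(.|d, 1, 1) is uniform over 0..d
        assert betabin_logpmf(3, 10, 1.0, 1.0) == pytest.approx(math.log(1 / 11))

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.5), (1, 1), (2, 5), (500, 500)])
    def test_pmf_normalizes(self, alpha, beta):
        d = 25
        total = sum(math.exp(betabin_logpmf(a, d, alpha, beta)) for a in range(d + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_betabinom(self):
        # independent cross-check of the log-gamma arithmetic
        for d in (1, 7, 40):
            for alpha, beta in ((0.5, 3.0), (2.0, 5.0), (500.0, 500.0)):
                a = np.arange(d + 1)
                ours = betabin_logpmf(a, d, alpha, beta)
                ref = scipy.stats.betabinom.logpmf(a, d, alpha, beta)
                np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("a,d", [(-1, 5), (6, 5)])
    def test_invalid_counts_rejected(self, a, d):
        with pytest.raises(ValueError):
            betabin_logpmf(a, d, 1.0, 1.0)


class TestPriorShapes:
    def test_balanced_prior_is_beta_2_2(self):
        assert prior_shapes(0.5, 0.05) == pytest.approx((2.0, 2.0))

    def test_variance_at_bernoulli_bound_rejected(self):
        with pytest.raises(ImproperPriorError):
            prior_shapes(0.5, 0.25)

    @given(mu=interior, lam=st.floats(min_value=1e-4, max_value=0.009))
    def test_moment_identities(self, mu, lam):
        alpha0, beta0 = prior_shapes(mu, lam)
        mean = alpha0 / (alpha0 + beta0)
        var = alpha0 * beta0 / ((alpha0 + beta0) ** 2 * (alpha0 + beta0 + 1))
        assert mean == pytest.approx(mu, abs=1e-12)
        assert var == pytest.approx(lam, abs=1e-12)


class TestReparameterization:
    @pytest.mark.parametrize(
        "eta,rho,expected",
        [
            (0.5, 0.5, 0.5),  # balanced diploid, no imbalance
            (0.3, 1.0, 1.0),  # LOH of the alternative allele
            (0.5, 0.3, 0.3),  # theta(0.5, rho) = rho
            (0.8, 0.5, 0.8),  # theta(eta, 0.5) = eta
        ],
    )
    def test_theta_examples(self, eta, rho, expected):
        assert theta_of_eta(eta, rho) == pytest.approx(expected)

    @given(eta=interior, rho=interior)
    def test_reflection_symmetry(self, eta, rho):
        assert theta_of_eta(1 - eta, 1 - rho) == pytest.approx(
            1 - theta_of_eta(eta, rho), abs=1e-12
        )

    def test_jacobian_is_one_at_balanced_raf(self):
        assert dtheta_deta(0.7, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("eta,rho", [(0.3, 0.1), (0.5, 0.9), (0.9, 0.2)])
    def test_jacobian_matches_finite_difference(self, eta, rho):
        h = 1e-6
        fd = (theta_of_eta(eta + h, rho) - theta_of_eta(eta - h, rho)) / (2 * h)
        assert dtheta_deta(eta, rho) == pytest.approx(fd, abs=1e-6)

    @given(eta=interior, rho=interior)
    def test_jacobian_positive(self, eta, rho):
        assert dtheta_deta(eta, rho) > 0


class TestPriorOverEta:
    def test_balanced_case_reduces_to_beta(self):
        # at rho=0.5 and mu=0.5: theta = eta, Jacobian = 1, prior = Beta(2,2)
        eta = np.linspace(0.05, 0.95, 19)
        ours = log_prior_eta(eta, 0.5, 0.5, 0.05)
        ref = scipy.stats.beta.logpdf(eta, 2, 2)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("mu", [0.1, 0.5, 0.9])
    def test_density_normalizes(self, rho, mu):
        # the induced prior can carry algebraic singularities at 0 and 1
        # (Beta shapes < 1), so integrate with quad's weighted endpoint rule
        lam = 0.05
        alpha0, beta0 = prior_shapes(mu, lam)

        def left(e):
            e = min(max(e, 1e-12), 1 - 1e-12)
            return math.exp(log_prior_eta(e, rho, mu, lam) - (alpha0 - 1) * math.log(e))

        def right(e):
            e = min(max(e, 1e-12), 1 - 1e-12)
            return math.exp(log_prior_eta(e, rho, mu, lam) - (beta0 - 1) * math.log1p(-e))

        with np.errstate(all="ignore"):
            i1, _ = scipy.integrate.quad(
                left, 0, 0.5, weight="alg", wvar=(alpha0 - 1, 0.0), limit=200
            )
            i2, _ = scipy.integrate.quad(
                right, 0.5, 1, weight="alg", wvar=(0.0, beta0 - 1), limit=200
            )
        assert i1 + i2 == pytest.approx(1.0, abs=1e-3)

    @given(eta=interior, rho=interior, mu=feasible_mu)
    def test_reflection_symmetry(self, eta, rho, mu):
        assert log_prior_eta(eta, rho, mu, 0.05) == pytest.approx(
            log_prior_eta(1 - eta, 1 - rho, 1 - mu, 0.05), abs=1e-9
        )


class TestPosterior:
    def test_no_samples_reduces_to_prior(self):
        snp = SNPModelInput(counts=(), rho=0.3, mu=0.55)
        for eta in (0.2, 0.5, 0.8):
            assert log_posterior_eta(eta, snp) == pytest.approx(
                log_prior_eta(eta, 0.3, 0.55, 0.05)
            )

    def test_balanced_single_sample_peaks_near_half(self):
        snp = SNPModelInput(counts=((5, 10),), rho=0.5, mu=0.5)
        eta = np.linspace(0, 1, 2001)[1:-1]
        lp = log_posterior_eta(eta, snp)
        assert abs(eta[np.argmax(lp)] - 0.5) < 0.01

    @given(
        a=st.integers(min_value=0, max_value=20),
        d=st.integers(min_value=0, max_value=20),
        eta=interior,
        rho=interior,
        mu=feasible_mu,
    )
    def test_reflection_symmetry(self, a, d, eta, rho, mu):
        a = min(a, d)
        snp = SNPModelInput(counts=((a, d),), rho=rho, mu=mu)
        mirrored = SNPModelInput(counts=((d - a, d),), rho=1 - rho, mu=1 - mu)
        assert log_posterior_eta(eta, snp) == pytest.approx(
            log_posterior_eta(1 - eta, mirrored), abs=1e-9
        )

    def test_rho_one_is_clamped_with_warning(self, caplog):
        snp = SNPModelInput(counts=((10, 10),), rho=1.0, mu=0.5)
        assert 0 < snp.rho < 1


class TestSampler:
    def test_trace_mean_matches_grid_oracle(self):
        snp = SNPModelInput(counts=((50, 100),) * 5, rho=0.5, mu=0.5)
        trace = sample_posterior(snp, mcmc=MCMCSettings(seed=11))
        mean, _ = grid_posterior_summary(snp)
        assert trace.mean() == pytest.approx(mean, abs=0.02)

    def test_saturated_counts_push_eta_high(self):
        snp = SNPModelInput(counts=((100, 100),) * 3, rho=0.5, mu=0.5)
        trace = sample_posterior(snp, mcmc=MCMCSettings(seed=3))
        assert trace.mean() > 0.9

    def test_seed_determinism_and_seed_independence_of_mean(self):
        snp = SNPModelInput(counts=((30, 60), (28, 61)), rho=0.5, mu=0.5)
        t1 = sample_posterior(snp, mcmc=MCMCSettings(seed=5))
        t2 = sample_posterior(snp, mcmc=MCMCSettings(seed=5))
        t3 = sample_posterior(snp, mcmc=MCMCSettings(seed=6))
        np.testing.assert_array_equal(t1, t2)
        assert t1.mean() == pytest.approx(t3.mean(), abs=0.03)

    def test_batch_agrees_with_scalar(self):
        a = np.array([[50, 48], [10, 12]], dtype=float)
        d = np.array([[100, 100], [40, 40]], dtype=float)
        traces, rates = sample_posterior_batch(
            a, d, rho=np.array([0.5, 0.3]), mu=np.array([0.5, 0.5]), mcmc=MCMCSettings(seed=2)
        )
        assert traces.shape == (2, 4000)
        assert np.all((rates > 0) & (rates <= 1))
        for k in range(2):
            snp = SNPModelInput(
                counts=tuple((int(x), int(y)) for x, y in zip(a[k], d[k])),
                rho=[0.5, 0.3][k],
                mu=0.5,
            )
            mean, _ = grid_posterior_summary(snp)
            assert traces[k].mean() == pytest.approx(mean, abs=0.03)

    def test_masked_cells_are_ignored(self):
        # a masked cell must not influence the chain: same seed, with and
        # without data planted in the masked position
        kw = dict(rho=np.array([0.5]), mu=np.array([0.5]), mcmc=MCMCSettings(seed=9))
        t_clean, _ = sample_posterior_batch(
            np.array([[50.0, 0.0]]), np.array([[100.0, 0.0]]),
            mask=np.array([[True, False]]), **kw,
        )
        t_garbage, _ = sample_posterior_batch(
            np.array([[50.0, 40.0]]), np.array([[100.0, 40.0]]),
            mask=np.array([[True, False]]), **kw,
        )
        np.testing.assert_array_equal(t_clean, t_garbage)


class TestHPD:
    def test_uniform_trace_width(self):
        trace = np.linspace(0, 1, 1000)
        lo, hi = hpd_interval(trace, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_constant_trace_degenerates(self):
        assert hpd_interval(np.full(200, 0.5), 0.95) == (0.5, 0.5)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(17)
        for trace in (
            rng.beta(2, 5, size=500),
            rng.normal(0.5, 0.1, size=301),
            np.concatenate([rng.beta(20, 5, 200), rng.beta(5, 20, 200)]),
        ):
            for mass in (0.5, 0.9, 0.95):
                assert hpd_interval(trace, mass) == brute_force_hpd(trace, mass)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.linspace(0, 1, 99), 0.95)


class TestCalling:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((0.62, 0.81), REF_BIASED),
            ((0.35, 0.55), NO_ASB),
            ((0.12, 0.38), ALT_BIASED),
            ((0.41, 0.59), NO_ASB),  # inside the zone
            ((0.45, 0.65), NO_ASB),  # straddles the upper edge
        ],
    )
    def test_zone_rule(self, interval, expected):
        assert call_asb(interval) == expected

    def test_methods_text_zone(self):
        # zone (0.5, 0.5): call whenever the interval excludes 0.5
        assert call_asb((0.51, 0.58), zone=(0.5, 0.5)) == REF_BIASED
        assert call_asb((0.42, 0.49), zone=(0.5, 0.5)) == ALT_BIASED
        assert call_asb((0.49, 0.51), zone=(0.5, 0.5)) == NO_ASB

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            ModelHyperParams(precision=-1)
        with pytest.raises(ValueError):
            ModelHyperParams(exclusion_zone=(0.6, 0.4))
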