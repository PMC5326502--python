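"""Beta-binomial Bayesian model of allelic imbalance at heterozygous SNPs.

The model targets the allelic balance ratio eta = Prob(binding | ref allele).
For a SNP covered by N samples with (ref count a_n, total count d_n), the
likelihood is beta-binomial with success probability

    theta(eta, rho) = eta*rho / (eta*rho + (1-eta)*(1-rho)),

where rho is the background reference-allele frequency (RAF; 0.5 in a
balanced diploid region, skewed under copy-number alteration).  The prior on
theta is a Beta with mean mu (the reference-mapping bias) and variance
lambda, transported to eta through the change of variables.  Inference is by
random-walk Metropolis-Hastings; calls are made from the shortest highest
posterior density (HPD) interval against an exclusion zone around 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "ModelHyperParams",
    "SNPModelInput",
    "MCMCSettings",
    "PosteriorResult",
    "REF_BIASED",
    "ALT_BIASED",
    "NO_ASB",
    "mean_precision_to_shapes",
    "betabin_logpmf",
    "prior_shapes",
    "theta_of_eta",
    "dtheta_deta",
    "log_prior_eta",
    "log_posterior_eta",
    "sample_posterior",
    "sample_posterior_batch",
    "hpd_interval",
    "call_asb",
    "fit_snp",
]

REF_BIASED = "REF_BIASED"
ALT_BIASED = "ALT_BIASED"
NO_ASB = "NO_ASB"

#: rho/mu values of exactly 0 or 1 are pulled inside (0,1) by this margin
#: before modeling; rho=1 makes eta unidentifiable (LOH limit).
INTERIOR_EPS = 1e-6


class ImproperPriorError(ValueError):
    """Raised when lambda >= mu*(1-mu), which yields non-positive Beta shapes."""


@dataclass(frozen=True)
class ModelHyperParams:
    """Hyperparameters of the beta-binomial model.

    precision
        Beta-binomial precision Lambda (= alpha + beta); larger means less
        overdispersion relative to the binomial.
    prior_variance
        Variance lambda of the Beta prior on theta; must satisfy
        lambda < mu*(1-mu) for every reference-mapping bias mu used.
    hpd_mass
        Posterior mass of the HPD credible interval.
    exclusion_zone
        (lo, hi) around 0.5; an ASB call requires the whole HPD interval to
        fall outside this zone.  (0.5, 0.5) reproduces the looser rule
        "interval does not contain 0.5".
    """

    precision: float = 1000.0
    prior_variance: float = 0.05
    hpd_mass: float = 0.95
    exclusion_zone: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"precision must be positive, got {self.precision}")
        if self.prior_variance <= 0:
            raise ValueError(f"prior_variance must be positive, got {self.prior_variance}")
        if not 0 < self.hpd_mass < 1:
            raise ValueError(f"hpd_mass must be in (0,1), got {self.hpd_mass}")
        lo, hi = self.exclusion_zone
        if not 0 < lo <= 0.5 <= hi < 1:
            raise ValueError(f"exclusion_zone must satisfy 0 < lo <= 0.5 <= hi < 1, got {self.exclusion_zone}")


@dataclass(frozen=True)
class MCMCSettings:
    """Random-walk Metropolis-Hastings settings (Gaussian proposal on eta)."""

    n_iter: int = 5000
    burn_in: int = 1000
    proposal_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")


def _clamp_interior(x: float, name: str) -> float:
    if x <= 0.0 or x >= 1.0:
        clamped = min(max(x, INTERIOR_EPS), 1.0 - INTERIOR_EPS)
        logger.warning("%s=%g outside (0,1); clamped to %g for modeling", name, x, clamped)
        return clamped
    return x


@dataclass(frozen=True)
class SNPModelInput:
    """Observed allelic counts and per-SNP bias parameters for one SNP.

    counts holds (a_n, d_n) pairs over the N samples covering the SNP after
    QC (missing samples already dropped); rho is the reference-allele
    frequency and mu the reference-mapping bias, both clamped to the open
    interval at construction.
    """

    counts: tuple[tuple[int, int], ...]
    rho: float
    mu: float
    snp_id: str = ""

    def __post_init__(self) -> None:
        for a, d in self.counts:
            if a < 0 or d < 0 or a > d:
                raise ValueError(f"invalid count pair (a={a}, d={d}); need 0 <= a <= d")
        object.__setattr__(self, "rho", _clamp_interior(float(self.rho), "rho"))
        object.__setattr__(self, "mu", _clamp_interior(float(self.mu), "mu"))

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    @property
    def pooled(self) -> tuple[int, int]:
        a = sum(c[0] for c in self.counts)
        d = sum(c[1] for c in self.counts)
        return a, d


@dataclass(frozen=True)
class PosteriorResult:
    """MCMC summary for one SNP: trace, HPD interval, posterior mean, call."""

    trace: np.ndarray
    hpd_lower: float
    hpd_upper: float
    point_estimate: float
    call: str
    acceptance_rate: float = float("nan")


def mean_precision_to_shapes(theta: float, precision: float) -> tuple[float, float]:
    """Convert (mean, precision) to Beta/beta-binomial shapes (alpha, beta).

    alpha = theta*Lambda, beta = (1-theta)*Lambda, so alpha + beta = Lambda.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError(f"theta must be in (0,1), got {theta}")
    if precision <= 0:
        raise ValueError(f"precision must be positive, got {precision}")
    return theta * precision, (1.0 - theta) * precision


def betabin_logpmf(a, d, alpha, beta):
    """Log pmf of the beta-binomial distribution, log BetaBin(a | d, alpha, beta).

    Computed with log-gamma arithmetic:
    log C(d, a) + log B(a + alpha, d - a + beta) - log B(alpha, beta).
    Broadcasts over array arguments; finite for all valid inputs.
    """
    a = np.asarray(a)
    d = np.asarray(d)
    if np.any(a < 0) or np.any(a > d):
        raise ValueError("require 0 <= a <= d")
    out = (
        gammaln(d + 1.0)
        - gammaln(a + 1.0)
        - gammaln(d - a + 1.0)
        + betaln(a + alpha, d - a + beta)
        - betaln(alpha, beta)
    )
    if out.ndim == 0:
        return float(out)
    return out


def prior_shapes(mu: float, prior_variance: float) -> tuple[float, float]:
    """Beta shapes (alpha0, beta0) with mean exactly mu and variance exactly lambda.

    alpha0 = ((1-mu)/lambda - 1/mu) * mu^2 and beta0 scaled to keep the mean;
    requires lambda < mu*(1-mu), otherwise the shapes are non-positive and the
    prior improper.
    """
    if not 0 < mu < 1:
        raise ValueError(f"mu must be in (0,1), got {mu}")
    if prior_variance >= mu * (1.0 - mu):
        raise ImproperPriorError(
            f"prior variance lambda={prior_variance} must be < mu*(1-mu)={mu * (1 - mu):.6g} (mu={mu})"
        )
    scale = (1.0 - mu) / prior_variance - 1.0 / mu
    return scale * mu * mu, scale * (mu - mu * mu)


def theta_of_eta(eta, rho):
    """Success probability theta as a function of allelic balance eta and RAF rho.

    theta = eta*rho / (eta*rho + (1-eta)*(1-rho)).  At rho=0.5, theta=eta;
    at rho=1 (LOH of the alternative allele), theta=1 for every eta.
    """
    eta = np.asarray(eta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    num = eta * rho
    den = num + (1.0 - eta) * (1.0 - rho)
    out = num / den
    if out.ndim == 0:
        return float(out)
    return out


def dtheta_deta(eta, rho):
    """Jacobian d theta / d eta of the change of variables; positive on (0,1)^2."""
    eta = np.asarray(eta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    den = eta * rho + (1.0 - eta) * (1.0 - rho)
    out = rho / den - eta * rho * (2.0 * rho - 1.0) / (den * den)
    if out.ndim == 0:
        return float(out)
    return out


def _log_beta_density(x, alpha0: float, beta0: float):
    return (alpha0 - 1.0) * np.log(x) + (beta0 - 1.0) * np.log1p(-x) - betaln(alpha0, beta0)


def log_prior_eta(eta, rho: float, mu: float, prior_variance: float):
    """Log prior density over eta induced by the Beta(mu, lambda) prior on theta.

    log Beta(theta(eta, rho) | alpha0, beta0) + log |d theta / d eta|.
    """
    alpha0, beta0 = prior_shapes(mu, prior_variance)
    theta = theta_of_eta(eta, rho)
    out = _log_beta_density(theta, alpha0, beta0) + np.log(dtheta_deta(eta, rho))
    if np.ndim(out) == 0:
        return float(out)
    return out


def log_posterior_eta(eta, snp: SNPModelInput, hp: ModelHyperParams = ModelHyperParams()):
    """Unnormalized log posterior of eta for one SNP (sum over samples + prior).

    eta may be a scalar or an array (evaluated pointwise, e.g. on a grid).
    With no samples, reduces to the prior alone.
    """
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    theta = np.atleast_1d(theta_of_eta(eta_arr, snp.rho))
    out = np.asarray(log_prior_eta(eta_arr, snp.rho, snp.mu, hp.prior_variance), dtype=float).copy()
    if snp.counts:
        a = np.array([c[0] for c in snp.counts], dtype=float)
        d = np.array([c[1] for c in snp.counts], dtype=float)
        alpha, beta = mean_precision_to_shapes(theta, hp.precision)
        ll = betabin_logpmf(a[None, :], d[None, :], alpha[:, None], beta[:, None])
        out = out + ll.sum(axis=1)
    if np.ndim(eta) == 0:
        return float(out[0])
    return out


def _batch_log_posterior(
    eta: np.ndarray,
    a: np.ndarray,
    d: np.ndarray,
    mask: np.ndarray,
    rho: np.ndarray,
    alpha0: np.ndarray,
    beta0: np.ndarray,
    log_choose: np.ndarray,
    precision: float,
) -> np.ndarray:
    """Vectorized log posterior for K independent SNPs at one eta value each.

    a, d, mask: (K, N) count matrices with mask marking observed cells;
    eta, rho, alpha0, beta0: (K,).  log_choose is the constant binomial
    coefficient term, precomputed once per data set.
    """
    theta = theta_of_eta(eta, rho)
    den = eta * rho + (1.0 - eta) * (1.0 - rho)
    jac = rho / den - eta * rho * (2.0 * rho - 1.0) / (den * den)
    lp = _log_beta_density(theta, alpha0, beta0) + np.log(jac)
    alpha = theta * precision
    beta = (1.0 - theta) * precision
    ll = (
        log_choose
        + betaln(a + alpha[:, None], d - a + beta[:, None])
        - betaln(alpha, beta)[:, None]
    )
    return lp + np.where(mask, ll, 0.0).sum(axis=1)


def sample_posterior_batch(
    a: np.ndarray,
    d: np.ndarray,
    rho: np.ndarray,
    mu: np.ndarray,
    hp: ModelHyperParams = ModelHyperParams(),
    mcmc: MCMCSettings = MCMCSettings(),
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run K independent Metropolis-Hastings chains, one per SNP, in lockstep.

    Parameters
    ----------
    a, d
        (K, N) arrays of reference and total counts; cells where ``mask`` is
        False are ignored (missing samples).
    rho, mu
        (K,) arrays of per-SNP RAF and reference-mapping bias.
    mask
        (K, N) boolean array of observed cells; default all observed.

    Returns
    -------
    traces : (K, n_iter - burn_in) array of post-burn-in eta samples.
    acceptance_rate : (K,) array.

    Raises
    ------
    RuntimeError
        If any chain accepts no proposal over the whole run (degenerate
        posterior or proposal).
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.ndim != 2 or a.shape != d.shape:
        raise ValueError("a and d must be (K, N) arrays of equal shape")
    K, _ = a.shape
    if mask is None:
        mask = np.ones_like(a, dtype=bool)
    rho = np.clip(np.asarray(rho, dtype=float), INTERIOR_EPS, 1.0 - INTERIOR_EPS)
    mu = np.clip(np.asarray(mu, dtype=float), INTERIOR_EPS, 1.0 - INTERIOR_EPS)
    shapes = [prior_shapes(float(m), hp.prior_variance) for m in mu]
    alpha0 = np.array([s[0] for s in shapes])
    beta0 = np.array([s[1] for s in shapes])
    log_choose = gammaln(d + 1.0) - gammaln(a + 1.0) - gammaln(d - a + 1.0)

    rng = np.random.default_rng(mcmc.seed)
    eta = np.full(K, 0.5)
    lp = _batch_log_posterior(eta, a, d, mask, rho, alpha0, beta0, log_choose, hp.precision)
    n_keep = mcmc.n_iter - mcmc.burn_in
    traces = np.empty((K, n_keep))
    accepted = np.zeros(K, dtype=np.int64)
    for it in range(mcmc.n_iter):
        prop = eta + rng.normal(0.0, mcmc.proposal_sd, size=K)
        inside = (prop > 0.0) & (prop < 1.0)
        lp_prop = np.full(K, -np.inf)
        if inside.any():
            # proposals outside (0,1) keep -inf and are always rejected
            safe = np.where(inside, prop, 0.5)
            lp_all = _batch_log_posterior(safe, a, d, mask, rho, alpha0, beta0, log_choose, hp.precision)
            lp_prop = np.where(inside, lp_all, -np.inf)
        accept = np.log(rng.uniform(size=K)) < lp_prop - lp
        eta = np.where(accept, prop, eta)
        lp = np.where(accept, lp_prop, lp)
        accepted += accept
        if it >= mcmc.burn_in:
            traces[:, it - mcmc.burn_in] = eta
    if np.any(accepted == 0):
        bad = int(np.flatnonzero(accepted == 0)[0])
        raise RuntimeError(f"MH chain {bad} accepted no proposals; degenerate posterior or proposal scale")
    return traces, accepted / mcmc.n_iter


def sample_posterior(
    snp: SNPModelInput,
    hp: ModelHyperParams = ModelHyperParams(),
    mcmc: MCMCSettings = MCMCSettings(),
) -> np.ndarray:
    """Draw posterior samples of eta for one SNP (post-burn-in trace)."""
    if snp.counts:
        a = np.array([[c[0] for c in snp.counts]], dtype=float)
        d = np.array([[c[1] for c in snp.counts]], dtype=float)
    else:
        a = np.zeros((1, 1))
        d = np.zeros((1, 1))
    traces, _ = sample_posterior_batch(
        a, d, np.array([snp.rho]), np.array([snp.mu]), hp=hp, mcmc=mcmc
    )
    return traces[0]


def hpd_interval(trace: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing the given mass of the sampled values.

    Among all contiguous windows of ceil(mass * len) sorted samples, returns
    the narrowest (ties broken by the smallest lower bound).
    """
    x = np.sort(np.asarray(trace, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"trace too short for an HPD interval ({n} < 100 samples)")
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0,1), got {mass}")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns first minimum: smallest lo on ties
    return float(x[i]), float(x[i + m - 1])


def call_asb(interval: tuple[float, float], zone: tuple[float, float] = (0.4, 0.6)) -> str:
    """Classify a credible interval against the exclusion zone around 0.5.

    REF_BIASED if the whole interval is above the zone, ALT_BIASED if below,
    NO_ASB otherwise.
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"interval lower bound {lo} exceeds upper bound {hi}")
    if lo > zone[1]:
        return REF_BIASED
    if hi < zone[0]:
        return ALT_BIASED
    return NO_ASB


def fit_snp(
    snp: SNPModelInput,
    hp: ModelHyperParams = ModelHyperParams(),
    mcmc: MCMCSettings = MCMCSettings(),
) -> PosteriorResult:
    """Full per-SNP inference: sample, summarize, and call."""
    trace = sample_posterior(snp, hp=hp, mcmc=mcmc)
    lo, hi = hpd_interval(trace, hp.hpd_mass)
    call = call_asb((lo, hi), hp.exclusion_zone)
    return PosteriorResult(
        trace=trace,
        hpd_lower=lo,
        hpd_upper=hi,
        point_estimate=float(trace.mean()),
        call=call,
    )
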