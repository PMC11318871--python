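"""Variational Bayesian weight primitives.

The encoder weights carry a fully factorized Gaussian variational posterior
``q(w | theta) = prod_k N(w_k | mu_k, sigma_k^2)`` with the scale
parameterized through a softplus, ``sigma = log(1 + exp(rho))``, so that any
real ``rho`` maps to a strictly positive ``sigma``.  The prior is a zero-mean
scale mixture of two Gaussians ``pi N(0, sigma1^2) + (1 - pi) N(0, sigma2^2)``
whose narrow component (``sigma2 << sigma1``) induces sparsity in the learned
weight means.

Everything here is plain numpy; sampling uses the reparameterization
``w = mu + sigma * eps`` with ``eps ~ N(0, 1)`` so gradients with respect to
``(mu, rho)`` are well defined for a fixed noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "VariationalParameterSet",
    "ScaleMixturePrior",
    "WeightSample",
    "softplus_scale",
    "softplus_derivative",
    "sample_weights",
    "log_posterior_density",
    "log_prior_density",
    "gaussian_kl",
]


def softplus_scale(rho):
    """Map pre-scale parameters ``rho`` to positive scales ``sigma``.

    Computes ``sigma = log(1 + exp(rho))`` elementwise in the numerically
    stable form ``max(rho, 0) + log1p(exp(-|rho|))``, which neither overflows
    for large positive ``rho`` nor underflows to zero for moderately negative
    ``rho``.

    Parameters
    ----------
    rho : array_like
        Real-valued pre-softplus parameters.

    Returns
    -------
    ndarray or float
        ``log(1 + exp(rho))``, same shape as the input, strictly positive.
    """
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("softplus_scale requires finite input")
    out = np.maximum(rho, 0.0) + np.log1p(np.exp(-np.abs(rho)))
    if out.ndim == 0:
        return float(out)
    return out


def softplus_derivative(rho):
    """Derivative of the softplus, i.e. the logistic sigmoid of ``rho``."""
    return expit(np.asarray(rho, dtype=float))


@dataclass
class VariationalParameterSet:
    """Per-weight posterior parameters ``theta = (mu, rho)``.

    ``mu`` holds the posterior means, ``rho`` the pre-softplus scale
    parameters; both share one arbitrary tensor shape (the layer's weight
    shape).  The posterior standard deviation is ``sigma = softplus(rho)``.
    """

    mu: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.mu.shape != self.rho.shape:
            raise ValueError(
                f"mu shape {self.mu.shape} != rho shape {self.rho.shape}"
            )
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.rho))):
            raise ValueError("mu and rho must be finite")

    @property
    def sigma(self) -> np.ndarray:
        return np.asarray(softplus_scale(self.rho))

    @property
    def size(self) -> int:
        return self.mu.size


@dataclass
class ScaleMixturePrior:
    """Zero-mean two-component Gaussian scale-mixture prior.

    ``log P(w) = sum_k log( pi N(w_k | 0, sigma1^2)
                            + (1 - pi) N(w_k | 0, sigma2^2) )``

    Defaults follow the setting used for every layer of the encoders:
    ``pi = 0.5, sigma1 = 1, sigma2 = exp(-6)``.  The very narrow second
    component acts like a spike at zero and drives unneeded weight means
    toward zero.
    """

    pi: float = 0.5
    sigma1: float = 1.0
    sigma2: float = float(np.exp(-6.0))

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")

    def _component_logpdfs(self, w: np.ndarray):
        lp1 = -0.5 * _LOG_2PI - np.log(self.sigma1) - 0.5 * (w / self.sigma1) ** 2
        lp2 = -0.5 * _LOG_2PI - np.log(self.sigma2) - 0.5 * (w / self.sigma2) ** 2
        return lp1, lp2

    def log_density(self, w) -> float:
        """Summed mixture log-density over all elements of ``w`` (log-sum-exp)."""
        w = np.asarray(w, dtype=float)
        lp1, lp2 = self._component_logpdfs(w)
        if self.pi == 1.0:
            return float(np.sum(lp1))
        if self.pi == 0.0:
            return float(np.sum(lp2))
        elem = np.logaddexp(np.log(self.pi) + lp1, np.log1p(-self.pi) + lp2)
        return float(np.sum(elem))

    def grad_log_density(self, w) -> np.ndarray:
        """Elementwise ``d log P / d w`` via component responsibilities."""
        w = np.asarray(w, dtype=float)
        if self.pi == 1.0:
            return -w / self.sigma1**2
        if self.pi == 0.0:
            return -w / self.sigma2**2
        lp1, lp2 = self._component_logpdfs(w)
        a1 = np.log(self.pi) + lp1
        a2 = np.log1p(-self.pi) + lp2
        # responsibility of component 1, computed stably
        r1 = expit(a1 - a2)
        return -w * (r1 / self.sigma1**2 + (1.0 - r1) / self.sigma2**2)


@dataclass
class WeightSample:
    """A concrete weight draw with its posterior and prior log-densities."""

    weights: np.ndarray
    log_q: float
    log_p: float
    eps: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not (np.isfinite(self.log_q) and np.isfinite(self.log_p)):
            raise ValueError("log_q and log_p must be finite")


def log_posterior_density(posterior: VariationalParameterSet, w) -> float:
    """``log q(w | theta)``: summed factorized-Gaussian log-density.

    Raises on shape mismatch between ``w`` and the posterior means.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != posterior.mu.shape:
        raise ValueError(
            f"weight shape {w.shape} does not match posterior shape "
            f"{posterior.mu.shape}"
        )
    sigma = posterior.sigma
    z = (w - posterior.mu) / sigma
    elem = -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z**2
    return float(np.sum(elem))


def log_prior_density(prior: ScaleMixturePrior, w) -> float:
    """``log P(w)`` under the scale-mixture prior (stable log-sum-exp)."""
    return prior.log_density(w)


def sample_weights(
    posterior: VariationalParameterSet,
    prior: ScaleMixturePrior,
    rng: np.random.Generator,
) -> WeightSample:
    """Draw ``w = mu + softplus(rho) * eps`` and score it under q and P.

    The standard-normal draw ``eps`` is returned alongside the sample so that
    callers can form reparameterization gradients with respect to
    ``(mu, rho)`` for this fixed noise realization.
    """
    eps = rng.standard_normal(posterior.mu.shape)
    w = posterior.mu + posterior.sigma * eps
    return WeightSample(
        weights=w,
        log_q=log_posterior_density(posterior, w),
        log_p=log_prior_density(prior, w),
        eps=eps,
    )


def gaussian_kl(mu, sigma, prior_sigma: float) -> float:
    """Closed-form ``KL( N(mu, sigma^2) || N(0, prior_sigma^2) )``, summed.

    Used as an independent oracle for the Monte-Carlo KL estimate when the
    prior degenerates to a single Gaussian (``pi = 1``).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    kl = (
        np.log(prior_sigma / sigma)
        + (sigma**2 + mu**2) / (2.0 * prior_sigma**2)
        - 0.5
    )
    return float(np.sum(kl))
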