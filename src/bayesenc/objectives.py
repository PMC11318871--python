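"""Training objectives.

The variational loss is the Monte-Carlo estimate of the tempered evidence
bound

    L = beta_v * KL[q(w|theta) || P(w)] - E_q [ log P(D | w) ]
      ~ (1/n) sum_i  beta_v * kl_scale * (log q(w_i|theta) - log P(w_i))
                     + PoissonNLL(D | w_i)

with ``w_i`` reparameterized draws from the posterior.  ``beta_v`` tempers
the KL term (beta_v < 1 is the cold-posterior regime); ``kl_scale`` is the
minibatch weighting 1 / n_batches so that the KL is counted exactly once per
pass over the data.

The Poisson likelihood term is ``sum_l  rhat_l - r_l log rhat_l`` (no
log r! term: responses are real-valued calcium signals), summed over all
neurons and stimuli in the batch.  With the summed likelihood and the
per-pass KL weighting, ``beta_v = 1`` recovers the untempered bound at
dataset scale and the beta_v axis keeps its meaning across batch sizes.

Gradients with respect to ``(mu, rho)`` for a fixed noise draw ``eps`` are
assembled analytically:

    d/dmu  [log q - log P] = -dlogP/dw
    d/drho [log q - log P] = sigmoid(rho) * ( -dlogP/dw * eps - 1/sigma )

(the explicit and pathwise dependencies of log q on mu cancel), while the
likelihood part backpropagates through ``w = mu + sigma * eps`` as usual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variational import ScaleMixturePrior, softplus_derivative

PRED_FLOOR = 1e-8


@dataclass
class ElboComponents:
    """Decomposed Monte-Carlo ELBO value (averaged over the MC samples)."""

    kl_term: float
    nll_term: float
    total: float
    n_samples: int
    beta_v: float


def poisson_nll(pred, target, grad: bool = False):
    """Poisson negative log-likelihood ``sum_l rhat - r log rhat``.

    Summed over all neurons and batch elements.  Predictions are floored at
    ``1e-8`` before the log.

    Parameters
    ----------
    pred : array (batch, neurons)
        Predicted rates; must be non-negative and finite.
    target : array (batch, neurons)
        Observed responses; must be non-negative.
    grad : bool
        If True, also return ``d nll / d pred``.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    if np.any(target < 0):
        raise ValueError("targets must be non-negative")
    if not np.all(np.isfinite(pred)) or np.any(pred < 0):
        raise ValueError("predictions must be finite and non-negative")
    p = np.maximum(pred, PRED_FLOOR)
    if np.any(p <= 0):
        raise ValueError("predictions non-positive after flooring")
    value = float(np.sum(p - target * np.log(p)))
    if not grad:
        return value
    g = 1.0 - target / p
    return value, g


def l2l1_penalty(conv_weights, fc_weights, lambda2: float, lambda1: float) -> float:
    """``lambda2 * sum(conv weights^2) + lambda1 * sum |fc weights|``."""
    if lambda2 < 0 or lambda1 < 0:
        raise ValueError("penalty coefficients must be non-negative")
    pen = 0.0
    for w in conv_weights:
        pen += lambda2 * float(np.sum(np.asarray(w) ** 2))
    if fc_weights is not None:
        pen += lambda1 * float(np.sum(np.abs(np.asarray(fc_weights))))
    return pen


def elbo_loss(encoder, batch, beta_v: float, n_samples: int = 1,
              kl_scale: float = 1.0, rng=None, return_grads: bool = False):
    """Monte-Carlo tempered ELBO for a variational encoder on one batch.

    Draws ``n_samples`` weight samples, averages
    ``beta_v * kl_scale * (log q - log P) + poisson_nll`` over them, and
    optionally returns gradients with respect to the posterior parameters
    (keyed ``<param>.mu`` / ``<param>.rho``).

    Returns
    -------
    ElboComponents, or (ElboComponents, grads dict) when ``return_grads``.
    """
    if beta_v < 0:
        raise ValueError("beta_v must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    stimuli, responses = batch
    prior: ScaleMixturePrior = encoder.prior
    bscale = beta_v * kl_scale

    kl_sum = 0.0
    nll_sum = 0.0
    grads = None
    for _ in range(n_samples):
        w, eps = encoder.sample_weight_draw(rng)
        pred, cache = encoder.forward(stimuli, weights=w, return_cache=True)
        nll, dpred = poisson_nll(pred, responses, grad=True)
        nll_sum += nll
        lq, lp = encoder.log_q_log_p(w)
        kl_sum += lq - lp
        if return_grads:
            gw, _ = encoder.backward(dpred, cache)
            if grads is None:
                grads = {}
            for k, post in encoder.posteriors.items():
                sig = np.asarray(post.sigma)
                sprime = softplus_derivative(post.rho)
                gp = prior.grad_log_density(w[k])
                gmu = gw[k] + bscale * (-gp)
                grho = sprime * (gw[k] * eps[k] + bscale * (-gp * eps[k] - 1.0 / sig))
                grads.setdefault(k + ".mu", 0.0)
                grads.setdefault(k + ".rho", 0.0)
                grads[k + ".mu"] = grads[k + ".mu"] + gmu
                grads[k + ".rho"] = grads[k + ".rho"] + grho

    kl_term = bscale * kl_sum / n_samples
    nll_term = nll_sum / n_samples
    comps = ElboComponents(
        kl_term=float(kl_term), nll_term=float(nll_term),
        total=float(kl_term + nll_term), n_samples=n_samples, beta_v=beta_v,
    )
    if not return_grads:
        return comps
    grads = {k: v / n_samples for k, v in grads.items()}
    return comps, grads


def map_loss(encoder, batch, prior: ScaleMixturePrior, kl_scale: float = 1.0,
             return_grads: bool = False):
    """MAP objective: Poisson NLL minus the scaled log-prior of the weights.

    No posterior/entropy term — the encoder carries point weights.
    """
    stimuli, responses = batch
    w = encoder.mean_weights()
    pred, cache = encoder.forward(stimuli, weights=w, return_cache=True)
    nll, dpred = poisson_nll(pred, responses, grad=True)
    log_p = sum(prior.log_density(w[k]) for k in w)
    total = float(nll - kl_scale * log_p)
    if not return_grads:
        return total
    gw, _ = encoder.backward(dpred, cache)
    grads = {k: gw[k] - kl_scale * prior.grad_log_density(w[k]) for k in w}
    return total, grads
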