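"""Evaluation metrics and model-comparison statistics.

CC (mean over neurons of the per-neuron Pearson correlation between
predicted and recorded responses) is the primary metric; RMSE and a Poisson
predictive log-likelihood complement it.  Repeat reliability is summarized
by the quality index QI = Var[E[C]_r]_t / E[Var[C]_t]_r for a response
matrix C of shape (stimuli t, repeats r); neurons are conventionally
retained when QI > 0.3.  Paired model comparisons use a two-sided sign-flip
permutation test on the paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

QI_DEFAULT_THRESHOLD = 0.3


@dataclass
class EvalReport:
    """Per-neuron and aggregate predictive metrics."""

    cc: float
    rmse: float
    loglik: float
    per_neuron: pd.DataFrame

    def to_csv(self, path):
        """One row per neuron plus a summary row."""
        df = self.per_neuron.copy()
        summary = pd.DataFrame(
            [{"neuron": "mean", "cc": self.cc, "rmse": self.rmse,
              "loglik": self.loglik}]
        )
        pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def per_neuron_pearson(pred, obs):
    """Per-neuron Pearson r; constant columns yield NaN with a warning."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    pc = pred - pred.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    sp = np.sqrt((pc**2).sum(axis=0))
    so = np.sqrt((oc**2).sum(axis=0))
    degenerate = (sp == 0) | (so == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * oc).sum(axis=0) / (sp * so)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} neuron(s) with constant responses "
            "excluded from CC", stacklevel=2,
        )
        r = np.where(degenerate, np.nan, r)
    return r


def correlation_metric(pred, obs) -> float:
    """Mean over neurons of per-neuron Pearson r (NaN neurons skipped)."""
    r = per_neuron_pearson(pred, obs)
    return float(np.nanmean(r))


def rmse_metric(pred, obs) -> float:
    """Root mean squared error over all (trial, neuron) entries."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _poisson_logpdf(rate, obs):
    rate = np.maximum(rate, 1e-8)
    return obs * np.log(rate) - rate


def loglik_metric(pred, obs, per_neuron: bool = False):
    """Poisson predictive log-likelihood (no log r! term).

    ``pred`` may be a point-rate array (plug-in likelihood) or a
    ``PredictiveSummary`` with stored samples, in which case the posterior
    predictive ``log mean_s P(obs | rate_s)`` is computed per entry
    (log-sum-exp over the sample axis).  Summed over neurons, averaged over
    trials.
    """
    from .encoders import PredictiveSummary

    obs = np.asarray(obs, dtype=float)
    if isinstance(pred, PredictiveSummary):
        if pred.samples is not None and not pred.single_sample:
            lls = _poisson_logpdf(pred.samples, obs[None])  # (S, T, N)
            from scipy.special import logsumexp
            ll = logsumexp(lls, axis=0) - np.log(lls.shape[0])
        else:
            ll = _poisson_logpdf(pred.mean, obs)
    else:
        rate = np.asarray(pred, dtype=float)
        if rate.shape != obs.shape:
            raise ValueError(f"shape mismatch: {rate.shape} vs {obs.shape}")
        ll = _poisson_logpdf(rate, obs)
    per = ll.mean(axis=0)  # per neuron, mean over trials
    if per_neuron:
        return per
    return float(per.sum())


def evaluate(pred_summary, obs) -> EvalReport:
    """Full report: CC, RMSE and log-likelihood, per neuron and aggregated."""
    from .encoders import PredictiveSummary

    if isinstance(pred_summary, PredictiveSummary):
        mean = pred_summary.mean
    else:
        mean = np.asarray(pred_summary, dtype=float)
        pred_summary = None
    obs = np.asarray(obs, dtype=float)
    r = per_neuron_pearson(mean, obs)
    rmse_n = np.sqrt(np.mean((mean - obs) ** 2, axis=0))
    ll_n = loglik_metric(pred_summary if pred_summary is not None else mean,
                         obs, per_neuron=True)
    per = pd.DataFrame({
        "neuron": np.arange(obs.shape[1]),
        "cc": r,
        "rmse": rmse_n,
        "loglik": ll_n,
    })
    return EvalReport(
        cc=float(np.nanmean(r)),
        rmse=float(np.sqrt(np.mean((mean - obs) ** 2))),
        loglik=float(ll_n.sum()),
        per_neuron=per,
    )


def quality_index(responses):
    """Repeat-reliability QI per neuron.

    Parameters
    ----------
    responses : array (stimuli t, repeats r, neurons) or (t, r)
        Repeated-stimulus response block.

    Returns
    -------
    qi : array (neurons,) — NaN where the denominator vanishes (flagged).
    """
    c = np.asarray(responses, dtype=float)
    squeeze = c.ndim == 2
    if squeeze:
        c = c[:, :, None]
    t, r = c.shape[0], c.shape[1]
    if t < 2 or r < 2:
        raise ValueError("QI requires at least 2 stimuli and 2 repeats")
    num = np.var(c.mean(axis=1), axis=0)          # Var over stimuli of repeat-mean
    den = np.mean(np.var(c, axis=0), axis=0)      # mean over repeats of var over stimuli
    with np.errstate(invalid="ignore", divide="ignore"):
        qi = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if np.any(den == 0):
        warnings.warn(
            f"{int((den == 0).sum())} neuron(s) with zero across-stimulus "
            "variance: QI undefined", stacklevel=2,
        )
    return qi[0] if squeeze else qi


def paired_permutation_test(a, b, n_repeats: int = 10_000, rng=None) -> float:
    """Two-sided paired sign-flip permutation test.

    Statistic: mean(a - b).  The null distribution is generated by randomly
    flipping the sign of each paired difference; the two-sided p-value uses
    the add-one correction ``(#{|perm| >= |obs|} + 1) / (n_repeats + 1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1-D with >= 2 pairs")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    d = a - b
    obs = abs(d.mean())
    signs = rng.integers(0, 2, size=(n_repeats, d.size)) * 2 - 1
    perm = np.abs(signs @ d) / d.size
    # tolerance so exact ties (e.g. a == b) count as >= despite fp noise
    count = int(np.sum(perm >= obs - 1e-12 * (1.0 + obs)))
    return (count + 1) / (n_repeats + 1)
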