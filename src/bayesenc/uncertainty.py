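"""Posterior-quality diagnostics.

Calibration curves compare nominal credible-interval levels against the
empirical coverage of observed responses under the Monte-Carlo predictive
distribution; well-calibrated models track the diagonal, overconfident ones
fall below it.  Weight-sparsity ratios quantify how much posterior-mean mass
sits within a few multiples of the narrow prior component's scale sigma2.
Partial correlation removes a confound (typically mean firing rate) before
correlating predictive performance with MEI variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_LEVELS = np.concatenate(([0.0], np.arange(0.05, 0.951, 0.05), [1.0]))
SPARSITY_KS = (2.0, 3.0, 4.0)


@dataclass
class CalibrationCurve:
    """Nominal credible levels vs empirical coverage."""

    nominal: np.ndarray
    empirical: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.nominal)

    def max_deviation(self) -> float:
        return float(np.max(np.abs(self.empirical - self.nominal)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nominal": self.nominal, "empirical": self.empirical})


@dataclass
class SparsityReport:
    """Fraction of posterior means within +-k*sigma2 for each threshold k."""

    beta_v: float
    thresholds: tuple
    ratios: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta_v": self.beta_v, "k": self.thresholds,
                             "ratio": self.ratios})


def calibration_curve(samples, observed, levels=None) -> CalibrationCurve:
    """Empirical coverage of central credible intervals.

    For each nominal level q the central interval is the
    ``[(1-q)/2, (1+q)/2]`` empirical quantile band of the predictive samples
    per (trial, neuron) cell; coverage pools all cells.  Nested quantile
    intervals make the curve monotone by construction.

    Parameters
    ----------
    samples : array (n_samples, trials, neurons)
        Monte-Carlo predictive draws (>= 20 samples).
    observed : array (trials, neurons)
    levels : sequence in [0, 1], optional
        Defaults to 0, 0.05, ..., 0.95, 1.
    """
    samples = np.asarray(samples, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if samples.ndim != 3 or samples.shape[1:] != observed.shape:
        raise ValueError("samples must be (n_samples, *observed.shape)")
    if samples.shape[0] < 20:
        raise ValueError("calibration requires at least 20 predictive samples")
    levels = DEFAULT_LEVELS if levels is None else np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("levels must lie in [0, 1]")
    emp = np.empty_like(levels)
    for i, q in enumerate(levels):
        lo = np.quantile(samples, (1.0 - q) / 2.0, axis=0)
        hi = np.quantile(samples, (1.0 + q) / 2.0, axis=0)
        emp[i] = np.mean((observed >= lo) & (observed <= hi))
    return CalibrationCurve(nominal=levels, empirical=emp)


def sparsity_ratio(mu, sigma2: float, k: float) -> float:
    """Fraction of weight means with ``|mu| <= k * sigma2``."""
    mu = np.concatenate([np.asarray(m, dtype=float).ravel() for m in
                         (mu if isinstance(mu, (list, tuple)) else [mu])])
    if mu.size == 0:
        raise ValueError("empty weight tensor")
    return float(np.mean(np.abs(mu) <= k * sigma2))


def sparsity_report(encoder, beta_v: float = np.nan,
                    ks=SPARSITY_KS) -> SparsityReport:
    """Sparsity ratios of an encoder's posterior weight means.

    Only the weight tensors (not biases) enter, thresholds are multiples of
    the prior's sigma2.
    """
    if encoder.is_variational:
        mus = [p.mu for k_, p in encoder.posteriors.items()
               if k_.endswith("weight")]
    else:
        mus = [w for k_, w in encoder.weights.items() if k_.endswith("weight")]
    sigma2 = encoder.prior.sigma2 if encoder.prior is not None else float(np.exp(-6))
    ratios = np.array([sparsity_ratio(mus, sigma2, k) for k in ks])
    return SparsityReport(beta_v=beta_v, thresholds=tuple(ks), ratios=ratios)


def partial_correlation(x, y, control):
    """Pearson correlation of x and y after regressing out ``control``.

    Both variables are linearly regressed (with intercept) on the control;
    the residuals are correlated and the p-value comes from the
    t-distribution with n - 3 degrees of freedom.

    Returns ``(cc, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = x.size
    if not (x.shape == y.shape == c.shape) or x.ndim != 1 or n < 4:
        raise ValueError("x, y, control must be equal-length 1-D with n >= 4")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x)))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y)))
    if sx <= tol_x or sy <= tol_y:
        warnings.warn("zero residual variance: partial correlation undefined",
                      stacklevel=2)
        return np.nan, np.nan
    r = float(rx @ ry / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def response_variance_correlation(encoder, block, stimuli,
                                  mode: str = "mean_substitute",
                                  n_samples: int = 100, rng=None):
    """Per-neuron Spearman correlation of predicted vs recorded variance.

    For each neuron, correlates the across-repeat variance of the recorded
    test responses with either (a) the predicted mean rate
    (``mean_substitute`` — for a Poisson neuron the mean equals the
    variance) or (b) the explicit Monte-Carlo predictive variance
    (``explicit_variance``), across the test stimuli.

    Returns an array of per-neuron Spearman rho (NaN where degenerate).
    """
    from .datasets import RepeatBlock

    responses = block.responses if isinstance(block, RepeatBlock) else np.asarray(block)
    t = responses.shape[0]
    if responses.shape[1] < 2:
        raise ValueError("need at least 2 repeats")
    rec_var = responses.var(axis=1, ddof=1)  # (t, neurons)
    if mode == "mean_substitute":
        pred = encoder.predict_mc(stimuli, n_samples=max(1, n_samples),
                                  rng=rng).mean if encoder.is_stochastic \
            else encoder.forward(stimuli)
        pred_stat = pred
    elif mode == "explicit_variance":
        summ = encoder.predict_mc(stimuli, n_samples=n_samples, rng=rng)
        pred_stat = summ.std**2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_neurons = rec_var.shape[1]
    out = np.full(n_neurons, np.nan)
    for j in range(n_neurons):
        if t < 3 or np.ptp(rec_var[:, j]) == 0 or np.ptp(pred_stat[:, j]) == 0:
            warnings.warn(f"neuron {j}: degenerate sequence, correlation "
                          "undefined", stacklevel=2)
            continue
        out[j] = sps.spearmanr(pred_stat[:, j], rec_var[:, j]).statistic
    return out
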