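"""CNN encoder architectures for neural system identification.

The shared architecture is two valid (stride-1, no-padding) convolutional
layers with ReLU nonlinearities, a fully connected readout across all
flattened feature-map units, and an exponential output that maps each
neuron's pre-activation to a strictly positive predicted rate.

Five variants share this forward map and differ in how weights are treated:

``baseline``
    Point weights, no regularization.
``l2l1``
    Point weights; L2 penalty on conv weights, L1 on the FC weights.
``map``
    Point weights trained with the scale-mixture log-prior as penalty.
``mc_dropout``
    Point weights with dropout active at the same rate in every layer during
    both training and prediction; prediction is Monte Carlo over masks.
``variational``
    A factorized Gaussian posterior per weight (Bayes by backprop);
    prediction is Monte Carlo over weight draws.

The sixth model of the family, the ensemble, is a set of ``l2l1`` encoders
combined by :func:`ensemble_predict`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .variational import (
    ScaleMixturePrior,
    VariationalParameterSet,
    softplus_scale,
    softplus_derivative,
)

VARIANTS = ("baseline", "l2l1", "map", "mc_dropout", "variational")

# Weight initialization: means from N(0, 0.1), biases zero; variational
# pre-scales start at rho = -5 (sigma ~ 0.0067) so training starts
# near-deterministic.
INIT_MU_STD = 0.1
INIT_RHO = -5.0


def flattened_feature_dim(input_hw, conv_specs: Sequence) -> int:
    """Flattened dimension after a stack of valid convolutions.

    Parameters
    ----------
    input_hw : (int, int)
        Input image height and width in pixels.
    conv_specs : sequence of (out_channels, kernel_h, kernel_w)
        One entry per convolutional layer, applied in order.

    Returns
    -------
    int
        ``out_channels_last * prod(dim - kernel + 1)`` composed over layers.

    Raises
    ------
    ValueError
        If any intermediate spatial dimension collapses to < 1.
    """
    h, w = input_hw
    out_channels = None
    for spec in conv_specs:
        out_channels, kh, kw = spec
        h, w = h - kh + 1, w - kw + 1
        if h < 1 or w < 1:
            raise ValueError(
                f"kernel ({kh},{kw}) does not fit remaining input ({h + kh - 1},{w + kw - 1})"
            )
    if out_channels is None:
        raise ValueError("need at least one conv layer")
    return int(out_channels * h * w)


@dataclass
class EncoderConfig:
    """Architecture and variant description of one encoder.

    ``conv1``/``conv2`` are ``(out_channels, kernel_h, kernel_w)``; stride is
    1 and there is no padding anywhere.
    """

    in_channels: int
    input_hw: tuple
    n_neurons: int
    conv1: tuple = (24, 9, 9)
    conv2: tuple = (48, 7, 7)
    variant: str = "variational"
    dropout_rate: float = 0.0

    def __post_init__(self):
        self.input_hw = tuple(int(v) for v in self.input_hw)
        self.conv1 = tuple(int(v) for v in self.conv1)
        self.conv2 = tuple(int(v) for v in self.conv2)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        # raises if kernels do not fit
        self.feature_dim

    @property
    def feature_dim(self) -> int:
        return flattened_feature_dim(self.input_hw, [self.conv1, self.conv2])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


@dataclass
class PredictiveSummary:
    """Mean/std of predicted rates across Monte-Carlo samples.

    ``std`` is zero (with ``single_sample=True``) when only one forward pass
    was available, e.g. for deterministic variants.
    """

    mean: np.ndarray
    std: np.ndarray
    samples: Optional[np.ndarray] = None
    single_sample: bool = False


def _he_like_init(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.normal(0.0, INIT_MU_STD, size=shape)


class ConvEncoder:
    """Two-conv/one-FC encoder with exponential output.

    Parameters
    ----------
    config : EncoderConfig
    prior : ScaleMixturePrior, optional
        Required for the ``variational`` and ``map`` variants.
    seed : int
        Initialization seed (weight means / point weights).
    """

    PARAM_KEYS = ("conv1.weight", "conv1.bias", "conv2.weight", "conv2.bias",
                  "fc.weight", "fc.bias")

    def __init__(self, config: EncoderConfig, prior: Optional[ScaleMixturePrior] = None,
                 seed: int = 0):
        self.config = config
        self.prior = prior
        if config.variant in ("variational", "map") and prior is None:
            raise ValueError(f"variant {config.variant!r} requires a prior")
        if config.variant == "mc_dropout" and config.dropout_rate == 0.0:
            raise ValueError("mc_dropout variant requires dropout_rate > 0")

        c1o, k1h, k1w = config.conv1
        c2o, k2h, k2w = config.conv2
        self._shapes = {
            "conv1.weight": (c1o, config.in_channels, k1h, k1w),
            "conv1.bias": (c1o,),
            "conv2.weight": (c2o, c1o, k2h, k2w),
            "conv2.bias": (c2o,),
            "fc.weight": (config.n_neurons, config.feature_dim),
            "fc.bias": (config.n_neurons,),
        }
        rng = np.random.default_rng(seed)
        if self.is_variational:
            self.posteriors = {}
            for k, shp in self._shapes.items():
                mu = _he_like_init(rng, shp) if k.endswith("weight") else np.zeros(shp)
                self.posteriors[k] = VariationalParameterSet(
                    mu=mu, rho=np.full(shp, INIT_RHO)
                )
        else:
            self.weights = {}
            for k, shp in self._shapes.items():
                self.weights[k] = (
                    _he_like_init(rng, shp) if k.endswith("weight") else np.zeros(shp)
                )

    # ------------------------------------------------------------------ meta
    @property
    def is_variational(self) -> bool:
        return self.config.variant == "variational"

    @property
    def is_stochastic(self) -> bool:
        return self.config.variant in ("variational", "mc_dropout")

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for s in self._shapes.values())

    # ------------------------------------------------------------ parameters
    def trainable_params(self) -> dict:
        """Flat dict of optimizer-facing arrays (views, updated in place)."""
        if self.is_variational:
            out = {}
            for k, post in self.posteriors.items():
                out[k + ".mu"] = post.mu
                out[k + ".rho"] = post.rho
            return out
        return self.weights

    def mean_weights(self) -> dict:
        """Deterministic weights: posterior means mu, or the point weights."""
        if self.is_variational:
            return {k: p.mu for k, p in self.posteriors.items()}
        return self.weights

    def sample_weight_draw(self, rng: np.random.Generator):
        """One reparameterized weight draw ``w = mu + sigma * eps``.

        Returns ``(weights, eps)`` dicts keyed like ``mean_weights``.
        """
        if not self.is_variational:
            raise ValueError("weight sampling requires the variational variant")
        w, eps = {}, {}
        for k, post in self.posteriors.items():
            e = rng.standard_normal(post.mu.shape)
            w[k] = post.mu + np.asarray(softplus_scale(post.rho)) * e
            eps[k] = e
        return w, eps

    def log_q_log_p(self, weights: dict):
        """(log q(w|theta), log P(w)) summed over all parameter tensors."""
        from .variational import log_posterior_density

        lq = sum(
            log_posterior_density(self.posteriors[k], weights[k])
            for k in self._shapes
        )
        lp = sum(self.prior.log_density(weights[k]) for k in self._shapes)
        return lq, lp

    # --------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, weights: Optional[dict] = None,
                dropout_rng: Optional[np.random.Generator] = None,
                return_cache: bool = False):
        """Predicted rates (B, n_neurons); strictly positive via exp output.

        ``weights`` defaults to the deterministic weights.  For the
        ``mc_dropout`` variant a ``dropout_rng`` draws fresh masks (dropout is
        active at prediction time as well; pass a rng to enable it).
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (self.config.in_channels, *self.config.input_hw):
            raise ValueError(
                f"stimulus shape {x.shape[1:]} does not match config "
                f"{(self.config.in_channels, *self.config.input_hw)}"
            )
        w = weights if weights is not None else self.mean_weights()
        rate = self.config.dropout_rate if self.config.variant == "mc_dropout" else 0.0
        use_dropout = rate > 0.0 and dropout_rng is not None

        a1, c1 = _nn.conv_forward(x, w["conv1.weight"], w["conv1.bias"])
        r1, m1 = _nn.relu_forward(a1)
        d1 = _nn.dropout_mask(r1.shape, rate, dropout_rng) if use_dropout else None
        h1 = r1 * d1 if use_dropout else r1

        a2, c2 = _nn.conv_forward(h1, w["conv2.weight"], w["conv2.bias"])
        r2, m2 = _nn.relu_forward(a2)
        d2 = _nn.dropout_mask(r2.shape, rate, dropout_rng) if use_dropout else None
        h2 = r2 * d2 if use_dropout else r2

        flat = h2.reshape(x.shape[0], -1)
        z, _ = _nn.fc_forward(flat, w["fc.weight"], w["fc.bias"])
        pred, ce = _nn.exp_forward(z)
        if not return_cache:
            return pred
        cache = {
            "w": w, "c1": c1, "m1": m1, "d1": d1,
            "c2": c2, "m2": m2, "d2": d2,
            "flat": flat, "h2_shape": h2.shape, "ce": ce,
        }
        return pred, cache

    def backward(self, grad_pred: np.ndarray, cache, need_input_grad: bool = False):
        """Backprop through the forward pass.

        Returns ``(param_grads, grad_input)`` where ``param_grads`` is keyed
        like ``mean_weights()``; ``grad_input`` is None unless
        ``need_input_grad`` (used for MEI synthesis).
        """
        w = cache["w"]
        dz = _nn.exp_backward(grad_pred, cache["ce"])
        dflat, gfw, gfb = _nn.fc_backward(dz, cache["flat"], w["fc.weight"])
        dh2 = dflat.reshape(cache["h2_shape"])
        if cache["d2"] is not None:
            dh2 = dh2 * cache["d2"]
        da2 = _nn.relu_backward(dh2, cache["m2"])
        dh1, g2w, g2b = _nn.conv_backward(da2, cache["c2"])
        if cache["d1"] is not None:
            dh1 = dh1 * cache["d1"]
        da1 = _nn.relu_backward(dh1, cache["m1"])
        dx, g1w, g1b = _nn.conv_backward(da1, cache["c1"],
                                         need_input_grad=need_input_grad)
        grads = {
            "conv1.weight": g1w, "conv1.bias": g1b,
            "conv2.weight": g2w, "conv2.bias": g2b,
            "fc.weight": gfw, "fc.bias": gfb,
        }
        return grads, dx

    def input_gradient(self, x: np.ndarray, neuron: int,
                       weights: Optional[dict] = None,
                       dropout_rng=None):
        """Gradient of one neuron's predicted activation w.r.t. the stimulus.

        Returns ``(activation, grad)`` for a single image ``x`` of shape
        (channels, h, w).
        """
        pred, cache = self.forward(x[None] if x.ndim == 3 else x,
                                   weights=weights, dropout_rng=dropout_rng,
                                   return_cache=True)
        grad_pred = np.zeros_like(pred)
        grad_pred[:, neuron] = 1.0
        _, dx = self.backward(grad_pred, cache, need_input_grad=True)
        return float(pred[0, neuron]), dx[0]

    # ------------------------------------------------------------ prediction
    def predict_mc(self, stimuli: np.ndarray, n_samples: int = 100,
                   rng: Optional[np.random.Generator] = None,
                   keep_samples: bool = False) -> PredictiveSummary:
        """Monte-Carlo predictive mean and std across weight/mask samples.

        Deterministic variants collapse to a single forward pass with zero
        std and ``single_sample=True``; the same convention applies for
        ``n_samples == 1``.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.is_stochastic:
            mean = self.forward(stimuli)
            return PredictiveSummary(
                mean=mean, std=np.zeros_like(mean),
                samples=mean[None] if keep_samples else None,
                single_sample=True,
            )
        if rng is None:
            rng = np.random.default_rng()
        draws = []
        for _ in range(n_samples):
            if self.is_variational:
                w, _ = self.sample_weight_draw(rng)
                draws.append(self.forward(stimuli, weights=w))
            else:
                draws.append(self.forward(stimuli, dropout_rng=rng))
        samples = np.stack(draws)
        mean = samples.mean(axis=0)
        if n_samples == 1:
            return PredictiveSummary(
                mean=mean, std=np.zeros_like(mean),
                samples=samples if keep_samples else None, single_sample=True,
            )
        std = samples.std(axis=0)
        return PredictiveSummary(
            mean=mean, std=std,
            samples=samples if keep_samples else None,
        )

    # ------------------------------------------------------------ checkpoint
    def state_dict(self) -> dict:
        if self.is_variational:
            out = {}
            for k, p in self.posteriors.items():
                out[k + ".mu"] = p.mu.copy()
                out[k + ".rho"] = p.rho.copy()
            return out
        return {k: v.copy() for k, v in self.weights.items()}

    def load_state_dict(self, state: dict):
        for k, v in self.trainable_params().items():
            v[...] = state[k]

    def save(self, path):
        """NPZ tensor archive with a JSON sidecar describing the config."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = {"config": self.config.to_dict()}
        if self.prior is not None:
            meta["prior"] = {
                "pi": self.prior.pi,
                "sigma1": self.prior.sigma1,
                "sigma2": self.prior.sigma2,
            }
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "ConvEncoder":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        config = EncoderConfig.from_dict(meta["config"])
        prior = ScaleMixturePrior(**meta["prior"]) if "prior" in meta else None
        enc = cls(config, prior=prior, seed=0)
        with np.load(path) as data:
            enc.load_state_dict({k: data[k] for k in data.files})
        return enc


def build_encoder(config: EncoderConfig, prior: Optional[ScaleMixturePrior] = None,
                  seed: int = 0) -> ConvEncoder:
    """Construct an encoder for the requested variant (thin factory)."""
    return ConvEncoder(config, prior=prior, seed=seed)


def ensemble_predict(encoders: Sequence[ConvEncoder], stimuli) -> PredictiveSummary:
    """Average the deterministic outputs of >= 2 encoders.

    The ensemble mean is the prediction; the across-member std is reported
    as the ensemble spread.
    """
    if len(encoders) < 2:
        raise ValueError("ensemble requires at least 2 encoders")
    outs = [e.forward(stimuli) for e in encoders]
    shapes = {o.shape for o in outs}
    if len(shapes) > 1:
        raise ValueError(f"ensemble members disagree on output shape: {shapes}")
    samples = np.stack(outs)
    return PredictiveSummary(mean=samples.mean(axis=0), std=samples.std(axis=0),
                             samples=samples)
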