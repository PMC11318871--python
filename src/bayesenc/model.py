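"""Model / results layer for fitting encoders to stimulus-response data.

``NeuralEncodingModel`` binds a :class:`StimulusResponseDataset` to an
encoder variant and its objective; ``fit`` runs seeded Adam training with
per-epoch validation and returns :class:`EncodingResults`, which carries the
best-epoch weights, the training history, evaluation metrics, and the
downstream analyses (Monte-Carlo prediction, MEI stacks, calibration,
sparsity) as methods.

Objective weighting convention: the Poisson NLL is summed over neurons and
averaged over the stimuli in a batch; KL/prior penalties are multiplied by
``kl_scale = 1 / n_batches`` so each is counted exactly once per pass over
the training data.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._nn import Adam
from .datasets import StimulusResponseDataset
from .encoders import ConvEncoder, EncoderConfig, PredictiveSummary
from .metrics import EvalReport, correlation_metric, evaluate
from .objectives import elbo_loss, map_loss, poisson_nll
from .variational import ScaleMixturePrior


def derive_rng(seed: int, *names) -> np.random.Generator:
    """Named, reproducible child generator of one global seed.

    Each pipeline stage (init, batching, MC draws, validation, MEI starts,
    permutations) gets its own stream so stages are independently
    reproducible.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))


def derive_seed(seed: int, *names) -> int:
    """Single integer (< 2^31) derived like :func:`derive_rng`."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    ss = np.random.SeedSequence([int(seed) % 2**31, *keys])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class TrainConfig:
    """Optimization settings (defaults: Adam, lr 3e-4, up to 200 epochs)."""

    lr: float = 3e-4
    max_epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    beta_v: float = 0.1
    data_fraction: float = 1.0
    n_samples: int = 1          # MC weight draws per training step
    val_mc_samples: int = 10    # MC draws for per-epoch validation CC

    def __post_init__(self):
        if self.lr <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, max_epochs and batch_size must be positive")
        if not 0.0 < self.data_fraction <= 1.0:
            raise ValueError("data_fraction must lie in (0, 1]")
        if self.beta_v < 0:
            raise ValueError("beta_v must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


class NeuralEncodingModel:
    """An encoder variant bound to a stimulus-response dataset.

    Parameters
    ----------
    dataset : StimulusResponseDataset
    variant : str
        One of baseline, l2l1, map, mc_dropout, variational.
    encoder_config : EncoderConfig, optional
        Defaults to an architecture sized from the dataset (16/16 channels,
        9x9 and 7x7 kernels when they fit).
    prior : ScaleMixturePrior, optional
        Defaults to (pi=0.5, sigma1=1, sigma2=exp(-6)) for variational/MAP.
    lambda2, lambda1 : float
        L2 (conv) and L1 (FC) coefficients for the l2l1 variant.
    dropout_rate : float
        Dropout probability for mc_dropout (same rate in every layer, active
        at train and test time).
    """

    def __init__(self, dataset: StimulusResponseDataset,
                 variant: str = "variational",
                 encoder_config: Optional[EncoderConfig] = None,
                 prior: Optional[ScaleMixturePrior] = None,
                 lambda2: float = 1e-3, lambda1: float = 1e-3,
                 dropout_rate: float = 0.5):
        self.dataset = dataset
        self.variant = variant
        if prior is None and variant in ("variational", "map"):
            prior = ScaleMixturePrior()
        self.prior = prior
        self.lambda2 = lambda2
        self.lambda1 = lambda1
        if encoder_config is None:
            encoder_config = self.default_config(dataset, variant, dropout_rate)
        self.encoder_config = encoder_config

    @staticmethod
    def default_config(dataset: StimulusResponseDataset, variant: str,
                       dropout_rate: float = 0.5) -> EncoderConfig:
        h, w = dataset.input_hw
        k1 = 9 if min(h, w) >= 16 else max(3, min(h, w) // 2)
        k2 = 7 if min(h - k1 + 1, w - k1 + 1) >= 10 else 3
        return EncoderConfig(
            in_channels=dataset.in_channels, input_hw=(h, w),
            n_neurons=dataset.n_neurons, conv1=(16, k1, k1), conv2=(16, k2, k2),
            variant=variant,
            dropout_rate=dropout_rate if variant == "mc_dropout" else 0.0,
        )

    # ------------------------------------------------------------------ fit
    def fit(self, config: Optional[TrainConfig] = None, verbose: bool = False,
            **kwargs) -> "EncodingResults":
        """Seeded Adam training with best-validation-epoch selection.

        Validation CC (mean over neurons) is computed each epoch — with
        ``val_mc_samples`` Monte-Carlo draws for stochastic variants — and
        the checkpoint with the highest validation CC is returned.  The
        entire run is a pure function of ``(dataset, config)``.
        """
        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a TrainConfig or keyword overrides")
        ds = self.dataset
        seed = config.seed

        enc = ConvEncoder(self.encoder_config, prior=self.prior,
                          seed=derive_seed(seed, "init"))

        n_train = ds.train_stimuli.shape[0]
        if config.data_fraction < 1.0:
            n_used = max(config.batch_size,
                         int(round(config.data_fraction * n_train)))
            idx = derive_rng(seed, "subsample").choice(n_train, size=n_used,
                                                       replace=False)
            train_s = ds.train_stimuli[idx]
            train_r = ds.train_responses[idx]
        else:
            train_s, train_r = ds.train_stimuli, ds.train_responses
        if train_s.shape[0] == 0 or ds.val_stimuli.shape[0] == 0:
            raise ValueError("empty train or validation split")

        n_used = train_s.shape[0]
        n_batches = int(np.ceil(n_used / config.batch_size))
        kl_scale = 1.0 / n_batches

        opt = Adam(enc.trainable_params(), lr=config.lr)
        batch_rng = derive_rng(seed, "batches")
        mc_rng = derive_rng(seed, "mc")

        history = []
        best_cc = -np.inf
        best_state = enc.state_dict()
        best_epoch = 0
        for epoch in range(config.max_epochs):
            order = batch_rng.permutation(n_used)
            ep_total = ep_kl = ep_nll = 0.0
            for b in range(n_batches):
                sl = order[b * config.batch_size:(b + 1) * config.batch_size]
                batch = (train_s[sl], train_r[sl])
                total, kl, nll, grads = self._batch_loss_grads(
                    enc, batch, config, kl_scale, mc_rng
                )
                opt.step(grads)
                ep_total += total
                ep_kl += kl
                ep_nll += nll
            val_cc = self._validation_cc(enc, config, epoch)
            history.append(dict(
                epoch=epoch, train_total=ep_total / n_batches,
                kl_term=ep_kl / n_batches, nll_term=ep_nll / n_batches,
                val_cc=val_cc,
            ))
            if val_cc > best_cc:
                best_cc = val_cc
                best_state = enc.state_dict()
                best_epoch = epoch
            if verbose:
                print(f"epoch {epoch:3d}  loss {ep_total / n_batches:10.3f}  "
                      f"val CC {val_cc:.4f}")
        enc.load_state_dict(best_state)
        return EncodingResults(
            model=self, encoder=enc, history=pd.DataFrame(history),
            best_epoch=best_epoch, best_val_cc=float(best_cc),
            train_config=config, n_train_used=n_used,
        )

    def _batch_loss_grads(self, enc, batch, config, kl_scale, mc_rng):
        variant = self.variant
        if variant == "variational":
            comps, grads = elbo_loss(
                enc, batch, beta_v=config.beta_v, n_samples=config.n_samples,
                kl_scale=kl_scale, rng=mc_rng, return_grads=True,
            )
            return comps.total, comps.kl_term, comps.nll_term, grads
        if variant == "map":
            total, grads = map_loss(enc, batch, self.prior, kl_scale=kl_scale,
                                    return_grads=True)
            return total, 0.0, total, grads
        # point-weight likelihood variants
        stim, resp = batch
        drng = mc_rng if variant == "mc_dropout" else None
        pred, cache = enc.forward(stim, dropout_rng=drng, return_cache=True)
        nll, dpred = poisson_nll(pred, resp, grad=True)
        grads, _ = enc.backward(dpred, cache)
        total = nll
        if variant == "l2l1":
            w = enc.weights
            pen = kl_scale * (
                self.lambda2 * (np.sum(w["conv1.weight"]**2)
                                + np.sum(w["conv2.weight"]**2))
                + self.lambda1 * np.sum(np.abs(w["fc.weight"]))
            )
            total = nll + float(pen)
            for k in ("conv1.weight", "conv2.weight"):
                grads[k] = grads[k] + kl_scale * 2.0 * self.lambda2 * w[k]
            grads["fc.weight"] = grads["fc.weight"] + kl_scale * self.lambda1 * np.sign(w["fc.weight"])
        return total, 0.0, nll, grads

    def _validation_cc(self, enc, config, epoch) -> float:
        ds = self.dataset
        rng = derive_rng(config.seed, "val", epoch)
        if enc.is_stochastic:
            summ = enc.predict_mc(ds.val_stimuli,
                                  n_samples=config.val_mc_samples, rng=rng)
            pred = summ.mean
        else:
            pred = enc.forward(ds.val_stimuli)
        return correlation_metric(pred, ds.val_responses)


class EncodingResults:
    """Fitted encoder with history, metrics and downstream analyses."""

    def __init__(self, model: NeuralEncodingModel, encoder: ConvEncoder,
                 history: pd.DataFrame, best_epoch: int, best_val_cc: float,
                 train_config: TrainConfig, n_train_used: int):
        self.model = model
        self.encoder = encoder
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_cc = best_val_cc
        self.train_config = train_config
        self.n_train_used = n_train_used

    # ------------------------------------------------------------ prediction
    def predict(self, stimuli=None) -> np.ndarray:
        """Deterministic forward pass (posterior means for variational)."""
        if stimuli is None:
            stimuli = self.model.dataset.test_stimuli
        return self.encoder.forward(stimuli)

    def predict_mc(self, stimuli=None, n_samples: int = 100,
                   seed: Optional[int] = None,
                   keep_samples: bool = False) -> PredictiveSummary:
        """Monte-Carlo predictive summary (100 samples by default)."""
        if stimuli is None:
            stimuli = self.model.dataset.test_stimuli
        rng = derive_rng(self.train_config.seed if seed is None else seed,
                         "predict")
        return self.encoder.predict_mc(stimuli, n_samples=n_samples, rng=rng,
                                       keep_samples=keep_samples)

    # ------------------------------------------------------------ evaluation
    def evaluate(self, n_samples: int = 100,
                 seed: Optional[int] = None) -> EvalReport:
        """CC / RMSE / log-likelihood against repeat-mean test responses."""
        ds = self.model.dataset
        obs = ds.test_means()
        if self.encoder.is_stochastic:
            summ = self.predict_mc(ds.test_stimuli, n_samples=n_samples,
                                   seed=seed, keep_samples=True)
        else:
            summ = self.encoder.predict_mc(ds.test_stimuli, n_samples=1)
        return evaluate(summ, obs)

    # -------------------------------------------------------------- analyses
    def sample_meis(self, neuron: int, n_samples: int = 100, steps: int = 100,
                    lr: float = 10.0, base_seed: Optional[int] = None):
        from .mei import sample_meis

        stats = self.model.dataset.image_stats
        if base_seed is None:
            base_seed = derive_seed(self.train_config.seed, "mei", neuron)
        return sample_meis(self.encoder, neuron, stats, n_samples=n_samples,
                           steps=steps, lr=lr, base_seed=base_seed)

    def mean_mei(self, neuron: int, steps: int = 100, lr: float = 10.0,
                 seed: Optional[int] = None):
        from .mei import generate_mei

        stats = self.model.dataset.image_stats
        rng = derive_rng(self.train_config.seed if seed is None else seed,
                         "mei-start", neuron)
        return generate_mei(self.encoder, neuron, stats, steps=steps, lr=lr,
                            rng=rng, weights=self.encoder.mean_weights())

    def calibration(self, n_samples: int = 100, levels=None,
                    seed: Optional[int] = None):
        from .uncertainty import calibration_curve

        ds = self.model.dataset
        summ = self.predict_mc(ds.test_stimuli, n_samples=n_samples, seed=seed,
                               keep_samples=True)
        return calibration_curve(summ.samples, ds.test_means(), levels=levels)

    def sparsity(self):
        from .uncertainty import sparsity_report

        return sparsity_report(self.encoder, beta_v=self.train_config.beta_v)

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        rep = self.evaluate(n_samples=50)
        lines = [
            "Neural encoding model results",
            "=" * 46,
            f"variant            : {self.model.variant}",
            f"neurons            : {self.model.dataset.n_neurons}",
            f"parameters         : {self.encoder.n_params}",
            f"training trials    : {self.n_train_used}",
            f"epochs run         : {len(self.history)}",
            f"best epoch (val CC): {self.best_epoch} ({self.best_val_cc:.4f})",
            "-" * 46,
            f"test CC            : {rep.cc:.4f}",
            f"test RMSE          : {rep.rmse:.4f}",
            f"test log-likelihood: {rep.loglik:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
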