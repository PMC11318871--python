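"""Linear-nonlinear-Poisson (LNP) simulator with known ground truth.

Generates populations of model neurons with Gabor or difference-of-Gaussians
receptive fields, drives them with white or pink-noise stimuli through
``rate = gain * nonlinearity(<filter, stimulus> + bias)``, and draws
Poisson responses.  Datasets mirror the structure of the recorded data:
single-trial train/validation splits plus a repeated test block.  Because
the generating filters are known, trained encoders can be scored by how
well their most exciting inputs recover them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datasets import ImageStats, RepeatBlock, StimulusResponseDataset

# Desk-scale default study conditions: 20 neurons, single-channel 18x18
# stimuli, 2000/200 train/validation trials, 50 test stimuli x 10 repeats.
DEFAULTS = dict(
    n_neurons=20, channels=1, hw=(18, 18),
    n_train=2000, n_val=200, n_test=50, n_repeats=10,
)


# --------------------------------------------------------------- stimuli
def generate_stimuli(n: int, channels: int, hw, kind: str = "gaussian_white",
                     seed: int = 0) -> np.ndarray:
    """Seeded stimulus ensemble, standardized to mean 0 / std 1 per channel.

    ``kind`` is ``gaussian_white`` (iid pixels) or ``pink_noise`` (amplitude
    spectrum ~ 1/f).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = hw
    if h < 1 or w < 1:
        raise ValueError(f"invalid stimulus size {hw}")
    rng = np.random.default_rng(seed)
    if kind == "gaussian_white":
        x = rng.standard_normal((n, channels, h, w))
    elif kind == "pink_noise":
        white = rng.standard_normal((n, channels, h, w))
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        f = np.sqrt(fy**2 + fx**2)
        f[0, 0] = 1.0  # leave DC unscaled; removed by standardization
        amp = 1.0 / f
        x = np.fft.ifft2(np.fft.fft2(white, axes=(2, 3)) * amp, axes=(2, 3)).real
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    mean = x.mean(axis=(0, 2, 3), keepdims=True)
    std = x.std(axis=(0, 2, 3), keepdims=True)
    return (x - mean) / std


# --------------------------------------------------------------- filters
def gabor_filter(hw, center, sigma: float, wavelength: float, theta: float,
                 phase: float = 0.0) -> np.ndarray:
    """A Gabor patch on an (h, w) grid, normalized to unit L2 norm."""
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yy -= center[0]
    xx -= center[1]
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    g = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * xr / wavelength + phase
    )
    g -= g.mean() * (np.abs(g) > 0)
    norm = np.linalg.norm(g)
    return g / norm if norm > 0 else g


def dog_filter(hw, center, sigma_c: float, sigma_s: float,
               polarity: float = 1.0) -> np.ndarray:
    """Difference-of-Gaussians (center-surround) filter, unit L2 norm."""
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    g = polarity * (
        np.exp(-d2 / (2 * sigma_c**2)) / sigma_c**2
        - np.exp(-d2 / (2 * sigma_s**2)) / sigma_s**2
    )
    norm = np.linalg.norm(g)
    return g / norm if norm > 0 else g


@dataclass
class GroundTruthPopulation:
    """Known LNP neurons: filters, biases, static nonlinearity, gain."""

    filters: np.ndarray  # (neurons, channels, h, w), unit-norm per neuron
    bias: np.ndarray
    nonlinearity: str = "exp"
    gain: float = 1.0
    rate_max: float = 50.0

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        self.bias = np.atleast_1d(np.asarray(self.bias, dtype=float))
        if self.filters.ndim != 4:
            raise ValueError("filters must be (neurons, channels, h, w)")
        if self.bias.shape[0] != self.filters.shape[0]:
            raise ValueError("bias length must equal neuron count")
        if self.nonlinearity not in ("exp", "softplus"):
            raise ValueError("nonlinearity must be 'exp' or 'softplus'")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_neurons(self) -> int:
        return self.filters.shape[0]

    def rates(self, stimuli) -> np.ndarray:
        """Firing rates (trials, neurons), clipped at ``rate_max``."""
        s = np.asarray(stimuli, dtype=float)
        drive = np.tensordot(s, self.filters, axes=([1, 2, 3], [1, 2, 3]))
        drive = drive + self.bias
        if self.nonlinearity == "exp":
            rate = self.gain * np.exp(drive)
        else:
            rate = self.gain * np.log1p(np.exp(np.minimum(drive, 30.0)))
        if np.any(rate > self.rate_max):
            warnings.warn(
                "rates clipped at rate_max "
                f"({int((rate > self.rate_max).sum())} entries)", stacklevel=2,
            )
            rate = np.minimum(rate, self.rate_max)
        return rate


def make_population(n_neurons: int = DEFAULTS["n_neurons"],
                    channels: int = DEFAULTS["channels"],
                    hw=DEFAULTS["hw"], seed: int = 0, kind: str = "gabor",
                    filter_scale: float = 1.0, gain: float = 1.0,
                    bias: float = 0.0) -> GroundTruthPopulation:
    """Random population with receptive fields well inside the image.

    Gabor parameters are drawn so the envelope (sigma 1.5-2.5 px) sits at
    least ~4 px from the border, keeping MEI localization assertable.
    """
    rng = np.random.default_rng(seed)
    h, w = hw
    filters = np.zeros((n_neurons, channels, h, w))
    margin = max(2, min(5, min(h, w) // 2 - 1))
    for i in range(n_neurons):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ch = int(rng.integers(0, channels))
        if kind == "gabor":
            f = gabor_filter(
                hw, (cy, cx),
                sigma=rng.uniform(1.5, 2.5),
                wavelength=rng.uniform(4.0, 8.0),
                theta=rng.uniform(0, np.pi),
                phase=rng.uniform(0, 2 * np.pi),
            )
        elif kind == "dog":
            f = dog_filter(hw, (cy, cx), sigma_c=rng.uniform(1.0, 1.8),
                           sigma_s=rng.uniform(2.5, 4.0),
                           polarity=float(rng.choice([-1.0, 1.0])))
        else:
            raise ValueError(f"unknown filter kind {kind!r}")
        filters[i, ch] = filter_scale * f
    return GroundTruthPopulation(
        filters=filters, bias=np.full(n_neurons, float(bias)), gain=gain,
    )


def simulate_responses(pop: GroundTruthPopulation, stimuli,
                       noise: str = "poisson", repeats: int = 1,
                       seed: int = 0) -> np.ndarray:
    """Responses for each stimulus: (trials, neurons) or (trials, repeats, neurons).

    ``noise='poisson'`` draws Poisson counts around the LNP rates;
    ``noise='none'`` returns the rates themselves.
    """
    rate = pop.rates(stimuli)
    if noise == "none":
        out = np.repeat(rate[:, None, :], repeats, axis=1)
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        out = rng.poisson(np.repeat(rate[:, None, :], repeats, axis=1)).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return out[:, 0, :] if repeats == 1 else out


def make_dataset(n_neurons: int = DEFAULTS["n_neurons"],
                 channels: int = DEFAULTS["channels"], hw=DEFAULTS["hw"],
                 n_train: int = DEFAULTS["n_train"], n_val: int = DEFAULTS["n_val"],
                 n_test: int = DEFAULTS["n_test"],
                 n_repeats: int = DEFAULTS["n_repeats"], seed: int = 0,
                 stimulus_kind: str = "gaussian_white", filter_kind: str = "gabor",
                 noise: str = "poisson", gain: float = 1.0, bias: float = 0.0,
                 pop: Optional[GroundTruthPopulation] = None):
    """Full synthetic dataset plus its generating population.

    Splits use disjoint stimulus draws; test responses carry ``n_repeats``
    Poisson repeats.  The whole dataset is a pure function of
    ``(seed, parameters)``.

    Returns ``(StimulusResponseDataset, GroundTruthPopulation)``.
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_tr, s_va, s_te, s_rtr, s_rva, s_rte = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7)
    ]
    if pop is None:
        pop = make_population(n_neurons, channels, hw, seed=s_pop,
                              kind=filter_kind, gain=gain, bias=bias)
    train_s = generate_stimuli(n_train, channels, hw, stimulus_kind, seed=s_tr)
    val_s = generate_stimuli(n_val, channels, hw, stimulus_kind, seed=s_va)
    test_s = generate_stimuli(n_test, channels, hw, stimulus_kind, seed=s_te)
    train_r = simulate_responses(pop, train_s, noise=noise, seed=s_rtr)
    val_r = simulate_responses(pop, val_s, noise=noise, seed=s_rva)
    test_r = simulate_responses(pop, test_s, noise=noise, repeats=n_repeats,
                                seed=s_rte)
    ds = StimulusResponseDataset(
        train_stimuli=train_s, train_responses=train_r,
        val_stimuli=val_s, val_responses=val_r,
        test_stimuli=test_s, test_block=RepeatBlock(test_r),
        metadata=dict(
            seed=seed, n_neurons=pop.n_neurons, channels=channels,
            hw=list(hw), n_train=n_train, n_val=n_val, n_test=n_test,
            n_repeats=n_repeats, stimulus_kind=stimulus_kind,
            filter_kind=filter_kind, noise=noise, gain=pop.gain,
        ),
    )
    return ds, pop


def filter_cosine_similarity(mei: np.ndarray, gt_filter: np.ndarray) -> float:
    """Cosine similarity between mean-subtracted MEI and ground-truth filter."""
    a = np.asarray(mei, dtype=float).ravel()
    b = np.asarray(gt_filter, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def recovery_check(encoder, pop: GroundTruthPopulation, stats: ImageStats,
                   steps: int = 100, lr: float = 10.0, seed: int = 0,
                   weights: Optional[dict] = None):
    """Score filter recovery: per-neuron MEI vs ground-truth cosine.

    MEIs are generated from the encoder's deterministic (mean) weights.
    Returns ``(per_neuron_scores, median)``; an untrained encoder simply
    scores near zero.
    """
    from .mei import generate_mei

    scores = np.zeros(pop.n_neurons)
    for i in range(pop.n_neurons):
        img, _ = generate_mei(encoder, i, stats, steps=steps, lr=lr,
                              rng=np.random.default_rng(seed + i),
                              weights=weights)
        scores[i] = filter_cosine_similarity(img, pop.filters[i])
    return scores, float(np.median(scores))
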