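"""Most exciting inputs (MEIs) with uncertainty.

An MEI is a stimulus that maximizes one model neuron's predicted response,
found by projected gradient ascent: each step ascends the activation and
re-normalizes the image to the training-set per-channel mean and std, and
the best iterate (including the start) is returned.

For stochastic encoders a *stack* of MEIs is obtained by freezing one
posterior weight draw (or dropout mask) per optimization run.  The stack's
per-pixel variance map summarizes epistemic uncertainty about the learned
transfer function; its mean over pixels is the neuron's MEI variance
``E[Var[C]_s]_hw`` (population-variance convention along the sample axis s).
A pixelwise sign-flip permutation test against zero marks where the MEI
significantly deviates from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import h5py
import numpy as np

from .datasets import ImageStats


def normalize_to_stats(image: np.ndarray, stats: ImageStats) -> np.ndarray:
    """Project an image onto the prescribed per-channel mean/std."""
    img = np.asarray(image, dtype=float)
    out = np.empty_like(img)
    for c in range(img.shape[0]):
        m = img[c].mean()
        s = img[c].std()
        if s == 0:
            out[c] = stats.mean[c]
        else:
            out[c] = (img[c] - m) / s * stats.std[c] + stats.mean[c]
    return out


@dataclass
class MEIStack:
    """Per-neuron matrix of sampled MEIs with derived uncertainty maps."""

    images: np.ndarray       # (s, channels, h, w)
    activations: np.ndarray  # (s,)
    variance_map: np.ndarray  # (channels, h, w), population variance over s
    mei_variance: float       # mean over (channels, h, w) of variance_map
    neuron: int = 0
    metadata: dict = None

    def save(self, path):
        """HDF5 archive (images, activations, variance_map) + JSON metadata."""
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.create_dataset("activations", data=self.activations)
            f.create_dataset("variance_map", data=self.variance_map)
            f.attrs["mei_variance"] = self.mei_variance
            f.attrs["neuron"] = self.neuron
            f.attrs["metadata"] = json.dumps(self.metadata or {})

    @classmethod
    def load(cls, path) -> "MEIStack":
        with h5py.File(path, "r") as f:
            return cls(
                images=f["images"][...],
                activations=f["activations"][...],
                variance_map=f["variance_map"][...],
                mei_variance=float(f.attrs["mei_variance"]),
                neuron=int(f.attrs["neuron"]),
                metadata=json.loads(f.attrs.get("metadata", "{}")),
            )


@dataclass
class SignificanceMap:
    """Pixelwise two-sided permutation p-values with an alpha mask."""

    p_values: np.ndarray  # (channels, h, w), in (0, 1]
    mask: np.ndarray      # boolean, True where p < alpha
    alpha: float = 0.01


def generate_mei(encoder, neuron: int, stats: ImageStats, steps: int = 100,
                 lr: float = 10.0, rng: Optional[np.random.Generator] = None,
                 weights: Optional[dict] = None,
                 dropout_seed: Optional[int] = None,
                 start: Optional[np.ndarray] = None):
    """Single MEI by projected gradient ascent.

    Starts from seeded Gaussian noise normalized to ``stats``; each of
    ``steps`` updates ascends the neuron's predicted activation with step
    size ``lr`` and re-projects onto the prescribed image statistics.  The
    iterate with the highest activation (the start included) is returned as
    ``(image, activation)``.

    ``weights`` freezes a specific weight draw (posterior sample or mean);
    ``dropout_seed`` freezes the dropout mask across all steps so the
    network stays fixed during one MEI's optimization.
    """
    if rng is None:
        rng = np.random.default_rng()
    cfg = encoder.config
    if not 0 <= neuron < cfg.n_neurons:
        raise ValueError(f"neuron index {neuron} out of range")
    if start is None:
        start = rng.standard_normal((cfg.in_channels, *cfg.input_hw))
    x = normalize_to_stats(start, stats)

    def eval_grad(img):
        drng = (np.random.default_rng(dropout_seed)
                if dropout_seed is not None else None)
        return encoder.input_gradient(img, neuron, weights=weights,
                                      dropout_rng=drng)

    best_act, grad = eval_grad(x)
    best_img = x.copy()
    for _ in range(steps):
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"non-finite MEI gradient for neuron {neuron}; aborting ascent"
            )
        x = normalize_to_stats(x + lr * grad, stats)
        act, grad = eval_grad(x)
        if act > best_act:
            best_act = act
            best_img = x.copy()
    return best_img, float(best_act)


def sample_meis(encoder, neuron: int, stats: ImageStats, n_samples: int = 100,
                base_seed: int = 0, steps: int = 100, lr: float = 10.0,
                share_start: bool = False,
                start_seed: Optional[int] = None) -> MEIStack:
    """MEI stack over frozen posterior samples.

    For sample ``i`` the encoder's stochastic element (weight draw or
    dropout mask) is seeded with ``base_seed + i`` and held fixed for that
    MEI's entire optimization.  Start noise comes from an independent seed
    stream so that weight uncertainty, not initialization, drives the spread
    (``share_start=True`` reuses one start across samples to measure the
    degenerate case).
    """
    if n_samples < 2:
        raise ValueError("MEI variance needs n_samples >= 2")
    if start_seed is None:
        start_seed = base_seed + 990_007  # independent of the weight seeds
    images, acts = [], []
    for i in range(n_samples):
        srng = np.random.default_rng(start_seed if share_start
                                     else start_seed + i)
        if encoder.is_variational:
            w, _ = encoder.sample_weight_draw(np.random.default_rng(base_seed + i))
            img, a = generate_mei(encoder, neuron, stats, steps=steps, lr=lr,
                                  rng=srng, weights=w)
        else:
            img, a = generate_mei(encoder, neuron, stats, steps=steps, lr=lr,
                                  rng=srng, weights=encoder.mean_weights(),
                                  dropout_seed=base_seed + i)
        images.append(img)
        acts.append(a)
    images = np.stack(images)
    vmap = images.var(axis=0)  # population variance along the sample axis
    return MEIStack(
        images=images, activations=np.asarray(acts), variance_map=vmap,
        mei_variance=float(vmap.mean()), neuron=neuron,
        metadata={"base_seed": base_seed, "start_seed": start_seed,
                  "steps": steps, "lr": lr, "share_start": share_start},
    )


def mei_variance(images: np.ndarray) -> float:
    """``E[Var[C]_s]_hw``: mean over pixels of across-sample variance."""
    images = np.asarray(images, dtype=float)
    return float(images.var(axis=0).mean())


def significance_map(stack, n_perm: int = 10_000, alpha: float = 0.01,
                     rng: Optional[np.random.Generator] = None,
                     bonferroni: bool = False,
                     chunk_elems: int = 10_000_000) -> SignificanceMap:
    """One-sample two-sided sign-flip permutation test per pixel.

    The statistic at each pixel is the mean over the s sampled MEIs; the
    null flips the sign of each sample independently per pixel.  P-values
    use the add-one correction.  No multiple-testing correction by default
    (``bonferroni=True`` scales alpha by the pixel count).
    """
    images = stack.images if isinstance(stack, MEIStack) else np.asarray(stack)
    if images.shape[0] < 2:
        raise ValueError("significance map needs at least 2 samples")
    if rng is None:
        rng = np.random.default_rng()
    s = images.shape[0]
    map_shape = images.shape[1:]
    vals = images.reshape(s, -1)
    n_pix = vals.shape[1]
    obs = np.abs(vals.mean(axis=0))
    counts = np.zeros(n_pix, dtype=np.int64)
    chunk = max(1, chunk_elems // (n_perm * s))
    for start in range(0, n_pix, chunk):
        v = vals[:, start:start + chunk]
        flips = rng.integers(0, 2, size=(n_perm, s, v.shape[1]),
                             dtype=np.int8) * 2 - 1
        perm = np.abs(np.einsum("nsk,sk->nk", flips, v)) / s
        tol = 1e-12 * (1.0 + obs[start:start + chunk])
        counts[start:start + chunk] = np.sum(
            perm >= obs[start:start + chunk] - tol, axis=0
        )
    p = ((counts + 1) / (n_perm + 1)).reshape(map_shape)
    level = alpha / n_pix if bonferroni else alpha
    return SignificanceMap(p_values=p, mask=p < level, alpha=level)


def activation_matrix(encoder, meis: np.ndarray,
                      weights: Optional[dict] = None) -> np.ndarray:
    """Cross-activation matrix: row i = neuron i's responses to all MEIs.

    ``meis`` holds one MEI per neuron, ordered by neuron index.  Entry
    (i, j) is neuron i's predicted response to neuron j's MEI; each row is
    divided by its maximum so the best stimulus per neuron scores 1.
    """
    meis = np.asarray(meis, dtype=float)
    if meis.shape[0] != encoder.config.n_neurons:
        raise ValueError("need exactly one MEI per neuron")
    preds = encoder.forward(meis, weights=weights)  # (n_meis, n_neurons)
    mat = preds.T  # rows: neurons, cols: MEIs
    row_max = mat.max(axis=1, keepdims=True)
    if np.any(row_max <= 0):
        raise ValueError("non-positive row maximum in activation matrix")
    return mat / row_max


def mei_ensemble_protocol(variational_encoders: Sequence,
                          l2l1_encoders: Sequence, neuron: int,
                          stats: ImageStats, n_samples: int = 100,
                          steps: int = 100, lr: float = 10.0,
                          base_seed: int = 0):
    """MEI ensembles from five seeds per model family.

    For each of the five variational encoders: ``n_samples`` posterior-
    sampled MEIs plus one mean-weight MEI; the pixelwise average of the five
    mean MEIs (re-normalized to ``stats``) is appended, giving
    ``5 * (n_samples + 1) + 1`` images (506 at the default 100 samples).
    For the five L2+L1 encoders: one MEI each plus their re-normalized
    average, giving 6.

    Returns ``(variational_meis, l2l1_meis)`` as stacked arrays.
    """
    if len(variational_encoders) != 5 or len(l2l1_encoders) != 5:
        raise ValueError("protocol requires exactly 5 encoders per family")
    var_meis = []
    mean_meis = []
    for s_idx, enc in enumerate(variational_encoders):
        stack = sample_meis(enc, neuron, stats, n_samples=n_samples,
                            base_seed=base_seed + 1000 * s_idx, steps=steps,
                            lr=lr)
        var_meis.extend(stack.images)
        img, _ = generate_mei(enc, neuron, stats, steps=steps, lr=lr,
                              rng=np.random.default_rng(base_seed + 77 + s_idx),
                              weights=enc.mean_weights())
        var_meis.append(img)
        mean_meis.append(img)
    var_meis.append(normalize_to_stats(np.mean(mean_meis, axis=0), stats))

    l2l1_meis = []
    for s_idx, enc in enumerate(l2l1_encoders):
        img, _ = generate_mei(enc, neuron, stats, steps=steps, lr=lr,
                              rng=np.random.default_rng(base_seed + 177 + s_idx))
        l2l1_meis.append(img)
    l2l1_meis.append(normalize_to_stats(np.mean(l2l1_meis, axis=0), stats))
    return np.stack(var_meis), np.stack(l2l1_meis)


def export_map_png(image: np.ndarray, path, title: str = ""):
    """Save a spatial map as PNG with a diverging red-positive colormap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[0]
    lim = np.abs(img).max() or 1.0
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(img, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
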