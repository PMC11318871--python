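"""MEI generation, stacks, significance maps, activation experiments."""

import numpy as np
import pytest

from bayesenc.datasets import ImageStats
from bayesenc.encoders import ConvEncoder, EncoderConfig
from bayesenc.mei import (MEIStack, activation_matrix, generate_mei,
                          mei_ensemble_protocol, mei_variance,
                          normalize_to_stats, sample_meis, significance_map)
from bayesenc.variational import ScaleMixturePrior

STATS = ImageStats(mean=np.array([0.0]), std=np.array([1.0]))


def build_linear_toy(filters: np.ndarray, scale: float = 0.2,
                     variant: str = "l2l1") -> ConvEncoder:
    """Encoder computing exp(scale * <f_i, x>) per neuron.

    conv1 holds one full-size kernel per neuron with a large positive bias
    so both ReLUs operate in their linear range; conv2 is a 1x1 identity and
    the FC layer subtracts the bias again.
    """
    n, c, h, w = filters.shape
    cfg = EncoderConfig(in_channels=c, input_hw=(h, w), n_neurons=n,
                        conv1=(n, h, w), conv2=(n, 1, 1), variant=variant)
    enc = ConvEncoder(cfg, seed=0)
    enc.weights["conv1.weight"][...] = scale * filters
    enc.weights["conv1.bias"][...] = 5.0
    enc.weights["conv2.weight"][...] = np.eye(n)[:, :, None, None]
    enc.weights["conv2.bias"][...] = 0.0
    enc.weights["fc.weight"][...] = np.eye(n)
    enc.weights["fc.bias"][...] = -5.0
    return enc


def random_filter(hw, seed):
    f = np.random.default_rng(seed).standard_normal((1, *hw))
    return f / np.linalg.norm(f)


class TestGenerateMEI:
    def test_activation_never_below_start(self):
        f = random_filter((8, 8), 0)
        enc = build_linear_toy(f[None])
        rng = np.random.default_rng(1)
        start = normalize_to_stats(rng.standard_normal((1, 8, 8)), STATS)
        img, act = generate_mei(enc, 0, STATS, steps=10, lr=10.0,
                                rng=np.random.default_rng(1))
        assert act >= enc.forward(start[None])[0, 0] - 1e-12

    def test_linear_toy_recovers_filter(self):
        """For exp(<f, x>) under fixed mean/std, the optimum is the
        mean-removed filter direction."""
        f = random_filter((10, 10), 3)
        enc = build_linear_toy(f[None])
        img, _ = generate_mei(enc, 0, STATS, steps=100, lr=10.0,
                              rng=np.random.default_rng(0))
        a = (img - img.mean()).ravel()
        b = (f - f.mean()).ravel()
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos > 0.99

    def test_zero_weight_encoder_keeps_start(self):
        cfg = EncoderConfig(in_channels=1, input_hw=(8, 8), n_neurons=2,
                            conv1=(2, 3, 3), conv2=(2, 3, 3),
                            variant="baseline")
        enc = ConvEncoder(cfg, seed=0)
        for k in enc.weights:
            enc.weights[k][...] = 0.0
        img, act = generate_mei(enc, 0, STATS, steps=5, lr=10.0,
                                rng=np.random.default_rng(2))
        assert act == pytest.approx(1.0)
        start = normalize_to_stats(
            np.random.default_rng(2).standard_normal((1, 8, 8)), STATS)
        np.testing.assert_allclose(img, start)

    def test_output_matches_image_stats(self):
        f = random_filter((8, 8), 1)
        enc = build_linear_toy(f[None])
        stats = ImageStats(mean=np.array([0.3]), std=np.array([1.7]))
        img, _ = generate_mei(enc, 0, stats, steps=20, lr=10.0,
                              rng=np.random.default_rng(0))
        assert abs(img[0].mean() - 0.3) < 1e-6
        assert abs(img[0].std() - 1.7) < 1e-6

    def test_invalid_neuron_raises(self):
        enc = build_linear_toy(random_filter((8, 8), 0)[None])
        with pytest.raises(ValueError):
            generate_mei(enc, 5, STATS)


class TestMEIStack:
    def _variational_toy(self, rho=-40.0):
        cfg = EncoderConfig(in_channels=1, input_hw=(8, 8), n_neurons=2,
                            conv1=(2, 3, 3), conv2=(2, 3, 3),
                            variant="variational")
        enc = ConvEncoder(cfg, prior=ScaleMixturePrior(), seed=7)
        for p in enc.posteriors.values():
            p.rho[...] = rho
        return enc

    def test_degenerate_posterior_zero_variance(self):
        enc = self._variational_toy(rho=-40.0)
        stack = sample_meis(enc, 0, STATS, n_samples=3, steps=5,
                            base_seed=0, share_start=True)
        assert stack.mei_variance == pytest.approx(0.0, abs=1e-20)

    def test_two_point_variance(self):
        imgs = np.zeros((2, 1, 4, 4))
        imgs[1] += 3.0
        assert mei_variance(imgs) == pytest.approx(9.0 / 4.0)

    def test_matches_brute_force_pixel_loop(self):
        imgs = np.random.default_rng(0).standard_normal((6, 1, 5, 5))
        brute = np.zeros((1, 5, 5))
        for c in range(1):
            for i in range(5):
                for j in range(5):
                    brute[c, i, j] = np.var(imgs[:, c, i, j])
        assert mei_variance(imgs) == pytest.approx(brute.mean(), abs=1e-10)

    def test_sample_permutation_invariant_and_zero_iff_identical(self):
        imgs = np.random.default_rng(1).standard_normal((5, 1, 4, 4))
        perm = imgs[np.random.default_rng(2).permutation(5)]
        assert mei_variance(imgs) == pytest.approx(mei_variance(perm))
        same = np.repeat(imgs[:1], 5, axis=0)
        assert mei_variance(same) == pytest.approx(0.0, abs=1e-30)
        assert mei_variance(imgs) > 0.0

    def test_requires_two_samples(self):
        enc = self._variational_toy()
        with pytest.raises(ValueError):
            sample_meis(enc, 0, STATS, n_samples=1)

    def test_stack_round_trip(self, tmp_path):
        enc = self._variational_toy(rho=-2.0)
        stack = sample_meis(enc, 1, STATS, n_samples=3, steps=3, base_seed=1)
        path = tmp_path / "stack.h5"
        stack.save(path)
        loaded = MEIStack.load(path)
        np.testing.assert_array_equal(loaded.images, stack.images)
        assert loaded.mei_variance == stack.mei_variance
        assert loaded.neuron == 1


class TestSignificanceMap:
    def test_constant_positive_pixels_significant(self):
        imgs = np.full((50, 1, 3, 3), 0.5)
        sig = significance_map(imgs, n_perm=2000, alpha=0.01,
                               rng=np.random.default_rng(0))
        assert np.all(sig.p_values <= 2.0 / 2001 + 1e-12)
        assert sig.mask.all()

    def test_zero_pixels_not_significant(self):
        imgs = np.zeros((50, 1, 3, 3))
        sig = significance_map(imgs, n_perm=500,
                               rng=np.random.default_rng(0))
        np.testing.assert_allclose(sig.p_values, 1.0)
        assert not sig.mask.any()

    def test_null_false_positive_rate(self):
        imgs = np.random.default_rng(3).standard_normal((40, 1, 40, 50))
        sig = significance_map(imgs, n_perm=1000, alpha=0.05,
                               rng=np.random.default_rng(4))
        rate = sig.mask.mean()
        # 2000 pixels at alpha 0.05: binomial 99.9% band
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_bonferroni_tightens_mask(self):
        imgs = np.random.default_rng(5).standard_normal((30, 1, 8, 8)) + 0.3
        rng = np.random.default_rng(6)
        raw = significance_map(imgs, n_perm=500, alpha=0.05, rng=rng)
        bonf = significance_map(imgs, n_perm=500, alpha=0.05,
                                rng=np.random.default_rng(6), bonferroni=True)
        assert bonf.mask.sum() <= raw.mask.sum()


class TestActivationMatrix:
    def test_rows_normalized_to_one(self):
        filters = np.stack([random_filter((8, 8), s) for s in range(3)])
        enc = build_linear_toy(filters)
        meis = np.stack([
            generate_mei(enc, i, STATS, steps=30, lr=10.0,
                         rng=np.random.default_rng(i))[0]
            for i in range(3)
        ])
        mat = activation_matrix(enc, meis)
        np.testing.assert_allclose(mat.max(axis=1), 1.0)

    def test_single_neuron(self):
        enc = build_linear_toy(random_filter((8, 8), 0)[None])
        mei = generate_mei(enc, 0, STATS, steps=10, lr=10.0,
                           rng=np.random.default_rng(0))[0]
        mat = activation_matrix(enc, mei[None])
        np.testing.assert_allclose(mat, [[1.0]])

    def test_diagonal_dominance_for_disjoint_filters(self):
        """With spatially disjoint receptive fields each neuron is driven
        best by its own MEI."""
        hw = (12, 12)
        filters = np.zeros((4, 1, *hw))
        centers = [(3, 3), (3, 9), (9, 3), (9, 9)]
        for i, (cy, cx) in enumerate(centers):
            patch = np.random.default_rng(i).standard_normal((3, 3))
            filters[i, 0, cy - 1:cy + 2, cx - 1:cx + 2] = patch / np.linalg.norm(patch)
        enc = build_linear_toy(filters)
        meis = np.stack([
            generate_mei(enc, i, STATS, steps=50, lr=10.0,
                         rng=np.random.default_rng(10 + i))[0]
            for i in range(4)
        ])
        mat = activation_matrix(enc, meis)
        diag_best = np.argmax(mat, axis=1) == np.arange(4)
        assert diag_best.mean() > 0.8


class TestEnsembleProtocol:
    def _families(self, hw=(8, 8)):
        f = random_filter(hw, 0)
        cfg = EncoderConfig(in_channels=1, input_hw=hw, n_neurons=1,
                            conv1=(1, hw[0], hw[1]), conv2=(1, 1, 1),
                            variant="variational")
        var_encs = []
        for s in range(5):
            enc = ConvEncoder(cfg, prior=ScaleMixturePrior(), seed=s)
            enc.posteriors["conv1.weight"].mu[...] = 0.2 * f[None]
            enc.posteriors["conv1.bias"].mu[...] = 5.0
            enc.posteriors["conv2.weight"].mu[...] = 1.0
            enc.posteriors["fc.weight"].mu[...] = 1.0
            enc.posteriors["fc.bias"].mu[...] = -5.0
            for p in enc.posteriors.values():
                p.rho[...] = -6.0
            var_encs.append(enc)
        l2l1_encs = [build_linear_toy(f[None]) for _ in range(5)]
        return var_encs, l2l1_encs

    def test_counts_506_and_6(self):
        var_encs, l2l1_encs = self._families()
        var_meis, l2l1_meis = mei_ensemble_protocol(
            var_encs, l2l1_encs, neuron=0, stats=STATS, n_samples=100,
            steps=3, lr=10.0, base_seed=0,
        )
        assert var_meis.shape[0] == 506  # 5 * (100 + 1) + 1
        assert l2l1_meis.shape[0] == 6   # 5 + 1

    def test_wrong_family_size_raises(self):
        var_encs, l2l1_encs = self._families()
        with pytest.raises(ValueError):
            mei_ensemble_protocol(var_encs[:4], l2l1_encs, 0, STATS,
                                  n_samples=2, steps=1)

    def test_all_outputs_match_stats(self):
        var_encs, l2l1_encs = self._families()
        var_meis, l2l1_meis = mei_ensemble_protocol(
            var_encs, l2l1_encs, neuron=0, stats=STATS, n_samples=2,
            steps=5, base_seed=1,
        )
        for batch in (var_meis, l2l1_meis):
            np.testing.assert_allclose(batch.mean(axis=(2, 3)), 0.0, atol=1e-6)
            np.testing.assert_allclose(
                batch.std(axis=(2, 3)), 1.0, atol=1e-6
            )

    def test_identical_l2l1_members_converge_to_same_mei(self):
        """With one shared deterministic encoder and a unique optimum the
        five member MEIs coincide after convergence."""
        _, l2l1_encs = self._families()
        _, l2l1_meis = mei_ensemble_protocol(
            self._families()[0], l2l1_encs, neuron=0, stats=STATS,
            n_samples=2, steps=150, base_seed=2,
        )
        spread = l2l1_meis[:5].std(axis=0).max()
        assert spread < 0.05
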