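"""Loss functions: Poisson NLL, tempered ELBO, MAP loss, L2+L1 penalty."""

import numpy as np
import pytest

from bayesenc.encoders import ConvEncoder, EncoderConfig
from bayesenc.objectives import (elbo_loss, l2l1_penalty, map_loss,
                                 poisson_nll)
from bayesenc.variational import (ScaleMixturePrior, gaussian_kl,
                                  log_posterior_density, softplus_scale)


class TestPoissonNLL:
    @pytest.mark.parametrize("pred, target, expected", [
        (1.0, 0.0, 1.0),                    # log term vanishes
        (1.0, 1.0, 1.0),                    # log 1 = 0
        (2.0, 3.0, 2.0 - 3.0 * np.log(2.0)),  # ~ -0.0794
    ])
    def test_single_entry(self, pred, target, expected):
        got = poisson_nll(np.array([[pred]]), np.array([[target]]))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_target_raises(self):
        with pytest.raises(ValueError):
            poisson_nll(np.ones((1, 1)), -np.ones((1, 1)))

    def test_negative_pred_raises(self):
        with pytest.raises(ValueError):
            poisson_nll(-np.ones((1, 1)), np.ones((1, 1)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            poisson_nll(np.ones((2, 3)), np.ones((2, 2)))

    def test_minimized_at_target(self):
        """For each observed r, the loss over rhat is minimal at rhat = r."""
        target = 2.5
        grid = np.linspace(0.5, 6.0, 1101)
        losses = [poisson_nll(np.array([[g]]), np.array([[target]]))
                  for g in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(target, abs=0.01)

    def test_floor_guards_log(self):
        val = poisson_nll(np.zeros((1, 1)), np.ones((1, 1)))
        assert np.isfinite(val)


class TestL2L1Penalty:
    def test_zero_weights(self):
        assert l2l1_penalty([np.zeros((2, 2))], np.zeros(3), 1.0, 1.0) == 0.0

    def test_single_conv_weight(self):
        assert l2l1_penalty([np.array([2.0])], None, 0.5, 0.0) == 2.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        convs = [rng.normal(size=(3, 2, 2)), rng.normal(size=(4,))]
        fc = rng.normal(size=(5, 6))
        lam2, lam1 = 0.3, 0.7
        brute = 0.0
        for w in convs:
            for v in w.ravel():
                brute += lam2 * v * v
        for v in fc.ravel():
            brute += lam1 * abs(v)
        got = l2l1_penalty(convs, fc, lam2, lam1)
        assert got == pytest.approx(brute, rel=1e-6)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            l2l1_penalty([np.ones(2)], np.ones(2), -0.1, 0.0)


class TestElboLoss:
    def test_beta_zero_is_pure_nll(self, micro_variational, micro_batch):
        rng = np.random.default_rng(0)
        comps = elbo_loss(micro_variational, micro_batch, beta_v=0.0,
                          n_samples=3, rng=rng)
        assert comps.kl_term == 0.0
        assert comps.total == pytest.approx(comps.nll_term)

    def test_negative_beta_raises(self, micro_variational, micro_batch):
        with pytest.raises(ValueError):
            elbo_loss(micro_variational, micro_batch, beta_v=-1.0)

    def test_composition_identity(self, micro_variational, micro_batch):
        """With one fixed draw, the ELBO equals the three ops composed."""
        enc = micro_variational
        seed = 123
        comps = elbo_loss(enc, micro_batch, beta_v=0.7, n_samples=1,
                          kl_scale=0.4, rng=np.random.default_rng(seed))
        w, _ = enc.sample_weight_draw(np.random.default_rng(seed))
        lq, lp = enc.log_q_log_p(w)
        nll = poisson_nll(enc.forward(micro_batch[0], weights=w),
                          micro_batch[1])
        assert comps.kl_term == pytest.approx(0.7 * 0.4 * (lq - lp))
        assert comps.nll_term == pytest.approx(nll)
        assert comps.total == pytest.approx(comps.kl_term + comps.nll_term)

    def test_kl_term_matches_closed_form_on_average(self, micro_batch):
        """With a pi=1 prior the mean KL term equals the analytic Gaussian KL."""
        cfg = EncoderConfig(in_channels=1, input_hw=(5, 5), n_neurons=2,
                            conv1=(2, 3, 3), conv2=(2, 2, 2),
                            variant="variational")
        prior = ScaleMixturePrior(pi=1.0, sigma1=1.0)
        enc = ConvEncoder(cfg, prior=prior, seed=5)
        rng = np.random.default_rng(9)
        beta_v, kl_scale = 0.5, 0.2
        n_calls, per_call = 200, 50
        vals = np.array([
            elbo_loss(enc, micro_batch, beta_v=beta_v, n_samples=per_call,
                      kl_scale=kl_scale, rng=rng).kl_term
            for _ in range(n_calls)
        ])
        kl = sum(
            gaussian_kl(p.mu, p.sigma, 1.0) for p in enc.posteriors.values()
        )
        expected = beta_v * kl_scale * kl
        se = vals.std() / np.sqrt(n_calls)
        assert abs(vals.mean() - expected) < 3 * se

    def test_monotone_in_beta_when_q_above_p(self, micro_variational,
                                             micro_batch):
        """Fixing the draw, a larger beta_v cannot decrease the total when
        log q >= log P at that draw."""
        enc = micro_variational
        seed = 4
        totals = []
        for beta in (0.1, 1.0, 5.0):
            comps = elbo_loss(enc, micro_batch, beta_v=beta, n_samples=1,
                              rng=np.random.default_rng(seed))
            kl_raw = comps.kl_term / beta
            totals.append(comps.total)
        assert kl_raw > 0  # log q > log P at this draw
        assert totals[0] <= totals[1] <= totals[2]

    def test_gradients_match_finite_difference(self, micro_variational,
                                               micro_batch):
        """Analytic reparameterization gradients vs central differences."""
        enc = micro_variational
        seed, h = 7, 1e-6

        def loss():
            return elbo_loss(enc, micro_batch, beta_v=0.5, n_samples=1,
                             kl_scale=0.7,
                             rng=np.random.default_rng(seed)).total

        _, grads = elbo_loss(enc, micro_batch, beta_v=0.5, n_samples=1,
                             kl_scale=0.7, rng=np.random.default_rng(seed),
                             return_grads=True)
        check_rng = np.random.default_rng(1)
        for key in ("conv1.weight.mu", "conv1.weight.rho", "conv2.weight.mu",
                    "fc.weight.mu", "fc.weight.rho", "fc.bias.rho"):
            pname, kind = key.rsplit(".", 1)
            arr = getattr(enc.posteriors[pname], kind)
            flat_idx = check_rng.choice(arr.size, min(4, arr.size),
                                        replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + h
                lp = loss()
                arr[ix] = orig - h
                lm = loss()
                arr[ix] = orig
                fd = (lp - lm) / (2 * h)
                assert grads[key][ix] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestMapLoss:
    @pytest.fixture
    def map_encoder(self):
        cfg = EncoderConfig(in_channels=1, input_hw=(5, 5), n_neurons=2,
                            conv1=(2, 3, 3), conv2=(2, 2, 2), variant="map")
        return ConvEncoder(cfg, prior=ScaleMixturePrior(pi=1.0, sigma1=1.0),
                           seed=3)

    def test_zero_weights_prior_term(self, map_encoder, micro_batch):
        from scipy import stats as sps

        enc = map_encoder
        for k in enc.weights:
            enc.weights[k][...] = 0.0
        prior = ScaleMixturePrior(pi=1.0, sigma1=1.0)
        kl_scale = 0.3
        total = map_loss(enc, micro_batch, prior, kl_scale=kl_scale)
        nll = poisson_nll(enc.forward(micro_batch[0]), micro_batch[1])
        expected_prior = -kl_scale * enc.n_params * sps.norm.logpdf(0, 0, 1)
        assert total == pytest.approx(nll + expected_prior)

    def test_prior_minimized_at_zero_weights(self, micro_batch):
        prior = ScaleMixturePrior()
        w = np.linspace(-0.5, 0.5, 101)
        dens = [prior.log_density(np.array(v)) for v in w]
        assert w[int(np.argmax(dens))] == pytest.approx(0.0, abs=1e-9)

    def test_elbo_degenerates_to_map_at_tiny_sigma(self, micro_batch):
        """At rho = -40 the ELBO's NLL and prior terms equal the MAP loss
        (up to the constant posterior entropy)."""
        cfg_v = EncoderConfig(in_channels=1, input_hw=(5, 5), n_neurons=2,
                              conv1=(2, 3, 3), conv2=(2, 2, 2),
                              variant="variational")
        prior = ScaleMixturePrior()
        enc_v = ConvEncoder(cfg_v, prior=prior, seed=3)
        for p in enc_v.posteriors.values():
            p.rho[...] = -40.0
        kl_scale = 0.5
        comps = elbo_loss(enc_v, micro_batch, beta_v=1.0, n_samples=1,
                          kl_scale=kl_scale, rng=np.random.default_rng(0))

        cfg_m = EncoderConfig(in_channels=1, input_hw=(5, 5), n_neurons=2,
                              conv1=(2, 3, 3), conv2=(2, 2, 2), variant="map")
        enc_m = ConvEncoder(cfg_m, prior=prior, seed=0)
        for k in enc_m.weights:
            enc_m.weights[k][...] = enc_v.posteriors[k].mu
        map_total = map_loss(enc_m, micro_batch, prior, kl_scale=kl_scale)
        # remove the posterior-entropy term at the (essentially deterministic)
        # draw; what remains is exactly the MAP objective
        w, _ = enc_v.sample_weight_draw(np.random.default_rng(0))
        lq, _ = enc_v.log_q_log_p(w)
        assert comps.total - kl_scale * lq == pytest.approx(map_total, rel=1e-9)
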