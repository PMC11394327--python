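"""Conditional U-Net contract, gradients, training loop, checkpoints."""

import numpy as np
import pytest

import dermahair as dh
from dermahair import ContractError, nn
from dermahair.denoiser import denoiser_loss_and_grads
from tests.conftest import make_pairs


class TestInit:
    def test_seeded_init_bit_identical(self, tiny_denoiser_config):
        a = dh.init_denoiser(tiny_denoiser_config, seed=3)
        b = dh.init_denoiser(tiny_denoiser_config, seed=3)
        assert set(a.theta) == set(b.theta)
        for k in a.theta:
            assert np.array_equal(a.theta[k], b.theta[k])

    def test_parameter_count_shape_arithmetic(self):
        # hand-computed for 1 stage, 8 base channels, 1 block, tdim 8, C=1:
        #   conv_in  8*2*3*3 + 8            = 152
        #   temb     2 * (8*8 + 8)          = 144
        #   down0.b0 (8*8*9+8)*2 + 8*8+8    = 1240
        #   mid      (8*8*9+8)*2 + 8*8+8    = 1240
        #   conv_out 1*8*3*3 + 1            = 73
        config = dh.DenoiserConfig(image_channels=1, base_channels=8,
                                   depth_multipliers=(1,), n_res_blocks=1,
                                   time_embed_dim=8)
        params = dh.init_denoiser(config, seed=0)
        assert params.n_parameters() == 152 + 144 + 1240 + 1240 + 73

    def test_invalid_configs_rejected(self):
        with pytest.raises(ContractError):
            dh.DenoiserConfig(depth_multipliers=())
        with pytest.raises(ContractError):
            dh.DenoiserConfig(depth_multipliers=(1, 0))
        with pytest.raises(ContractError):
            dh.DenoiserConfig(time_embed_dim=7)


class TestPredictNoise:
    def test_deterministic_and_shape(self, tiny_denoiser_config, rng):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        x = rng.standard_normal((16, 16))
        y = rng.standard_normal((16, 16))
        out1 = dh.predict_noise(params, x, y, 0.5)
        out2 = dh.predict_noise(params, x, y, 0.5)
        assert np.array_equal(out1, out2)
        assert out1.shape == (16, 16)
        assert np.all(np.isfinite(out1))

    def test_non_divisible_size_padded_and_cropped(self, tiny_denoiser_config,
                                                   rng):
        # two stages -> divisor 2; odd sizes go through reflect pad + crop
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        x = rng.standard_normal((13, 11))
        y = rng.standard_normal((13, 11))
        out = dh.predict_noise(params, x, y, 0.3)
        assert out.shape == (13, 11)
        assert np.all(np.isfinite(out))

    def test_conditioning_resized_to_match(self, tiny_denoiser_config, rng):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        x_small = rng.standard_normal((8, 8))
        y = rng.standard_normal((16, 16))
        out = dh.predict_noise(params, x_small, y, 0.3)
        assert out.shape == (16, 16)

    def test_conditioning_changes_output(self, tiny_denoiser_config, rng):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        y = rng.standard_normal((16, 16))
        a = dh.predict_noise(params, rng.standard_normal((16, 16)), y, 0.5)
        b = dh.predict_noise(params, rng.standard_normal((16, 16)), y, 0.5)
        assert not np.array_equal(a, b)


class TestGradients:
    def test_two_parameter_toy_denoiser_finite_difference(self, rng):
        # f(y_t) = a * y_t + b through the tape; loss = MSE(f, eps)
        y_t = rng.standard_normal((5, 5))
        eps = rng.standard_normal((5, 5))
        a0, b0 = 0.7, -0.2

        # analytic gradient via the tape: pred = a * y_t + b as two
        # rank-1 dense layers over the flattened field
        a = nn.Tensor(np.array([a0]), requires_grad=True)
        b = nn.Tensor(np.array([b0]), requires_grad=True)
        pred = nn.add(nn.linear(nn.reshape(a, (1, 1)),
                                nn.Tensor(y_t.reshape(-1, 1)),
                                nn.Tensor(np.zeros(y_t.size))),
                      nn.linear(nn.reshape(b, (1, 1)),
                                nn.Tensor(np.ones((y_t.size, 1))),
                                nn.Tensor(np.zeros(y_t.size))))
        loss = nn.mse_loss(pred, eps.reshape(1, -1))
        loss.backward()
        analytic = {"a": a.grad.copy(), "b": b.grad.copy()}

        def scalar_loss(params):
            pred = params["a"][0] * y_t + params["b"][0]
            return float(np.mean((pred - eps) ** 2))

        fd = nn.finite_difference_grads(scalar_loss,
                                        {"a": np.array([a0]),
                                         "b": np.array([b0])})
        for k in ("a", "b"):
            rel = abs(fd[k][0] - analytic[k][0]) / abs(fd[k][0])
            assert rel < 1e-4

    def test_full_network_finite_difference_spot_check(self,
                                                       tiny_denoiser_config,
                                                       rng):
        params = dh.init_denoiser(tiny_denoiser_config, seed=1)
        x = rng.standard_normal((1, 1, 8, 8))
        y = rng.standard_normal((1, 1, 8, 8))
        eps = rng.standard_normal((1, 1, 8, 8))
        gam = np.array([0.4])
        _, grads = denoiser_loss_and_grads(params.theta, tiny_denoiser_config,
                                           x, y, gam, eps)

        def loss_fn(theta):
            l, _ = denoiser_loss_and_grads(theta, tiny_denoiser_config, x, y,
                                           gam, eps, want_grads=False)
            return l

        h = 1e-6
        rng_idx = np.random.default_rng(0)
        for name in ("conv_in.W", "mid.conv2.W", "temb.fc2.W", "conv_out.b",
                     "up0.b0.conv1.W"):
            flat = params.theta[name].ravel()
            for i in rng_idx.choice(flat.size, size=min(3, flat.size),
                                    replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp = loss_fn(params.theta)
                flat[i] = orig - h
                lm = loss_fn(params.theta)
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[name].ravel()[i]
                assert abs(fd - an) / max(1e-10, abs(fd)) < 1e-4


class TestTrainStep:
    def test_zero_learning_rate_keeps_params(self, tiny_denoiser_config):
        pairs = make_pairs(0, 4)
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        before = {k: v.copy() for k, v in params.theta.items()}
        opt = nn.Adam(lr=0.0)
        sch = dh.make_schedule(dh.DiffusionConfig(T=10))
        loss = dh.train_step(params, pairs, sch, opt,
                             np.random.default_rng(0))
        assert np.isfinite(loss) and loss > 0
        for k in before:
            assert np.array_equal(params.theta[k], before[k])

    def test_overfit_one_batch_loss_decreases(self, tiny_denoiser_config):
        # fixed batch, fixed noise draws per step via reseeded rng stream
        pairs = make_pairs(1, 4)
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        opt = nn.Adam(lr=2e-3)
        sch = dh.make_schedule(dh.DiffusionConfig(T=10))
        losses = [dh.train_step(params, pairs, sch, opt,
                                np.random.default_rng(42))
                  for _ in range(50)]
        assert losses[-1] < losses[0]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_empty_batch_rejected(self, tiny_denoiser_config):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        sch = dh.make_schedule(dh.DiffusionConfig(T=10))
        with pytest.raises(ContractError):
            dh.train_step(params, [], sch, nn.Adam(), np.random.default_rng(0))


class TestTrain:
    def test_one_iteration_changes_params(self, tiny_denoiser_config):
        pairs = make_pairs(2, 4)
        cfg = dh.TrainConfig(learning_rate=1e-3, iterations=1, batch_size=2,
                             seed=0)
        params, history = dh.train(pairs, cfg, dh.DiffusionConfig(T=10),
                                   tiny_denoiser_config)
        init = dh.init_denoiser(tiny_denoiser_config, seed=0)
        assert len(history) == 1
        assert any(not np.array_equal(params.theta[k], init.theta[k])
                   for k in params.theta)

    def test_empty_dataset_rejected(self, tiny_denoiser_config):
        with pytest.raises(ContractError):
            dh.train([], dh.TrainConfig(iterations=1),
                     dh.DiffusionConfig(T=10), tiny_denoiser_config)

    def test_resume_reproduces_uninterrupted_run(self, tiny_denoiser_config,
                                                 tmp_path):
        pairs = make_pairs(3, 4)
        diff = dh.DiffusionConfig(T=10)
        full_cfg = dh.TrainConfig(learning_rate=1e-3, iterations=12,
                                  batch_size=2, seed=7)
        params_full, hist_full = dh.train(pairs, full_cfg, diff,
                                          tiny_denoiser_config)
        ckpt_cfg = dh.TrainConfig(learning_rate=1e-3, iterations=6,
                                  batch_size=2, seed=7, checkpoint_every=6,
                                  checkpoint_dir=str(tmp_path))
        dh.train(pairs, ckpt_cfg, diff, tiny_denoiser_config)
        params_res, hist_res = dh.train(
            pairs, full_cfg, diff, tiny_denoiser_config,
            resume_from=tmp_path / "ckpt_000006.npz")
        assert hist_res == hist_full
        for k in params_full.theta:
            assert np.array_equal(params_full.theta[k], params_res.theta[k])


class TestCheckpoints:
    def test_round_trip_bit_identical(self, tiny_denoiser_config, tmp_path):
        params = dh.init_denoiser(tiny_denoiser_config, seed=5)
        opt = nn.Adam(lr=1e-3)
        sch = dh.make_schedule(dh.DiffusionConfig(T=10))
        path = dh.save_checkpoint(params, opt, tmp_path / "c.npz",
                                  schedule=sch)
        loaded, extras, sched_back = dh.load_checkpoint(path)
        assert loaded.config == tiny_denoiser_config
        for k in params.theta:
            assert np.array_equal(loaded.theta[k], params.theta[k])
        assert np.array_equal(sched_back.gamma, sch.gamma)
        assert extras["opt_state"]["lr"] == 1e-3

    def test_tampered_file_rejected(self, tiny_denoiser_config, tmp_path):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        path = dh.save_checkpoint(params, None, tmp_path / "t.npz")
        data = bytearray(path.read_bytes())
        data[10:60] = b"\x00" * 50
        path.write_bytes(bytes(data))
        with pytest.raises(OSError):
            dh.load_checkpoint(path)

    def test_mismatched_config_rejected(self, tiny_denoiser_config, tmp_path):
        params = dh.init_denoiser(tiny_denoiser_config, seed=0)
        path = dh.save_checkpoint(params, nn.Adam(), tmp_path / "m.npz")
        other = dh.DenoiserConfig(image_channels=1, base_channels=16,
                                  depth_multipliers=(1, 2), n_res_blocks=1,
                                  time_embed_dim=8)
        with pytest.raises(OSError):
            dh.train(make_pairs(0, 2),
                     dh.TrainConfig(iterations=2, batch_size=1, seed=0),
                     dh.DiffusionConfig(T=5), other, resume_from=path)
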