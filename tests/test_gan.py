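"""Network construction, training contracts, inference, serialization.

Training tests run at toy scale (short windows, few units) so the whole
module stays in the seconds range; the full-scale architecture is only
instantiated, never trained, here.
"""

import numpy as np
import pytest

from eegdenoise import gan, nn
from eegdenoise.gan import (
    DiscriminatorSpec, GeneratorSpec, TrainConfig, build_discriminator,
    build_generator, denoise, load_model, save_model, train,
)

from conftest import make_segments


def tiny_config(window_len=32, epochs=3, seed=0):
    return TrainConfig(
        epochs=epochs, batch_size=4, seed=seed, learning_rate=3e-3,
        generator=GeneratorSpec(window_len=window_len, lstm_units=(8, 8)),
        discriminator=DiscriminatorSpec(window_len=window_len,
                                        lstm_units=(8, 4)),
    )


@pytest.fixture
def tiny_pairs():
    noisy = make_segments(16, length=32, seed=1)
    clean = [s.with_data(np.tanh(0.5 * s.x)) for s in noisy]
    return noisy, clean


class TestArchitecture:
    def test_full_scale_generator_shapes_and_range(self):
        g = build_generator(gan.paper_generator(640), seed=0)
        out = g.forward(np.random.default_rng(0).uniform(-1, 1, (1, 640, 1)))
        assert out.shape == (1, 640, 1)
        assert np.max(np.abs(out)) < 1.0

    def test_first_lstm_layer_parameter_count(self):
        g = build_generator(gan.paper_generator(640), seed=0)
        first = g.layers[0]
        count = sum(p.size for p in first.params)
        assert count == nn.lstm_param_count(1, 64) == 16_896

    def test_full_scale_discriminator_structure(self):
        spec = gan.paper_discriminator(640)
        assert spec.lstm_units == (1024, 512, 256, 128)
        assert spec.flatten_width == 640 * 128 == 81_920

    def test_discriminator_output_in_unit_interval(self, rng):
        d = build_discriminator(DiscriminatorSpec(window_len=32,
                                                  lstm_units=(8, 4)), seed=0)
        out = d.forward(rng.uniform(-1, 1, (5, 32, 1)))
        assert out.shape == (5, 1)
        assert np.all((out > 0) & (out < 1))

    def test_generator_output_bounded_for_extreme_inputs(self, rng):
        g = build_generator(GeneratorSpec(window_len=16, lstm_units=(4,)),
                            seed=3)
        out = g.forward(rng.uniform(-100, 100, (2, 16, 1)))
        assert np.max(np.abs(out)) < 1.0


class TestGradients:
    def test_generator_backprop_matches_finite_differences(self, rng):
        g = build_generator(GeneratorSpec(window_len=10, lstm_units=(5, 4)),
                            seed=1)
        x = rng.standard_normal((3, 10, 1))
        t = 0.5 * rng.standard_normal((3, 10, 1))
        out = g.forward(x)
        g.zero_grads()
        g.backward(out - t)  # gradient of 0.5 ||out - t||^2
        eps = 1e-6
        for p, grad in zip(g.params, g.grads):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = 0.5 * np.sum((g.forward(x) - t) ** 2)
            p[idx] = orig - eps
            lm = 0.5 * np.sum((g.forward(x) - t) ** 2)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_discriminator_backprop_and_input_gradient(self, rng):
        d = build_discriminator(DiscriminatorSpec(window_len=10,
                                                  lstm_units=(6, 5)), seed=2)
        x = rng.standard_normal((3, 10, 1))
        y = np.array([[1.0], [0.0], [1.0]])

        def loss():
            return nn.bce_loss(d.forward(x), y)[0]

        prob = d.forward(x)
        _, dlogit = nn.bce_loss(prob, y)
        d.zero_grads()
        dx = d.backward(dlogit)
        eps = 1e-6
        for p, grad in zip(d.params, d.grads):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps),
                                              rel=1e-4, abs=1e-7)
        i0 = (1, 4, 0)
        orig = x[i0]
        x[i0] = orig + eps
        lp = loss()
        x[i0] = orig - eps
        lm = loss()
        x[i0] = orig
        assert dx[i0] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestTraining:
    def test_seeded_runs_reproduce_loss_history(self, tiny_pairs):
        noisy, clean = tiny_pairs
        h1 = train(noisy, clean, tiny_config(epochs=3, seed=7)).history
        h2 = train(noisy, clean, tiny_config(epochs=3, seed=7)).history
        assert h1 == h2

    def test_identity_task_mse_decreases(self):
        noisy = make_segments(16, length=32, seed=2)
        model = train(noisy, noisy, tiny_config(epochs=5, seed=1))
        mse = model.history["generator_mse"]
        assert all(a > b for a, b in zip(mse[:5], mse[1:5]))

    def test_unpaired_inputs_rejected(self, tiny_pairs):
        noisy, clean = tiny_pairs
        with pytest.raises(ValueError):
            train(noisy, clean[:-1], tiny_config())

    def test_discriminator_frozen_during_generator_update(self, tiny_pairs):
        # replicate one generator-only step: D gradients are computed to
        # pass the adversarial signal through, but D weights stay put.
        noisy, clean = tiny_pairs
        cfg = tiny_config()
        G = build_generator(cfg.generator, seed=0)
        D = build_discriminator(cfg.discriminator, seed=1)
        opt_g = nn.Adam(G, lr=cfg.learning_rate)
        before = D.checksum()
        X = np.stack([s.x for s in noisy])[:, :, None]
        S = np.stack([s.x for s in clean])[:, :, None]
        fake = G.forward(X)
        _, dmse = nn.mse_loss(fake, S)
        prob = D.forward(fake)
        _, dlogit = nn.bce_loss(prob, np.ones((len(noisy), 1)))
        dadv = D.backward(dlogit)
        G.zero_grads()
        G.backward(dmse + 5e-4 * dadv)
        opt_g.step()
        assert D.checksum() == before

    def test_history_length_matches_epochs(self, tiny_pairs):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=4))
        assert len(model.history["generator_loss"]) == 4
        assert len(model.history["discriminator_loss"]) == 4


class TestDenoise:
    def test_count_metadata_and_range(self, tiny_pairs):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=1))
        out = denoise(model, noisy)
        assert len(out) == len(noisy)
        assert all(a.channel == b.channel and a.kind is b.kind
                   for a, b in zip(noisy, out))
        assert all(np.max(np.abs(s.x)) < 1.0 for s in out)

    def test_inference_deterministic_and_batch_invariant(self, tiny_pairs):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=1))
        once = denoise(model, noisy, batch_size=64)
        again = denoise(model, noisy, batch_size=64)
        one_at_a_time = [denoise(model, [s], batch_size=1)[0] for s in noisy]
        for a, b, c in zip(once, again, one_at_a_time):
            assert np.array_equal(a.x, b.x)
            assert np.max(np.abs(a.x - c.x)) < 1e-6

    def test_window_length_mismatch_rejected(self, tiny_pairs):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=1))
        with pytest.raises(ValueError):
            denoise(model, make_segments(2, length=16))


class TestSerialization:
    def test_round_trip_preserves_outputs_and_config(self, tiny_pairs,
                                                     tmp_path):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=2, seed=3))
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        for a, b in zip(denoise(model, noisy), denoise(back, noisy)):
            assert np.array_equal(a.x, b.x)
        assert back.config == model.config
        assert back.history == model.history

    def test_corrupted_file_rejected(self, tiny_pairs, tmp_path):
        noisy, clean = tiny_pairs
        model = train(noisy, clean, tiny_config(epochs=1))
        path = tmp_path / "model.npz"
        save_model(model, path)
        path.write_bytes(b"not a weights file")
        with pytest.raises(ValueError):
            load_model(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent.npz")
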