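"""VAE machinery: reparameterization, KL closed forms, the negative-ELBO
decomposition, architecture contracts, training and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respaug import vae as vm
from respaug.features import MelSpec, MelSpecParams
from respaug.vae import (
    EncoderOutput,
    VAEConfig,
    build_vae,
    generate_samples,
    kl_divergence,
    reparameterize,
    train_vae,
    vae_loss,
)

PARAMS = MelSpecParams(norm_min=-23.0, norm_max=3.0)


def small_config(variant, **kw):
    defaults = dict(
        variant=variant, spec_shape=(16, 16), pool=(1, 1),
        intermediate_dim=32, bottleneck_dim=16, epochs=5, batch_size=8,
        seed=0,
    )
    defaults.update(kw)
    return VAEConfig(**defaults)


def specs_for(label, n, seed=0, shape=(16, 16)):
    rng = np.random.default_rng(seed)
    base = np.clip(rng.random(shape), 0, 1)
    return [
        MelSpec(np.clip(base + 0.02 * rng.standard_normal(shape), 0, 1),
                PARAMS, label)
        for _ in range(n)
    ]


class TestReparameterize:
    def test_negligible_variance_returns_mu(self):
        enc = EncoderOutput(np.array([1.5, -2.0]), np.full(2, -50.0))
        z = reparameterize(enc, np.random.default_rng(0))
        assert np.allclose(z, enc.mu, atol=1e-10)

    def test_monte_carlo_moments(self):
        enc = EncoderOutput(np.zeros(1), np.zeros(1))
        rng = np.random.default_rng(0)
        draws = np.array([reparameterize(enc, rng)[0] for _ in range(100000)])
        assert abs(draws.mean()) < 4 / np.sqrt(len(draws))
        assert abs(draws.var() - 1.0) < 0.05

    def test_fixed_rng_is_deterministic(self):
        enc = EncoderOutput(np.array([0.3]), np.array([0.1]))
        a = reparameterize(enc, np.random.default_rng(7))
        b = reparameterize(enc, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestKLDivergence:
    def test_standard_normal_gives_zero(self):
        assert kl_divergence(EncoderOutput(np.zeros(2), np.zeros(2))) == 0.0

    def test_unit_mean_closed_form(self):
        # 0.5 * (mu^2 + e^0 - 1 - 0) = 0.5 for mu=1, logvar=0, dim 1
        enc = EncoderOutput(np.array([1.0]), np.array([0.0]))
        assert kl_divergence(enc) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=4),
           st.lists(st.floats(-5, 3), min_size=1, max_size=4))
    def test_nonnegative(self, mu, lv):
        k = min(len(mu), len(lv))
        enc = EncoderOutput(np.array(mu[:k]), np.array(lv[:k]))
        assert kl_divergence(enc) >= 0.0


class TestVaeLoss:
    def test_perfect_reconstruction_standard_posterior_gives_zero(self):
        x = np.random.default_rng(0).random((2, 4, 4))
        enc = EncoderOutput(np.zeros((2, 2)), np.zeros((2, 2)))
        assert vae_loss(x, x, enc, beta=1.0) == 0.0

    def test_beta_zero_is_pure_reconstruction(self):
        rng = np.random.default_rng(0)
        x, xh = rng.random((2, 4, 4)), rng.random((2, 4, 4))
        enc = EncoderOutput(rng.normal(size=(2, 2)),
                            rng.normal(size=(2, 2)))
        expected = ((x - xh).reshape(2, -1) ** 2).sum(axis=1).mean()
        assert vae_loss(x, xh, enc, beta=0.0) == pytest.approx(expected)

    def test_beta_linearity_recovers_kl(self):
        rng = np.random.default_rng(1)
        x, xh = rng.random((3, 4, 4)), rng.random((3, 4, 4))
        enc = EncoderOutput(rng.normal(size=(3, 2)),
                            rng.normal(size=(3, 2)))
        delta = vae_loss(x, xh, enc, 2.0) - vae_loss(x, xh, enc, 1.0)
        assert delta == pytest.approx(kl_divergence(enc), abs=1e-9)

    def test_elbo_decomposition_to_1e6(self):
        rng = np.random.default_rng(2)
        x, xh = rng.random((3, 4, 4)), rng.random((3, 4, 4))
        enc = EncoderOutput(rng.normal(size=(3, 2)),
                            rng.normal(size=(3, 2)))
        recon = vae_loss(x, xh, enc, beta=0.0)
        assert vae_loss(x, xh, enc, beta=1.0) == pytest.approx(
            recon + kl_divergence(enc), abs=1e-6
        )

    def test_shape_mismatch_rejected(self):
        enc = EncoderOutput(np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            vae_loss(np.zeros((2, 3)), np.zeros((2, 4)), enc)


class TestBuildVae:
    def test_mlp_forward_preserves_shape_in_unit_interval(self):
        cfg = small_config("mlp")
        model = build_vae(cfg)
        from respaug.nn import Tensor
        x = Tensor(np.random.default_rng(0).random((3, 16, 16)))
        mu, lv = model.encode(x)
        assert mu.shape == (3, 2) and lv.shape == (3, 2)
        out = model.decode(mu)
        assert out.shape == (3, 16, 16)
        assert out.data.min() >= 0 and out.data.max() <= 1

    def test_cnn_decoder_upsamples_grid_by_eight(self):
        cfg = small_config("cnn")
        model = build_vae(cfg)
        from respaug.nn import Tensor
        z = Tensor(np.zeros((2, 2)))
        out = model.decode(z)
        assert model.grid[1:] == (16 // 8, 16 // 8)
        assert out.shape == (2, 16, 16)  # 3 stride-2 deconvs: x8 from grid

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            VAEConfig(variant="gan")

    def test_non_divisible_shape_rejected_for_conv(self):
        with pytest.raises(ValueError, match="divisible"):
            small_config("cnn", spec_shape=(18, 16))


class TestTraining:
    def test_overfits_repeated_spectrogram(self):
        cfg = small_config("mlp", epochs=200, batch_size=16,
                           learning_rate=1e-3)
        specs = [specs_for("URTI", 1, seed=3)[0]] * 50
        tv = train_vae(build_vae(cfg), specs, cfg)
        assert tv.loss_history[-1] < 0.1 * tv.loss_history[0]

    def test_fixed_seed_reproduces_loss_history(self):
        cfg = small_config("mlp", epochs=5)
        specs = specs_for("URTI", 12)
        a = train_vae(build_vae(cfg), specs, cfg)
        b = train_vae(build_vae(cfg), specs, cfg)
        assert a.loss_history == b.loss_history

    def test_loss_trend_decreases(self):
        cfg = small_config("cnn", epochs=30, batch_size=8)
        specs = specs_for("LRTI", 12, seed=1)
        tv = train_vae(build_vae(cfg), specs, cfg)
        first = np.mean(tv.loss_history[:10])
        last = np.mean(tv.loss_history[-10:])
        assert last < first

    def test_majority_class_rejected_by_guard(self):
        cfg = small_config("mlp")
        with pytest.raises(ValueError, match="COPD"):
            train_vae(build_vae(cfg), specs_for("COPD", 4), cfg)

    def test_mixed_classes_rejected_for_unconditional(self):
        cfg = small_config("mlp")
        specs = specs_for("URTI", 3) + specs_for("LRTI", 3)
        with pytest.raises(ValueError, match="one class"):
            train_vae(build_vae(cfg), specs, cfg)

    def test_empty_training_set_rejected(self):
        cfg = small_config("mlp")
        with pytest.raises(ValueError, match="empty"):
            train_vae(build_vae(cfg), [], cfg)

    def test_conditional_single_class_warns(self):
        cfg = small_config("conditional", epochs=1)
        with pytest.warns(UserWarning, match="single class"):
            train_vae(build_vae(cfg), specs_for("URTI", 6), cfg)

    def test_conditional_label_changes_output(self):
        """After training on two visually distinct classes, the decoder
        must produce different spectrograms for the same latent code."""
        cfg = small_config("conditional", epochs=60, batch_size=8)
        rng = np.random.default_rng(0)
        bright = [MelSpec(np.clip(0.8 + 0.05 * rng.standard_normal((16, 16)),
                                  0, 1), PARAMS, "URTI") for _ in range(8)]
        dark = [MelSpec(np.clip(0.2 + 0.05 * rng.standard_normal((16, 16)),
                                0, 1), PARAMS, "LRTI") for _ in range(8)]
        tv = train_vae(build_vae(cfg), bright + dark, cfg)
        a = generate_samples(tv, 1, "URTI", np.random.default_rng(0))[0]
        b = generate_samples(tv, 1, "LRTI", np.random.default_rng(0))[0]
        assert a.values.mean() > b.values.mean()


@pytest.fixture(scope="module")
def trained():
    cfg = small_config("mlp", epochs=10)
    return train_vae(build_vae(cfg), specs_for("URTI", 12), cfg)


class TestGenerateSamples:

    def test_requested_count_returned(self, trained):
        out = generate_samples(trained, 7, rng=np.random.default_rng(0))
        assert len(out) == 7
        assert all(s.label == "URTI" for s in out)

    def test_nonpositive_count_rejected(self, trained):
        with pytest.raises(ValueError):
            generate_samples(trained, 0)

    def test_identical_rng_identical_outputs(self, trained):
        a = generate_samples(trained, 3, rng=np.random.default_rng(5))
        b = generate_samples(trained, 3, rng=np.random.default_rng(5))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.values, sb.values)

    def test_outputs_satisfy_melspec_invariants(self, trained):
        for s in generate_samples(trained, 100,
                                  rng=np.random.default_rng(1)):
            assert s.values.shape == (16, 16)
            assert s.values.min() >= 0.0 and s.values.max() <= 1.0

    def test_wrong_class_request_rejected(self, trained):
        with pytest.raises(ValueError, match="URTI"):
            generate_samples(trained, 1, class_label="LRTI")
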