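"""Architecture presets, parameter sharing, and the gradient penalty."""

import math

import numpy as np
import pytest

from eegadapt.losses import gradient_penalty
from eegadapt.networks import MLPDiscriminator, build_preset
from eegadapt.nn import Context


def shape_oracle(input_hw: int, conv_groups) -> int:
    """Independent shape propagation: valid conv then ceil-mode 2x2 pool."""
    hw = input_hw
    for group in conv_groups:
        for (_, _, k) in group:
            hw = hw - k + 1
        hw = math.ceil(hw / 2)
    return hw


class TestPresets:
    def test_cross_day_maps_32x32_to_256_features(self):
        nets = build_preset("cross_day", n_classes=2, n_domains=2, seed=0)
        x = np.random.default_rng(0).normal(size=(6, 5, 32, 32))
        ctx = Context("train", domain_ids=np.array([0, 0, 0, 1, 1, 1]),
                      rng=np.random.default_rng(1))
        feats = nets.forward_generator(x, ctx)
        assert feats.shape == (6, 256)
        # reference flatten size: 7 x 7 x 64 under valid conv + ceil pooling
        assert (nets.spec.flatten_hw, nets.spec.flatten_ch) == (7, 64)

    def test_cross_subject_feature_width_256(self):
        nets = build_preset("cross_subject", seed=0)
        assert nets.spec.feature_dim == 256
        assert nets.spec.flatten_ch == 128

    @pytest.mark.parametrize("preset", ["cross_day", "compact"])
    def test_flatten_matches_shape_oracle(self, preset):
        from eegadapt.networks import PRESETS

        nets = build_preset(preset, seed=0)
        assert nets.spec.flatten_hw == shape_oracle(32, PRESETS[preset]["conv_groups"])

    def test_zero_image_yields_finite_features(self):
        for preset in ("cross_day", "cross_subject"):
            nets = build_preset(preset, seed=0)
            ctx = Context("train", domain_ids=np.array([0, 0, 1, 1]),
                          rng=np.random.default_rng(0))
            feats = nets.forward_generator(np.zeros((4, 5, 32, 32)), ctx)
            assert np.all(np.isfinite(feats))

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            build_preset("bogus")

    def test_resolution_mismatch_raises_with_dims(self):
        nets = build_preset("cross_day", seed=0)
        with pytest.raises(ValueError, match="32"):
            nets.forward_generator(np.zeros((2, 5, 16, 16)), Context("eval"))

    def test_generator_parameters_shared_across_domains(self):
        # one parameter store serves both domains; only BN stats are per-domain
        nets = build_preset("compact", seed=0)
        params_before = [layer.params[k] for _, layer, k in nets.generator.named_params()]
        x = np.random.default_rng(0).normal(size=(8, 5, 32, 32))
        ctx = Context("train", domain_ids=np.r_[np.zeros(4, int), np.ones(4, int)],
                      rng=np.random.default_rng(0))
        nets.forward_generator(x, ctx)
        params_after = [layer.params[k] for _, layer, k in nets.generator.named_params()]
        assert all(a is b for a, b in zip(params_before, params_after))
        for bn in nets.bn_layers():
            assert set(bn.running) == {0, 1}
            for key in ("gamma", "beta"):
                assert isinstance(bn.params[key], np.ndarray)  # single shared affine


class TestForwardHeads:
    def _feats(self, nets, n=6):
        rng = np.random.default_rng(3)
        return rng.normal(size=(n, nets.spec.feature_dim))

    def test_softmax_heads_are_probability_rows(self):
        nets = build_preset("compact", n_classes=4, seed=0)
        f = self._feats(nets)
        for out in (nets.forward_classifier(f), nets.forward_discriminator(f)):
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)
            assert out.min() >= 0

    def test_eval_mode_is_deterministic(self):
        nets = build_preset("compact", seed=0)
        x = np.random.default_rng(0).normal(size=(4, 5, 32, 32))
        train_ctx = Context("train", domain_ids=np.array([0, 0, 1, 1]),
                            rng=np.random.default_rng(0))
        nets.forward_generator(x, train_ctx)  # populate BN stats
        ctx = lambda: Context("eval", domain_ids=np.array([0, 0, 1, 1]))
        a = nets.forward_generator(x, ctx())
        b = nets.forward_generator(x, ctx())
        np.testing.assert_array_equal(a, b)

    def test_batch_permutation_equivariance(self):
        nets = build_preset("compact", seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 5, 32, 32))
        dom = np.array([0, 0, 0, 1, 1, 1])
        nets.forward_generator(x, Context("train", domain_ids=dom,
                                          rng=np.random.default_rng(0)))
        perm = np.array([3, 1, 5, 0, 2, 4])
        a = nets.forward_generator(x, Context("eval", domain_ids=dom))
        b = nets.forward_generator(x[perm], Context("eval", domain_ids=dom[perm]))
        np.testing.assert_allclose(b, a[perm], atol=1e-6)


class _LinearToy:
    """s(x) = w . x with an analytic input gradient."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def input_gradient(self, x):
        return np.tile(self.w, (np.atleast_2d(x).shape[0], 1))


class _QuadraticToy:
    """s(x) = x^T A x / 2; grad = (A + A^T) x / 2."""

    def __init__(self, a):
        self.a = np.asarray(a, dtype=float)

    def input_gradient(self, x):
        return np.atleast_2d(x) @ (self.a + self.a.T).T / 2.0


class TestGradientPenalty:
    def test_unit_slope_linear_gives_zero(self, rng):
        w = rng.standard_normal(5)
        w /= np.linalg.norm(w)
        pts = rng.standard_normal((9, 5))
        assert gradient_penalty(_LinearToy(w), pts) == pytest.approx(0.0, abs=1e-12)

    def test_slope_two_gives_one(self):
        assert gradient_penalty(_LinearToy([2.0]), np.array([[0.3], [5.0]])) == pytest.approx(1.0)

    def test_constant_function_gives_one(self, rng):
        assert gradient_penalty(_LinearToy([0.0, 0.0]), rng.standard_normal((4, 2))) == pytest.approx(1.0)

    def test_quadratic_matches_hand_computed_value(self, rng):
        # s(x) = x^T A x / 2 with symmetric A: grad = A x, penalty has closed form
        a = np.diag([2.0, 3.0])
        pts = rng.standard_normal((20, 2))
        grads = pts @ a
        expected = np.mean((np.linalg.norm(grads, axis=1) - 1.0) ** 2)
        assert gradient_penalty(_QuadraticToy(a), pts) == pytest.approx(expected, abs=1e-8)

    def test_no_gradient_interface_raises(self):
        with pytest.raises(TypeError, match="finite differences"):
            gradient_penalty(object(), np.zeros((1, 2)))

    @pytest.mark.parametrize("hidden", [(), (16,), (16, 8)])
    def test_discriminator_penalty_param_grads_match_finite_differences(self, hidden, rng):
        disc = MLPDiscriminator(6, 2, rng, hidden=hidden)
        x = rng.standard_normal((7, 6))
        disc.zero_grad()
        disc.penalty_param_grads(x)
        for d in disc.denses:
            w = d.params["weight"]
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in w.shape)
                eps, old = 1e-6, w[idx]
                w[idx] = old + eps
                up = disc.gradient_penalty(x)
                w[idx] = old - eps
                down = disc.gradient_penalty(x)
                w[idx] = old
                assert d.grads["weight"][idx] == pytest.approx(
                    (up - down) / (2 * eps), abs=1e-8, rel=1e-6
                )

    def test_discriminator_input_gradient_is_exact_for_linear_case(self, rng):
        disc = MLPDiscriminator(4, 2, rng, hidden=())
        g, _ = disc.input_gradient(rng.standard_normal((3, 4)))
        np.testing.assert_allclose(g, np.tile(disc.denses[0].params["weight"][0], (3, 1)))
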