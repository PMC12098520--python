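"""Network contracts: SE block arithmetic, Res_CAB vs a loop oracle,
shape chain, probability heads, ablation flags."""

import numpy as np
import pytest

from adgsleep import autodiff as ad
from adgsleep import network as net
from adgsleep.autodiff import Tensor
from adgsleep.network import (ConfigurationError, ModelConfig, init_params,
                              label_predict, domain_predict, res_cab,
                              se_block)
from tests.conftest import REDUCED_MODEL


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# independent loop-based oracle for conv + SE + residual
# ---------------------------------------------------------------------------

def conv2d_loops(x, w, b, stride=1):
    """Direct convolution with explicit loops, 'same' zero padding (NHWC)."""
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ho, wo = -(-h // stride), -(-wd // stride)
    pt = max((ho - 1) * stride + kh - h, 0) // 2
    pl = max((wo - 1) * stride + kw - wd, 0) // 2
    out = np.zeros((n, ho, wo, cout))
    for bi in range(n):
        for oi in range(ho):
            for oj in range(wo):
                for co in range(cout):
                    acc = b[co]
                    for ki in range(kh):
                        for kj in range(kw):
                            ii = oi * stride + ki - pt
                            jj = oj * stride + kj - pl
                            if 0 <= ii < h and 0 <= jj < wd:
                                acc += (x[bi, ii, jj] * w[ki, kj, :, co]).sum()
                    out[bi, oi, oj, co] = acc
    return out


def se_loops(o, w1, b1, w2, b2):
    z = o.mean(axis=(1, 2))
    s = _sigmoid(np.maximum(z @ w1 + b1, 0) @ w2 + b2)
    return o * s[:, None, None, :]


class TestSeBlock:
    def test_zero_input_gives_half_weights_and_zero_output(self):
        """Zero feature map, zero biases: squeeze z = 0, excitation
        s = sigmoid(0) = 0.5 per channel, rescaled output = 0."""
        o = Tensor(np.zeros((1, 3, 3, 2)))
        w1 = Tensor(np.eye(2)); b1 = Tensor(np.zeros(2))
        w2 = Tensor(np.eye(2)); b2 = Tensor(np.zeros(2))
        out = se_block(o, w1, b1, w2, b2)
        np.testing.assert_array_equal(out.data, 0.0)
        z = ad.mean(o, axis=(1, 2))
        s = ad.sigmoid(ad.matmul(ad.relu(ad.matmul(z, w1) + b1), w2) + b2)
        np.testing.assert_allclose(s.data, 0.5)

    def test_hand_worked_identity_weight_example(self):
        """H=W=1, C=2, identity weights, o=(2,4): s=(sigma(2), sigma(4)) =
        (0.880797, 0.982014), output = (1.761594, 3.928055)."""
        o = Tensor(np.array([2.0, 4.0]).reshape(1, 1, 1, 2))
        eye, zero = Tensor(np.eye(2)), Tensor(np.zeros(2))
        out = se_block(o, eye, zero, eye, zero)
        np.testing.assert_allclose(
            out.data.ravel(), [1.761594, 3.928055], atol=1e-5)

    def test_constant_channel_squeeze_is_exact(self, rng):
        c_vals = np.array([1.7, -0.3, 2.2])
        o = Tensor(np.broadcast_to(c_vals, (1, 4, 5, 3)).copy())
        z = ad.mean(o, axis=(1, 2))
        np.testing.assert_allclose(z.data.ravel(), c_vals, rtol=1e-6)

    def test_saturated_excitation_makes_identity(self, rng):
        """Forcing s -> 1 (huge positive second-layer bias) reduces the SE
        block to the identity on the feature map."""
        o = Tensor(rng.standard_normal((2, 4, 4, 3)))
        w1 = Tensor(rng.standard_normal((3, 3)) * 0.1)
        w2 = Tensor(np.zeros((3, 3)))
        out = se_block(o, w1, Tensor(np.zeros(3)), w2,
                       Tensor(np.full(3, 50.0)))
        np.testing.assert_allclose(out.data, o.data, rtol=1e-5)


class TestResCab:
    def _zero_params(self, cin, cout, with_proj):
        p = {}
        p["blk.conv.w"] = Tensor(np.zeros((3, 3, cin, cout)), requires_grad=True)
        p["blk.conv.b"] = Tensor(np.zeros(cout), requires_grad=True)
        mid = max(cout // max(cout // 16, 1), 1)
        p["blk.se.fc1.w"] = Tensor(np.zeros((cout, mid)))
        p["blk.se.fc1.b"] = Tensor(np.zeros(mid))
        p["blk.se.fc2.w"] = Tensor(np.zeros((mid, cout)))
        p["blk.se.fc2.b"] = Tensor(np.zeros(cout))
        if with_proj:
            p["blk.shortcut.w"] = Tensor(np.zeros((1, 1, cin, cout)))
            p["blk.shortcut.b"] = Tensor(np.zeros(cout))
        return p

    def test_zero_weights_standard_variant_is_relu_identity(self, rng):
        x_pos = Tensor(np.abs(rng.standard_normal((1, 4, 4, 2))))
        p = self._zero_params(2, 2, with_proj=False)
        out = res_cab(x_pos, p, "blk", variant="standard")
        np.testing.assert_allclose(out.data, x_pos.data, rtol=1e-6)

    def test_zero_weights_clip_negative_inputs(self, rng):
        x = Tensor(rng.standard_normal((1, 4, 4, 2)))
        p = self._zero_params(2, 2, with_proj=False)
        out = res_cab(x, p, "blk", variant="standard")
        np.testing.assert_allclose(out.data, np.maximum(x.data, 0), rtol=1e-6)

    def test_channel_mismatch_directs_to_projection(self, rng):
        x = Tensor(rng.standard_normal((1, 4, 4, 2)))
        p = self._zero_params(2, 4, with_proj=False)
        with pytest.raises(ConfigurationError, match="projection"):
            res_cab(x, p, "blk", variant="standard")

    @pytest.mark.parametrize("variant,stride", [("standard", 1),
                                                ("projection", 1),
                                                ("projection", 2)])
    def test_matches_loop_oracle_on_pinned_input(self, variant, stride, rng):
        """Res_CAB equals a literal loop implementation of conv + squeeze +
        excite + rescale + shortcut + ReLU within 1e-6 on a 4x4x2 input."""
        cin = cout = 2
        x = rng.standard_normal((1, 4, 4, cin)).astype(np.float32)
        w = (rng.standard_normal((3, 3, cin, cout)) * 0.3).astype(np.float32)
        b = (rng.standard_normal(cout) * 0.1).astype(np.float32)
        mid = max(cout // max(cout // 16, 1), 1)
        w1 = (rng.standard_normal((cout, mid)) * 0.3).astype(np.float32)
        b1 = (rng.standard_normal(mid) * 0.1).astype(np.float32)
        w2 = (rng.standard_normal((mid, cout)) * 0.3).astype(np.float32)
        b2 = (rng.standard_normal(cout) * 0.1).astype(np.float32)
        ws = (rng.standard_normal((1, 1, cin, cout)) * 0.3).astype(np.float32)
        bs = (rng.standard_normal(cout) * 0.1).astype(np.float32)
        p = {"blk.conv.w": Tensor(w), "blk.conv.b": Tensor(b),
             "blk.se.fc1.w": Tensor(w1), "blk.se.fc1.b": Tensor(b1),
             "blk.se.fc2.w": Tensor(w2), "blk.se.fc2.b": Tensor(b2),
             "blk.shortcut.w": Tensor(ws), "blk.shortcut.b": Tensor(bs)}
        out = res_cab(Tensor(x), p, "blk", variant=variant, stride=stride)
        o = se_loops(conv2d_loops(x, w, b, stride), w1, b1, w2, b2)
        shortcut = x if variant == "standard" else conv2d_loops(x, ws, bs, stride)
        expected = np.maximum(o + shortcut, 0)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_use_se_false_skips_recalibration(self, rng):
        """Channel-attention ablation: output = relu(conv(x) + x)."""
        cin = 2
        x = rng.standard_normal((1, 4, 4, cin)).astype(np.float32)
        w = (rng.standard_normal((3, 3, cin, cin)) * 0.3).astype(np.float32)
        b = np.zeros(cin, np.float32)
        p = {"blk.conv.w": Tensor(w), "blk.conv.b": Tensor(b)}
        out = res_cab(Tensor(x), p, "blk", variant="standard", use_se=False)
        expected = np.maximum(conv2d_loops(x, w, b) + x, 0)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)


class TestShapeChain:
    def test_reference_config_shapes(self):
        """(128,128,10) -> encoder (8,8,256) -> features (32,256) ->
        heads (5,) and (9,)."""
        cfg = ModelConfig()
        params = init_params(cfg)
        x = Tensor(np.random.default_rng(0).standard_normal(
            (1, 128, 128, 10)).astype(np.float32))
        with ad.no_grad():
            feats_enc = net.encode(x, params, cfg)
            features = net.feature_extract(x, params, cfg)
            stage = label_predict(features, params)
            dom = domain_predict(features, params)
        assert feats_enc[-1].shape == (1, 8, 8, 256)
        assert features.shape == (1, 32, 256)
        assert stage.shape == (1, 5)
        assert dom.shape == (1, 9)

    def test_wrong_input_shape_rejected(self):
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=2)
        params = init_params(cfg)
        with pytest.raises(ValueError):
            net.feature_extract(Tensor(np.zeros((1, 16, 16, 10))), params, cfg)

    def test_feature_extract_is_pure(self, rng):
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=2)
        params = init_params(cfg)
        x = Tensor(rng.standard_normal((2, 32, 32, 10)).astype(np.float32))
        with ad.no_grad():
            a = net.feature_extract(x, params, cfg)
            b = net.feature_extract(x, params, cfg)
        np.testing.assert_array_equal(a.data, b.data)


class TestHeads:
    def _features(self, rng, cfg):
        return Tensor(rng.standard_normal(
            (3, cfg.seq_len, cfg.feature_dim)).astype(np.float32))

    def test_zero_weights_give_uniform_distributions(self, rng):
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=9)
        params = init_params(cfg)
        for k, p in params.items():
            if k.startswith(("cls.", "dom.")):
                p.data[:] = 0.0
        f = self._features(rng, cfg)
        np.testing.assert_allclose(label_predict(f, params).data, 0.2,
                                   atol=1e-6)
        np.testing.assert_allclose(domain_predict(f, params).data, 1 / 9,
                                   atol=1e-6)

    def test_softmax_of_unit_logit(self):
        """softmax(1,0,0,0,0) = (0.40461, 0.14885, ...)."""
        s = ad.softmax(Tensor([[1.0, 0, 0, 0, 0]]))
        np.testing.assert_allclose(
            s.data.ravel(),
            [0.40461, 0.14885, 0.14885, 0.14885, 0.14885], atol=1e-5)

    def test_softmax_shift_invariance(self, rng):
        logits = rng.standard_normal((4, 5)).astype(np.float32)
        a = ad.softmax(Tensor(logits)).data
        b = ad.softmax(Tensor(logits + 7.3)).data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_probability_heads_always_valid_distributions(self, rng):
        """Over 100 random feature draws both heads emit components in
        (0,1) summing to 1 within 1e-6."""
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=9)
        params = init_params(cfg)
        for _ in range(100):
            f = Tensor(rng.standard_normal(
                (1, cfg.seq_len, cfg.feature_dim)).astype(np.float32) * 3)
            for probs in (label_predict(f, params).data,
                          domain_predict(f, params).data):
                assert np.all(probs > 0) and np.all(probs < 1)
                np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_domain_head_width_matches_n_domains(self, rng):
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=4)
        params = init_params(cfg)
        f = self._features(rng, cfg)
        assert domain_predict(f, params).shape == (3, 4)


class TestAblationAndCheckpoints:
    def test_no_discriminator_means_no_domain_parameters(self):
        cfg = ModelConfig(**REDUCED_MODEL, use_discriminator=False)
        params = init_params(cfg)
        assert not any(k.startswith("dom.") for k in params)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = ModelConfig(**REDUCED_MODEL, n_domains=3, seed=5)
        params = init_params(cfg)
        net.save_checkpoint(tmp_path / "model.npz", params, cfg)
        loaded, cfg2 = net.load_checkpoint(tmp_path / "model.npz")
        assert cfg2 == cfg
        for k in params:
            np.testing.assert_array_equal(loaded[k].data, params[k].data)
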