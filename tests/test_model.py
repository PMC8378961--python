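"""Network blocks: shape ledger, residual identities, error feedback, oracles."""

import numpy as np
import pytest

from mcrn.data import ImageGray
from mcrn.errors import ConfigError, ShapeError
from mcrn.model import (
    ModelConfig,
    ScaleSpec,
    StageCache,
    build_model,
    channel_attention,
    dilated_multichannel_block,
    down_block,
    forward_tensor,
    init_features,
    load_checkpoint,
    mcrn_forward,
    reconstruct,
    residual_attention_block,
    residual_attention_module,
    save_checkpoint,
    up_block,
)
from mcrn.nn import Tensor, conv2d, l1_mean

from .oracles import np_channel_attention, np_forward_one_stage

rng = np.random.default_rng(11)


def zero_(cw):
    cw.w.data[:] = 0
    cw.b.data[:] = 0
    return cw


@pytest.fixture(scope="module")
def model64():
    return build_model(ModelConfig(base_channels=64, n_ud_stages=3, scale=2), seed=0)


@pytest.fixture()
def model16():
    return build_model(ModelConfig(base_channels=16, n_ud_stages=2, scale=2), seed=1)


class TestConfig:
    def test_scale_5_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(scale=5)
        with pytest.raises(ConfigError):
            build_model(ModelConfig(scale=2), 0).config.__class__(scale=5)

    def test_scale_spec_geometry(self):
        for s, (k, st, p) in {2: (4, 2, 1), 3: (7, 3, 2), 4: (8, 4, 2)}.items():
            spec = ScaleSpec.for_scale(s)
            assert (spec.kernel, spec.stride, spec.pad) == (k, st, p)
            assert spec.kernel - 2 * spec.pad == spec.stride == s

    def test_non_increasing_dilations_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(dilation_rates=(1, 3, 3))

    def test_attention_bottleneck_is_base_over_16(self):
        assert ModelConfig(base_channels=64).attention_channels == 4

    def test_same_seed_identical_weights(self):
        cfg = ModelConfig(base_channels=16, n_ud_stages=1)
        a = build_model(cfg, seed=9).parameters()
        b = build_model(cfg, seed=9).parameters()
        for k in a:
            np.testing.assert_array_equal(a[k].data, b[k].data)

    def test_different_seed_differs(self):
        cfg = ModelConfig(base_channels=16, n_ud_stages=1)
        a = build_model(cfg, seed=1).parameters()
        b = build_model(cfg, seed=2).parameters()
        assert any(not np.array_equal(a[k].data, b[k].data) for k in a)


class TestShapeLedger:
    """Channel/geometry ledger at gamma = 2 (kernel/stride/pad table)."""

    def test_initial_layer_1_to_64(self, model64):
        assert model64.init.w.shape == (64, 1, 3, 3)
        out = init_features(Tensor(rng.uniform(size=(1, 1, 32, 32))), model64.init)
        assert out.shape == (1, 64, 32, 32)

    def test_rab_conv_geometry(self, model64):
        rab = model64.rabs[0]
        assert rab.conv.w.shape == (64, 64, 3, 3)
        assert rab.att_down.w.shape == (4, 64, 1, 1)
        assert rab.att_up.w.shape == (64, 4, 1, 1)

    def test_up_down_deconv_geometry(self, model64):
        st = model64.stages[0]
        assert st.p.w.shape == (64, 64, 4, 4)
        assert st.g.w.shape == (64, 64, 4, 4)
        assert st.q.w.shape == (64, 64, 4, 4)

    def test_cascade_reductions(self, model64):
        assert model64.stages[1].reduce_1x1.w.shape == (64, 128, 1, 1)
        assert model64.stages[2].k.w.shape == (64, 192, 1, 1)
        assert model64.cascade_reduce.w.shape == (64, 192, 1, 1)

    def test_reconstruction_geometry(self, model64):
        assert model64.recon.pre.w.shape == (256, 64, 3, 3)
        assert model64.recon.post.w.shape == (1, 64, 3, 3)

    def test_stage_grid_shapes(self, model16):
        cache = StageCache()
        forward_tensor(Tensor(rng.uniform(size=(1, 1, 16, 16))), model16, cache)
        assert cache.n_stages == 2
        assert len(cache.L_history) == 3  # seed + 2 down-block outputs
        for h in cache.H_history:
            assert h.shape == (1, 16, 32, 32)
        for l in cache.L_history:
            assert l.shape == (1, 16, 16, 16)


class TestBlockContracts:
    def test_init_rejects_multichannel(self, model64):
        with pytest.raises(ShapeError):
            init_features(Tensor(rng.uniform(size=(1, 3, 16, 16))), model64.init)

    def test_init_zero_weights_zero_output(self, model16):
        m = build_model(model16.config, seed=3)
        zero_(m.init)
        out = init_features(Tensor(rng.uniform(size=(1, 1, 12, 12))), m.init)
        np.testing.assert_array_equal(out.data, 0)

    def test_init_shift_equivariance_interior(self, model16):
        x = rng.uniform(size=(1, 1, 12, 12))
        shifted = np.roll(x, 1, axis=3)
        a = init_features(Tensor(x), model16.init).data
        b = init_features(Tensor(shifted), model16.init).data
        # interior columns shift identically (border differs due to padding)
        np.testing.assert_allclose(a[..., 2:-2], np.roll(b, -1, axis=3)[..., 2:-2],
                                   atol=1e-12)

    def test_dilated_block_shape_and_residual(self, model16):
        x = Tensor(rng.uniform(size=(1, 16, 12, 12)))
        out = dilated_multichannel_block(
            x, model16.dil_branches, model16.dil_fuse, model16.config.dilation_rates
        )
        assert out.shape == x.shape
        m = build_model(model16.config, seed=4)
        zero_(m.dil_fuse)
        out2 = dilated_multichannel_block(
            x, m.dil_branches, m.dil_fuse, m.config.dilation_rates
        )
        np.testing.assert_array_equal(out2.data, x.data)

    def test_rate5_branch_receptive_field_11(self):
        # gradient-support probe: a dilation-5 3x3 conv spans 2*5+1 = 11 pixels
        x = Tensor(np.zeros((1, 1, 23, 23)), requires_grad=True)
        w = Tensor(rng.uniform(0.5, 1.0, size=(1, 1, 3, 3)))
        y = conv2d(x, w, pad=5, dilation=5)
        g = np.zeros(y.shape)
        g[0, 0, 11, 11] = 1.0
        y.backward(g)
        support = np.argwhere(x.grad[0, 0] != 0)
        lo, hi = support.min(axis=0), support.max(axis=0)
        assert tuple(hi - lo + 1) == (11, 11)

    def test_channel_attention_zero_weights_half_gate(self, model16):
        m = build_model(model16.config, seed=5)
        rab = m.rabs[0]
        zero_(rab.att_down)
        zero_(rab.att_up)
        x = Tensor(rng.uniform(size=(1, 16, 6, 6)))
        out = channel_attention(x, rab.att_down, rab.att_up)
        np.testing.assert_allclose(out.data, 0.5 * x.data, atol=1e-12)

    def test_channel_attention_gates_in_open_interval(self, model64):
        rab = model64.rabs[1]
        x = Tensor(rng.standard_normal((1, 64, 5, 5)) * 50)
        out = channel_attention(x, rab.att_down, rab.att_up)
        ratio = out.data / np.where(x.data == 0, 1, x.data)
        assert np.all(np.abs(out.data) <= np.abs(x.data))
        assert np.all((ratio[x.data != 0] > 0) & (ratio[x.data != 0] < 1))

    def test_channel_attention_matches_bruteforce_oracle(self, model64):
        rab = model64.rabs[0]
        x = rng.uniform(size=(64, 4, 4))
        ours = channel_attention(
            Tensor(x[None]), rab.att_down, rab.att_up
        ).data[0]
        oracle = np_channel_attention(
            x,
            rab.att_down.w.data, rab.att_down.b.data,
            rab.att_up.w.data, rab.att_up.b.data,
        )
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_rab_identity_when_zeroed(self, model16):
        m = build_model(model16.config, seed=6)
        zero_(m.rabs[0].conv)
        x = Tensor(rng.uniform(size=(1, 16, 8, 8)))
        out = residual_attention_block(x, m.rabs[0])
        np.testing.assert_array_equal(out.data, x.data)

    def test_rab_shape_contract(self, model64):
        x = Tensor(rng.uniform(size=(1, 64, 16, 16)))
        assert residual_attention_block(x, model64.rabs[0]).shape == x.shape

    def test_ra_module_identity_when_zeroed(self, model16):
        m = build_model(model16.config, seed=7)
        for rab in m.rabs:
            zero_(rab.conv)
        zero_(m.ra_tail)
        x = Tensor(rng.uniform(size=(1, 16, 8, 8)))
        out = residual_attention_module(x, m.rabs, m.ra_tail)
        np.testing.assert_array_equal(out.data, x.data)


class TestUpDownBlocks:
    def _cache_with_L(self, m, n=1, size=8):
        cache = StageCache()
        for _ in range(n):
            cache.L_history.append(
                Tensor(rng.uniform(size=(1, m.config.base_channels, size, size)))
            )
        return cache

    def test_up_block_shape(self, model64):
        cache = StageCache()
        cache.L_history.append(Tensor(rng.uniform(size=(1, 64, 16, 16))))
        h = up_block(cache, model64.stages[0], model64.config.scale_spec)
        assert h.shape == (1, 64, 32, 32)
        assert len(cache.H_history) == 1

    def test_down_block_shape(self, model64):
        cache = StageCache()
        cache.H_history.append(Tensor(rng.uniform(size=(1, 64, 32, 32))))
        l = down_block(cache, model64.stages[0], model64.config.scale_spec)
        assert l.shape == (1, 64, 16, 16)

    def test_up_block_zero_weights_zero_output(self, model16):
        m = build_model(model16.config, seed=8)
        st = m.stages[0]
        for cw in (st.reduce_1x1, st.p, st.g, st.q, st.k):
            zero_(cw)
        cache = self._cache_with_L(m)
        h = up_block(cache, st, m.config.scale_spec)
        np.testing.assert_array_equal(h.data, 0)

    def test_up_block_error_feedback_vanishes(self, model16):
        # constant-bias construction forcing e_l = 0 => H == H0 exactly
        m = build_model(model16.config, seed=9)
        st = m.stages[0]
        zero_(st.reduce_1x1)
        st.reduce_1x1.b.data[:] = 0.3
        zero_(st.p)
        st.p.b.data[:] = 0.7
        zero_(st.g)
        st.g.b.data[:] = 0.3  # L0 becomes the same constant as L_prev
        cache = self._cache_with_L(m)
        h = up_block(cache, st, m.config.scale_spec)
        inter = cache.intermediates[-1]
        np.testing.assert_allclose(inter["e_l"].data, 0, atol=1e-15)
        np.testing.assert_array_equal(h.data, inter["H0"].data)
        assert np.all(h.data > 0)

    def test_down_block_error_feedback_vanishes(self, model16):
        m = build_model(model16.config, seed=10)
        st = m.stages[0]
        zero_(st.k)
        st.k.b.data[:] = 0.4
        zero_(st.g)  # L1 = 0 and the e_h-path conv has zero bias too (shared g)
        zero_(st.p)
        st.p.b.data[:] = 0.4  # H3 constant equals H2 constant => e_h = 0
        cache = StageCache()
        cache.H_history.append(Tensor(rng.uniform(size=(1, 16, 16, 16))))
        l = down_block(cache, st, m.config.scale_spec)
        inter = cache.intermediates[-1]
        np.testing.assert_allclose(inter["e_h"].data, 0, atol=1e-15)
        np.testing.assert_allclose(l.data, inter["L1"].data, atol=1e-15)

    def test_empty_history_raises(self, model64):
        with pytest.raises(ShapeError):
            up_block(StageCache(), model64.stages[0], model64.config.scale_spec)
        with pytest.raises(ShapeError):
            down_block(StageCache(), model64.stages[0], model64.config.scale_spec)

    def test_mismatched_history_dims_raise(self, model64):
        cache = StageCache()
        cache.L_history.append(Tensor(rng.uniform(size=(1, 64, 8, 8))))
        cache.L_history.append(Tensor(rng.uniform(size=(1, 64, 9, 9))))
        with pytest.raises(ShapeError):
            up_block(cache, model64.stages[1], model64.config.scale_spec)


class TestReconstruct:
    def test_shape_contract(self, model64):
        t = Tensor(rng.uniform(size=(1, 64, 16, 16)))
        out = reconstruct(t, model64.recon, 2)
        assert out.shape == (1, 1, 32, 32)

    def test_zero_weights_constant_beta(self, model16):
        m = build_model(model16.config, seed=12)
        zero_(m.recon.pre)
        zero_(m.recon.post)
        beta = 0.42
        m.recon.post.b.data[:] = beta
        t = Tensor(rng.uniform(size=(1, 16, 8, 8)))
        out = reconstruct(t, m.recon, 2)
        np.testing.assert_allclose(out.data, beta, atol=1e-15)


class TestForward:
    def test_shape_24_to_48(self, model16):
        img = ImageGray(rng.uniform(size=(24, 24)))
        out = mcrn_forward(img, model16)
        assert (out.height, out.width) == (48, 48)

    def test_deterministic(self, model16):
        img = ImageGray(rng.uniform(size=(16, 16)))
        a = mcrn_forward(img, model16)
        b = mcrn_forward(img, model16)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_small_input_rejected(self, model16):
        with pytest.raises(ShapeError):
            mcrn_forward(ImageGray(rng.uniform(size=(4, 4))), model16)

    def test_scale3_and_4_shapes(self):
        for s in (3, 4):
            m = build_model(ModelConfig(base_channels=16, n_ud_stages=1, scale=s), 0)
            out = mcrn_forward(ImageGray(rng.uniform(size=(8, 8))), m)
            assert (out.height, out.width) == (8 * s, 8 * s)

    def test_one_stage_forward_matches_bruteforce_oracle(self):
        m = build_model(ModelConfig(base_channels=16, n_ud_stages=1, scale=2), seed=2)
        x = rng.uniform(size=(4, 4))
        ours = forward_tensor(Tensor(x[None, None]), m).data[0, 0]
        oracle = np_forward_one_stage(x, m)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_gradient_reaches_initial_layer(self, model16):
        x = Tensor(rng.uniform(size=(1, 1, 8, 8)))
        model16.zero_grad()
        out = forward_tensor(x, model16)
        loss = l1_mean(out, Tensor(np.zeros(out.shape)))
        loss.backward()
        assert model16.init.w.grad is not None
        assert np.any(model16.init.w.grad != 0)


class TestCheckpoint:
    def test_roundtrip_bit_identical(self, model16, tmp_path):
        save_checkpoint(model16, tmp_path / "m.npz", extra={"note": 1})
        loaded, extra = load_checkpoint(tmp_path / "m.npz")
        assert extra == {"note": 1}
        a, b = model16.parameters(), loaded.parameters()
        for k in a:
            np.testing.assert_array_equal(a[k].data, b[k].data)

    def test_config_mismatch_rejected(self, model16, tmp_path):
        save_checkpoint(model16, tmp_path / "m.npz")
        with pytest.raises(ConfigError):
            load_checkpoint(tmp_path / "m.npz",
                            expect_config=ModelConfig(base_channels=64))
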