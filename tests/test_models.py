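"""Network building blocks, model structure, inference, spline baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srflow as sf
from srflow._nn.autograd import Tensor
from srflow._nn.layers import SEBlock
from srflow._nn.optim import Adam
from srflow.losses import combined_loss_t
from srflow.models import TINY_PRESET, infer, load_checkpoint, save_checkpoint


class TestVoxelShuffle:
    def test_shape_arithmetic(self, rng):
        out = sf.voxel_shuffle(rng.standard_normal((8, 2, 2, 2)), 2)
        assert out.shape == (1, 4, 4, 4)

    def test_index_mapping(self):
        # input channel a*s^2 + b*s + e lands at spatial offset (a, b, e)
        s = 2
        feat = np.zeros((8, 1, 1, 1))
        feat[5] = 1.0  # a, b, e = 1, 0, 1
        out = sf.voxel_shuffle(feat, s)
        assert out[0, 1, 0, 1] == 1.0 and out.sum() == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        s=st.integers(1, 3),
        c=st.integers(1, 3),
        h=st.integers(1, 3),
        w=st.integers(1, 3),
        d=st.integers(1, 3),
        seed=st.integers(0, 100),
    )
    def test_bijection_and_multiset(self, s, c, h, w, d, seed):
        feat = np.random.default_rng(seed).standard_normal((c * s**3, h, w, d))
        out = sf.voxel_shuffle(feat, s)
        np.testing.assert_array_equal(sf.inverse_voxel_shuffle(out, s), feat)
        assert np.array_equal(np.sort(out.ravel()), np.sort(feat.ravel()))

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sf.voxel_shuffle(np.zeros((6, 2, 2, 2)), 2)


class TestSEBlock:
    def test_gating_properties(self, rng):
        se = SEBlock(8, 4, np.random.default_rng(0))
        x = rng.standard_normal((2, 8, 4, 4, 4))
        out = se(Tensor(x)).data
        assert out.shape == x.shape
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)  # gates in (0, 1)
        zero = se(Tensor(np.zeros_like(x))).data
        assert np.all(zero == 0.0)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SEBlock(8, 3, np.random.default_rng(0))


class TestModelStructure:
    @pytest.mark.parametrize(
        "s,lr_shape", [(2, (24, 24, 12)), (3, (16, 16, 8)), (4, (12, 12, 6))]
    )
    def test_output_shape_per_scale(self, rng, s, lr_shape):
        cfg = sf.ModelConfig(scale=s, **TINY_PRESET)
        net = sf.build_model(cfg, seed=0)
        out = net.forward_array(rng.standard_normal(lr_shape + (3,)))
        assert out.shape == (48, 48, 24, 3)

    def test_init_determinism(self):
        cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
        a = sf.build_model(cfg, seed=5)
        b = sf.build_model(cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_zeroed_residual_branch_reduces_to_coarse(self, rng):
        cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
        net = sf.build_model(cfg, seed=2)
        x = rng.standard_normal((8, 8, 8, 3))
        net.zero_residual_branch()
        full = net.forward_array(x)
        coarse = np.moveaxis(
            net.coarse_forward(Tensor(np.moveaxis(x, -1, 0)[None])).data[0], 0, -1
        )
        np.testing.assert_allclose(full, coarse, atol=1e-12)

    def test_parameter_count_regression(self):
        """Layer-by-layer arithmetic for the tiny preset (C=8, N=M=1, p=4,
        r=4, s=2), counted once by hand and frozen:

        head 3x3x3 3->8:      648 v + 8 g + 8 b   =   664
        block expand 8->32:   256 v + 32 g + 32 b =   320
        block project 32->8: 6912 v + 8 g + 8 b   =  6928
        block SE 8<->2:       16 + 2 + 16 + 8     =    42
        deep tail 8->64:    13824 v + 64 g + 64 b = 13952
        coarse 3->64:        5184 v + 64 g + 64 b =  5312
        final 8->3:           648 v + 3 g + 3 b   =   654
        """
        cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
        assert sf.build_model(cfg, seed=0).n_parameters() == 27872

    def test_wdsr3d_variant_has_no_se(self):
        cfg = sf.ModelConfig(scale=2, variant="wdsr3d", **TINY_PRESET)
        net = sf.build_model(cfg, seed=0)
        assert all(blk.se is None for grp in net.groups for blk in grp)

    def test_gradient_reaches_every_parameter(self, rng):
        net = sf.build_model(sf.ModelConfig(scale=2, **TINY_PRESET), seed=0)
        x = rng.standard_normal((4, 3, 6, 6, 6)) * 0.8
        ref = rng.standard_normal((4, 3, 12, 12, 12)) * 0.5
        loss = combined_loss_t(net(Tensor(x)), ref)
        net.zero_grad()
        loss.backward()
        for p in net.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0.0)

    def test_network_gradient_matches_finite_differences(self, rng):
        cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
        net = sf.build_model(cfg, seed=3)
        x = rng.standard_normal((1, 3, 5, 5, 5)) * 0.4
        ref = rng.standard_normal((1, 3, 10, 10, 10)) * 0.4

        def loss_val():
            return combined_loss_t(net(Tensor(x)), ref).item()

        loss = combined_loss_t(net(Tensor(x)), ref)
        net.zero_grad()
        loss.backward()
        eps = 1e-6
        checked = 0
        for p in (net.parameters()[0], net.parameters()[7], net.parameters()[-1]):
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + eps
            hi = loss_val()
            p.data[idx] = old - eps
            lo = loss_val()
            p.data[idx] = old
            num = (hi - lo) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
            checked += 1
        assert checked == 3


class TestInference:
    @pytest.mark.parametrize("variant", ["srflow", "wdsr3d"])
    def test_tiled_matches_whole_volume(self, rng, variant):
        cfg = sf.ModelConfig(scale=2, variant=variant, **TINY_PRESET)
        net = sf.build_model(cfg, seed=1)
        x = rng.standard_normal((16, 16, 16, 3)) * 0.3
        whole = infer(net, x)
        tiled = infer(net, x, tile_shape=(12, 12, 12), overlap=8)
        assert whole.shape == (32, 32, 32, 3)
        assert np.abs(whole - tiled).max() < 1e-4

    def test_deterministic_given_weights(self, tiny_net, rng):
        x = rng.standard_normal((8, 8, 8, 3))
        np.testing.assert_array_equal(
            tiny_net.forward_array(x), tiny_net.forward_array(x)
        )

    def test_undersized_tile_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError, match="tile"):
            infer(tiny_net, rng.standard_normal((16, 16, 16, 3)),
                  tile_shape=(6, 6, 6), overlap=8)

    @pytest.mark.parametrize("variant", ["srflow", "wdsr3d"])
    def test_translation_consistency(self, rng, variant):
        """Shifting the input by one LR voxel shifts the output interior by
        s HR voxels (checked away from borders)."""
        cfg = sf.ModelConfig(scale=2, variant=variant, **TINY_PRESET)
        net = sf.build_model(cfg, seed=1)
        x = rng.standard_normal((16, 16, 16, 3)) * 0.3
        out = net.forward_array(x)
        out_shifted = net.forward_array(np.roll(x, 1, axis=0))
        m = 12
        diff = np.abs(np.roll(out, 2, axis=0) - out_shifted)
        assert diff[m:-m, m:-m, m:-m].max() < 1e-4


class TestCubicSpline:
    def test_constant_reproduction(self):
        const = np.full((8, 8, 8, 3), 0.7)
        up = sf.cubic_spline_upsample(const, 2)
        np.testing.assert_allclose(up, 0.7, rtol=1e-12)

    def test_linear_reproduction(self):
        g = np.arange(8.0)
        lin = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1) / 7.0
        up = sf.cubic_spline_upsample(lin, 2)
        h = np.arange(16.0) / 2
        ref = np.stack(np.meshgrid(h, h, h, indexing="ij"), axis=-1) / 7.0
        assert np.abs(up - ref).max() < 1e-10

    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal((8, 8, 8, 3))
        np.testing.assert_array_equal(sf.cubic_spline_upsample(x, 1), x)

    def test_estimator_interface(self, rng):
        est = sf.CubicSplineUpsampler(scale=3).fit()
        x = rng.standard_normal((2, 8, 8, 8, 3))
        out = est.predict(x)
        assert out.shape == (2, 24, 24, 24, 3)
        assert est.get_params() == {"scale": 3}


class TestCheckpoints:
    def test_round_trip(self, tmp_path, rng):
        est = sf.SRFlowRegressor(
            scale=2, epochs=1, patches_per_epoch=8, batch_size=2,
            patch_shape=(4, 4, 4), random_state=0, **TINY_PRESET
        )
        X = rng.standard_normal((2, 8, 8, 8, 3)) * 0.4
        y = rng.standard_normal((2, 16, 16, 16, 3)) * 0.4
        est.fit(X, y)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, est)
        back = load_checkpoint(path)
        np.testing.assert_array_equal(back.predict(X[0]), est.predict(X[0]))
        assert back.v_max_ == est.v_max_
        assert back.get_params() == est.get_params()


def test_one_adam_step_reduces_loss_on_fixed_batch(rng):
    cfg = sf.ModelConfig(scale=2, **TINY_PRESET)
    net = sf.build_model(cfg, seed=4)
    x = rng.standard_normal((2, 3, 6, 6, 6)) * 0.5
    ref = rng.standard_normal((2, 3, 12, 12, 12)) * 0.3
    opt = Adam(net.parameters(), lr=1e-3)
    losses = []
    for _ in range(5):
        loss = combined_loss_t(net(Tensor(x)), ref)
        losses.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert losses[-1] < losses[0]
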