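"""Network blocks: maxout competition, dense blocks, attention, topology."""

import itertools

import numpy as np
import pytest

from obseg.errors import ShapeError, SpecError
from obseg.image_io import VolumeImage, default_affine, extract_multislice_stacks
from obseg.networks import (NetworkSpec, build_localization_net,
                            build_segmentation_net, build_view_nets,
                            forward_view, load_checkpoint, localization_spec,
                            save_checkpoint, segmentation_spec)
from obseg.nn import SelfAttention2d, Tensor, maxout_fuse
from obseg.nn import autograd as ag


class TestMaxout:
    def test_elementwise_maximum(self):
        out = maxout_fuse(np.array([[1.0, -2.0]]), np.array([[0.0, 3.0]]))
        np.testing.assert_array_equal(out, [[1.0, 3.0]])

    def test_idempotent_and_commutative(self, rng):
        a = rng.standard_normal((4, 5)).astype(np.float32)
        b = rng.standard_normal((4, 5)).astype(np.float32)
        np.testing.assert_array_equal(maxout_fuse(a, a), a)
        np.testing.assert_array_equal(maxout_fuse(a, b), maxout_fuse(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            maxout_fuse(np.zeros((2, 2)), np.zeros((3, 2)))


class TestNetworkSpec:
    def test_attention_requires_sum_fusion_and_3x3(self):
        with pytest.raises(SpecError):
            NetworkSpec(attention=True, kernel=5, skip_fusion="sum")
        with pytest.raises(SpecError):
            NetworkSpec(attention=True, kernel=3, skip_fusion="maxout")
        with pytest.raises(SpecError):
            NetworkSpec(attention=False, kernel=3, skip_fusion="maxout")

    def test_attention_channels_divisible_by_8(self):
        with pytest.raises(SpecError):
            segmentation_spec(filters=12)


class TestCompetitiveDenseBlock:
    def _block(self, is_first, in_ch=8, seed=3):
        from obseg.networks import CompetitiveDenseBlock
        spec = segmentation_spec(filters=8)
        return CompetitiveDenseBlock(in_ch, spec, np.random.default_rng(seed),
                                     is_first=is_first)

    def test_output_shape(self, rng):
        blk = self._block(is_first=True, in_ch=3)
        x = Tensor(rng.random((2, 3, 12, 12)).astype(np.float32))
        assert blk(x).data.shape == (2, 8, 12, 12)

    def test_first_block_variant_is_a_distinct_function(self, rng):
        x = rng.random((1, 8, 10, 10)).astype(np.float32)
        a = self._block(is_first=True)
        b = self._block(is_first=False)
        b.load_state_dict({k: v for k, v in a.state_dict().items()
                           if k in dict.fromkeys(
                               f"{kind}:{n}" for kind, n in
                               [(kk.split(':')[0], kk.split(':', 1)[1])
                                for kk in b.state_dict()])})
        a.eval(), b.eval()
        assert not np.allclose(a(Tensor(x)).data, b(Tensor(x)).data)

    def test_matches_straight_line_composition(self, rng):
        """Independently coded numpy composition of the same primitive
        sequence (PReLU -> conv -> BN, maxout chaining) in eval mode."""
        blk = self._block(is_first=False)
        blk.eval()
        for p in blk.parameters():
            p.data = p.data.astype(np.float64)
        x = rng.standard_normal((1, 8, 9, 9))

        def conv_ref(inp, w, b):
            C_out, C_in, k, _ = w.shape
            p = k // 2
            xp = np.pad(inp, ((0, 0), (p, p), (p, p)))
            out = np.zeros((C_out, inp.shape[1], inp.shape[2]))
            for co in range(C_out):
                for ci in range(C_in):
                    for di in range(k):
                        for dj in range(k):
                            out[co] += (w[co, ci, di, dj]
                                        * xp[ci, di:di + 9, dj:dj + 9])
                out[co] += b[co]
            return out

        def bn_ref(inp, bn):
            g = bn.gamma.data[:, None, None]
            b = bn.beta.data[:, None, None]
            mu = bn.running_mean[:, None, None]
            var = bn.running_var[:, None, None]
            return g * (inp - mu) / np.sqrt(var + bn.eps) + b

        def prelu_ref(inp, slope):
            return np.where(inp > 0, inp, slope.data * inp)

        h = x[0].astype(np.float64)
        x1 = bn_ref(conv_ref(prelu_ref(h, blk.act1.slope),
                             blk.conv1.weight.data, blk.conv1.bias.data), blk.bn1)
        m1 = np.maximum(x1, h)
        x2 = bn_ref(conv_ref(prelu_ref(m1, blk.act2.slope),
                             blk.conv2.weight.data, blk.conv2.bias.data), blk.bn2)
        m2 = np.maximum(x2, m1)
        x3 = bn_ref(conv_ref(prelu_ref(m2, blk.act3.slope),
                             blk.conv3.weight.data, blk.conv3.bias.data), blk.bn3)
        got = blk(Tensor(x[None][0])).data[0]
        np.testing.assert_allclose(got, x3, atol=1e-9)


class TestSelfAttention:
    def _oracle(self, att, x):
        """Brute-force double loop over all N^2 position pairs."""
        B, C, H, W = x.shape
        N = H * W
        out = np.empty_like(x, dtype=np.float64)
        wa, ba = att.proj_a.weight.data[..., 0, 0], att.proj_a.bias.data
        wb, bb = att.proj_b.weight.data[..., 0, 0], att.proj_b.bias.data
        wc, bc = att.proj_c.weight.data[..., 0, 0], att.proj_c.bias.data
        alpha = att.alpha.data.item()
        for b in range(B):
            flat = x[b].reshape(C, N).astype(np.float64)
            fa = wa @ flat + ba[:, None]
            fb = wb @ flat + bb[:, None]
            fc = wc @ flat + bc[:, None]
            s = np.empty((N, N))
            for j in range(N):
                e = np.array([np.exp(fa[:, i] @ fb[:, j]) for i in range(N)])
                s[j] = e / e.sum()
            ctx = np.empty((C, N))
            for j in range(N):
                ctx[:, j] = sum(s[j, i] * fc[:, i] for i in range(N))
            out[b] = (alpha * ctx + flat).reshape(C, H, W)
        return out

    @pytest.mark.parametrize("C,H,W", [(8, 2, 3), (8, 3, 4), (16, 2, 2),
                                       (16, 4, 3)])
    def test_matches_nested_loop_oracle(self, C, H, W, rng):
        att = SelfAttention2d(C, np.random.default_rng(5), norm_mode="identity")
        att.alpha.data[:] = 0.7  # exercise the non-trivial residual path
        att.eval()
        x = rng.standard_normal((2, C, H, W)).astype(np.float32)
        got = att(Tensor(x)).data
        np.testing.assert_allclose(got, self._oracle(att, x), atol=1e-5)

    def test_identity_at_initialisation(self, rng):
        att = SelfAttention2d(8, np.random.default_rng(0), norm_mode="identity")
        assert att.alpha.data.item() == 0.0
        x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(att(Tensor(x)).data, x)

    def test_attention_map_rows_sum_to_one(self, rng):
        att = SelfAttention2d(8, np.random.default_rng(2))
        x = rng.standard_normal((2, 8, 3, 3)).astype(np.float32)
        S = att.attention_map(x)
        np.testing.assert_allclose(S.sum(axis=-1), 1.0, atol=1e-6)

    def test_channels_not_divisible_by_8(self):
        with pytest.raises(SpecError):
            SelfAttention2d(12, np.random.default_rng(0))


class TestTopology:
    def test_localization_probabilities_sum_to_one(self, rng):
        net = build_localization_net(localization_spec(filters=16),
                                     np.random.default_rng(0))
        net.eval()
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        p = net(Tensor(x)).data
        assert p.shape == (2, 2, 32, 32)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all() and (p <= 1).all()

    def test_three_views_have_identical_parameter_counts(self):
        nets = build_view_nets(localization_spec(filters=16), seed=4)
        counts = {v: n.parameter_count() for v, n in nets.items()}
        assert len(set(counts.values())) == 1

    def test_segmentation_net_has_nine_zero_initialised_attention_modules(self):
        net = build_segmentation_net(segmentation_spec(filters=16),
                                     np.random.default_rng(0))
        mods = net.attention_modules()
        assert len(mods) == 9
        assert all(m.alpha.data.item() == 0.0 for m in mods)

    def test_segmentation_forward_full_crop_size(self, rng):
        net = build_segmentation_net(segmentation_spec(filters=16),
                                     np.random.default_rng(0))
        net.eval()
        x = rng.random((1, 3, 96, 96)).astype(np.float32)
        with ag.no_grad():
            p = net(Tensor(x)).data
        assert p.shape == (1, 2, 96, 96)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_attention_ablation_equivalence(self, rng):
        """alpha=0 with identity output normalisation reproduces the
        attention-free forward pass of the same weights."""
        net = build_segmentation_net(segmentation_spec(filters=8),
                                     np.random.default_rng(3))
        net.eval()
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        net.set_attention_norm_mode("identity")
        with_att = net(Tensor(x)).data
        originals = []
        for m in net.attention_modules():
            originals.append(m.forward)
            m.forward = lambda t: t  # excise the module entirely
        without = net(Tensor(x)).data
        for m, f in zip(net.attention_modules(), originals):
            m.forward = f
        np.testing.assert_allclose(with_att, without, atol=1e-5)

    def test_attention_size_limit(self, rng):
        net = build_segmentation_net(segmentation_spec(filters=8),
                                     np.random.default_rng(0))
        with pytest.raises(SpecError):
            net(Tensor(rng.random((1, 3, 112, 112)).astype(np.float32)))


class TestPooling:
    def test_unpool_restores_maxima_positions(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 8, 8)).astype(np.float32))
        pooled, idx = ag.max_pool2x2(x)
        restored = ag.max_unpool2x2(pooled, idx).data
        # each 2x2 window: maximum at its original position, zeros elsewhere
        r = x.data.reshape(2, 3, 4, 2, 4, 2)
        rr = restored.reshape(2, 3, 4, 2, 4, 2)
        for b, c, i, j in itertools.product(range(2), range(3), range(4), range(4)):
            win = r[b, c, i, :, j, :]
            out = rr[b, c, i, :, j, :]
            k = np.unravel_index(win.argmax(), (2, 2))
            assert out[k] == win.max()
            assert (out.sum() == out[k])


class TestForwardView:
    def _stacks(self, rng, shape=(20, 24, 28)):
        vol = VolumeImage(rng.random(shape).astype(np.float32),
                          default_affine(1.0))
        return extract_multislice_stacks(vol, "axial")

    def test_probability_slabs(self, rng):
        net = build_localization_net(localization_spec(filters=16),
                                     np.random.default_rng(1))
        stacks = self._stacks(rng)
        probs = forward_view(net, stacks)
        assert probs.shape == (28, 2, 20, 24)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_eval_mode_is_deterministic(self, rng):
        net = build_localization_net(localization_spec(filters=16),
                                     np.random.default_rng(1))
        stacks = self._stacks(rng, (16, 16, 6))
        a = forward_view(net, stacks)
        b = forward_view(net, stacks)
        np.testing.assert_array_equal(a, b)


class TestCheckpoints:
    def test_round_trip(self, tmp_path, rng):
        spec = segmentation_spec(filters=8)
        net = build_segmentation_net(spec, np.random.default_rng(6))
        net.eval()
        x = rng.random((1, 3, 16, 16)).astype(np.float32)
        before = net(Tensor(x)).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path, stage="seg", view="axial", split=2,
                        meta={"best_val_dice": 0.5})
        loaded, header = load_checkpoint(path, expected_spec=spec)
        after = loaded(Tensor(x)).data
        np.testing.assert_array_equal(before, after)
        assert header["view"] == "axial" and header["split"] == 2

    def test_spec_mismatch_detected(self, tmp_path):
        from obseg.errors import ConfigurationError
        net = build_segmentation_net(segmentation_spec(filters=8),
                                     np.random.default_rng(0))
        path = tmp_path / "c.npz"
        save_checkpoint(net, path, stage="seg", view="axial")
        with pytest.raises(ConfigurationError):
            load_checkpoint(path, expected_spec=segmentation_spec(filters=16))
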