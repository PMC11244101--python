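"""Fusion network: shapes, attention invariants, fusion algebra, training smoke."""

import dataclasses

import numpy as np
import pytest

from radarid.network import (NetworkConfig, FusionNet, UnimodalNet, BranchNet,
                             ChannelAttention, SpatialAttention, CBAMFusion,
                             TemporalSelfAttention, save_checkpoint,
                             load_checkpoint)
from radarid.nn import Tensor, Adam, cross_entropy, softmax

CFG = NetworkConfig(n_classes=5, k_bins=7, window_length=128, rng_seed=3)


def _x(rng, n=2, m=3, k=7, l=128):
    return rng.normal(size=(n, m, k, l)).astype(np.float32)


class TestBranch:
    def test_output_shape_with_unit_conv_stride(self):
        """Stride-1 conv block + two stride-(1,2) blocks: [1,7,512] -> [64,7,128]."""
        cfg = NetworkConfig(n_classes=5, k_bins=7, window_length=512,
                            conv_block_time_stride=1)
        branch = BranchNet(cfg, np.random.default_rng(0))
        out = branch(Tensor(np.zeros((1, 1, 7, 512), np.float32)))
        assert out.shape == (1, 64, 7, 128)
        assert cfg.time_steps == 128

    def test_default_output_shape(self, rng):
        branch = BranchNet(CFG, np.random.default_rng(0))
        out = branch(Tensor(_x(rng, m=1)[:, 0:1]))
        assert out.shape == (2, CFG.branch_out_channels, 7, CFG.time_steps)

    @pytest.mark.parametrize("blocks", [0, 1, 2, 3])
    def test_residual_block_ablation_axis(self, blocks, rng):
        cfg = dataclasses.replace(CFG, n_residual_blocks=blocks)
        net = FusionNet(cfg)
        out = net(Tensor(_x(rng)))
        assert out.shape == (2, 5)

    def test_zero_input_zero_output_in_inference(self):
        """Bias-free weights, inference-mode BN: zeros map to zeros."""
        branch = BranchNet(CFG, np.random.default_rng(0))
        branch.eval()
        for p in branch.parameters():
            if p.data.ndim >= 2 or p.data.sum() != p.data.size:  # skip BN gamma=1
                p.data = np.zeros_like(p.data)
        out = branch(Tensor(np.zeros((1, 1, 7, 128), np.float32)))
        assert np.allclose(out.data, 0.0)


class TestChannelAttention:
    def test_zero_mlp_gives_half(self, rng):
        ca = ChannelAttention(16, 8, np.random.default_rng(0))
        for p in ca.parameters():
            p.data = np.zeros_like(p.data)
        mc = ca(Tensor(rng.normal(size=(2, 16, 3, 4)).astype(np.float32)))
        assert mc.shape == (2, 16, 1, 1)
        assert np.allclose(mc.data, 0.5)

    def test_range_is_open_unit_interval(self, rng):
        ca = ChannelAttention(16, 8, np.random.default_rng(1))
        mc = ca(Tensor(rng.normal(size=(3, 16, 4, 4)).astype(np.float32)))
        assert (mc.data > 0).all() and (mc.data < 1).all()

    def test_constant_channels_match_hand_oracle(self):
        """Per-channel-constant input: max = avg pool, so M_C = sigmoid(2*MLP(v))."""
        ca = ChannelAttention(2, 2, np.random.default_rng(2))
        v = np.array([[1.5, -0.5]], dtype=np.float32)
        x = np.broadcast_to(v[:, :, None, None], (1, 2, 3, 3)).astype(np.float32)
        mc = ca(Tensor(x.copy()))
        w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
        w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
        h = np.maximum(v @ w1 + b1, 0.0) @ w2 + b2
        expect = 1.0 / (1.0 + np.exp(-2.0 * h))
        assert np.allclose(mc.data.reshape(1, 2), expect, atol=1e-6)

    def test_reduction_larger_than_channels_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(4, 8, np.random.default_rng(0))


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        sa = SpatialAttention(7, np.random.default_rng(0))
        for p in sa.parameters():
            p.data = np.zeros_like(p.data)
        ms = sa(Tensor(rng.normal(size=(2, 16, 5, 9)).astype(np.float32)))
        assert ms.shape == (2, 1, 5, 9)
        assert np.allclose(ms.data, 0.5)

    def test_channel_permutation_invariance(self, rng):
        sa = SpatialAttention(7, np.random.default_rng(1))
        x = rng.normal(size=(1, 8, 4, 6)).astype(np.float32)
        perm = rng.permutation(8)
        assert np.allclose(sa(Tensor(x)).data, sa(Tensor(x[:, perm])).data,
                           atol=1e-6)


class TestFusion:
    def test_additive_identity_before_attention(self, rng):
        fusion = CBAMFusion(CFG, np.random.default_rng(0))
        f1 = rng.normal(size=(1, 64, 7, 8)).astype(np.float32)
        zero = np.zeros_like(f1)
        out1 = fusion([Tensor(f1), Tensor(zero), Tensor(zero)])
        out2 = fusion([Tensor(f1), Tensor(f1 * 0), Tensor(f1 * 0)])
        assert np.allclose(out1.data, out2.data)

    def test_contraction_property(self, rng):
        """|F''| <= |F| element-wise: both attention weights are < 1."""
        fusion = CBAMFusion(CFG, np.random.default_rng(0))
        fs = [Tensor(rng.normal(size=(2, 64, 7, 8)).astype(np.float32))
              for _ in range(3)]
        out = fusion(fs)
        f_sum = fs[0].data + fs[1].data + fs[2].data
        assert (np.abs(out.data) <= np.abs(f_sum) + 1e-7).all()
        assert (fusion.last_mc > 0).all() and (fusion.last_mc < 1).all()
        assert (fusion.last_ms > 0).all() and (fusion.last_ms < 1).all()

    @pytest.mark.parametrize("scheme", ["channel-homog", "distance-homog"])
    def test_alternative_fusion_schemes_run(self, scheme, rng):
        cfg = dataclasses.replace(CFG, fusion=scheme)
        net = FusionNet(cfg)
        out = net(Tensor(_x(rng)))
        assert out.shape == (2, 5)


class TestTemporalAttention:
    def test_single_step_returns_v(self, rng):
        """Wt=1: the attention distribution is [[1]] and the output equals V."""
        att = TemporalSelfAttention(6, 4, np.random.default_rng(0))
        x = rng.normal(size=(1, 3, 2, 1)).astype(np.float32)   # Wt = 1
        out = att(Tensor(x))
        assert np.allclose(att.last_attention, 1.0)
        ft = x.transpose(0, 3, 1, 2).reshape(1, 1, 6)
        proj = ft @ att.proj.weight.data + att.proj.bias.data
        v = proj @ att.wv.weight.data + att.wv.bias.data
        assert np.allclose(out.data, v, atol=1e-5)

    def test_zero_query_gives_uniform_attention(self, rng):
        """W_Q = 0 (and zero bias): A' is uniform and the output is the
        column-mean of V replicated across time steps."""
        att = TemporalSelfAttention(6, 4, np.random.default_rng(1))
        att.wq.weight.data = np.zeros_like(att.wq.weight.data)
        att.wq.bias.data = np.zeros_like(att.wq.bias.data)
        x = rng.normal(size=(1, 3, 2, 5)).astype(np.float32)
        out = att(Tensor(x))
        assert np.allclose(att.last_attention, 1.0 / 5.0, atol=1e-6)
        ft = x.transpose(0, 3, 1, 2).reshape(1, 5, 6)
        proj = ft @ att.proj.weight.data + att.proj.bias.data
        v = proj @ att.wv.weight.data + att.wv.bias.data
        assert np.allclose(out.data, np.broadcast_to(v.mean(axis=1, keepdims=True),
                                                     out.shape), atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        att = TemporalSelfAttention(6, 4, np.random.default_rng(2))
        att(Tensor(rng.normal(size=(3, 3, 2, 9)).astype(np.float32)))
        assert np.allclose(att.last_attention.sum(axis=-1), 1.0, atol=1e-6)


class TestClassifierOutputs:
    def test_probabilities_sum_to_one(self, rng):
        net = FusionNet(CFG).eval()
        proba = net.predict_proba(_x(rng, n=4))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba > 0).all() and (proba < 1).all()

    def test_softmax_shift_invariance_and_stability(self):
        z = Tensor(np.array([[0.0, 0.0, 0.0], [5.0, -995.0, 5.0]], np.float32))
        p = softmax(z, axis=1).data
        assert np.allclose(p[0], 1 / 3)
        assert p[1, 1] < 1e-20 and np.isfinite(p).all()
        shifted = softmax(Tensor(z.data + 123.0), axis=1).data
        assert np.allclose(shifted, p, atol=1e-9)

    def test_branch_shuffling_changes_outputs(self, rng):
        """Branches have independent weights, so permuting the modality order
        changes the prediction."""
        net = FusionNet(CFG).eval()
        x = _x(rng, n=2)
        out = net(Tensor(x)).data
        out_perm = net(Tensor(x[:, [2, 0, 1]])).data
        assert not np.allclose(out, out_perm, atol=1e-4)

    def test_unimodal_consumes_single_channel(self, rng):
        net = UnimodalNet(CFG).eval()
        out = net(Tensor(_x(rng, m=1)))
        assert out.shape == (2, 5)
        with pytest.raises(ValueError):
            net(Tensor(_x(rng, m=3)))


class TestTrainingSmoke:
    def test_one_step_reduces_batch_loss(self, rng):
        net = FusionNet(CFG)
        x, y = _x(rng, n=8), np.arange(8) % 5
        opt = Adam(net.parameters(), lr=1e-3)
        net.train()
        l0 = cross_entropy(net(Tensor(x)), y)
        l0.backward()
        opt.step()
        opt.zero_grad()
        l1 = cross_entropy(net(Tensor(x)), y)
        assert float(l1.data) < float(l0.data)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = FusionNet(CFG).eval()
        x = _x(rng)
        before = net(Tensor(x)).data
        save_checkpoint(net, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz").eval()
        assert np.allclose(back(Tensor(x)).data, before, atol=1e-7)
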