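"""Three-branch residual network with spatial-channel attention fusion and
temporal self-attention for radar vital-sign identity recognition.

Architecture
------------
Each modality window [1 x K bins x L frames] passes through its own branch
(shared architecture, independent weights): a conv block (conv 3x3 -> BN ->
ReLU, time stride 4 — its job is to pull the long frame axis toward the short
bin axis) followed by ``n_residual_blocks`` residual blocks.  Block i maps
``base*2^i -> base*2^(i+1)`` channels with stride (1, 2) on the time axis, so
the default two blocks turn [1 x 7 x 512] into [64 x 7 x 32].

The three branch outputs are fused CBAM-style: element-wise sum F, channel
attention M_C = sigmoid(MLP(maxpool F) + MLP(avgpool F)) with a shared
two-layer MLP (reduction r), F' = M_C * F; spatial attention from the
channel-wise max/mean maps concatenated and convolved k x k to one map,
F'' = M_S * F'.  Two alternative fusion schemes (channel-dimension and
distance-dimension homogenization + concatenation) are available for the
ablation study.

F'' is reshaped to a time-series matrix [Wt x C*H], linearly projected to
d_model features, and passed through scaled dot-product self-attention
softmax(Q K^T / sqrt(d_k)) V; the result is flattened, mapped to a 128-d
embedding and a softmax classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (Tensor, Module, ModuleList, Conv2d, BatchNorm2d, Linear,
                 concat, softmax)

__all__ = ["NetworkConfig", "BranchNet", "ChannelAttention", "SpatialAttention",
           "CBAMFusion", "HomogenizedFusion", "TemporalSelfAttention",
           "ClassifierHead", "FusionNet", "UnimodalNet", "build_model",
           "save_checkpoint", "load_checkpoint"]

FUSION_SCHEMES = ("cbam", "channel-homog", "distance-homog")


@dataclass(frozen=True)
class NetworkConfig:
    n_classes: int
    k_bins: int = 7
    window_length: int = 512
    n_residual_blocks: int = 2
    base_channels: int = 16
    conv_block_time_stride: int = 4
    channel_attention_reduction: int = 8
    spatial_attention_kernel: int = 7
    attention_model_dim: int = 64       # d_model = d_k, single head
    embedding_dim: int = 128
    fusion: str = "cbam"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.embedding_dim < 1 or self.attention_model_dim < 1:
            raise ValueError("embedding and attention dims must be >= 1")
        if self.n_residual_blocks < 0 or self.base_channels < 1:
            raise ValueError("invalid branch configuration")
        if self.fusion not in FUSION_SCHEMES:
            raise ValueError(f"fusion must be one of {FUSION_SCHEMES}")
        if self.spatial_attention_kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")

    @property
    def branch_out_channels(self) -> int:
        return self.base_channels * 2 ** self.n_residual_blocks

    @property
    def time_steps(self) -> int:
        s = self.conv_block_time_stride
        wt = (self.window_length + s - 1) // s    # 'same'-padded strided convs
        for _ in range(self.n_residual_blocks):
            wt = (wt + 1) // 2
        return wt


class ResidualBlock(Module):
    """Residual path: conv-BN-ReLU-conv-BN; shortcut: 1x1 conv-BN; sum -> ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: tuple[int, int],
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.shortcut = Conv2d(c_in, c_out, 1, rng, stride=stride, padding=(0, 0))
        self.bn_sc = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        main = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (main + self.bn_sc(self.shortcut(x))).relu()


class BranchNet(Module):
    """Per-modality spatial feature extractor (conv block + residual blocks)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        # The conv block's role is size correction: its time stride pulls the
        # frame axis toward the bin axis before 2-D feature extraction.
        self.conv = Conv2d(1, cfg.base_channels, 3, rng,
                           stride=(1, cfg.conv_block_time_stride))
        self.bn = BatchNorm2d(cfg.base_channels)
        blocks = []
        c = cfg.base_channels
        for _ in range(cfg.n_residual_blocks):
            blocks.append(ResidualBlock(c, c * 2, stride=(1, 2), rng=rng))
            c *= 2
        self.blocks = ModuleList(blocks)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn(self.conv(x)).relu()
        for block in self.blocks:
            out = block(out)
        return out


class ChannelAttention(Module):
    """Shared-MLP channel attention over global max- and average-pooled maps."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels < reduction or channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, f: Tensor) -> Tensor:
        mx = f.amax(axis=(2, 3))          # [N, C]
        av = f.mean(axis=(2, 3))
        mc = (self._mlp(mx) + self._mlp(av)).sigmoid()
        n, c = mc.shape
        return mc.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Single k x k conv over concatenated channel-wise max/mean maps."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, kernel, rng)

    def forward(self, f: Tensor) -> Tensor:
        mx = f.amax(axis=1, keepdims=True)    # [N, 1, H, W]
        av = f.mean(axis=1, keepdims=True)
        return self.conv(concat([mx, av], axis=1)).sigmoid()


class CBAMFusion(Module):
    """Element-wise sum of branch features, reweighted by channel then spatial
    attention: F'' = M_S * (M_C * (F1 + F2 + F3))."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.channel = ChannelAttention(cfg.branch_out_channels,
                                        cfg.channel_attention_reduction, rng)
        self.spatial = SpatialAttention(cfg.spatial_attention_kernel, rng)
        self.last_mc: np.ndarray | None = None
        self.last_ms: np.ndarray | None = None

    def forward(self, feats: list[Tensor]) -> Tensor:
        f = feats[0]
        for other in feats[1:]:
            f = f + other
        mc = self.channel(f)
        fp = mc * f
        ms = self.spatial(fp)
        self.last_mc, self.last_ms = mc.data, ms.data
        return ms * fp


class HomogenizedFusion(Module):
    """Ablation fusion schemes: collapse (mean) and normalize one dimension of
    each branch feature, then concatenate along a new axis.

    ``mode='channel'`` collapses the channel dimension -> (features, bins, time);
    ``mode='distance'`` collapses the bin dimension -> (features, channels, time).
    """

    def __init__(self, mode: str):
        if mode not in ("channel", "distance"):
            raise ValueError("mode must be 'channel' or 'distance'")
        self.mode = mode

    @staticmethod
    def _normalize(x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
        return (x - mu) * (var + 1e-6) ** -0.5

    def forward(self, feats: list[Tensor]) -> Tensor:
        axis = 1 if self.mode == "channel" else 2
        collapsed = [self._normalize(f.mean(axis=axis, keepdims=True)) for f in feats]
        return concat(collapsed, axis=axis)


class TemporalSelfAttention(Module):
    """Scaled dot-product self-attention over the time axis of F''."""

    def __init__(self, in_features: int, d_model: int, rng: np.random.Generator):
        if d_model < 1:
            raise ValueError("d_k must be >= 1")
        self.proj = Linear(in_features, d_model, rng)
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.d_model = d_model
        self.last_attention: np.ndarray | None = None

    def forward(self, f: Tensor) -> Tensor:
        # [N, C, H, Wt] -> time-major series [N, Wt, C*H] -> project to d_model.
        n, c, h, wt = f.shape
        ft = self.proj(f.transpose((0, 3, 1, 2)).reshape(n, wt, c * h))
        q, k, v = self.wq(ft), self.wk(ft), self.wv(ft)
        a = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(self.d_model))
        a_dist = softmax(a, axis=-1)
        self.last_attention = a_dist.data
        return a_dist @ v                  # [N, Wt, d_model]


class ClassifierHead(Module):
    """Flatten -> 128-d embedding (ReLU) -> class logits."""

    def __init__(self, in_features: int, embedding_dim: int, n_classes: int,
                 rng: np.random.Generator):
        self.fc_embed = Linear(in_features, embedding_dim, rng)
        self.fc_out = Linear(embedding_dim, n_classes, rng)

    def forward(self, ft: Tensor) -> Tensor:
        n = ft.shape[0]
        emb = self.fc_embed(ft.reshape(n, -1)).relu()
        return self.fc_out(emb)

    def embed(self, ft: Tensor) -> Tensor:
        return self.fc_embed(ft.reshape(ft.shape[0], -1)).relu()


class _BaseNet(Module):
    config: NetworkConfig

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.eval()
        logits = self(Tensor(x))
        return softmax(logits, axis=1).data

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class FusionNet(_BaseNet):
    """Full multimodal model: three branches, fusion, temporal attention, head."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.rng_seed)
        self.config = cfg
        self.branches = ModuleList([BranchNet(cfg, rng) for _ in range(3)])
        if cfg.fusion == "cbam":
            self.fusion = CBAMFusion(cfg, rng)
            c, h = cfg.branch_out_channels, cfg.k_bins
        elif cfg.fusion == "channel-homog":
            self.fusion = HomogenizedFusion("channel")
            c, h = 3, cfg.k_bins
        else:
            self.fusion = HomogenizedFusion("distance")
            c, h = cfg.branch_out_channels, 3
        self.attention = TemporalSelfAttention(c * h, cfg.attention_model_dim, rng)
        self.head = ClassifierHead(cfg.time_steps * cfg.attention_model_dim,
                                   cfg.embedding_dim, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected [N x 3 x K x L] input, got {x.shape}")
        n, _, k, l = x.shape
        feats = [branch(x_m.reshape(n, 1, k, l))
                 for branch, x_m in zip(self.branches, _split_modalities(x))]
        fused = self.fusion(feats)
        return self.head(self.attention(fused))


class UnimodalNet(_BaseNet):
    """Single-branch variant (no fusion), identical attention and classifier."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.rng_seed)
        self.config = cfg
        self.branch = BranchNet(cfg, rng)
        self.attention = TemporalSelfAttention(
            cfg.branch_out_channels * cfg.k_bins, cfg.attention_model_dim, rng)
        self.head = ClassifierHead(cfg.time_steps * cfg.attention_model_dim,
                                   cfg.embedding_dim, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected [N x 1 x K x L] input, got {x.shape}")
        return self.head(self.attention(self.branch(x)))


def _split_modalities(x: Tensor) -> list[Tensor]:
    n, m, k, l = x.shape
    # slicing via transpose/reshape keeps the graph simple: x is a leaf here
    return [Tensor(x.data[:, i], requires_grad=False) for i in range(m)]


def build_model(cfg: NetworkConfig, modality: str | None = None) -> _BaseNet:
    return UnimodalNet(cfg) if modality is not None else FusionNet(cfg)


def save_checkpoint(model: _BaseNet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps({"config": asdict(model.config),
                    "kind": type(model).__name__}).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> _BaseNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg = NetworkConfig(**meta["config"])
        model = UnimodalNet(cfg) if meta["kind"] == "UnimodalNet" else FusionNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
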