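"""Multiscale SE-residual 1-D convolutional network (MSDNN).

The backbone replaces every plain width-17 convolution with a *multiscale
convolution block* (MSConv): four parallel 1-D convolutions with kernel
widths 3, 5, 9 and 17, each producing a quarter of the output channels,
concatenated channelwise.  Since (3+5+9+17)/4 = 8.5 taps per input-output
channel pair versus 17 for the plain kernel, an MSConv carries exactly half
the weights of the width-17 convolution it replaces while seeing the signal
at four receptive-field scales at once.

The network is a residual stack: a stem MSConv, then ``residual_units``
units where unit k carries ``base_channels + growth*k`` channels (default
64 + 16k), each unit holding two MSConv blocks (the first downsampling by
stride 2), batch-norm, dropout, a squeeze-and-excitation channel gate, and
a strided 1x1 projection shortcut.  A global average pool and linear head
produce per-class logits; sigmoid activation yields multilabel
probabilities.  Setting ``ms_kernels=(17,)`` recovers a plain single-scale
baseline behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module


@dataclass
class MsdnnConfig:
    input_leads: int = 12
    input_samples: int = 7500
    ms_kernels: tuple[int, ...] = (3, 5, 9, 17)
    base_channels: int = 64
    growth: int = 16
    residual_units: int = 8
    dropout: float = 0.2
    se_ratio: int = 16
    n_classes: int = 60
    proj_dim: int = 128
    stem_stride: int = 2

    def __post_init__(self) -> None:
        if self.residual_units < 1:
            raise ValueError("need at least one residual unit")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        k = len(self.ms_kernels)
        for ch in self.channel_sequence():
            if ch % k:
                raise ValueError(
                    f"channel count {ch} not divisible by {k} branches")

    def channel_sequence(self) -> list[int]:
        """Output channels of unit k = base + growth*k."""
        return [self.base_channels + self.growth * k
                for k in range(self.residual_units)]

    @classmethod
    def desk(cls, n_classes: int = 7, input_samples: int = 1000,
             **overrides) -> "MsdnnConfig":
        """Small configuration for CPU-scale experiments: same topology,
        reduced width/depth/input length."""
        kw = dict(input_leads=12, input_samples=input_samples,
                  base_channels=16, growth=8, residual_units=3,
                  se_ratio=4, n_classes=n_classes, proj_dim=32)
        kw.update(overrides)
        return cls(**kw)


def msconv_weight_count(in_ch: int, out_ch: int,
                        kernels: tuple[int, ...] = (3, 5, 9, 17)) -> float:
    """Analytic weight count (no bias) of an MSConv block."""
    per_branch = out_ch / len(kernels)
    return sum(k * in_ch * per_branch for k in kernels)


def conv_weight_count(in_ch: int, out_ch: int, kernel: int) -> int:
    """Weight count (no bias) of a plain 1-D convolution."""
    return kernel * in_ch * out_ch


class MSConv(Module):
    """Parallel multi-kernel convolutions concatenated channelwise."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 kernels: tuple[int, ...] = (3, 5, 9, 17),
                 rng: np.random.Generator | None = None, bias: bool = False):
        if out_ch % len(kernels):
            raise ValueError(
                f"out_ch={out_ch} not divisible by {len(kernels)} branches")
        rng = rng or np.random.default_rng(0)
        per = out_ch // len(kernels)
        self.branches = [nn.Conv1d(in_ch, per, k, stride, bias=bias, rng=rng)
                         for k in kernels]
        self.per = per

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([b(x) for b in self.branches], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        for i, b in enumerate(self.branches):
            part = b.backward(dy[:, i * self.per:(i + 1) * self.per])
            dx = part if dx is None else dx + part
        return dx


class SEBlock(Module):
    """Squeeze-and-excitation channel gate: global average over time, a
    two-layer bottleneck (reduction ``ratio``), sigmoid gating."""

    def __init__(self, channels: int, ratio: int = 16,
                 rng: np.random.Generator | None = None):
        hidden = max(1, channels // ratio)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        s = x.mean(axis=2)
        z = self.fc1(s)
        zr = np.maximum(z, 0.0)
        gate = nn.sigmoid(self.fc2(zr))
        self._cache = (x, s, z, gate, length)
        return x * gate[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, z, gate, length = self._cache
        dx = dy * gate[:, :, None]
        dgate = (dy * x).sum(axis=2)
        dpre = dgate * gate * (1.0 - gate)
        dzr = self.fc2.backward(dpre)
        dz = dzr * (z > 0)
        ds = self.fc1.backward(dz)
        dx += ds[:, :, None] / length
        return dx


class ResidualUnit(Module):
    """Two MSConv blocks (first strided), BN/ReLU/dropout, SE gate on the
    residual branch, strided 1x1 projection shortcut, ReLU after the add."""

    def __init__(self, in_ch: int, out_ch: int, cfg: MsdnnConfig,
                 rng: np.random.Generator, dropout_rng: np.random.Generator):
        self.conv1 = MSConv(in_ch, out_ch, stride=2, kernels=cfg.ms_kernels,
                            rng=rng)
        self.bn1 = nn.BatchNorm1d(out_ch)
        self.relu1 = nn.ReLU()
        self.drop = nn.Dropout(cfg.dropout, rng=dropout_rng)
        self.conv2 = MSConv(out_ch, out_ch, stride=1, kernels=cfg.ms_kernels,
                            rng=rng)
        self.bn2 = nn.BatchNorm1d(out_ch)
        self.se = SEBlock(out_ch, cfg.se_ratio, rng=rng)
        self.short_conv = nn.Conv1d(in_ch, out_ch, 1, stride=2, bias=False,
                                    rng=rng)
        self.short_bn = nn.BatchNorm1d(out_ch)
        self.relu_out = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        branch = self.bn2(self.conv2(
            self.drop(self.relu1(self.bn1(self.conv1(x))))))
        branch = self.se(branch)
        short = self.short_bn(self.short_conv(x))
        return self.relu_out(branch + short)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dx = self.short_conv.backward(self.short_bn.backward(d))
        db = self.se.backward(d)
        db = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.drop.backward(self.conv2.backward(self.bn2.backward(db))))))
        return dx + db


class Msdnn(Module):
    """Encoder + linear classification head.

    ``forward_logits`` returns per-class logits; :func:`nn.sigmoid` of those
    is the multilabel probability vector.  The final convolutional feature
    maps are cached for class-activation mapping.
    """

    def __init__(self, cfg: MsdnnConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        channels = cfg.channel_sequence()
        self.stem = MSConv(cfg.input_leads, channels[0],
                           stride=cfg.stem_stride, kernels=cfg.ms_kernels,
                           rng=rng)
        self.stem_bn = nn.BatchNorm1d(channels[0])
        self.stem_relu = nn.ReLU()
        self.units = []
        in_ch = channels[0]
        for out_ch in channels:
            self.units.append(ResidualUnit(in_ch, out_ch, cfg, rng, drop_rng))
            in_ch = out_ch
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(in_ch, cfg.n_classes, rng=rng)
        self.feature_channels = in_ch
        self._feature_maps: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------
    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """(B, leads, L) -> pooled (B, C) features."""
        h = self.stem_relu(self.stem_bn(self.stem(x)))
        for unit in self.units:
            h = unit(h)
        self._feature_maps = h
        return self.gap(h)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.head(self.forward_features(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_logits(x)

    def backward_from_features(self, dfeat: np.ndarray) -> np.ndarray:
        d = self.gap.backward(dfeat)
        for unit in reversed(self.units):
            d = unit.backward(d)
        return self.stem.backward(self.stem_bn.backward(
            self.stem_relu.backward(d)))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backward_from_features(self.head.backward(dlogits))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.set_train(False)
        return nn.sigmoid(self.forward_logits(x))


class ProjectionHead(Module):
    """Two-layer MLP projecting pooled features to the contrastive manifold."""

    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        self.fc1 = nn.Linear(in_f, in_f, rng=rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(in_f, out_f, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2(self.relu(self.fc1(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.fc2.backward(dy)))


def build_msdnn(cfg: MsdnnConfig, seed: int = 0) -> Msdnn:
    """Deterministic construction of the network from its configuration."""
    return Msdnn(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    """Exact trainable-parameter count of a built network."""
    return model.n_parameters()


def class_activation_map(model: Msdnn, signal: np.ndarray,
                         class_id: int) -> np.ndarray:
    """CAM for one record: head-weighted sum of the final feature maps,
    linearly upsampled to the input length and min-max normalised to [0,1].

    ``signal`` is (leads, samples); returns a length-``samples`` map.
    """
    if not 0 <= class_id < model.cfg.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    model.set_train(False)
    model.forward_features(signal[None])
    fmaps = model._feature_maps[0]                      # (C, L')
    w = model.head.weight.data[class_id]                # (C,)
    cam = w @ fmaps                                     # (L',)
    n = signal.shape[1]
    xp = np.linspace(0, n - 1, cam.size)
    cam_up = np.interp(np.arange(n), xp, cam)
    lo, hi = cam_up.min(), cam_up.max()
    if hi - lo < 1e-12:
        return np.zeros(n)
    return (cam_up - lo) / (hi - lo)
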