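"""Spatial and Channel Reconstruction Convolution (SCConv).

SCConv suppresses redundancy in convolutional features in two stages.  The
Spatial Reconstruction Unit (SRU) group-normalizes the feature map, ranks
channels by the magnitude of their trainable GN scale gamma (channels whose
gamma is large carry more spatial variation), gates the channels into an
"informative" and a "redundant" set with a sigmoid threshold, and
cross-reconstructs the two sets so information still flows between them.
The Channel Reconstruction Unit (CRU) splits the channels, compresses each
part with 1x1 convolutions, extracts rich features from the upper part with
a 3x3 groupwise plus 1x1 pointwise convolution, keeps shallow detail in the
lower part, and fuses the two paths with SKNet-style pooled softmax
attention.

Both units preserve the (B, C, H, W) shape.  Gates are recomputed from the
current gamma each forward pass and treated as constants in the backward
pass (they are binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError, DegenerateWeightsError

__all__ = [
    "SRUParams",
    "CRUParams",
    "importance_weights",
    "binary_gates",
    "SpatialReconstructionUnit",
    "ChannelReconstructionUnit",
    "SCConv",
]


@dataclass(frozen=True)
class SRUParams:
    num_groups: int = 4
    gate_threshold: float = 0.5
    eps: float = 1e-5

    def __post_init__(self):
        if not 0.0 < self.gate_threshold < 1.0:
            raise ConfigurationError("gate_threshold must be in (0, 1)")
        if self.eps <= 0:
            raise ConfigurationError("eps must be positive")


@dataclass(frozen=True)
class CRUParams:
    v: float = 0.5        # fraction of channels routed to the rich upper path
    g: int = 2            # groups of the 3x3 groupwise convolution
    squeeze: int = 2      # channel-compression ratio of the 1x1 squeezes

    def __post_init__(self):
        if not 0.0 < self.v < 1.0:
            raise ConfigurationError("split ratio v must be in (0, 1)")
        if self.g < 1 or self.squeeze < 1:
            raise ConfigurationError("g and squeeze must be >= 1")


def importance_weights(gn_scale: np.ndarray) -> np.ndarray:
    """Normalized per-channel importance W_gamma = |gamma_i| / sum_j |gamma_j|.

    The magnitude is used because the trainable GN scale may go negative
    while the weights must be nonnegative importances.
    """
    gamma = np.abs(np.asarray(gn_scale, dtype=np.float64))
    total = gamma.sum()
    if total == 0:
        raise DegenerateWeightsError("all GN scales are zero")
    return gamma / total


def binary_gates(w_gamma: np.ndarray, threshold: float = 0.5):
    """Complementary binary channel gates from sigmoid-mapped importances.

    W1 selects informative channels (sigmoid(W_gamma) > threshold), W2 its
    complement.  Note sigmoid of a nonnegative weight is >= 0.5, so with the
    default threshold only exactly-zero importances gate off; the threshold
    is exposed for that reason.
    """
    w_gamma = np.asarray(w_gamma, dtype=np.float64)
    sig = 1.0 / (1.0 + np.exp(-w_gamma))
    w1 = (sig > threshold).astype(np.float64)
    return w1, 1.0 - w1


class SpatialReconstructionUnit(nn.Module):
    def __init__(self, channels: int, params: SRUParams = SRUParams()):
        super().__init__()
        if channels % 2:
            raise ConfigurationError("cross reconstruction needs even channels")
        if channels % params.num_groups:
            raise ConfigurationError("num_groups must divide channels")
        self.params = params
        self.channels = channels
        self.gn = nn.GroupNorm(params.num_groups, channels, eps=params.eps)

    def gates(self):
        w_gamma = importance_weights(self.gn.gamma.data)
        return binary_gates(w_gamma, self.params.gate_threshold)

    def forward(self, f0):
        C = self.channels
        f = self.gn(f0)
        w1, w2 = self.gates()
        w1 = Tensor(w1.astype(f.dtype).reshape(1, C, 1, 1))
        w2 = Tensor(w2.astype(f.dtype).reshape(1, C, 1, 1))
        f1w = ad.mul(w1, f)
        f2w = ad.mul(w2, f)
        h = C // 2
        f11 = f1w[:, :h]
        f12 = f1w[:, h:]
        f21 = f2w[:, :h]
        f22 = f2w[:, h:]
        # cross reconstruction: swap halves between the two gated streams
        fw1 = ad.add(f11, f22)
        fw2 = ad.add(f21, f12)
        return ad.concat([fw1, fw2], axis=1)


class ChannelReconstructionUnit(nn.Module):
    def __init__(self, channels: int, rng, params: CRUParams = CRUParams()):
        super().__init__()
        p = params
        up = int(p.v * channels)
        low = channels - up
        if up < 1 or low < 1:
            raise ConfigurationError("split leaves an empty channel group")
        up_sq = max(up // p.squeeze, 1)
        low_sq = max(low // p.squeeze, 1)
        if up_sq % p.g or channels % p.g:
            raise ConfigurationError("squeezed upper channels not divisible by g")
        if channels - low_sq < 1:
            raise ConfigurationError("lower path exceeds output channels")
        self.params = p
        self.channels = channels
        self.up = up
        self.squeeze_up = nn.Conv2d(up, up_sq, 1, rng, bias=False)
        self.squeeze_low = nn.Conv2d(low, low_sq, 1, rng, bias=False)
        self.gwc = nn.Conv2d(up_sq, channels, 3, rng, groups=p.g, bias=False)
        self.pwc_up = nn.Conv2d(up_sq, channels, 1, rng, bias=False)
        self.pwc_low = nn.Conv2d(low_sq, channels - low_sq, 1, rng, bias=False)

    def forward(self, fw):
        x_up = self.squeeze_up(fw[:, : self.up])
        x_low = self.squeeze_low(fw[:, self.up:])
        y1 = ad.add(self.gwc(x_up), self.pwc_up(x_up))
        y2 = ad.concat([self.pwc_low(x_low), x_low], axis=1)
        return self.fuse(y1, y2)

    @staticmethod
    def fuse(y1, y2):
        """SKNet-style fusion: pooled softmax attention over the two paths."""
        s1 = ad.tmean(y1, axis=(2, 3), keepdims=True)
        s2 = ad.tmean(y2, axis=(2, 3), keepdims=True)
        m = Tensor(np.maximum(s1.data, s2.data))  # stabilizer, constant
        e1 = ad.exp(ad.sub(s1, m))
        e2 = ad.exp(ad.sub(s2, m))
        denom = ad.add(e1, e2)
        b1 = ad.div(e1, denom)
        b2 = ad.div(e2, denom)
        return ad.add(ad.mul(b1, y1), ad.mul(b2, y2))

    @staticmethod
    def attention_weights(y1, y2):
        """Per-channel path weights (sum to 1); exposed for inspection."""
        s1 = y1.data.mean(axis=(2, 3), keepdims=True)
        s2 = y2.data.mean(axis=(2, 3), keepdims=True)
        m = np.maximum(s1, s2)
        e1, e2 = np.exp(s1 - m), np.exp(s2 - m)
        return e1 / (e1 + e2), e2 / (e1 + e2)


class SCConv(nn.Module):
    """SRU followed by CRU; shape-preserving."""

    def __init__(self, channels: int, rng,
                 sru: SRUParams = SRUParams(), cru: CRUParams = CRUParams()):
        super().__init__()
        self.sru = SpatialReconstructionUnit(channels, sru)
        self.cru = ChannelReconstructionUnit(channels, rng, cru)

    def forward(self, f0):
        return self.cru(self.sru(f0))
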