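"""Spatial and Channel Hybrid Attention Fusion (scHAF) for skip connections.

Shallow encoder features carry the fine spatial detail that deformable
registration needs, but not all of it is registration-relevant.  scHAF
filters a shallow feature grid F (C channels over a D x H x W grid) through
two attention branches and fuses them:

* **channel branch** — a learned 1x1x1 convolution collapses the C channels
  into a single spatial attention map, which is broadcast back over channels
  and multiplied pointwise with F (giving ``F_channel``);
* **space branch** — global max pooling and global average pooling produce
  two length-C vectors (MP, AP); their concatenation (length 2C) passes
  through a two-layer MLP (2C -> hidden -> C, ReLU between) to give a
  per-channel weight vector, broadcast over space and multiplied pointwise
  with F (giving ``F_space``);
* **hybrid fusion** — the elementwise product, sum and maximum of
  ``F_channel`` and ``F_space`` are concatenated along channels (3C) and a
  learned 3x3x3 convolution maps back to C channels.

The branch names are kept as scHAF defines them (the 1x1x1-conv
spatial-map branch is called the *channel* branch and the pooled per-channel
branch the *space* branch), even though they are transposed relative to the
usual attention terminology; the constructions themselves are what the
package implements and tests.

Both attention maps pass through a sigmoid by default, bounding weights in
(0, 1); this is configurable (``attention_activation="none"``) because the
gating nonlinearity is a free design choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, global_maxpool, maximum, relu, sigmoid
from ._nn import Conv3d, Linear, Module

__all__ = ["SchafConfig", "Schaf"]


@dataclass(frozen=True)
class SchafConfig:
    """Hyper-parameters of a scHAF block.

    ``mlp_ratio`` sets the hidden width of the space-branch MLP as
    ``ceil(2C / mlp_ratio)`` (default 2, i.e. 2C -> C -> C: compress then
    restore).  ``attention_activation`` gates both attention maps.
    """

    mlp_ratio: float = 2.0
    attention_activation: str = "sigmoid"

    def __post_init__(self):
        if self.mlp_ratio <= 0:
            raise ValueError(f"mlp_ratio must be positive, got {self.mlp_ratio}")
        if self.attention_activation not in ("sigmoid", "none"):
            raise ValueError(
                f"attention_activation must be 'sigmoid' or 'none', "
                f"got {self.attention_activation!r}"
            )

    def hidden_width(self, channels: int) -> int:
        return max(1, math.ceil(2 * channels / self.mlp_ratio))


class Schaf(Module):
    """One scHAF block for feature grids of ``channels`` channels."""

    def __init__(self, channels: int, cfg: SchafConfig, rng: np.random.Generator):
        super().__init__()
        if channels < 1:
            raise ValueError(f"channel count must be >= 1, got {channels}")
        self.channels = channels
        self.cfg = cfg
        hidden = cfg.hidden_width(channels)
        self.spatial_map_conv = Conv3d(channels, 1, kernel=1, rng=rng)
        self.mlp1 = Linear(2 * channels, hidden, rng=rng)
        self.mlp2 = Linear(hidden, channels, rng=rng)
        self.fuse_conv = Conv3d(3 * channels, channels, kernel=3, rng=rng)

    # -- branches -------------------------------------------------------------
    def _gate(self, x: Tensor) -> Tensor:
        return sigmoid(x) if self.cfg.attention_activation == "sigmoid" else x

    def channel_branch(self, f: Tensor) -> Tensor:
        """1x1x1 conv -> single spatial map, broadcast over channels, times f."""
        att = self._gate(self.spatial_map_conv(f))  # (N, 1, D, H, W)
        return f * att

    def space_branch(self, f: Tensor) -> Tensor:
        """Pooled MP/AP vectors -> two-layer MLP -> per-channel weights, times f."""
        mp = global_maxpool(f)                      # (N, C)
        ap = f.mean(axis=(2, 3, 4))                 # (N, C)
        mpap = concat([mp, ap], axis=1)             # (N, 2C)
        att = self._gate(self.mlp2(relu(self.mlp1(mpap))))
        n, c = att.shape
        return f * att.reshape(n, c, 1, 1, 1)

    def hybrid_fuse(self, fc: Tensor, fs: Tensor) -> Tensor:
        """Concat(product, sum, max) along channels, then 3x3x3 conv back to C."""
        if fc.shape != fs.shape:
            raise ValueError(f"branch shapes differ: {fc.shape} vs {fs.shape}")
        fused = concat([fc * fs, fc + fs, maximum(fc, fs)], axis=1)
        return self.fuse_conv(fused)

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {f.shape[1]}"
            )
        return self.hybrid_fuse(self.channel_branch(f), self.space_branch(f))
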