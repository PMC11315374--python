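"""Dual-branch multi-scale feature extractors.

The classifier consumes two feature pyramids per image: one from a *local*
encoder whose receptive fields grow only through strided patch convolutions
(sliding-window perception, the convolutional premise), and one from a
*global* encoder that additionally mixes a full-field context vector into
every spatial position at each stage (image-wide perception, the
self-attention premise).  Both emit three scales, B1/B2/B3, at strides
8/16/32 with strictly increasing channel counts, so the two pyramids are
shape-compatible scale by scale — the precondition of adaptive fusion.

The encoders here are deliberately small so the full network trains in
seconds on a CPU; `BranchSpec` abstracts the taps so larger encoders can be
dropped in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeMismatchError
from .tensor import Tensor

__all__ = ["BranchSpec", "FeaturePyramid", "TinyLocalEncoder", "TinyGlobalEncoder",
           "make_test_branch", "extract_pyramid"]

DEFAULT_STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class BranchSpec:
    """Declared taps of one branch: channels and strides of B1/B2/B3."""

    name: str
    kind: str                      # "local" | "global"
    stage_channels: tuple[int, int, int]
    stage_strides: tuple[int, int, int] = DEFAULT_STRIDES
    pretrained: bool = False

    def __post_init__(self):
        if self.kind not in ("local", "global"):
            raise ConfigurationError(f"branch kind must be local/global, got {self.kind!r}")
        if any(c < 1 for c in self.stage_channels):
            raise ConfigurationError(f"channels must be positive: {self.stage_channels}")
        if not (self.stage_strides[0] < self.stage_strides[1] < self.stage_strides[2]):
            raise ConfigurationError(f"strides must increase: {self.stage_strides}")


@dataclass
class FeaturePyramid:
    """Ordered (B1, B2, B3) feature maps with their strides."""

    maps: tuple[Tensor, Tensor, Tensor]
    strides: tuple[int, int, int] = DEFAULT_STRIDES

    def __post_init__(self):
        sizes = [m.shape[-2] * m.shape[-1] for m in self.maps]
        if not (sizes[0] > sizes[1] > sizes[2]):
            raise ShapeMismatchError(
                f"pyramid spatial sizes must strictly decrease, got {sizes}")

    def __iter__(self):
        return iter(self.maps)


class _GlobalContext(nn.Module):
    """Adds a transformed global-average vector to every spatial position.

    This is the full-field mixing stage: a change anywhere in the input
    perturbs the output at every position, which no stack of the patch
    convolutions used here can do.
    """

    def __init__(self, channels: int, rng, dtype=np.float32):
        super().__init__()
        self.proj = nn.Conv2d(channels, channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        ctx = x.mean(axis=(2, 3), keepdims=True)       # N,C,1,1
        return x + self.proj(ctx.tanh())


class _TinyEncoder(nn.Module):
    """Patch-merging trunk: 4x4/4 stem then 2x2/2 downsampling stages.

    All spatial aggregation happens in non-overlapping patch convolutions,
    so the receptive field of a B3 cell is exactly its 32x32 input tile;
    1x1 convolutions add depth without growing it.  Subclasses insert the
    global mixing stage where appropriate.
    """

    def __init__(self, widths: tuple[int, int, int], rng, dtype=np.float32,
                 global_mixing: bool = False):
        super().__init__()
        self.widths = tuple(widths)
        c1, c2, c3 = widths
        stem_w = max(8, c1 // 2)
        self.stem = nn.Sequential(
            nn.Conv2d(3, stem_w, 4, stride=4, rng=rng, dtype=dtype),
            nn.BatchNorm2d(stem_w, dtype=dtype), nn.ReLU(),
        )
        def stage(cin, cout):
            layers = [
                nn.Conv2d(cin, cout, 2, stride=2, rng=rng, dtype=dtype),
                nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU(),
                nn.Conv2d(cout, cout, 1, rng=rng, dtype=dtype),
                nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU(),
            ]
            if global_mixing:
                layers.append(_GlobalContext(cout, rng=rng, dtype=dtype))
            return nn.Sequential(*layers)
        self.stage1 = stage(stem_w, c1)
        self.stage2 = stage(c1, c2)
        self.stage3 = stage(c2, c3)

    def forward(self, x: Tensor) -> FeaturePyramid:
        if x.shape[-1] % DEFAULT_STRIDES[-1] or x.shape[-2] % DEFAULT_STRIDES[-1]:
            raise ShapeMismatchError(
                f"input spatial size {x.shape[-2]}x{x.shape[-1]} must be divisible "
                f"by the largest stride {DEFAULT_STRIDES[-1]}")
        b1 = self.stage1(self.stem(x))
        b2 = self.stage2(b1)
        b3 = self.stage3(b2)
        return FeaturePyramid((b1, b2, b3))


class TinyLocalEncoder(_TinyEncoder):
    """Purely local perception: strided patch convolutions only."""

    def __init__(self, widths, rng, dtype=np.float32):
        super().__init__(widths, rng, dtype=dtype, global_mixing=False)


class TinyGlobalEncoder(_TinyEncoder):
    """Adds full-field context mixing after every stage."""

    def __init__(self, widths, rng, dtype=np.float32):
        super().__init__(widths, rng, dtype=dtype, global_mixing=True)


def make_test_branch(kind: str, widths: tuple[int, int, int] = (16, 32, 64),
                     seed: int = 0, dtype=np.float32) -> tuple[BranchSpec, nn.Module]:
    """Build a seeded tiny encoder plus its BranchSpec."""
    if any(w < 1 for w in widths):
        raise ConfigurationError(f"widths must be positive: {widths}")
    rng = np.random.default_rng(seed)
    spec = BranchSpec(name=f"tiny-{kind}", kind=kind, stage_channels=tuple(widths))
    if kind == "local":
        enc = TinyLocalEncoder(widths, rng, dtype=dtype)
    elif kind == "global":
        enc = TinyGlobalEncoder(widths, rng, dtype=dtype)
    else:
        raise ConfigurationError(f"kind must be 'local' or 'global', got {kind!r}")
    return spec, enc


def extract_pyramid(image: Tensor, encoder: nn.Module) -> FeaturePyramid:
    """Run one image (3,H,W) or batch (N,3,H,W) through an encoder."""
    if image.ndim == 3:
        pyr = encoder(image.reshape(1, *image.shape))
        return FeaturePyramid(tuple(m.reshape(m.shape[1:]) for m in pyr.maps),
                              pyr.strides)
    return encoder(image)
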