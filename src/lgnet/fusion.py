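"""Feature-fusion blocks: adaptive local/global fusion and cross-scale fusion.

Three operators live here, all shape-contracted on NCHW batches:

* **AFF** (adaptive feature fusion) — fuses a local-branch and a global-branch
  feature map of identical shape by learning, at every spatial position, a
  pair of complementary weights.  The two maps are concatenated along the
  channel axis, a 3x3 convolution maps the 2C channels to 2, and a softmax
  across those two output channels yields gates ``W_L`` and ``W_G`` with
  ``W_L + W_G = 1`` everywhere.  The fused map is the pointwise convex
  combination ``A = X_L * W_L + X_G * W_G``.

* **HMU** (hierarchical mixed-scale unit) — a residual refinement block.
  Channels are expanded by convolution, split into ``G`` groups, and the
  groups are processed iteratively: each group is convolved into three equal
  parts, the first part is carried forward and concatenated with the next
  group (feature interaction), the second parts jointly produce modulation
  weights ``alpha`` through a 1x1 convolution and a squashing nonlinearity,
  and the third parts — scaled by ``alpha`` — are projected back to the input
  width, normalised, and added to the (optionally activated) input:
  ``H = A(X) + N(T(alpha * concat(g3)))``.

* **HMUFF** (HMU-guided feature fusion) — cross-scale fusion of two maps
  that share a channel count but may differ spatially.  Both are refined by
  an HMU, flattened over space, and compared through the negative Gram
  matrix ``-E = -FH1^T FH2``; softmax-normalising ``-E`` along one spatial
  axis yields a stochastic "differentiated feature" matrix that transfers a
  weighted average of one map's positions onto each position of the other.
  The transfers are added residually: ``X12 = X1 + F12``, ``X21 = X2 + F21``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeMismatchError
from .tensor import Tensor, concatenate

__all__ = [
    "HMUConfig",
    "FlattenedFeature",
    "DifferenceMatrix",
    "AFF",
    "HMU",
    "HMUFF",
    "aff_weights",
    "aff_forward",
    "hmu_forward",
    "flatten_spatial",
    "difference_matrix",
    "hmuff_forward",
]


def _as_batched(x: Tensor) -> tuple[Tensor, bool]:
    """Accept a single C,H,W map or an N,C,H,W batch; return batched form."""
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim == 4:
        return x, False
    raise ShapeMismatchError(f"expected a 3-D map or 4-D batch, got shape {x.shape}")


def _maybe_unbatch(x: Tensor, was_single: bool) -> Tensor:
    return x.reshape(x.shape[1:]) if was_single else x


# ---------------------------------------------------------------------- AFF

class AFF(nn.Module):
    """Adaptive fusion of equal-shape local and global feature maps.

    The fusion weights come from a 3x3 convolution (stride 1, padding 1,
    bias) over the channel-concatenated inputs, mapped to 2 channels and
    softmax-normalised across those channels at each spatial position.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.conv = nn.Conv2d(2 * channels, 2, kernel_size=3, stride=1, padding=1,
                              bias=True, rng=rng, dtype=dtype)

    def weights(self, x_local: Tensor, x_global: Tensor) -> Tensor:
        """Gate maps of shape (N, 2, H, W); slice 0 is W_L, slice 1 is W_G."""
        if x_local.shape != x_global.shape:
            raise ShapeMismatchError(
                f"AFF inputs must share C,H,W: local {x_local.shape} vs "
                f"global {x_global.shape}")
        y = concatenate([x_local, x_global], axis=1)
        return self.conv(y).softmax(axis=1)

    def forward(self, x_local: Tensor, x_global: Tensor) -> Tensor:
        w = self.weights(x_local, x_global)
        return x_local * w[:, 0:1] + x_global * w[:, 1:2]


def aff_weights(x_local: Tensor, x_global: Tensor, aff: AFF) -> Tensor:
    xl, single = _as_batched(x_local)
    xg, _ = _as_batched(x_global)
    return _maybe_unbatch(aff.weights(xl, xg), single)


def aff_forward(x_local: Tensor, x_global: Tensor, aff: AFF) -> Tensor:
    xl, single = _as_batched(x_local)
    xg, _ = _as_batched(x_global)
    return _maybe_unbatch(aff(xl, xg), single)


# ---------------------------------------------------------------------- HMU

@dataclass(frozen=True)
class HMUConfig:
    """Structural hyperparameters of the hierarchical mixed-scale unit.

    ``expanded_channels`` may pin the width after channel expansion; when
    ``None`` the width is the smallest multiple of ``3 * groups`` at or above
    ``expansion * C``, which guarantees both divisibility invariants (the
    expanded width divides into ``groups`` groups, and each group into three
    equal parts).
    """

    groups: int = 4
    expansion: float = 2.0
    kernel_size: int = 3
    residual_activation: str = "identity"   # or "relu"
    modulation_activation: str = "sigmoid"  # or "tanh01"
    expanded_channels: int | None = None

    def __post_init__(self):
        if self.groups < 1:
            raise ConfigurationError(f"groups must be >= 1, got {self.groups}")
        if self.expansion <= 0:
            raise ConfigurationError(f"expansion must be positive, got {self.expansion}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError(
                f"kernel_size must be odd and positive, got {self.kernel_size}")
        if self.residual_activation not in ("identity", "relu"):
            raise ConfigurationError(
                f"unknown residual_activation {self.residual_activation!r}")
        if self.modulation_activation not in ("sigmoid", "tanh01"):
            raise ConfigurationError(
                f"unknown modulation_activation {self.modulation_activation!r}")

    def expanded_width(self, channels: int) -> int:
        unit = 3 * self.groups
        if self.expanded_channels is not None:
            e = self.expanded_channels
            if e % self.groups != 0 or (e // self.groups) % 3 != 0:
                raise ConfigurationError(
                    f"expanded_channels={e} is not divisible into {self.groups} "
                    f"groups of three equal parts (needs a multiple of {unit})")
            return e
        target = self.expansion * channels
        return max(unit, int(np.ceil(target / unit)) * unit)


class HMU(nn.Module):
    """Residual block: groupwise iteration then channelwise modulation.

    Submodules follow the stage names: ``expand`` widens the channels,
    ``group_convs[j]`` maps group ``j`` (concatenated with the part carried
    from group ``j-1``) to its three parts, ``modulate`` is the 1x1
    convolution producing the logits of the modulation weights ``alpha``,
    ``proj_out`` is the final convolution ``T`` back to the input width and
    ``norm`` the normalisation ``N``.
    """

    def __init__(self, channels: int, cfg: HMUConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or HMUConfig()
        self.channels = channels
        rng = rng or np.random.default_rng(0)
        k = self.cfg.kernel_size
        pad = k // 2
        E = self.cfg.expanded_width(channels)
        G = self.cfg.groups
        self.expanded = E
        self.group_width = E // G
        self.part_width = self.group_width // 3
        self.expand = nn.Conv2d(channels, E, k, padding=pad, rng=rng, dtype=dtype)
        convs = []
        for j in range(G):
            cin = self.group_width + (0 if j == 0 else self.part_width)
            convs.append(nn.Conv2d(cin, self.group_width, k, padding=pad,
                                   rng=rng, dtype=dtype))
        self.group_convs = nn.ModuleList(convs)
        mod_width = G * self.part_width
        self.modulate = nn.Conv2d(mod_width, mod_width, 1, rng=rng, dtype=dtype)
        self.proj_out = nn.Conv2d(mod_width, channels, k, padding=pad,
                                  rng=rng, dtype=dtype)
        self.norm = nn.BatchNorm2d(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"HMU built for {self.channels} channels, input has {x.shape[1]}")
        y = self.expand(x)
        w, p = self.group_width, self.part_width
        carry = None
        parts2, parts3 = [], []
        for j, conv in enumerate(self.group_convs):
            gj = y[:, j * w:(j + 1) * w]
            inp = gj if carry is None else concatenate([carry, gj], axis=1)
            out = conv(inp)
            carry = out[:, 0:p]
            parts2.append(out[:, p:2 * p])
            parts3.append(out[:, 2 * p:3 * p])
        logits = self.modulate(concatenate(parts2, axis=1))
        if self.cfg.modulation_activation == "sigmoid":
            alpha = logits.sigmoid()
        else:
            alpha = (logits.tanh() + 1.0) * 0.5
        content = alpha * concatenate(parts3, axis=1)
        branch = self.norm(self.proj_out(content))
        residual = x.relu() if self.cfg.residual_activation == "relu" else x
        return residual + branch

    def zero_output_branch(self) -> None:
        """Zero the final projection so the block reduces to its residual path."""
        self.proj_out.weight.data[...] = 0
        self.proj_out.bias.data[...] = 0


def hmu_forward(x: Tensor, hmu: HMU) -> Tensor:
    xb, single = _as_batched(x)
    return _maybe_unbatch(hmu(xb), single)


# ------------------------------------------------------- flatten / difference

@dataclass
class FlattenedFeature:
    """A feature map flattened over space: (..., C, S) with S = H * W.

    Flattening is row-major over (H, W), and the source sizes are recorded so
    the reshape is invertible.
    """

    values: Tensor
    source_height: int
    source_width: int

    @property
    def positions(self) -> int:
        return self.source_height * self.source_width

    def unflatten(self) -> Tensor:
        lead = self.values.shape[:-1]
        return self.values.reshape(*lead, self.source_height, self.source_width)


@dataclass
class DifferenceMatrix:
    """Softmax-normalised negative-similarity matrix between two flat maps.

    ``values`` has shape (..., S1, S2); ``normalization_axis`` records which
    spatial axis was softmax-normalised ("rows": each row sums to 1 over S2;
    "cols": each column sums to 1 over S1).
    """

    values: Tensor
    normalization_axis: str


def flatten_spatial(x: Tensor) -> FlattenedFeature:
    """Flatten (..., C, H, W) to (..., C, S) row-major."""
    h, w = x.shape[-2], x.shape[-1]
    return FlattenedFeature(x.reshape(*x.shape[:-2], h * w), h, w)


def difference_matrix(fh1: FlattenedFeature, fh2: FlattenedFeature,
                      axis: str = "rows", temperature: float = 1.0) -> DifferenceMatrix:
    """Stochastic matrix Md = softmax(-FH1^T FH2) along the requested axis."""
    if fh1.values.shape[-2] != fh2.values.shape[-2]:
        raise ShapeMismatchError(
            f"flattened features must share the channel axis: "
            f"{fh1.values.shape} vs {fh2.values.shape}")
    if axis not in ("rows", "cols"):
        raise ConfigurationError(f"axis must be 'rows' or 'cols', got {axis!r}")
    e = fh1.values.swapaxes(-1, -2) @ fh2.values
    logits = -e if temperature == 1.0 else -e / temperature
    md = logits.softmax(axis=-1 if axis == "rows" else -2)
    return DifferenceMatrix(md, axis)


# -------------------------------------------------------------------- HMUFF

class HMUFF(nn.Module):
    """Cross-scale fusion of two maps sharing a channel count.

    Each input is refined by its own HMU; the refined maps are flattened,
    their negative Gram matrix is softmax-normalised row-wise (for the
    transfer onto the first map) and column-wise (for the transfer onto the
    second), and each map receives the matching weighted average of the
    other's positions as a residual.
    """

    def __init__(self, channels: int, cfg: HMUConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 temperature: float = 1.0):
        super().__init__()
        self.channels = channels
        self.temperature = temperature
        rng = rng or np.random.default_rng(0)
        self.hmu1 = HMU(channels, cfg, rng=rng, dtype=dtype)
        self.hmu2 = HMU(channels, cfg, rng=rng, dtype=dtype)

    def fusion_terms(self, x1: Tensor, x2: Tensor) -> tuple[Tensor, Tensor]:
        """The additive transfers (F12, F21) before the residual sums."""
        if x1.shape[1] != self.channels or x2.shape[1] != self.channels:
            raise ShapeMismatchError(
                f"HMUFF built for {self.channels} channels, inputs have "
                f"{x1.shape[1]} and {x2.shape[1]}")
        h1 = self.hmu1(x1)
        h2 = self.hmu2(x2)
        fh1 = flatten_spatial(h1)
        fh2 = flatten_spatial(h2)
        md_rows = difference_matrix(fh1, fh2, "rows", self.temperature).values
        md_cols = difference_matrix(fh1, fh2, "cols", self.temperature).values
        f12 = md_rows @ fh2.values.swapaxes(-1, -2)            # (N, S1, C)
        f21 = md_cols.swapaxes(-1, -2) @ fh1.values.swapaxes(-1, -2)  # (N, S2, C)
        f12 = f12.swapaxes(-1, -2).reshape(x1.shape)
        f21 = f21.swapaxes(-1, -2).reshape(x2.shape)
        return f12, f21

    def forward(self, x1: Tensor, x2: Tensor) -> tuple[Tensor, Tensor]:
        f12, f21 = self.fusion_terms(x1, x2)
        return x1 + f12, x2 + f21


def hmuff_forward(x1: Tensor, x2: Tensor, hmuff: HMUFF) -> tuple[Tensor, Tensor]:
    x1b, single = _as_batched(x1)
    x2b, _ = _as_batched(x2)
    x12, x21 = hmuff(x1b, x2b)
    return _maybe_unbatch(x12, single), _maybe_unbatch(x21, single)
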