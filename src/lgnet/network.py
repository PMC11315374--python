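"""The dual-branch local/global classification network.

Pipeline per image batch: both encoders emit three-scale pyramids; at each
active scale the local and global maps are fused adaptively (AFF); each fused
map is projected by a 1x1 convolution to a common width so the cross-scale
equations' shared-channel precondition holds; every scale pair in the fusion
topology exchanges information through HMUFF, with each branch's incoming
fusion terms summed before the residual add; finally each branch is globally
average-pooled into its own linear classifier head (deep supervision).

Training minimises the unweighted sum of per-branch cross-entropies; at
inference the per-branch logits are aggregated (by default: arithmetic mean,
then softmax).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbones import make_test_branch
from .errors import ConfigurationError, DataError
from .fusion import AFF, HMUFF, HMUConfig
from .tensor import Tensor, concatenate

__all__ = ["LGNetConfig", "LGNet", "lgnet_loss", "predict", "save_checkpoint",
           "load_checkpoint", "CHECKPOINT_VERSION"]

BRANCH_NAMES = ("B1", "B2", "B3")
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class LGNetConfig:
    num_classes: int = 4
    widths: tuple[int, int, int] = (16, 32, 64)
    common_width: int = 16          # channel width shared by cross-scale fusion
    hmu: HMUConfig = field(default_factory=HMUConfig)
    hmuff_topology: tuple[tuple[str, str], ...] = (
        ("B1", "B2"), ("B2", "B3"), ("B1", "B3"))
    active_branches: tuple[str, ...] = BRANCH_NAMES
    use_aff: bool = True
    use_hmuff: bool = True
    inference_aggregation: str = "mean_logits"
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    input_size: int = 64
    seed: int = 0
    encoder_mode: str = "dual"      # "dual" | "local" | "global" (single-model ablation)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {self.num_classes}")
        if self.encoder_mode not in ("dual", "local", "global"):
            raise ConfigurationError(f"invalid encoder_mode {self.encoder_mode!r}")
        bad = [b for b in self.active_branches if b not in BRANCH_NAMES]
        if bad or not self.active_branches:
            raise ConfigurationError(f"invalid active branches: {self.active_branches}")
        for a, b in self.hmuff_topology:
            if a not in BRANCH_NAMES or b not in BRANCH_NAMES or a == b:
                raise ConfigurationError(f"invalid topology pair: {(a, b)}")

    @property
    def active_pairs(self) -> tuple[tuple[str, str], ...]:
        act = set(self.active_branches)
        return tuple((a, b) for a, b in self.hmuff_topology
                     if a in act and b in act)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LGNetConfig":
        d = dict(d)
        d["hmu"] = HMUConfig(**d["hmu"])
        for key in ("widths", "active_branches", "loss_weights"):
            d[key] = tuple(d[key])
        d["hmuff_topology"] = tuple(tuple(p) for p in d["hmuff_topology"])
        return cls(**d)


class LGNet(nn.Module):
    def __init__(self, cfg: LGNetConfig, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.encoder_mode in ("dual", "local"):
            _, self.local_encoder = make_test_branch("local", cfg.widths,
                                                     seed=cfg.seed, dtype=dtype)
        if cfg.encoder_mode in ("dual", "global"):
            _, self.global_encoder = make_test_branch("global", cfg.widths,
                                                      seed=cfg.seed + 1, dtype=dtype)
        d = cfg.common_width
        self.affs = nn.ModuleList()
        self.projs = nn.ModuleList()
        self.heads = nn.ModuleList()
        self._branch_idx = [BRANCH_NAMES.index(b) for b in cfg.active_branches]
        for i in self._branch_idx:
            if cfg.encoder_mode == "dual":
                self.affs.append(AFF(cfg.widths[i], rng=rng, dtype=dtype))
            self.projs.append(nn.Conv2d(cfg.widths[i], d, 1, rng=rng, dtype=dtype))
            self.heads.append(nn.Linear(d, cfg.num_classes, rng=rng, dtype=dtype))
        self.pairs = list(cfg.active_pairs)
        self.hmuffs = nn.ModuleList(
            [HMUFF(d, cfg.hmu, rng=rng, dtype=dtype) for _ in self.pairs])

    # ------------------------------------------------------------------ core
    def _branch_features(self, x: Tensor) -> dict[str, Tensor]:
        mode = self.cfg.encoder_mode
        pyr_l = self.local_encoder(x) if mode in ("dual", "local") else None
        pyr_g = self.global_encoder(x) if mode in ("dual", "global") else None
        feats: dict[str, Tensor] = {}
        for pos, i in enumerate(self._branch_idx):
            name = BRANCH_NAMES[i]
            if mode == "dual":
                xl, xg = pyr_l.maps[i], pyr_g.maps[i]
                fused = self.affs[pos](xl, xg) if self.cfg.use_aff else (xl + xg) * 0.5
            else:
                fused = (pyr_l or pyr_g).maps[i]
            feats[name] = self.projs[pos](fused)
        if self.cfg.use_hmuff and self.pairs:
            terms: dict[str, list[Tensor]] = {b: [] for b in feats}
            for (a, b), block in zip(self.pairs, self.hmuffs):
                f_ab, f_ba = block.fusion_terms(feats[a], feats[b])
                terms[a].append(f_ab)
                terms[b].append(f_ba)
            for name in feats:
                for t in terms[name]:
                    feats[name] = feats[name] + t
        return feats

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        """Per-branch logits: {branch name: (N, K) tensor}."""
        feats = self._branch_features(x)
        return {name: self.heads[pos](nn.global_avg_pool(feats[name]))
                for pos, name in enumerate(self.cfg.active_branches)}

    def extract_embedding(self, x: Tensor) -> Tensor:
        """Concatenated pooled per-branch features preceding the heads."""
        feats = self._branch_features(x)
        pooled = [nn.global_avg_pool(feats[name]) for name in self.cfg.active_branches]
        return pooled[0] if len(pooled) == 1 else concatenate(pooled, axis=1)


# ------------------------------------------------------------------- loss

def lgnet_loss(logits: dict[str, Tensor], labels: np.ndarray,
               weights: dict[str, float] | None = None
               ) -> tuple[Tensor, dict[str, float]]:
    """Weighted (default: unweighted) sum of per-branch cross-entropies.

    Returns the scalar loss tensor plus per-branch component values for
    logging.
    """
    labels = np.asarray(labels)
    first = next(iter(logits.values()))
    k = first.shape[-1]
    bad = np.flatnonzero((labels < 0) | (labels >= k))
    if bad.size:
        raise DataError(
            f"label {labels[bad[0]]} at index {bad[0]} outside [0, {k})")
    n = labels.shape[0]
    total = None
    components: dict[str, float] = {}
    for name, lg in logits.items():
        logp = lg.log_softmax(axis=-1)
        picked = logp[np.arange(n), labels]
        ce = -(picked.sum() / n)
        w = 1.0 if weights is None else float(weights.get(name, 1.0))
        term = ce * w if w != 1.0 else ce
        components[name] = float(ce.data)
        total = term if total is None else total + term
    return total, components


def predict(logits: dict[str, Tensor], rule: str = "mean_logits"
            ) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate branch logits into (predicted class, class probabilities).

    Default rule: arithmetic mean of the per-branch logits, softmax, argmax;
    ties break toward the lowest class index.
    """
    if rule != "mean_logits":
        raise ConfigurationError(f"unknown aggregation rule {rule!r}")
    arrs = [lg.data for lg in logits.values()]
    mean = np.mean(arrs, axis=0)
    shifted = mean - mean.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs.argmax(axis=-1), probs


# -------------------------------------------------------------- checkpoints

def save_checkpoint(path, model: LGNet, vocabulary: list[str],
                    norm_mean=None, norm_std=None, extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + config + class vocabulary."""
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "vocabulary": list(vocabulary),
        "norm_mean": None if norm_mean is None else list(map(float, norm_mean)),
        "norm_std": None if norm_std is None else list(map(float, norm_std)),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, dtype=np.float32):
    """Rebuild the model from a checkpoint; returns (model, meta dict)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta['format_version']}")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = LGNetConfig.from_dict(meta["config"])
    model = LGNet(cfg, dtype=dtype)
    model.load_state_dict(state)
    model.eval()
    return model, meta
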