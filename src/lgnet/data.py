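"""Datasets: folder reading, deterministic splitting, augmentation, and a
synthetic leaf-lesion image generator.

The generator encodes the premise that motivates a dual local/global
architecture: some diseases show as a few spatially confined, textured
lesions (detectable only from local structure), others as widespread
discoloration of the whole leaf (detectable from image-level statistics).
Classes therefore come in two modes:

* ``local`` classes draw 1-3 compact high-contrast spots ("blotch") or a
  swarm of tiny speckles ("speckle") on the leaf.  The two local families
  share the same lesion colour distribution and approximately the same total
  lesion area, so their pixel histograms are nearly indistinguishable — a
  classifier must use spatial texture to tell them apart.
* ``global`` classes recolour a widespread mottle field covering at least
  40% of the leaf toward class-specific hues (yellowing vs. browning), so
  image-level colour statistics suffice.

All generation is driven by one `numpy` generator seeded from the spec, so a
given spec reproduces its images bit for bit (and byte for byte when written
as PNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError, DataError

__all__ = ["ImageRecord", "LabeledImageSet", "SyntheticSpec", "read_image_folder",
           "split_dataset", "split_sizes", "augment", "generate_synthetic",
           "write_image_tree", "histogram_probe_accuracy", "images_to_array"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class ImageRecord:
    label: int
    path: str | None = None
    image: np.ndarray | None = None     # uint8 HWC, loaded lazily when path-backed
    split: str | None = None

    def load(self) -> np.ndarray:
        if self.image is not None:
            return self.image
        try:
            with Image.open(self.path) as im:
                return np.asarray(im.convert("RGB"))
        except OSError as e:
            raise DataError(f"unreadable image file {self.path}: {e}") from e


@dataclass
class LabeledImageSet:
    records: list[ImageRecord]
    vocabulary: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "LabeledImageSet":
        return LabeledImageSet(
            [r for r in self.records if r.split == split], self.vocabulary)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


def images_to_array(records: list[ImageRecord]) -> np.ndarray:
    """Stack records into a float32 NCHW array scaled to [0, 1]."""
    imgs = np.stack([r.load() for r in records])
    return imgs.transpose(0, 3, 1, 2).astype(np.float32) / 255.0


# ------------------------------------------------------------------ reading

def read_image_folder(root) -> LabeledImageSet:
    """Read a class-per-folder tree; vocabulary is the sorted folder names."""
    root = Path(root)
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise DataError(f"no class subdirectories under {root}")
    records = []
    import warnings
    for label, cname in enumerate(classes):
        files = sorted(p for p in (root / cname).iterdir()
                       if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            warnings.warn(f"class folder {cname!r} contains no images")
        records.extend(ImageRecord(label=label, path=str(p)) for p in files)
    return LabeledImageSet(records, classes)


# ----------------------------------------------------------------- splitting

def split_sizes(n: int, ratios: tuple[float, ...]) -> tuple[int, ...]:
    """Floor-from-the-back rounding: later splits get floor(n * ratio), the
    first split absorbs the remainder (so 32,660 at 9:1 gives 29,394/3,266)."""
    if any(r <= 0 for r in ratios):
        raise ConfigurationError(f"ratios must be positive: {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1: {ratios}")
    tail = [int(np.floor(n * r)) for r in ratios[1:]]
    first = n - sum(tail)
    if first < 0 or (n >= len(ratios) and first == 0):
        raise ConfigurationError(f"cannot split {n} records into {ratios}")
    return (first, *tail)


DEFAULT_SPLIT_NAMES = {1: ("train",), 2: ("train", "val"), 3: ("train", "val", "test")}


def split_dataset(dataset: LabeledImageSet, ratios: tuple[float, ...], seed: int,
                  names: tuple[str, ...] | None = None) -> LabeledImageSet:
    """Tag records with splits by a global (non-stratified) seeded shuffle."""
    n = len(dataset.records)
    if n < len(ratios):
        raise ConfigurationError(f"{n} records cannot fill {len(ratios)} splits")
    names = names or DEFAULT_SPLIT_NAMES.get(len(ratios))
    if names is None or len(names) != len(ratios):
        raise ConfigurationError("provide one name per split ratio")
    sizes = split_sizes(n, ratios)
    order = np.random.default_rng(seed).permutation(n)
    start = 0
    for size, name in zip(sizes, names):
        for idx in order[start:start + size]:
            dataset.records[idx].split = name
        start += size
    return dataset


# --------------------------------------------------------------- augmentation

def augment(image: np.ndarray, rng: np.random.Generator,
            max_rotation: float = 30.0) -> np.ndarray:
    """Training-time augmentation: uniform rotation in +-max_rotation degrees
    and a horizontal flip with probability 0.5.  Input/output uint8 HWC."""
    angle = rng.uniform(-max_rotation, max_rotation)
    flip = rng.random() < 0.5
    im = Image.fromarray(image)
    im = im.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    out = np.asarray(im)
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


# ------------------------------------------------------------------ synthesis

LOCAL_FAMILIES = ("blotch", "speckle")
GLOBAL_FAMILIES = ("yellow", "brown")


@dataclass(frozen=True)
class SyntheticSpec:
    num_classes: int = 4
    images_per_class: int = 250
    image_size: int = 64
    seed: int = 0
    # one (mode, family) per class; default alternates local/global families
    class_defs: tuple[tuple[str, str], ...] | None = None

    def resolved_classes(self) -> list[tuple[str, str, str]]:
        """(name, mode, family) per class."""
        if self.class_defs is not None:
            defs = list(self.class_defs)
        else:
            defs = []
            for k in range(self.num_classes):
                if k % 2 == 0:
                    defs.append(("local", LOCAL_FAMILIES[(k // 2) % 2]))
                else:
                    defs.append(("global", GLOBAL_FAMILIES[(k // 2) % 2]))
        if len(defs) != self.num_classes:
            raise ConfigurationError(
                f"{len(defs)} class definitions for {self.num_classes} classes")
        modes = {m for m, _ in defs}
        if self.num_classes >= 2 and modes != {"local", "global"}:
            raise ConfigurationError(
                "need at least one 'local' and one 'global' class")
        # index prefix keeps sorted folder order equal to generation order
        return [(f"c{k:02d}_{m}_{fam}", m, fam) for k, (m, fam) in enumerate(defs)]


def _smooth_field(rng: np.random.Generator, size: int, coarse: int = 8) -> np.ndarray:
    """Low-frequency random field in [0,1]: coarse noise, upsampled, box-blurred."""
    base = rng.standard_normal((coarse, coarse))
    rep = size // coarse
    f = np.kron(base, np.ones((rep, rep)))
    k = np.ones(rep + 1) / (rep + 1)
    f = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, f)
    f = np.apply_along_axis(lambda c: np.convolve(c, k, mode="same"), 0, f)
    f = f - f.min()
    return f / max(f.max(), 1e-9)


def _leaf_canvas(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Textured green elliptic leaf on a dark backdrop; returns (image, mask)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy, cx = size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2)
    ay = size * rng.uniform(0.36, 0.46)
    ax = size * rng.uniform(0.28, 0.40)
    theta = rng.uniform(0, np.pi)
    y0, x0 = yy - cy, xx - cx
    yr = y0 * np.cos(theta) + x0 * np.sin(theta)
    xr = -y0 * np.sin(theta) + x0 * np.cos(theta)
    mask = (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0
    img = np.empty((size, size, 3), dtype=np.float64)
    backdrop = rng.uniform(15, 30)
    img[...] = backdrop + rng.normal(0, 3, (size, size, 1))
    base_g = rng.uniform(110, 150)
    texture = _smooth_field(rng, size)
    grain = rng.normal(0, 6, (size, size))
    green = np.stack([
        base_g * 0.45 + 18 * texture + grain * 0.6,
        base_g + 25 * texture + grain,
        base_g * 0.35 + 12 * texture + grain * 0.5,
    ], axis=-1)
    img[mask] = green[mask]
    return img, mask


def _lesion_color(rng: np.random.Generator) -> np.ndarray:
    """Dark-brown necrotic colour shared by both local families."""
    r = rng.uniform(85, 115)
    return np.array([r, r * rng.uniform(0.52, 0.62), r * rng.uniform(0.28, 0.38)])


def _draw_disc(img, mask, cy, cx, radius, color, blend, inner_radius=0.0):
    """Blend `color` into a disc (or annulus, if inner_radius > 0) exactly
    once per pixel, so repeated draws cannot change the blend depth."""
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disc = (d2 <= radius ** 2) & (d2 > inner_radius ** 2) & mask
    img[disc] = (1 - blend) * img[disc] + blend * color


def _spot_center(rng, mask, radius=0.0, avoid=(), tries=60):
    """A random leaf position whose disc fits inside the leaf and clears
    previously placed discs (best effort within `tries` attempts)."""
    ys, xs = np.nonzero(mask)
    size = mask.shape[0]
    r = int(np.ceil(radius))
    best = None
    for _ in range(tries):
        i = rng.integers(len(ys))
        cy, cx = int(ys[i]), int(xs[i])
        if r and not (r <= cy < size - r and r <= cx < size - r
                      and mask[cy - r, cx] and mask[cy + r, cx]
                      and mask[cy, cx - r] and mask[cy, cx + r]):
            continue
        best = (cy, cx)
        if all((cy - oy) ** 2 + (cx - ox) ** 2 > (radius + orad) ** 2
               for oy, ox, orad in avoid):
            return cy, cx
    return best if best is not None else (int(ys[0]), int(xs[0]))


def _render_local(img, mask, family: str, rng: np.random.Generator) -> None:
    # the two local families share total lesion area AND the per-pixel shade
    # distribution (70% dark rim tone, 30% bright centre tone), so colour
    # histograms cannot separate them; only the spatial arrangement differs
    target_area = rng.uniform(90, 190)
    color = _lesion_color(rng)
    dark = rng.uniform(0.68, 0.76)
    bright = rng.uniform(1.15, 1.30)
    dark_fraction = 0.7
    placed = []
    if family == "blotch":
        n_spots = rng.integers(1, 4)
        area_each = target_area / n_spots
        for _ in range(n_spots):
            radius = np.sqrt(area_each / np.pi) * rng.uniform(0.95, 1.05)
            cy, cx = _spot_center(rng, mask, radius, placed)
            placed.append((cy, cx, radius))
            # bright centre sized so its area share matches 1 - dark_fraction
            core = radius * np.sqrt(1 - dark_fraction)
            _draw_disc(img, mask, cy, cx, radius, color * dark, 0.9,
                       inner_radius=core)
            _draw_disc(img, mask, cy, cx, core, color * bright, 0.9)
    else:  # speckle
        dot_r = rng.uniform(1.0, 1.4)
        n_dots = max(4, int(round(target_area / (np.pi * dot_r ** 2))))
        for _ in range(n_dots):
            cy, cx = _spot_center(rng, mask, dot_r, placed)
            placed.append((cy, cx, dot_r))
            shade = dark if rng.random() < dark_fraction else bright
            _draw_disc(img, mask, cy, cx, dot_r, color * shade, 0.9)


def _render_global(img, mask, family: str, rng: np.random.Generator) -> None:
    field = _smooth_field(rng, img.shape[0])
    vals = field[mask]
    coverage = rng.uniform(0.45, 0.7)     # fraction of the leaf discoloured
    thr = np.quantile(vals, 1 - coverage)
    region = (field >= thr) & mask
    strength = np.clip((field - thr) / max(1e-9, field.max() - thr), 0, 1)
    s = (strength[region] * rng.uniform(0.5, 0.8) + 0.2)[:, None]
    if family == "yellow":
        tint = np.array([205.0, 185.0, 55.0])
    else:  # brown
        tint = np.array([120.0, 70.0, 35.0])
    tint = tint * rng.uniform(0.9, 1.1)
    img[region] = (1 - s) * img[region] + s * tint


def generate_synthetic(spec: SyntheticSpec) -> LabeledImageSet:
    """Render the synthetic set; classes exactly balanced, bit-reproducible."""
    classes = spec.resolved_classes()
    rng = np.random.default_rng(spec.seed)
    records = []
    for label, (_, mode, family) in enumerate(classes):
        for _ in range(spec.images_per_class):
            img, mask = _leaf_canvas(rng, spec.image_size)
            if mode == "local":
                _render_local(img, mask, family, rng)
            else:
                _render_global(img, mask, family, rng)
            img += rng.normal(0, 2.0, img.shape)
            arr = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            records.append(ImageRecord(label=label, image=arr))
    return LabeledImageSet(records, [name for name, _, _ in classes])


def write_image_tree(dataset: LabeledImageSet, root) -> list[Path]:
    """Write the set as a class-per-folder PNG tree (deterministic bytes)."""
    root = Path(root)
    counters = dict.fromkeys(range(len(dataset.vocabulary)), 0)
    paths = []
    for rec in dataset.records:
        cname = dataset.vocabulary[rec.label]
        d = root / cname
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"{cname}_{counters[rec.label]:05d}.png"
        Image.fromarray(rec.load()).save(p, format="PNG")
        rec.path = str(p)
        counters[rec.label] += 1
        paths.append(p)
    return paths


def write_split_manifest(dataset: LabeledImageSet, path) -> None:
    """Plain-text table (path, class, split), one record per line."""
    with open(path, "w") as fh:
        fh.write("path\tclass\tsplit\n")
        for rec in dataset.records:
            fh.write(f"{rec.path}\t{dataset.vocabulary[rec.label]}\t{rec.split}\n")


# ------------------------------------------------------------ self-test probe

def histogram_probe_accuracy(dataset: LabeledImageSet, classes: tuple[int, int],
                             seed: int = 0, bins: int = 8) -> float:
    """Held-out accuracy of a logistic model on per-channel colour histograms.

    Used as the generator's self-test: global-mode class pairs should be
    separable from histograms alone, local-mode pairs should not.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    recs = [r for r in dataset.records if r.label in classes]
    feats, labels = [], []
    for r in recs:
        img = r.load()
        hist = [np.histogram(img[..., c], bins=bins, range=(0, 256),
                             density=True)[0] for c in range(3)]
        feats.append(np.concatenate(hist))
        labels.append(int(r.label == classes[1]))
    x = np.asarray(feats)
    y = np.asarray(labels)
    xtr, xte, ytr, yte = train_test_split(x, y, test_size=0.25, random_state=seed,
                                          stratify=y)
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, random_state=seed)).fit(xtr, ytr)
    return float(clf.score(xte, yte))
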