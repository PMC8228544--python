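"""Synthetic visual stimuli for the sensory-substitution pipeline.

Two stimulus families are generated entirely in code so that every
downstream stage (sonification, audio networks, behavioral protocol) is
testable without external downloads:

* **digit-like glyphs** — 28x28 white-on-black stroke-rendered digits in
  ten classes with per-sample affine jitter, a hermetic stand-in for a
  handwritten-digit corpus (a loader for real IDX-format digit files is
  provided for when such a corpus is locally available; nothing is ever
  downloaded);
* **shape set** — the 25-image behavioral stimulus set: 5 basic shapes
  (circle, square, triangle, cross, horizontal line) plus 4 parameterized
  affine variants of each.

Images are luminance matrices in [0, 1] with row 0 at the top.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "StimulusSet",
    "DatasetSplit",
    "generate_digit_glyphs",
    "generate_shape_set",
    "split_dataset",
    "load_idx_images",
    "save_stimulus_set",
    "load_stimulus_set",
    "BASIC_SHAPES",
]

BASIC_SHAPES = ("circle", "square", "triangle", "cross", "line")

# Seven-segment-style stroke endpoints in unit coordinates (x right, y down).
_SEG = {
    "top": ((0.25, 0.15), (0.75, 0.15)),
    "mid": ((0.25, 0.50), (0.75, 0.50)),
    "bot": ((0.25, 0.85), (0.75, 0.85)),
    "ul": ((0.25, 0.15), (0.25, 0.50)),
    "ur": ((0.75, 0.15), (0.75, 0.50)),
    "ll": ((0.25, 0.50), (0.25, 0.85)),
    "lr": ((0.75, 0.50), (0.75, 0.85)),
    "diag7": ((0.75, 0.15), (0.35, 0.85)),
}

_DIGIT_SEGMENTS = {
    0: ["top", "ul", "ur", "ll", "lr", "bot"],
    1: ["ur", "lr"],
    2: ["top", "ur", "mid", "ll", "bot"],
    3: ["top", "ur", "mid", "lr", "bot"],
    4: ["ul", "ur", "mid", "lr"],
    5: ["top", "ul", "mid", "lr", "bot"],
    6: ["top", "ul", "mid", "ll", "lr", "bot"],
    7: ["top", "diag7"],
    8: ["top", "ul", "ur", "mid", "ll", "lr", "bot"],
    9: ["top", "ul", "ur", "mid", "lr", "bot"],
}


@dataclass
class StimulusSet:
    """An ordered collection of grayscale stimuli with integer labels."""

    images: np.ndarray          # (N, H, W) luminance in [0, 1]
    labels: np.ndarray          # (N,) integer class ids
    family: str                 # "digit_like" or "shape"
    seed: int
    names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test index lists."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def _segment_distance(px: np.ndarray, py: np.ndarray,
                      a: tuple[float, float], b: tuple[float, float]
                      ) -> np.ndarray:
    """Euclidean distance from each grid point to segment a-b."""
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    denom = dx * dx + dy * dy
    if denom == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def _render_strokes(segments, size: int, thickness: float) -> np.ndarray:
    """Anti-aliased white-on-black rendering of a list of unit-square strokes."""
    coords = (np.arange(size) + 0.5) / size
    px, py = np.meshgrid(coords, coords)  # py indexes rows (top = 0)
    dist = np.full((size, size), np.inf)
    for seg in segments:
        dist = np.minimum(dist, _segment_distance(px, py, seg[0], seg[1]))
    # soft edge one pixel wide around the stroke core
    edge = 1.0 / size
    img = np.clip((thickness - dist) / edge + 1.0, 0.0, 1.0)
    return img


def _random_affine(img: np.ndarray, rng: np.random.Generator,
                   max_rot_deg: float = 10.0, max_shift: float = 0.07,
                   scale_range: tuple[float, float] = (0.9, 1.1)
                   ) -> np.ndarray:
    """Small seeded affine jitter about the image centre."""
    size = img.shape[0]
    theta = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    s = rng.uniform(*scale_range)
    shift = rng.uniform(-max_shift, max_shift, size=2) * size
    c, sn = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -sn], [sn, c]]) / s
    centre = (size - 1) / 2.0
    offset = centre - mat @ (centre + shift)
    out = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def generate_digit_glyphs(n_per_class: int, seed: int, size: int = 28,
                          white_on_black: bool = True) -> StimulusSet:
    """Generate ``10 * n_per_class`` stroke-rendered digit glyphs.

    Each sample is the class's canonical stroke pattern with random affine
    jitter (rotation, shift, scale) drawn from a generator seeded by
    ``seed``, so the corpus is bit-reproducible.

    Raises
    ------
    ValueError
        If ``size`` is too small to render distinguishable strokes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if size < 8:
        raise ValueError(f"size={size} too small to render digit strokes "
                         "(minimum 8)")
    rng = np.random.default_rng(seed)
    thickness = max(0.06, 1.5 / size)
    bases = {d: _render_strokes([_SEG[s] for s in _DIGIT_SEGMENTS[d]],
                                size, thickness)
             for d in range(10)}
    images = np.empty((10 * n_per_class, size, size))
    labels = np.empty(10 * n_per_class, dtype=np.int64)
    k = 0
    for d in range(10):
        for _ in range(n_per_class):
            images[k] = _random_affine(bases[d], rng)
            labels[k] = d
            k += 1
    if not white_on_black:
        images = 1.0 - images
    return StimulusSet(images=images, labels=labels, family="digit_like",
                       seed=seed,
                       names=[f"digit{l}_{i}" for i, l in enumerate(labels)])


# -- shape set ----------------------------------------------------------

def _shape_mask(name: str, size: int) -> np.ndarray:
    coords = (np.arange(size) + 0.5) / size - 0.5
    x, y = np.meshgrid(coords, coords)
    if name == "circle":
        return (np.hypot(x, y) <= 0.33).astype(float)
    if name == "square":
        return ((np.abs(x) <= 0.30) & (np.abs(y) <= 0.30)).astype(float)
    if name == "triangle":
        # upward-pointing isoceles triangle
        return ((y >= -0.32) & (y <= 0.34) &
                (np.abs(x) <= 0.36 * (y + 0.32) / 0.66)).astype(float)
    if name == "cross":
        bar = 0.09
        return (((np.abs(x) <= bar) & (np.abs(y) <= 0.36)) |
                ((np.abs(y) <= bar) & (np.abs(x) <= 0.36))).astype(float)
    if name == "line":
        return ((np.abs(y) <= 0.07) & (np.abs(x) <= 0.40)).astype(float)
    raise ValueError(f"unknown shape {name!r}")


def _apply_affine(img: np.ndarray, rot_deg: float = 0.0,
                  scale: tuple[float, float] = (1.0, 1.0),
                  shift: tuple[float, float] = (0.0, 0.0),
                  shear: float = 0.0) -> np.ndarray:
    size = img.shape[0]
    theta = np.deg2rad(rot_deg)
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    sc = np.diag([1.0 / scale[0], 1.0 / scale[1]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    mat = sc @ sh @ rot
    centre = (size - 1) / 2.0
    offset = centre - mat @ (centre + np.asarray(shift) * size)
    out = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def generate_shape_set(seed: int, size: int = 64,
                       white_on_black: bool = True) -> StimulusSet:
    """Generate the 25-image behavioral stimulus set.

    Five basic shapes and four affine variants of each (scale, aspect,
    rotation + shift, shear), with small seeded jitter on the variant
    parameters.  Label ``5*b + v`` encodes basic shape ``b`` and variant
    index ``v`` (0 = the unperturbed basic shape).
    """
    if size < 16:
        raise ValueError("size must be >= 16 for the shape set")
    rng = np.random.default_rng(seed)
    images, labels, names = [], [], []
    for b, name in enumerate(BASIC_SHAPES):
        base = _shape_mask(name, size)
        variants = [
            base,
            _apply_affine(base, scale=(0.72 + 0.05 * rng.uniform(),) * 2),
            _apply_affine(base, scale=(1.0, 0.58 + 0.05 * rng.uniform())),
            _apply_affine(base, rot_deg=25.0 + 8.0 * rng.uniform(),
                          shift=(0.08, 0.05)),
            _apply_affine(base, shear=0.30 + 0.08 * rng.uniform()),
        ]
        for v, img in enumerate(variants):
            images.append(img)
            labels.append(5 * b + v)
            names.append(f"{name}_v{v}")
    images = np.stack(images)
    if not white_on_black:
        images = 1.0 - images
    return StimulusSet(images=images, labels=np.asarray(labels),
                       family="shape", seed=seed, names=names)


def split_dataset(set_size: int, seed: int) -> DatasetSplit:
    """Shuffled 80/20 train/test split with 20% of train as validation.

    Test size is rounded half-up first, then validation from the training
    portion; the remainder is train.  Partition is exhaustive and disjoint.
    """
    if set_size < 10:
        raise ValueError("set_size must be >= 10")
    n_test = int(np.floor(0.2 * set_size + 0.5))
    n_val = int(np.floor(0.2 * 0.8 * set_size + 0.5))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(set_size)
    return DatasetSplit(test=np.sort(idx[:n_test]),
                        validation=np.sort(idx[n_test:n_test + n_val]),
                        train=np.sort(idx[n_test + n_val:]))


# -- I/O ----------------------------------------------------------------

def load_idx_images(images_path: str | Path, labels_path: str | Path,
                    limit: int | None = None) -> StimulusSet:
    """Load a locally available IDX-format digit corpus (never downloads)."""
    with open(images_path, "rb") as f:
        magic, n, rows, cols = struct.unpack(">IIII", f.read(16))
        if magic != 2051:
            raise ValueError("not an IDX image file")
        if limit is not None:
            n = min(n, limit)
        data = np.frombuffer(f.read(n * rows * cols), dtype=np.uint8)
    with open(labels_path, "rb") as f:
        magic, nl = struct.unpack(">II", f.read(8))
        if magic != 2049:
            raise ValueError("not an IDX label file")
        labels = np.frombuffer(f.read(min(nl, n)), dtype=np.uint8)[:n]
    images = data.reshape(n, rows, cols).astype(np.float64) / 255.0
    return StimulusSet(images=images, labels=labels.astype(np.int64),
                       family="digit_like", seed=-1)


def save_stimulus_set(sset: StimulusSet, out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, label) in enumerate(zip(sset.images, sset.labels)):
        name = sset.names[i] if sset.names else f"stim_{i:04d}"
        fname = f"{i:04d}_{name}.png"
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L"
                        ).save(out / fname)
        entries.append({"id": i, "file": fname, "label": int(label),
                        "name": name})
    manifest = {"family": sset.family, "seed": sset.seed, "images": entries}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_stimulus_set(manifest_path: str | Path) -> StimulusSet:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    images, labels, names = [], [], []
    for e in manifest["images"]:
        img = np.asarray(Image.open(mpath.parent / e["file"]),
                         dtype=np.float64) / 255.0
        images.append(img)
        labels.append(e["label"])
        names.append(e["name"])
    return StimulusSet(images=np.stack(images), labels=np.asarray(labels),
                       family=manifest["family"], seed=manifest["seed"],
                       names=names)
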