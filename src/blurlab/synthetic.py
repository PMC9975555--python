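"""Procedural shape-texture image dataset.

Every class is defined by BOTH a distinct global shape (a fixed polygon
prototype) and a distinct class-linked local texture (a flip-symmetric plaid:
two superposed gratings at orientations ±theta). Images composite the class
shape, filled with the class texture, over a low-contrast noise background
with randomized pose (translation / rotation / scale), so classifiers can in
principle rely on shape, texture, or both. Cue-conflict images pair the shape
of one class with the texture of another and carry two labels.

Textures are plaids rather than single oriented gratings so that horizontal
flipping (a standard training augmentation) maps each class texture onto
itself instead of onto another class's orientation. Object mean luminance
(0.72) differs from the background mean (0.42) so the silhouette remains
visible after strong blur, which is what makes shape-based recognition of
blurred images possible at all.

All randomness flows from explicit seeds; generation is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassSpec",
    "SceneParams",
    "DatasetManifest",
    "SyntheticDataset",
    "CueConflictSpec",
    "CueConflictSet",
    "default_class_specs",
    "render_object_image",
    "generate_dataset",
    "generate_cue_conflict_set",
]

OBJECT_MEAN = 0.72
OBJECT_AMP = 0.25
BACKGROUND_MEAN = 0.42
BACKGROUND_NOISE_AMP = 0.06

SCALE_RANGE = (0.55, 0.78)
ROTATION_RANGE = (-30.0, 30.0)

#: plaid carrier frequencies in cycles per image side, and the 8 orientations
TEXTURE_FREQS = (8.0, 14.0)
TEXTURE_THETAS = tuple(np.linspace(0.0, 90.0, 8))


# ---------------------------------------------------------------------------
# shape prototype library (fixed assets: vertices in unit coords, max radius 1)

def _regular_polygon(n: int, rot: float = 0.0) -> np.ndarray:
    a = np.deg2rad(rot) + 2 * np.pi * np.arange(n) / n
    return np.stack([np.cos(a), np.sin(a)], axis=1)


def _star(n: int, inner: float = 0.45) -> np.ndarray:
    a = np.pi / 2 + 2 * np.pi * np.arange(2 * n) / (2 * n)
    r = np.where(np.arange(2 * n) % 2 == 0, 1.0, inner)
    return np.stack([r * np.cos(a), r * np.sin(a)], axis=1)


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    v = v - v.mean(axis=0)
    return v / np.abs(np.linalg.norm(v, axis=1)).max()


def _shape_library() -> dict[str, np.ndarray]:
    lib: dict[str, np.ndarray] = {
        "triangle": _regular_polygon(3, rot=90),
        "square": _regular_polygon(4, rot=45),
        "pentagon": _regular_polygon(5, rot=90),
        "hexagon": _regular_polygon(6),
        "circle": _regular_polygon(40),
        "star5": _star(5),
        "star6": _star(6),
        "star4": _star(4, inner=0.35),
        "cross": np.array([
            (-1, 0.33), (-0.33, 0.33), (-0.33, 1), (0.33, 1), (0.33, 0.33),
            (1, 0.33), (1, -0.33), (0.33, -0.33), (0.33, -1), (-0.33, -1),
            (-0.33, -0.33), (-1, -0.33),
        ], dtype=float),
        "arrow": np.array([
            (-1, 0.3), (0.1, 0.3), (0.1, 0.75), (1, 0), (0.1, -0.75),
            (0.1, -0.3), (-1, -0.3),
        ], dtype=float),
        "tshape": np.array([
            (-1, 1), (1, 1), (1, 0.4), (0.3, 0.4), (0.3, -1), (-0.3, -1),
            (-0.3, 0.4), (-1, 0.4),
        ], dtype=float),
        "lshape": np.array([
            (-1, 1), (-0.3, 1), (-0.3, -0.3), (1, -0.3), (1, -1), (-1, -1),
        ], dtype=float),
        "diamond": np.array([(0, 1), (0.45, 0), (0, -1), (-0.45, 0)], dtype=float),
        "ellipse": np.stack(
            [np.cos(np.linspace(0, 2 * np.pi, 40, endpoint=False)),
             0.45 * np.sin(np.linspace(0, 2 * np.pi, 40, endpoint=False))], axis=1),
        "bolt": np.array([
            (-0.35, 1), (0.45, 1), (0.05, 0.25), (0.6, 0.25), (-0.45, -1),
            (-0.1, -0.1), (-0.6, -0.1),
        ], dtype=float),
        "blob": np.array([  # fixed irregular smooth-ish polygon
            (1.0, 0.1), (0.7, 0.55), (0.45, 0.5), (0.1, 0.95), (-0.4, 0.7),
            (-0.8, 0.75), (-0.95, 0.2), (-0.6, -0.15), (-0.85, -0.55),
            (-0.35, -0.85), (0.1, -0.6), (0.5, -0.9), (0.8, -0.5), (0.55, -0.15),
        ], dtype=float),
    }
    return {name: _normalize(v) for name, v in lib.items()}


SHAPE_LIBRARY = _shape_library()
SHAPE_ORDER = (
    "triangle", "square", "pentagon", "hexagon", "circle", "star5", "star6",
    "star4", "cross", "arrow", "tshape", "lshape", "diamond", "ellipse",
    "bolt", "blob",
)


@dataclass(frozen=True)
class ClassSpec:
    """One object class: a shape prototype plus a plaid texture.

    theta is the plaid half-angle in degrees (components at ±theta), freq the
    carrier frequency in cycles per image side.
    """

    class_id: int
    name: str
    shape: np.ndarray  # (V, 2) closed contour control points, max radius 1
    theta: float
    freq: float

    def texture_params(self) -> dict:
        return {"theta": self.theta, "freq": self.freq}


def default_class_specs(n_classes: int = 16) -> list[ClassSpec]:
    """The fixed library of class definitions (up to 16 classes)."""
    if not 2 <= n_classes <= 16:
        raise ValueError("n_classes must be in [2, 16]")
    specs = []
    for i in range(n_classes):
        specs.append(ClassSpec(
            class_id=i,
            name=SHAPE_ORDER[i],
            shape=SHAPE_LIBRARY[SHAPE_ORDER[i]],
            theta=TEXTURE_THETAS[i % 8],
            freq=TEXTURE_FREQS[0] if i < 8 else TEXTURE_FREQS[1],
        ))
    return specs


@dataclass(frozen=True)
class SceneParams:
    """Pose and nuisance parameters of one rendered scene (all seeded)."""

    translation: tuple[float, float]
    rotation: float      # degrees
    scale: float         # object radius as a fraction of image half-side
    seed: int            # master seed for this scene (background, phase)

    @staticmethod
    def draw(seed: int, image_size: int) -> "SceneParams":
        """Draw scene parameters such that the object stays fully in frame."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        scale = rng.uniform(*SCALE_RANGE)
        rotation = rng.uniform(*ROTATION_RANGE)
        half = image_size / 2.0
        margin = half * (1.0 - scale) - 1.0
        tx, ty = rng.uniform(-margin, margin, size=2)
        return SceneParams((float(tx), float(ty)), float(rotation), float(scale), seed)


def _object_mask(shape: np.ndarray, scene: SceneParams, image_size: int,
                 supersample: int = 2) -> np.ndarray:
    """Soft [0,1] silhouette mask (supersampled rasterization of the contour)."""
    s = supersample
    n = image_size * s
    half = image_size / 2.0
    th = np.deg2rad(scene.rotation)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    verts = shape @ rot.T * (scene.scale * half)
    verts = verts + np.array([half + scene.translation[0], half + scene.translation[1]])
    yy, xx = np.mgrid[0:n, 0:n]
    pts = np.stack([(xx.ravel() + 0.5) / s, (yy.ravel() + 0.5) / s], axis=1)
    inside = MplPath(verts).contains_points(pts).reshape(n, n)
    return inside.reshape(image_size, s, image_size, s).mean(axis=(1, 3))


def _plaid(theta: float, freq: float, image_size: int, rng: np.random.Generator) -> np.ndarray:
    """Flip-symmetric plaid texture field in [-1, 1] with seeded phase jitter."""
    jitter = rng.uniform(-3.0, 3.0)
    f = freq * rng.uniform(0.95, 1.05)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    out = np.zeros((image_size, image_size))
    for sign, ph in zip((1.0, -1.0), phases):
        a = np.deg2rad(sign * (theta + jitter))
        out += np.sin(2 * np.pi * f * (xx * np.cos(a) + yy * np.sin(a)) / image_size + ph)
    return out / 2.0


def render_object_image(cls: ClassSpec, scene: SceneParams, image_size: int = 64,
                        texture_of: ClassSpec | None = None,
                        return_mask: bool = False):
    """Render one labeled image: class shape filled with a class texture.

    ``texture_of`` overrides the texture source (used for cue-conflict images);
    the silhouette depends only on ``cls.shape`` and the scene geometry, so a
    cue-conflict render shares its mask bit-for-bit with the pure render of the
    shape class under the same scene.
    """
    tex_cls = cls if texture_of is None else texture_of
    ss = np.random.SeedSequence([scene.seed, 1])
    bg_rng = np.random.default_rng(ss)
    tex_rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 2]))

    mask = _object_mask(cls.shape, scene, image_size)
    bg = BACKGROUND_MEAN + BACKGROUND_NOISE_AMP * np.clip(
        gaussian_filter(bg_rng.standard_normal((image_size, image_size)), 1.5) * 2.5,
        -1.5, 1.5)
    tex = OBJECT_MEAN + OBJECT_AMP * _plaid(tex_cls.theta, tex_cls.freq, image_size, tex_rng)
    img = bg * (1.0 - mask) + tex * mask
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    img = np.repeat(img[:, :, None], 3, axis=2)
    if return_mask:
        return img, mask
    return img


# ---------------------------------------------------------------------------
# dataset generation

@dataclass
class DatasetManifest:
    """Record of everything needed to regenerate or locate the dataset."""

    n_classes: int
    image_size: int
    master_seed: int
    class_names: list[str]
    records: list[dict] = field(default_factory=list)

    def counts(self) -> dict:
        out: dict[str, dict[int, int]] = {}
        for r in self.records:
            out.setdefault(r["split"], {}).setdefault(r["class_id"], 0)
            out[r["split"]][r["class_id"]] += 1
        return out

    def to_json(self) -> str:
        return json.dumps({
            "n_classes": self.n_classes, "image_size": self.image_size,
            "master_seed": self.master_seed, "class_names": self.class_names,
            "records": self.records,
        }, indent=1)

    @staticmethod
    def from_json(text: str) -> "DatasetManifest":
        d = json.loads(text)
        return DatasetManifest(d["n_classes"], d["image_size"], d["master_seed"],
                               d["class_names"], d["records"])

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _scene_seed(master_seed: int, split: str, class_id: int, idx: int) -> int:
    split_code = {"train": 1, "test": 2}[split]
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(split_code, class_id, idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class SyntheticDataset:
    """In-memory dataset: class-balanced, seed-disjoint train/test splits."""

    train_images: np.ndarray  # (Ntr, H, W, 3) float32
    train_labels: np.ndarray  # (Ntr,) int64
    test_images: np.ndarray
    test_labels: np.ndarray
    classes: list[ClassSpec]
    manifest: DatasetManifest

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def save(self, out_dir: str | Path) -> None:
        """Write PNGs under ``<dir>/<split>/<class>/`` plus the JSON manifest."""
        from PIL import Image

        out = Path(out_dir)
        arrays = {"train": (self.train_images, self.train_labels),
                  "test": (self.test_images, self.test_labels)}
        idx_by_split = {"train": 0, "test": 0}
        for rec in self.manifest.records:
            split = rec["split"]
            imgs, _ = arrays[split]
            img = imgs[idx_by_split[split]]
            idx_by_split[split] += 1
            p = out / rec["path"]
            p.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8)).save(p)
        (out / "manifest.json").write_text(self.manifest.to_json())

    @staticmethod
    def load(in_dir: str | Path) -> "SyntheticDataset":
        from PIL import Image

        root = Path(in_dir)
        manifest = DatasetManifest.from_json((root / "manifest.json").read_text())
        classes = default_class_specs(manifest.n_classes)
        data: dict[str, tuple[list, list]] = {"train": ([], []), "test": ([], [])}
        for rec in manifest.records:
            img = np.asarray(Image.open(root / rec["path"]), dtype=np.float32) / 255.0
            data[rec["split"]][0].append(img)
            data[rec["split"]][1].append(rec["class_id"])
        return SyntheticDataset(
            np.stack(data["train"][0]), np.asarray(data["train"][1], dtype=np.int64),
            np.stack(data["test"][0]), np.asarray(data["test"][1], dtype=np.int64),
            classes, manifest)


def generate_dataset(n_classes: int = 16, n_train: int = 128, n_test: int = 32,
                     image_size: int = 64, master_seed: int = 0) -> SyntheticDataset:
    """Generate a class-balanced dataset with seed-disjoint train/test splits.

    Per-image scene seeds derive from ``(master_seed, split, class, index)``
    via :class:`numpy.random.SeedSequence` spawn keys, so splits are disjoint
    by construction and regeneration with the same master seed is
    bit-identical.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_train < 1 or n_test < 1:
        raise ValueError("per-class counts must be positive")
    classes = default_class_specs(n_classes)
    manifest = DatasetManifest(n_classes, image_size, master_seed,
                               [c.name for c in classes])
    splits = {"train": n_train, "test": n_test}
    images: dict[str, list[np.ndarray]] = {"train": [], "test": []}
    labels: dict[str, list[int]] = {"train": [], "test": []}
    for split, n_per in splits.items():
        for cls in classes:
            for idx in range(n_per):
                seed = _scene_seed(master_seed, split, cls.class_id, idx)
                scene = SceneParams.draw(seed, image_size)
                images[split].append(render_object_image(cls, scene, image_size))
                labels[split].append(cls.class_id)
                manifest.records.append({
                    "path": f"{split}/class_{cls.class_id:02d}/img_{idx:05d}.png",
                    "class_id": cls.class_id, "split": split, "scene_seed": seed,
                })
    return SyntheticDataset(
        np.stack(images["train"]), np.asarray(labels["train"], dtype=np.int64),
        np.stack(images["test"]), np.asarray(labels["test"], dtype=np.int64),
        classes, manifest)


# ---------------------------------------------------------------------------
# cue-conflict set

@dataclass(frozen=True)
class CueConflictSpec:
    """One ordered (shape, texture) class pairing and how many images to render."""

    shape_class: int
    texture_class: int
    n_per_pair: int = 1

    def __post_init__(self) -> None:
        if self.shape_class == self.texture_class:
            raise ValueError("cue-conflict requires shape_class != texture_class")
        if self.n_per_pair < 1:
            raise ValueError("n_per_pair must be positive")


@dataclass
class CueConflictSet:
    """Images carrying the shape of one class and the texture of another."""

    images: np.ndarray        # (N, H, W, 3) float32
    shape_labels: np.ndarray  # (N,) int64
    texture_labels: np.ndarray
    scene_seeds: np.ndarray

    def __len__(self) -> int:
        return len(self.images)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "image": np.arange(len(self.images)),
            "shape_class": self.shape_labels,
            "texture_class": self.texture_labels,
            "scene_seed": self.scene_seeds,
        })


def generate_cue_conflict_set(classes: list[ClassSpec], n_per_pair: int = 1,
                              image_size: int = 64, master_seed: int = 0) -> CueConflictSet:
    """Render ``n_per_pair`` images for every ordered (shape, texture) class pair.

    Every image has shape_class != texture_class; with C classes the set has
    ``C*(C-1)*n_per_pair`` images, i.e. ``(C-1)*n_per_pair`` per shape class.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for cue conflict")
    if n_per_pair < 1:
        raise ValueError("n_per_pair must be positive")
    imgs, shp, tex, seeds = [], [], [], []
    for cs in classes:
        for ct in classes:
            if cs.class_id == ct.class_id:
                continue
            for idx in range(n_per_pair):
                ss = np.random.SeedSequence(
                    entropy=master_seed,
                    spawn_key=(3, cs.class_id, ct.class_id, idx))
                seed = int(ss.generate_state(1, dtype=np.uint32)[0])
                scene = SceneParams.draw(seed, image_size)
                imgs.append(render_object_image(cs, scene, image_size, texture_of=ct))
                shp.append(cs.class_id)
                tex.append(ct.class_id)
                seeds.append(seed)
    return CueConflictSet(np.stack(imgs), np.asarray(shp, dtype=np.int64),
                          np.asarray(tex, dtype=np.int64), np.asarray(seeds))
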