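"""Synthetic laparoscopic-like scene generator.

Produces small RGB frames that mimic the structural features of surgical
video that the localization pipeline depends on, without any real data:

* dark, textured tissue-like background (low-frequency noise, optional blur);
* each tool rendered as a bright elongated capsule whose base sits on a frame
  border (instruments enter the field of view from the edges) with a brighter
  "tip" blob at its interior end;
* per-class distinctive colours so presence is learnable from image-level
  labels alone;
* severe class imbalance via per-class presence probabilities defaulting to
  the Cholec80 occurrence proportions;
* optional interior "distractor" blobs that deliberately do NOT touch a
  border, to exercise the edge-touch contour filter negatively.

Every frame is a pure function of ``(config.seed, frame_index)``, so datasets
regenerate byte-identically and frames can be produced in any order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

from .constants import CLASS_NAMES, default_prevalences
from .errors import ConfigurationError

# Bright, mutually distant RGB colours, one per tool class (project order).
TOOL_COLORS: dict[str, tuple[int, int, int]] = {
    "grasper": (230, 60, 60),
    "bipolar": (60, 110, 230),
    "hook": (240, 210, 60),
    "scissors": (60, 220, 220),
    "clipper": (220, 60, 220),
    "irrigator": (80, 230, 80),
    "specimen_bag": (235, 235, 235),
}

MANIFEST_NAME = "manifest.csv"
BOXES_NAME = "boxes.csv"


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution.

    ``class_prevalences`` are independent per-class Bernoulli presence
    probabilities; ``max_tools_per_frame`` caps how many sampled presences are
    actually rendered.  ``distractor_rate`` is the probability of adding one
    interior blob that touches no border (unlabelled, no ground-truth box).
    """

    image_size: tuple[int, int] = (64, 64)  # (height, width) px
    class_names: tuple[str, ...] = CLASS_NAMES
    class_prevalences: tuple[float, ...] = tuple(default_prevalences())
    max_tools_per_frame: int = 3
    blur_sigma: float = 0.6
    noise_level: float = 0.02
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ConfigurationError(f"image_size must be >= 32 px per side, got {self.image_size}")
        if len(self.class_names) < 1:
            raise ConfigurationError("at least one tool class is required")
        if len(self.class_prevalences) != len(self.class_names):
            raise ConfigurationError("class_prevalences length must match class_names")
        if any(not 0.0 <= p <= 1.0 for p in self.class_prevalences):
            raise ConfigurationError("class prevalences must lie in [0, 1]")
        if self.max_tools_per_frame < 0:
            raise ConfigurationError("max_tools_per_frame must be >= 0")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ConfigurationError("noise_level must lie in [0, 1]")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ConfigurationError("distractor_rate must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class GroundTruthBox:
    """Tight axis-aligned box of one rendered tool (0-based, half-open)."""

    class_id: int
    box: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class ManifestRecord:
    frame_path: str
    video_id: int
    labels: np.ndarray  # multi-hot, length K
    boxes: list[GroundTruthBox]


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    seed: int
    config: SceneConfig

    def video_ids(self) -> list[int]:
        return sorted({r.video_id for r in self.records})

    def class_counts(self, video_ids: Sequence[int] | None = None) -> np.ndarray:
        """Number of frames containing each class, optionally restricted to videos."""
        keep = self.records if video_ids is None else [r for r in self.records if r.video_id in set(video_ids)]
        if not keep:
            return np.zeros(self.config.n_classes, dtype=int)
        return np.sum([r.labels for r in keep], axis=0).astype(int)


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    # order-independent reproducibility: stream keyed on (seed, frame_index)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed % (2**63), spawn_key=(frame_index,)))


def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Dark tissue-like texture: a few octaves of upsampled value noise."""
    base = np.array([38.0, 16.0, 14.0])  # dark red-brown
    img = np.ones((h, w, 3)) * base
    for cell, amp in ((8, 22.0), (4, 10.0)):
        grid = rng.standard_normal((max(2, h // cell), max(2, w // cell)))
        up = zoom(grid, (h / grid.shape[0], w / grid.shape[1]), order=1)[:h, :w]
        img += amp * up[..., None] * np.array([1.0, 0.55, 0.45])
    return np.clip(img, 0.0, 90.0)


def _capsule_mask(h: int, w: int, p0: np.ndarray, p1: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of points within ``radius`` of segment p0-p1 ((x, y) coords)."""
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs, ys], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros((h, w))
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    return dist2 <= radius**2


def _disk_mask(h: int, w: int, center: np.ndarray, radius: float) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2


def _render_tool(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one edge-anchored elongated tool; returns its boolean support mask.

    The base point lies exactly on a uniformly chosen border, the shaft points
    inward with +/-45 deg jitter, and a brighter tip disk caps the interior end,
    so the support always intersects the border.
    """
    edge = rng.integers(4)  # 0 top, 1 bottom, 2 left, 3 right
    if edge == 0:
        p0 = np.array([rng.uniform(2, w - 3), 0.0])
        normal = np.array([0.0, 1.0])
    elif edge == 1:
        p0 = np.array([rng.uniform(2, w - 3), float(h - 1)])
        normal = np.array([0.0, -1.0])
    elif edge == 2:
        p0 = np.array([0.0, rng.uniform(2, h - 3)])
        normal = np.array([1.0, 0.0])
    else:
        p0 = np.array([float(w - 1), rng.uniform(2, h - 3)])
        normal = np.array([-1.0, 0.0])
    ang = rng.uniform(-np.pi / 4, np.pi / 4)
    c, s = np.cos(ang), np.sin(ang)
    direction = np.array([c * normal[0] - s * normal[1], s * normal[0] + c * normal[1]])
    length = rng.uniform(0.35, 0.8) * min(h, w)
    p1 = p0 + length * direction
    p1[0] = np.clip(p1[0], 3.0, w - 4.0)
    p1[1] = np.clip(p1[1], 3.0, h - 4.0)
    radius = rng.uniform(1.6, max(2.2, min(h, w) / 18))
    shaft = _capsule_mask(h, w, p0, p1, radius)
    tip = _disk_mask(h, w, p1, radius * 1.7)
    return shaft | tip, p1, radius


def _paint(frame: np.ndarray, mask: np.ndarray, color: tuple[int, int, int], rng: np.random.Generator) -> None:
    jitter = rng.uniform(-15, 15, size=3)
    frame[mask] = np.clip(np.array(color, dtype=float) + jitter, 0, 255)


def _tight_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _sample_present_classes(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    """Class indices present in a frame: independent Bernoulli draws, capped."""
    present = rng.random(config.n_classes) < np.asarray(config.class_prevalences)
    idx = np.flatnonzero(present)
    if idx.size > config.max_tools_per_frame:
        idx = rng.choice(idx, size=config.max_tools_per_frame, replace=False)
        idx.sort()
    return idx


def sample_labels(config: SceneConfig, frame_index: int) -> np.ndarray:
    """Multi-hot label vector of a frame without rendering it.

    Presence sampling is the first RNG consumption of the per-frame stream,
    so this agrees bit-for-bit with the labels :func:`generate_scene` emits —
    a fast path for statistical checks over many frames.
    """
    if frame_index < 0:
        raise ConfigurationError("frame_index must be >= 0")
    rng = _frame_rng(config.seed, frame_index)
    labels = np.zeros(config.n_classes, dtype=int)
    labels[_sample_present_classes(rng, config)] = 1
    return labels


def generate_scene(
    config: SceneConfig, frame_index: int
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthBox]]:
    """Render one frame; returns (H x W x 3 uint8 image, multi-hot labels, boxes).

    Deterministic in ``(config.seed, frame_index)``.  Label bit k is 1 iff at
    least one class-k shape was rendered; each box is the tight bounding box
    of one shape's pre-blur pixel support.
    """
    if frame_index < 0:
        raise ConfigurationError("frame_index must be >= 0")
    h, w = config.image_size
    rng = _frame_rng(config.seed, frame_index)
    idx = _sample_present_classes(rng, config)
    frame = _background(rng, h, w)

    labels = np.zeros(config.n_classes, dtype=int)
    boxes: list[GroundTruthBox] = []
    for k in idx:
        name = config.class_names[k]
        color = TOOL_COLORS.get(name, (220, 220, 220))
        mask, tip_center, radius = _render_tool(rng, h, w)
        if not mask.any():  # pragma: no cover - capsule always covers its base
            continue
        _paint(frame, mask, color, rng)
        # brighter tip, scaled along the tool's own colour so class hue is preserved
        tip = _disk_mask(h, w, tip_center, radius * 1.2) & mask
        frame[tip] = np.clip(frame[tip] * 1.25, 0, 255)
        labels[k] = 1
        boxes.append(GroundTruthBox(class_id=int(k), box=_tight_box(mask)))

    if rng.random() < config.distractor_rate:
        m = max(8, min(h, w) // 6)
        center = np.array([rng.uniform(m, w - 1 - m), rng.uniform(m, h - 1 - m)])
        r = rng.uniform(2.0, m / 2.5)
        blob = _disk_mask(h, w, center, r)
        _paint(frame, blob, (200, 200, 160), rng)

    if config.blur_sigma > 0:
        for ch in range(3):
            frame[..., ch] = gaussian_filter(frame[..., ch], sigma=config.blur_sigma)
    if config.noise_level > 0:
        frame = frame + rng.uniform(-1, 1, size=frame.shape) * (config.noise_level * 255.0)
    return np.clip(np.round(frame), 0, 255).astype(np.uint8), labels, boxes


def generate_dataset(
    config: SceneConfig, n_frames: int, n_videos: int, out_dir: str | Path
) -> DatasetManifest:
    """Write ``n_frames`` PNGs plus manifest/box CSVs; frames assigned to videos round-robin."""
    if n_videos < 1 or n_frames < n_videos:
        raise ConfigurationError("need n_frames >= n_videos >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    for i in range(n_frames):
        frame, labels, boxes = generate_scene(config, i)
        rel = f"frame_{i:06d}.png"
        Image.fromarray(frame).save(out / rel)
        records.append(ManifestRecord(frame_path=rel, video_id=i % n_videos, labels=labels, boxes=boxes))
    manifest = DatasetManifest(records=records, seed=config.seed, config=config)
    write_manifest(manifest, out)
    return manifest


def write_manifest(manifest: DatasetManifest, out_dir: str | Path) -> None:
    out = Path(out_dir)
    names = manifest.config.class_names
    with open(out / MANIFEST_NAME, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_path", "video_id", *names])
        for r in manifest.records:
            writer.writerow([r.frame_path, r.video_id, *r.labels.tolist()])
    with open(out / BOXES_NAME, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_path", "class_id", "x_min", "y_min", "x_max", "y_max"])
        for r in manifest.records:
            for b in r.boxes:
                writer.writerow([r.frame_path, b.class_id, *b.box])


def load_manifest(data_dir: str | Path, config: SceneConfig | None = None) -> DatasetManifest:
    """Read a manifest + box CSV pair written by :func:`generate_dataset`."""
    data = Path(data_dir)
    boxes_by_frame: dict[str, list[GroundTruthBox]] = {}
    with open(data / BOXES_NAME, newline="") as fh:
        for row in csv.DictReader(fh):
            boxes_by_frame.setdefault(row["frame_path"], []).append(
                GroundTruthBox(
                    class_id=int(row["class_id"]),
                    box=(int(row["x_min"]), int(row["y_min"]), int(row["x_max"]), int(row["y_max"])),
                )
            )
    records: list[ManifestRecord] = []
    with open(data / MANIFEST_NAME, newline="") as fh:
        reader = csv.DictReader(fh)
        names = [c for c in reader.fieldnames if c not in ("frame_path", "video_id")]
        for row in reader:
            labels = np.array([int(row[c]) for c in names], dtype=int)
            records.append(
                ManifestRecord(
                    frame_path=row["frame_path"],
                    video_id=int(row["video_id"]),
                    labels=labels,
                    boxes=boxes_by_frame.get(row["frame_path"], []),
                )
            )
    if config is None:
        config = SceneConfig(class_names=tuple(names), class_prevalences=tuple([0.0] * len(names)))
    return DatasetManifest(records=records, seed=config.seed, config=config)


def export_coco(manifest: DatasetManifest, path: str | Path) -> None:
    """COCO-style JSON export of the ground-truth boxes (xywh box convention)."""
    h, w = manifest.config.image_size
    images = [
        {"id": i, "file_name": r.frame_path, "height": h, "width": w}
        for i, r in enumerate(manifest.records)
    ]
    categories = [{"id": k, "name": name} for k, name in enumerate(manifest.config.class_names)]
    annotations = []
    aid = 0
    for i, r in enumerate(manifest.records):
        for b in r.boxes:
            x0, y0, x1, y1 = b.box
            annotations.append(
                {
                    "id": aid,
                    "image_id": i,
                    "category_id": b.class_id,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                }
            )
            aid += 1
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations, "categories": categories}, fh)
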