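"""Heat map -> bounding box post-processing.

The weakly supervised detector never sees box labels; boxes emerge from the
classifier's attention by classical image processing:

1. quantize the class heat map to 8 bits and binarize at the Otsu threshold
   (the gray level maximizing between-class intensity variance);
2. extract 8-connected foreground components ("contours");
3. filter out implausible components — a surgical instrument enters the
   scene through a trocar, so its contour must touch a frame edge, and tiny
   speckle components are dropped by an area floor;
4. take each surviving component's tight bounding box and run greedy
   per-class non-maximum suppression;
5. attach the classifier's class probability as the detection confidence;
   classes whose probability does not exceed the presence threshold produce
   no detections at all.

Coordinates are 0-based with x rightward and y downward; boxes are half-open
``(x_min, y_min, x_max, y_max)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigurationError, DegenerateImageError
from .gradcam import grad_cam, heatmap_to_uint8

Box = tuple[int, int, int, int]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class Detection:
    class_id: int
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> int:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class Contour:
    """One 8-connected foreground component: pixel set, ordered boundary, area."""

    pixels: np.ndarray  # (N, 2) of (x, y)
    boundary: np.ndarray  # ordered perimeter positions, (M, 2) of (x, y)
    area: int


@dataclass(frozen=True)
class LocalizationConfig:
    edge_margin_px: int = 2
    min_area_fraction: float = 0.005
    nms_iou_threshold: float = 0.5
    presence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.edge_margin_px < 0:
            raise ConfigurationError("edge_margin_px must be >= 0")
        if not 0.0 <= self.min_area_fraction < 1.0:
            raise ConfigurationError("min_area_fraction must lie in [0, 1)")
        if not 0.0 < self.nms_iou_threshold <= 1.0:
            raise ConfigurationError("nms_iou_threshold must lie in (0, 1]")
        if not 0.0 < self.presence_threshold < 1.0:
            raise ConfigurationError("presence_threshold must lie in (0, 1)")


def otsu_threshold(gray: np.ndarray) -> int:
    """Threshold maximizing between-class variance of the 256-bin histogram.

    Ties break toward the smallest threshold; foreground is ``value > t``.
    Raises :class:`DegenerateImageError` on a constant image, which carries
    no foreground/background structure (callers treat the mask as empty).
    """
    g = np.asarray(gray)
    if g.size == 0:
        raise ConfigurationError("empty image")
    hist = np.bincount(g.astype(np.uint8).ravel(), minlength=256)
    # exact integer arithmetic: sigma_B^2(t) is proportional to
    # (S*c0 - N*s0)^2 / (c0*(N-c0)) with integer cumulative count c0 and
    # cumulative intensity sum s0 -- compared as exact fractions so that
    # mathematical ties (e.g. empty bins between modes) break toward the
    # smallest t instead of on floating-point noise
    c0 = np.cumsum(hist).tolist()
    s0 = np.cumsum(hist * np.arange(256)).tolist()
    n = int(c0[-1])
    s = int(s0[-1])
    best_t = None
    best_num, best_den = -1, 1
    for t in range(256):
        c = int(c0[t])
        if c == 0 or c == n:
            continue
        num = (s * c - n * int(s0[t])) ** 2
        den = c * (n - c)
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    if best_t is None:
        raise DegenerateImageError("constant image: between-class variance undefined")
    return best_t


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Ordered perimeter of a boolean component mask as (x, y) pixel positions."""
    padded = np.pad(component.astype(float), 1)
    traces = measure.find_contours(padded, 0.5)
    if not traces:
        ys, xs = np.nonzero(component)
        return np.stack([xs, ys], axis=1)
    longest = max(traces, key=len)
    h, w = component.shape
    out: list[tuple[int, int]] = []
    for r, c in longest:
        # marching-squares points sit between pixels; snap to the adjacent
        # pixel that belongs to the component
        for yy, xx in (
            (int(np.floor(r)) - 1, int(np.floor(c)) - 1),
            (int(np.floor(r)) - 1, int(np.ceil(c)) - 1),
            (int(np.ceil(r)) - 1, int(np.floor(c)) - 1),
            (int(np.ceil(r)) - 1, int(np.ceil(c)) - 1),
        ):
            if 0 <= yy < h and 0 <= xx < w and component[yy, xx]:
                if not out or out[-1] != (xx, yy):
                    out.append((xx, yy))
                break
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return np.array(out, dtype=int)


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """8-connected components, ordered by their top-left-most pixel (raster order)."""
    m = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(m, structure=_EIGHT)
    contours = []
    for lab in range(1, n + 1):
        component = labeled == lab
        ys, xs = np.nonzero(component)
        first = int(np.lexsort((xs, ys))[0])
        contours.append(
            (
                (int(ys[first]), int(xs[first])),
                Contour(
                    pixels=np.stack([xs, ys], axis=1),
                    boundary=_trace_boundary(component),
                    area=int(len(xs)),
                ),
            )
        )
    contours.sort(key=lambda t: t[0])
    return [c for _, c in contours]


def filter_contours(
    contours: Sequence[Contour], image_size: tuple[int, int], config: LocalizationConfig
) -> list[Contour]:
    """Keep contours that touch a frame edge (within margin) and clear the area floor."""
    h, w = image_size
    min_area = config.min_area_fraction * h * w
    kept = []
    for c in contours:
        xs, ys = c.pixels[:, 0], c.pixels[:, 1]
        touches = (
            (xs <= config.edge_margin_px).any()
            or (ys <= config.edge_margin_px).any()
            or (xs >= w - 1 - config.edge_margin_px).any()
            or (ys >= h - 1 - config.edge_margin_px).any()
        )
        if touches and c.area >= min_area:
            kept.append(c)
    return kept


def contour_to_bbox(contour: Contour) -> Box:
    """Tight axis-aligned half-open box over the contour's pixels."""
    if contour.pixels.size == 0:
        raise ValueError("empty contour has no bounding box")
    xs, ys = contour.pixels[:, 0], contour.pixels[:, 1]
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, 0) * max(ih, 0)
    return inter / (area_a + area_b - inter)


def nms(detections: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy same-class non-maximum suppression.

    Repeatedly keeps the highest-confidence remaining detection (ties: larger
    area, then input order) and discards others overlapping it with
    IoU > ``iou_threshold``; output sorted by confidence descending.
    """
    remaining = sorted(
        range(len(detections)), key=lambda i: (-detections[i].confidence, -detections[i].area, i)
    )
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(detections[best])
        remaining = [i for i in remaining if iou(detections[i].box, detections[best].box) <= iou_threshold]
    return kept


def boxes_from_heatmap(
    heat_values: np.ndarray,
    config: LocalizationConfig,
    class_id: int = 0,
    confidence: float = 1.0,
) -> list[Detection]:
    """Run the threshold/contour/filter/NMS chain on one heat map.

    ``heat_values`` is an H x W map in [0, 1]; the confidence attached to every
    surviving box is the caller-supplied class probability.
    """
    q = heatmap_to_uint8(heat_values)
    try:
        t = otsu_threshold(q)
    except DegenerateImageError:
        return []
    mask = q > t
    if not mask.any():
        return []
    contours = filter_contours(extract_contours(mask), q.shape, config)
    dets = [Detection(class_id=class_id, box=contour_to_bbox(c), confidence=confidence) for c in contours]
    return nms(dets, config.nms_iou_threshold)


def localize(model, image: np.ndarray, config: LocalizationConfig | None = None) -> list[Detection]:
    """Full weakly supervised detection for one frame.

    For every class whose predicted probability exceeds the presence
    threshold: Grad-CAM -> Otsu -> contours -> edge/area filter -> boxes ->
    per-class NMS.  Classes at or below the threshold yield no detections.
    """
    if config is None:
        config = LocalizationConfig()
    prediction = model.predict(image)
    detections: list[Detection] = []
    for k, prob in enumerate(prediction.probabilities):
        if prob <= config.presence_threshold:
            continue
        hm = grad_cam(model, image, k)
        detections.extend(boxes_from_heatmap(hm.values, config, class_id=k, confidence=float(prob)))
    return detections


# -- detection I/O -----------------------------------------------------------

DETECTIONS_HEADER = ["frame_path", "class_id", "confidence", "x_min", "y_min", "x_max", "y_max"]


def write_detections_csv(rows: Sequence[tuple[str, Detection]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTIONS_HEADER)
        for frame_path, d in rows:
            writer.writerow([frame_path, d.class_id, f"{d.confidence:.6f}", *d.box])


def read_detections_csv(path: str | Path) -> list[tuple[str, Detection]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                (
                    row["frame_path"],
                    Detection(
                        class_id=int(row["class_id"]),
                        box=(int(row["x_min"]), int(row["y_min"]), int(row["x_max"]), int(row["y_max"])),
                        confidence=float(row["confidence"]),
                    ),
                )
            )
    return out


def export_detections_coco(rows: Sequence[tuple[str, Detection]], path: str | Path) -> None:
    frames = sorted({fp for fp, _ in rows})
    frame_id = {fp: i for i, fp in enumerate(frames)}
    results = [
        {
            "image_id": frame_id[fp],
            "category_id": d.class_id,
            "bbox": [d.box[0], d.box[1], d.box[2] - d.box[0], d.box[3] - d.box[1]],
            "score": d.confidence,
        }
        for fp, d in rows
    ]
    Path(path).write_text(json.dumps({"images": frames, "annotations": results}))
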