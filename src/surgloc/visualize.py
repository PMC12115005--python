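"""Overlay rendering: heat maps, ground-truth boxes (blue), predictions (green)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import DataError
from .gradcam import HeatMap, overlay_heatmap
from .localization import Detection
from .synthetic import GroundTruthBox

TRUTH_COLOR = (50, 80, 255)  # blue
PRED_COLOR = (60, 220, 60)  # green


def _draw_rect(img: np.ndarray, box, color, thickness: int = 2) -> None:
    h, w = img.shape[:2]
    x0, y0, x1, y1 = (int(v) for v in box)
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    for t in range(thickness):
        if y0 + t < h:
            img[y0 + t, x0:x1] = color
        if 0 <= y1 - 1 - t < h:
            img[y1 - 1 - t, x0:x1] = color
        if x0 + t < w:
            img[y0:y1, x0 + t] = color
        if 0 <= x1 - 1 - t < w:
            img[y0:y1, x1 - 1 - t] = color


def render_overlay(
    frame: np.ndarray,
    heatmap: HeatMap | None = None,
    detections: Sequence[Detection] = (),
    truths: Sequence[GroundTruthBox] = (),
    alpha: float = 0.4,
) -> np.ndarray:
    """Blend the false-color heat map over the frame and draw both box sets.

    ``alpha=0`` reproduces the annotated original frame exactly.
    """
    out = np.asarray(frame).copy()
    if heatmap is not None:
        if heatmap.values.shape != out.shape[:2]:
            raise DataError(
                f"heat map {heatmap.values.shape} does not match frame {out.shape[:2]}"
            )
        out = overlay_heatmap(out, heatmap, alpha=alpha)
    for t in truths:
        _draw_rect(out, t.box, TRUTH_COLOR)
    for d in detections:
        _draw_rect(out, d.box, PRED_COLOR)
    return out


def save_overlay(
    frame: np.ndarray,
    out_path: str | Path,
    heatmap: HeatMap | None = None,
    detections: Sequence[Detection] = (),
    truths: Sequence[GroundTruthBox] = (),
    alpha: float = 0.4,
) -> None:
    Image.fromarray(render_overlay(frame, heatmap, detections, truths, alpha)).save(out_path)
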