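"""Gradient-weighted class activation mapping (Grad-CAM).

Given a classifier whose last layer before the head is spatially indexed,
the attention of class k is recovered without any localization supervision:

1. forward pass; backward pass of the class-k *logit* (not the sigmoid
   probability, whose gradient saturates) down to the feature layer;
2. average the gradients over the spatial grid to get one importance weight
   per channel;
3. sum the feature maps weighted by those importances and rectify (ReLU) —
   only features with positive influence on the class score contribute;
4. bilinearly upsample the coarse map to the input size and min-max
   normalize to [0, 1]; a constant map normalizes to all zeros.

Rectification is exposed as a flag (default on); 8-bit quantization happens
only when handing off to thresholding, the heat map itself stays real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .errors import ShapeError
from .nn.backbone import FEATURE_LAYER_NAME


@dataclass(frozen=True)
class FeatureMapStack:
    """C' x H' x W' activations (or gradients) of one spatial layer."""

    values: np.ndarray
    layer_name: str = FEATURE_LAYER_NAME

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ShapeError(f"expected nonempty (C', H', W') stack, got {self.values.shape}")


@dataclass(frozen=True)
class HeatMap:
    """Per-class attention raster in [0, 1], same size as the source frame."""

    values: np.ndarray
    class_id: int
    source_frame: str = ""


def channel_weights(gradients: FeatureMapStack | np.ndarray) -> np.ndarray:
    """Spatially averaged gradients: one importance weight per channel."""
    g = gradients.values if isinstance(gradients, FeatureMapStack) else np.asarray(gradients)
    if g.ndim != 3 or g.shape[1] < 1 or g.shape[2] < 1:
        raise ShapeError(f"expected (C', H', W') gradients, got shape {g.shape}")
    return g.mean(axis=(1, 2))


def cam(features: FeatureMapStack | np.ndarray, weights: np.ndarray, apply_relu: bool = True) -> np.ndarray:
    """Importance-weighted sum of feature maps, rectified by default."""
    a = features.values if isinstance(features, FeatureMapStack) else np.asarray(features)
    w = np.asarray(weights, dtype=float)
    if a.ndim != 3 or w.ndim != 1 or a.shape[0] != w.size:
        raise ShapeError(f"channel mismatch: features {a.shape}, weights {w.shape}")
    out = np.tensordot(w, a, axes=(0, 0))
    return np.maximum(out, 0.0) if apply_relu else out


def upsample_normalize(coarse: np.ndarray, target: tuple[int, int], class_id: int = 0, source_frame: str = "") -> HeatMap:
    """Bilinear upsampling to ``target`` then min-max normalization to [0, 1].

    A constant coarse map carries no localization signal and maps to the
    all-zero heat map.
    """
    c = np.asarray(coarse, dtype=float)
    h, w = target
    if h < c.shape[0] or w < c.shape[1]:
        raise ShapeError(f"target {target} smaller than coarse map {c.shape}")
    up = _sk_resize(c, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        values = np.zeros((h, w))
    else:
        values = (up - lo) / (hi - lo)
    return HeatMap(values=values, class_id=class_id, source_frame=source_frame)


def grad_cam(model, image: np.ndarray, class_id: int, apply_relu: bool = True) -> HeatMap:
    """End-to-end heat map for one frame and one class.

    ``model`` is a trained :class:`~surgloc.classifier.ModelHandle`; the
    backward pass targets the pre-sigmoid logit of ``class_id``.
    """
    if not 0 <= class_id < model.n_classes:
        raise IndexError(f"class_id {class_id} out of range for K={model.n_classes}")
    x = model.preprocess(image)[None]
    logits = model.backbone.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_id] = 1.0
    grads = model.backbone.feature_gradients(dlogits)[0]
    feats = model.backbone.features[0]
    coarse = cam(feats, channel_weights(grads), apply_relu=apply_relu)
    return upsample_normalize(coarse, image.shape[:2], class_id=class_id)


def heatmap_to_uint8(heatmap: HeatMap | np.ndarray) -> np.ndarray:
    """round(255 * v) quantization used when handing off to Otsu thresholding."""
    v = heatmap.values if isinstance(heatmap, HeatMap) else np.asarray(heatmap)
    return np.round(255.0 * v).astype(np.uint8)


def save_heatmap_png(heatmap: HeatMap, path) -> None:
    Image.fromarray(heatmap_to_uint8(heatmap), mode="L").save(path)


def overlay_heatmap(frame: np.ndarray, heatmap: HeatMap, alpha: float = 0.4) -> np.ndarray:
    """False-color (jet) heat-map blend over the frame; warmer = more attention."""
    cmap = colormaps["jet"]
    colored = (cmap(heatmap.values)[..., :3] * 255.0).astype(float)
    blended = (1 - alpha) * frame.astype(float) + alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def save_overlay_png(frame: np.ndarray, heatmap: HeatMap, path, alpha: float = 0.4) -> None:
    Image.fromarray(overlay_heatmap(frame, heatmap, alpha)).save(path)
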