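"""Self-contained validation studies for the localization pipeline.

Two desk-scale studies exercise the method end to end on synthetic inputs:

* :func:`planted_blob_study` — bypasses the classifier entirely and feeds the
  heat-map post-processing chain constructed heat maps containing Gaussian
  blobs with known extents: 1-3 "tools" whose centers sit on a frame border
  (so the edge-touch filter should keep them) and 0-2 interior "distractors"
  (which the filter should reject).  Reports the fraction of planted blobs
  recovered at IoU >= 0.5 and the fraction of distractors producing no
  detection.

* :func:`end_to_end_study` — generates a synthetic dataset, trains the
  surrogate classifier on a video-level split, and scores both tool-presence
  classification (recall/F1/mAP) and weakly supervised localization (mean F1
  under both matching conventions) on the held-out videos.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from . import classifier as clf
from . import evaluation as ev
from .localization import LocalizationConfig, boxes_from_heatmap, iou
from .synthetic import SceneConfig, generate_dataset

# Blobs are steep-edged super-Gaussians exp(-(d/sigma)^6): their thresholded
# support is nearly independent of where the threshold lands between ~30% and
# ~70% of the peak, so each blob has a well-defined ground-truth extent.
_BLOB_EXPONENT = 6
_HALF_MAX = np.log(2.0) ** (1.0 / _BLOB_EXPONENT)  # half-maximum radius in sigmas


def _gaussian_blob(size: int, cx: float, cy: float, sigma: float, amp: float) -> np.ndarray:
    ys, xs = np.mgrid[0:size, 0:size]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    return amp * np.exp(-(np.sqrt(d2) / sigma) ** _BLOB_EXPONENT)


def _blob_box(size: int, cx: float, cy: float, sigma: float) -> tuple[int, int, int, int]:
    """Tight box of the blob's half-maximum support, clipped to the frame."""
    r = _HALF_MAX * sigma
    x0 = int(max(np.floor(cx - r), 0))
    y0 = int(max(np.floor(cy - r), 0))
    x1 = int(min(np.ceil(cx + r) + 1, size))
    y1 = int(min(np.ceil(cy + r) + 1, size))
    return x0, y0, x1, y1


def make_planted_heatmap(
    rng: np.random.Generator, size: int = 64
) -> tuple[np.ndarray, list[tuple[int, int, int, int]], list[tuple[int, int, int, int]]]:
    """One synthetic heat map with edge-anchored blobs and interior distractors.

    Returns (heat map in [0, 1], planted boxes, distractor boxes).
    """
    heat = np.zeros((size, size))
    planted: list[tuple[int, int, int, int]] = []
    centers_taken: list[tuple[int, int, int, int]] = []
    n_blobs = int(rng.integers(1, 4))
    for _ in range(n_blobs):
        sigma = float(rng.uniform(4.0, 7.0))
        edge = int(rng.integers(4))
        along = float(rng.uniform(0.2 * size, 0.8 * size))
        if edge == 0:
            cx, cy = along, 0.0
        elif edge == 1:
            cx, cy = along, float(size - 1)
        elif edge == 2:
            cx, cy = 0.0, along
        else:
            cx, cy = float(size - 1), along
        # keep planted blobs well apart so their thresholded supports stay separate
        box = _blob_box(size, cx, cy, sigma)
        pad = int(np.ceil(2.0 * sigma))
        padded = (box[0] - pad, box[1] - pad, box[2] + pad, box[3] + pad)
        if any(iou(padded, b) > 0.0 for b in centers_taken):
            continue
        heat += _gaussian_blob(size, cx, cy, sigma, float(rng.uniform(0.85, 1.0)))
        planted.append(box)
        centers_taken.append(padded)
    distractors: list[tuple[int, int, int, int]] = []
    for _ in range(int(rng.integers(0, 3))):
        sigma = float(rng.uniform(2.5, 4.0))
        margin = int(np.ceil(_HALF_MAX * sigma)) + 10
        cx = float(rng.uniform(margin, size - 1 - margin))
        cy = float(rng.uniform(margin, size - 1 - margin))
        box = _blob_box(size, cx, cy, sigma)
        pad = int(np.ceil(2.0 * sigma))
        padded = (box[0] - pad, box[1] - pad, box[2] + pad, box[3] + pad)
        if any(iou(padded, b) > 0.0 for b in centers_taken):
            continue
        heat += _gaussian_blob(size, cx, cy, sigma, float(rng.uniform(0.6, 0.9)))
        distractors.append(box)
        centers_taken.append(padded)
    return np.clip(heat, 0.0, 1.0), planted, distractors


def planted_blob_study(
    n_maps: int = 200,
    seed: int = 0,
    config: LocalizationConfig | None = None,
    size: int = 64,
) -> dict[str, float]:
    """Recovery/rejection rates of the heat-map -> box chain on planted blobs."""
    if config is None:
        config = LocalizationConfig()
    rng = np.random.default_rng(seed)
    n_planted = n_recovered = n_distract = n_rejected = 0
    for _ in range(n_maps):
        heat, planted, distractors = make_planted_heatmap(rng, size)
        detections = boxes_from_heatmap(heat, config)
        det_boxes = [d.box for d in detections]
        for box in planted:
            n_planted += 1
            if any(iou(box, db) >= 0.5 for db in det_boxes):
                n_recovered += 1
        for box in distractors:
            n_distract += 1
            if not any(iou(box, db) >= 0.5 for db in det_boxes):
                n_rejected += 1
    return {
        "n_maps": n_maps,
        "n_planted": n_planted,
        "n_distractors": n_distract,
        "recovery_rate": n_recovered / n_planted if n_planted else float("nan"),
        "rejection_rate": n_rejected / n_distract if n_distract else float("nan"),
    }


def end_to_end_study(
    n_frames: int = 500,
    n_videos: int = 8,
    scene_seed: int = 123,
    train_seed: int = 0,
    split_seed: int = 1,
    workdir: str | Path | None = None,
    localization_config: LocalizationConfig | None = None,
) -> dict:
    """Simulate -> train surrogate (8 epochs) -> evaluate on held-out videos.

    Uses the default scene distribution (Cholec80-proportional prevalences)
    and a 50/50 video-level split.  Returns classification and localization
    summaries on the test side, as fractions in [0, 1].
    """
    from .localization import localize

    if localization_config is None:
        localization_config = LocalizationConfig()
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = tmp.name
    workdir = Path(workdir)
    try:
        scene = SceneConfig(seed=scene_seed)
        manifest = generate_dataset(scene, n_frames, n_videos, workdir)
        plan = ev.make_splits(manifest.video_ids(), "fixed_fraction", 0.5, seed=split_seed)
        train_videos, test_videos = plan.folds[0]
        config = clf.surrogate_train_config(seed=train_seed)
        model = clf.train(
            "surrogate_small", manifest, train_videos, config, workdir, zero_count_policy="unit"
        )
        test_records = [r for r in manifest.records if r.video_id in set(test_videos)]
        frames = [
            np.asarray(Image.open(workdir / r.frame_path).convert("RGB")) for r in test_records
        ]
        probs = model.predict_batch(np.stack([model.preprocess(f) for f in frames]))
        labels = np.array([r.labels for r in test_records])
        cls_report = ev.classification_report(
            probs, labels, scene.class_names, threshold=0.5, skip_undefined_ap=True
        )
        pairs = [
            (localize(model, frame, localization_config), r.boxes)
            for frame, r in zip(frames, test_records)
        ]
        loc_reports = {
            mode: ev.localization_report(pairs, scene.class_names, mode=mode)
            for mode in ("paper", "standard")
        }
        return {
            "n_frames": n_frames,
            "n_train_videos": len(train_videos),
            "n_test_frames": len(test_records),
            "final_train_loss": model.loss_history[-1],
            "classification": {
                "mean_recall": cls_report.mean_recall / 100.0,
                "mean_f1": cls_report.mean_f1 / 100.0,
                "mAP": cls_report.mean_ap / 100.0 if cls_report.mean_ap is not None else None,
                "per_class_ap": {
                    k: v["ap"] / 100.0 for k, v in cls_report.per_class.items() if "ap" in v
                },
            },
            "localization": {
                mode: {
                    "mean_f1": rep.localization_mean_f1 / 100.0
                    if rep.localization_mean_f1 is not None
                    else None,
                    "per_class_f1": {k: v / 100.0 for k, v in rep.localization_per_class.items()},
                }
                for mode, rep in loc_reports.items()
            },
        }
    finally:
        if tmp is not None:
            tmp.cleanup()
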