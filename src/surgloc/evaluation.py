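"""Classification and localization evaluation, plus video-level data splits.

Classification metrics per class: recall and F1 at a fixed probability
threshold (default 0.5) and non-interpolated average precision

    AP = sum_k Precision(k) * DeltaRecall(k)

over the descending score ranking, with mAP the unweighted class mean.

Localization is scored by F1 over accumulated per-class confusion counts.
Two detection-matching conventions are provided:

* mode "paper": a detection is a true positive iff its presence confidence
  exceeds the confidence threshold AND it matches a ground-truth box with
  IoU above the IoU threshold.  Every other detection — low confidence, or
  confident but poorly localized — counts as a false negative, as do
  unmatched ground-truth boxes.  Under this convention no detection is ever
  a false positive (the false-negative clauses cover all failure cases), so
  precision is 1 whenever any true positive exists.
* mode "standard": the COCO-style convention — low-confidence detections are
  ignored, confident unmatched detections are false positives, unmatched
  truths are false negatives.

Matching is greedy and one-to-one per class: detections in descending
confidence order each claim the best-IoU still-unmatched truth.

Splits are always video-level: all frames of one video land on the same side
of every train/test division, both for k-fold cross-validation and for the
fixed-fraction (e.g. 40/40) split.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError, UndefinedAPError
from .localization import Detection, iou
from .synthetic import GroundTruthBox

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        tn = None if self.tn is None or other.tn is None else self.tn + other.tn
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, tn)


@dataclass
class EvalReport:
    """Per-class and mean metrics, all as percentages in [0, 100]."""

    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_recall: float | None = None
    mean_f1: float | None = None
    mean_ap: float | None = None
    localization_per_class: dict[str, float] = field(default_factory=dict)
    localization_mean_f1: float | None = None

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "means": {"recall": self.mean_recall, "f1": self.mean_f1, "mAP": self.mean_ap},
            "localization_per_class": self.localization_per_class,
            "localization_mean_f1": self.localization_mean_f1,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_csv(self, path: str | Path) -> None:
        """Rows = tools, columns = metrics (classification table layout)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tool", "recall_pct", "f1_pct", "ap_pct", "localization_f1_pct"])
            tools = list(self.per_class) or list(self.localization_per_class)
            for tool in tools:
                m = self.per_class.get(tool, {})
                writer.writerow(
                    [
                        tool,
                        _fmt(m.get("recall")),
                        _fmt(m.get("f1")),
                        _fmt(m.get("ap")),
                        _fmt(self.localization_per_class.get(tool)),
                    ]
                )
            writer.writerow(
                ["mean", _fmt(self.mean_recall), _fmt(self.mean_f1), _fmt(self.mean_ap), _fmt(self.localization_mean_f1)]
            )


def _fmt(v: float | None) -> str:
    return "" if v is None else f"{v:.2f}"


# -- scalar metrics ----------------------------------------------------------


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall); a zero denominator yields 0 for that component."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Non-interpolated AP over the descending-score ranking (ties: input order)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise DataError(f"scores {s.shape} and labels {y.shape} must be equal-length vectors")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedAPError("no positive labels: AP undefined")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    ranks = np.arange(1, y.size + 1)
    precision_at_k = cum_tp / ranks
    # recall increments by 1/n_pos exactly at positive ranks
    return float(np.sum(precision_at_k[y_sorted == 1]) / n_pos)


def mean_ap(per_class_ap: Sequence[float]) -> float:
    ap = np.asarray(per_class_ap, dtype=float)
    if ap.size == 0:
        raise DataError("mean AP over zero classes is undefined")
    return float(ap.mean())


# -- classification report ---------------------------------------------------


def classification_report(
    probabilities: np.ndarray,
    labels: np.ndarray,
    class_names: Sequence[str],
    threshold: float = 0.5,
    skip_undefined_ap: bool = False,
) -> EvalReport:
    """Per-class recall/F1 at ``threshold`` plus ranking AP, and their means.

    Classes without positive test labels have undefined AP; by default this
    propagates as :class:`UndefinedAPError`, or with ``skip_undefined_ap``
    the class is dropped from the AP mean (logged) while keeping recall/F1.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape or p.ndim != 2 or p.shape[1] != len(class_names):
        raise DataError(f"misaligned predictions {p.shape} / labels {y.shape} / {len(class_names)} classes")
    report = EvalReport()
    recalls, f1s, aps = [], [], []
    for k, name in enumerate(class_names):
        pred = p[:, k] > threshold
        counts = ConfusionCounts(
            tp=int(np.sum(pred & (y[:, k] == 1))),
            fp=int(np.sum(pred & (y[:, k] == 0))),
            fn=int(np.sum(~pred & (y[:, k] == 1))),
        )
        prec, rec = precision_recall(counts)
        f1 = f1_score(prec, rec)
        entry = {"recall": 100.0 * rec, "f1": 100.0 * f1}
        try:
            ap = average_precision(p[:, k], y[:, k])
            entry["ap"] = 100.0 * ap
            aps.append(100.0 * ap)
        except UndefinedAPError:
            if not skip_undefined_ap:
                raise
            logger.warning("class %r has no positive labels; omitted from mAP", name)
        recalls.append(entry["recall"])
        f1s.append(entry["f1"])
        report.per_class[name] = entry
    report.mean_recall = float(np.mean(recalls))
    report.mean_f1 = float(np.mean(f1s))
    report.mean_ap = float(np.mean(aps)) if aps else None
    return report


# -- detection matching ------------------------------------------------------


def match_detections(
    detections: Sequence[Detection],
    truths: Sequence[GroundTruthBox],
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.5,
    mode: str = "paper",
) -> dict[int, ConfusionCounts]:
    """Confusion counts per class for ONE frame (see module docstring for modes)."""
    if not 0.0 < conf_threshold < 1.0 or not 0.0 < iou_threshold < 1.0:
        raise ConfigurationError("thresholds must lie in (0, 1)")
    if mode not in ("paper", "standard"):
        raise ConfigurationError(f"unknown matching mode {mode!r}")
    counts: dict[int, ConfusionCounts] = {}
    class_ids = {d.class_id for d in detections} | {t.class_id for t in truths}
    for cid in class_ids:
        dets = [d for d in detections if d.class_id == cid]
        gts = [t for t in truths if t.class_id == cid]
        c = ConfusionCounts()
        confident = sorted(
            (d for d in dets if d.confidence > conf_threshold),
            key=lambda d: (-d.confidence, -d.area),
        )
        low_conf = [d for d in dets if d.confidence <= conf_threshold]
        unmatched_truths = list(range(len(gts)))
        for d in confident:
            best_j, best_iou = None, iou_threshold
            for j in unmatched_truths:
                v = iou(d.box, gts[j].box)
                if v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None:
                unmatched_truths.remove(best_j)
                c.tp += 1
            else:
                if mode == "paper":
                    c.fn += 1  # confident but poorly localized
                else:
                    c.fp += 1
        if mode == "paper":
            c.fn += len(low_conf)  # below the presence-confidence bar
        c.fn += len(unmatched_truths)  # missed objects
        counts[cid] = c
    return counts


def match_dataset(
    frames: Sequence[tuple[Sequence[Detection], Sequence[GroundTruthBox]]],
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.5,
    mode: str = "paper",
) -> dict[int, ConfusionCounts]:
    """Accumulate :func:`match_detections` counts over many frames."""
    total: dict[int, ConfusionCounts] = {}
    for detections, truths in frames:
        for cid, c in match_detections(detections, truths, conf_threshold, iou_threshold, mode).items():
            total[cid] = total.get(cid, ConfusionCounts()) + c
    return total


def localization_report(
    frames: Sequence[tuple[Sequence[Detection], Sequence[GroundTruthBox]]],
    class_names: Sequence[str],
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.5,
    mode: str = "paper",
) -> EvalReport:
    """Per-class localization F1 (percent) and the unweighted class mean.

    Classes with neither ground-truth boxes nor detections anywhere in the
    frame set are omitted from the report (logged).
    """
    counts = match_dataset(frames, conf_threshold, iou_threshold, mode)
    report = EvalReport()
    f1s = []
    for cid, name in enumerate(class_names):
        if cid not in counts:
            logger.info("class %r: no truths and no detections; omitted", name)
            continue
        prec, rec = precision_recall(counts[cid])
        f1 = 100.0 * f1_score(prec, rec)
        report.localization_per_class[name] = f1
        f1s.append(f1)
    report.localization_mean_f1 = float(np.mean(f1s)) if f1s else None
    return report


# -- video-level splits ------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train ids, test ids)
    scheme: str
    seed: int

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scheme": self.scheme,
                    "seed": self.seed,
                    "folds": [{"train": list(tr), "test": list(te)} for tr, te in self.folds],
                },
                indent=2,
            )
        )


def make_splits(
    video_ids: Sequence[int], scheme: str, k_or_fraction: float, seed: int = 0
) -> SplitPlan:
    """Group-aware split of whole videos into train/test sides.

    ``scheme="kfold"``: ``k_or_fraction`` is the integer fold count; test sets
    are disjoint, jointly cover all videos, and differ in size by at most 1.
    ``scheme="fixed_fraction"``: one shuffled split with the given train
    fraction (0.5 reproduces a 40/40 split of 80 videos).
    """
    ids = list(video_ids)
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate video ids")
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 videos to split")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    if scheme == "kfold":
        k = int(k_or_fraction)
        if k < 2 or k > len(ids):
            raise ConfigurationError(f"k={k} invalid for {len(ids)} videos")
        test_sets = np.array_split(np.array(shuffled), k)
        folds = tuple(
            (tuple(sorted(set(ids) - set(te.tolist()))), tuple(sorted(te.tolist())))
            for te in test_sets
        )
    elif scheme == "fixed_fraction":
        frac = float(k_or_fraction)
        if not 0.0 < frac < 1.0:
            raise ConfigurationError("train fraction must lie in (0, 1)")
        n_train = int(round(frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        folds = (
            (tuple(sorted(shuffled[:n_train])), tuple(sorted(shuffled[n_train:]))),
        )
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    return SplitPlan(folds=folds, scheme=scheme, seed=seed)
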