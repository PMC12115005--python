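"""Class-weight-balanced multi-label tool-presence classification.

A frame may contain several tools at once, so presence is modelled as K
independent binary outcomes and trained with binary cross-entropy on logits.
Tool usage is heavily imbalanced (hook and grasper dominate; scissors is
rare), which biases an unweighted loss toward the common classes.  Each
class k therefore receives the balancing weight

    CW_k = N / (K * n_k)

where N is the number of training images, K the number of classes, and n_k
the number of training images containing class k — computed on the training
split only, so no information about test prevalence leaks into the loss.
The per-sample training loss is

    L = sum_k CW_k * BCEWithLogits(y_k, z_k)

averaged over the batch.  Optimization is Adam with linear learning-rate
warmup from 0 over a configured number of steps, then a constant rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize

from .errors import ConfigurationError, DataError, DegenerateClassError, ShapeError
from .nn.backbone import build_backbone
from .synthetic import DatasetManifest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassWeightVector:
    """Balancing weights CW_k = N / (K * n_k) together with their inputs."""

    weights: np.ndarray
    n_train_images: int
    class_counts: np.ndarray
    n_classes: int


@dataclass(frozen=True)
class Prediction:
    """Per-class logits and their sigmoid probabilities for one frame."""

    logits: np.ndarray
    probabilities: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule.

    Defaults are the fine-tuning recipe for a large pretrained backbone
    (lr 5e-5, batch 32, 1000 warmup steps, 8 epochs, Adam betas 0.9/0.999).
    For the from-scratch surrogate use :func:`surrogate_train_config`, which
    keeps the epoch count but raises the learning rate and shrinks the batch.
    """

    learning_rate: float = 5e-5
    batch_size: int = 32
    warmup_steps: int = 1000
    epochs: int = 8
    optimizer_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    use_class_weights: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ConfigurationError("learning_rate, batch_size and epochs must be positive")
        if self.warmup_steps < 0:
            raise ConfigurationError("warmup_steps must be >= 0")


def surrogate_train_config(**overrides) -> TrainConfig:
    """Training recipe suited to the small from-scratch surrogate backbone.

    A few hundred optimizer steps at 5e-5 cannot move a randomly initialized
    network, so the rate is raised to 5e-3 with a short warmup, and the batch
    is shrunk to 8 so that 8 epochs on a few hundred frames still provide
    enough optimizer steps to converge.
    """
    base = dict(learning_rate=5e-3, warmup_steps=20, batch_size=8)
    base.update(overrides)
    return TrainConfig(**base)


def compute_class_weights(class_counts: Sequence[int], n_train_images: int) -> ClassWeightVector:
    """CW_k = N / (K * n_k); every class must occur at least once."""
    counts = np.asarray(class_counts, dtype=float)
    if n_train_images <= 0:
        raise DegenerateClassError("n_train_images must be positive")
    bad = np.flatnonzero(counts <= 0)
    if bad.size:
        raise DegenerateClassError(
            f"class(es) {bad.tolist()} have no training samples; balancing weight undefined"
        )
    k = counts.size
    weights = n_train_images / (k * counts)
    return ClassWeightVector(
        weights=weights,
        n_train_images=int(n_train_images),
        class_counts=counts.astype(int),
        n_classes=int(k),
    )


def weighted_bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | ClassWeightVector | None = None
) -> float:
    """Sum over classes of w_k * BCEWithLogits(y_k, z_k), numerically stable.

    Uses the log-sum-exp form ``max(z,0) - z*y + log(1 + exp(-|z|))`` so the
    result is finite for any finite logits.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    if isinstance(weights, ClassWeightVector):
        w = weights.weights
    elif weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=float)
    if z.shape != y.shape or z.shape != w.shape:
        raise ShapeError(f"length mismatch: logits {z.shape}, targets {y.shape}, weights {w.shape}")
    per_class = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(np.sum(w * per_class))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ModelHandle:
    """A trained classifier: backbone plus the metadata needed to reuse it."""

    backbone: object
    backbone_spec: str
    class_names: tuple[str, ...]
    input_size: int
    train_config: TrainConfig
    class_weights: ClassWeightVector | None
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """uint8 H x W x 3 -> float32 (3, S, S) in [0, 1], bilinear resize if needed."""
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise DataError(f"expected H x W x 3 RGB image, got shape {img.shape}")
        if img.shape[:2] != (self.input_size, self.input_size):
            img = resize(img, (self.input_size, self.input_size), order=1, preserve_range=True, anti_aliasing=False)
        return (img.astype(np.float32) / 255.0).transpose(2, 0, 1)

    def predict(self, image: np.ndarray) -> Prediction:
        x = self.preprocess(image)[None]
        logits = self.backbone.forward(x)[0].astype(float)
        return Prediction(logits=logits, probabilities=sigmoid(logits))

    def predict_batch(self, images: np.ndarray, chunk: int = 32) -> np.ndarray:
        """(N, 3, S, S) preprocessed batch -> (N, K) probabilities.

        Evaluated in chunks to bound the convolution workspace memory.
        """
        parts = [
            sigmoid(self.backbone.forward(images[i : i + chunk]).astype(float))
            for i in range(0, images.shape[0], chunk)
        ]
        return np.concatenate(parts, axis=0)

    # -- persistence: npz checkpoint + JSON sidecar --------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.backbone.params)
        sidecar = {
            "backbone_spec": self.backbone_spec,
            "class_names": list(self.class_names),
            "input_size": self.input_size,
            "train_config": {
                "learning_rate": self.train_config.learning_rate,
                "batch_size": self.train_config.batch_size,
                "warmup_steps": self.train_config.warmup_steps,
                "epochs": self.train_config.epochs,
                "optimizer_betas": list(self.train_config.optimizer_betas),
                "seed": self.train_config.seed,
                "use_class_weights": self.train_config.use_class_weights,
            },
            "class_weights": None
            if self.class_weights is None
            else {
                "weights": self.class_weights.weights.tolist(),
                "n_train_images": self.class_weights.n_train_images,
                "class_counts": self.class_weights.class_counts.tolist(),
                "n_classes": self.class_weights.n_classes,
            },
            "loss_history": self.loss_history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        tc = meta["train_config"]
        config = TrainConfig(
            learning_rate=tc["learning_rate"],
            batch_size=tc["batch_size"],
            warmup_steps=tc["warmup_steps"],
            epochs=tc["epochs"],
            optimizer_betas=tuple(tc["optimizer_betas"]),
            seed=tc["seed"],
            use_class_weights=tc["use_class_weights"],
        )
        backbone = build_backbone(
            meta["backbone_spec"], len(meta["class_names"]), meta["input_size"], seed=config.seed
        )
        with np.load(path.with_suffix(".npz")) as data:
            backbone.load_params({k: data[k] for k in data.files})
        cw = meta["class_weights"]
        weights = (
            None
            if cw is None
            else ClassWeightVector(
                weights=np.array(cw["weights"]),
                n_train_images=cw["n_train_images"],
                class_counts=np.array(cw["class_counts"]),
                n_classes=cw["n_classes"],
            )
        )
        return cls(
            backbone=backbone,
            backbone_spec=meta["backbone_spec"],
            class_names=tuple(meta["class_names"]),
            input_size=meta["input_size"],
            train_config=config,
            class_weights=weights,
            loss_history=list(meta.get("loss_history", [])),
        )


def _load_split(
    manifest: DatasetManifest, split: Sequence[int], data_dir: str | Path, input_size: int
) -> tuple[np.ndarray, np.ndarray]:
    data = Path(data_dir)
    keep = [r for r in manifest.records if r.video_id in set(split)]
    if not keep:
        raise DataError(f"no frames for video ids {list(split)}")
    images = np.empty((len(keep), 3, input_size, input_size), dtype=np.float32)
    labels = np.empty((len(keep), manifest.config.n_classes), dtype=np.float32)
    for i, r in enumerate(keep):
        img = np.asarray(Image.open(data / r.frame_path).convert("RGB"))
        if img.shape[:2] != (input_size, input_size):
            img = resize(img, (input_size, input_size), order=1, preserve_range=True, anti_aliasing=False)
        images[i] = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)
        labels[i] = r.labels
    return images, labels


def train(
    backbone_spec: str,
    dataset: DatasetManifest,
    split: Sequence[int],
    config: TrainConfig,
    data_dir: str | Path,
    input_size: int | None = None,
    zero_count_policy: str = "error",
) -> ModelHandle:
    """Train a registered backbone on the frames of the given videos.

    ``zero_count_policy`` governs classes absent from the training split when
    class weighting is on: "error" (default) raises, "unit" assigns weight 1
    to the empty class and logs it (there is no imbalance information to use).
    Deterministic given ``config.seed`` on the surrogate backbone.
    """
    if input_size is None:
        input_size = dataset.config.image_size[0]
    backbone = build_backbone(backbone_spec, dataset.config.n_classes, input_size, seed=config.seed)
    images, labels = _load_split(dataset, split, data_dir, input_size)
    n = images.shape[0]

    weights_vec: ClassWeightVector | None = None
    if config.use_class_weights:
        counts = labels.sum(axis=0).astype(int)
        if (counts <= 0).any() and zero_count_policy == "unit":
            empty = np.flatnonzero(counts <= 0)
            logger.warning("classes %s absent from training split; using unit weight", empty.tolist())
            safe = compute_class_weights(np.maximum(counts, 1), n)
            w = safe.weights.copy()
            w[empty] = 1.0
            weights_vec = ClassWeightVector(w, n, counts, counts.size)
        else:
            weights_vec = compute_class_weights(counts, n)
        w_arr = weights_vec.weights.astype(np.float32)
    else:
        w_arr = np.ones(dataset.config.n_classes, dtype=np.float32)

    # prior-initialized output biases: start each logit at the log-odds of its
    # training prevalence so early steps are not spent learning base rates
    prev = np.clip(labels.mean(axis=0), 1e-3, 1 - 1e-3)
    backbone.head.b[:] = np.log(prev / (1 - prev)).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    optimizer = backbone.make_optimizer(config.optimizer_betas)
    history: list[float] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            x, y = images[batch], labels[batch]
            logits = backbone.forward(x)
            # mean over the batch of the per-sample class-weighted BCE sum
            z = logits.astype(np.float64)
            per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
            loss = float(np.mean(np.sum(w_arr * per, axis=1)))
            dlogits = (w_arr * (sigmoid(z) - y) / len(batch)).astype(np.float32)
            grads = backbone.backward(dlogits)
            step += 1
            warm = min(1.0, step / config.warmup_steps) if config.warmup_steps else 1.0
            optimizer.step(grads, config.learning_rate * warm)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.info("epoch %d/%d: mean training loss %.6f", epoch + 1, config.epochs, history[-1])

    return ModelHandle(
        backbone=backbone,
        backbone_spec=backbone_spec,
        class_names=tuple(dataset.config.class_names),
        input_size=input_size,
        train_config=config,
        class_weights=weights_vec,
        loss_history=history,
    )


def predict(model: ModelHandle, image: np.ndarray) -> Prediction:
    """Module-level convenience wrapper around :meth:`ModelHandle.predict`."""
    return model.predict(image)
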