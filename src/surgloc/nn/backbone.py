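"""Surrogate classification backbones with an exposed spatial feature layer.

The localization pipeline only requires a differentiable multi-label
classifier whose last layer before the classification head is spatially
indexed (so that class-score gradients with respect to that layer define a
class activation map).  ``SurrogateSmallCNN`` provides exactly that at desk
scale: conv-relu-pool -> conv-relu (the designated feature layer) -> global
max pooling -> linear logits, ~5k parameters, trained from scratch in
seconds on synthetic scenes.

Global max pooling is the presence head: a tool is present iff at least one
location responds, so the class logit should not scale with object area the
way average pooling makes it.  The class-activation map is unaffected in
form — gradients of a logit w.r.t. the feature layer are spatially averaged
into channel weights either way.

Additional backbones (e.g. an adapter around a pretrained transformer whose
patch-token grid plays the role of the feature layer) can be registered via
:func:`register_backbone`; only the surrogate ships with the package.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..errors import ConfigurationError
from .layers import Adam, Conv2d, GlobalMaxPool, Linear, MaxPool2, ReLU

FEATURE_LAYER_NAME = "conv2_relu"


class SurrogateSmallCNN:
    """Tiny CNN multi-label classifier with gradient access to its feature layer."""

    def __init__(self, n_classes: int, input_size: int = 64, channels: tuple[int, int] = (16, 32), seed: int = 0):
        if input_size % 2:
            raise ConfigurationError("input_size must be even (one 2x2 pooling stage)")
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.input_size = input_size
        self.channels = channels
        self.conv1 = Conv2d(3, channels[0], rng)
        self.relu1 = ReLU()
        self.pool = MaxPool2()
        self.conv2 = Conv2d(channels[0], channels[1], rng)
        self.relu2 = ReLU()
        self.presence_pool = GlobalMaxPool()
        self.head = Linear(channels[1], n_classes, rng)
        self._features: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float32 in [0, 1] -> logits (N, K)."""
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.pool.forward(h)
        self._features = self.relu2.forward(self.conv2.forward(h))
        return self.head.forward(self.presence_pool.forward(self._features))

    @property
    def features(self) -> np.ndarray:
        """Activations of the designated feature layer from the last forward pass."""
        if self._features is None:
            raise RuntimeError("run forward() first")
        return self._features

    def feature_gradients(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar in logit space w.r.t. the feature layer, (N, C', H', W')."""
        return self.presence_pool.backward(self.head.backward(dlogits))

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Full backward pass; returns parameter gradients."""
        d = self.feature_gradients(dlogits)
        d = self.conv2.backward(self.relu2.backward(d))
        d = self.pool.backward(d)
        self.conv1.backward(self.relu1.backward(d))
        return self.grads

    # -- parameter plumbing --------------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2), ("head", self.head)):
            for k, v in layer.params.items():
                out[f"{name}.{k}"] = v
        return out

    @property
    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2), ("head", self.head)):
            for k, v in layer.grads.items():
                out[f"{name}.{k}"] = v
        return out

    def load_params(self, values: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            np.copyto(v, values[k])

    def make_optimizer(self, betas: tuple[float, float]) -> Adam:
        return Adam(self.params, betas=betas)


BackboneFactory = Callable[..., SurrogateSmallCNN]

_REGISTRY: dict[str, BackboneFactory] = {}


def register_backbone(name: str, factory: BackboneFactory) -> None:
    _REGISTRY[name] = factory


def build_backbone(spec: str, n_classes: int, input_size: int, seed: int):
    if spec not in _REGISTRY:
        raise ConfigurationError(
            f"unknown backbone {spec!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[spec](n_classes=n_classes, input_size=input_size, seed=seed)


register_backbone("surrogate_small", SurrogateSmallCNN)
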