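"""Conventional residual-network baseline: stage-5 features + softmax head.

This is the unmodified five-stage extractor (no fine/coarse skip
concatenation) followed by the conventional classifier: global average
pooling of the stage-5 map, one fully connected layer, softmax over the two
classes.  Training minimises cross-entropy with Adam over mini-batches.

The backbone is frozen during training (transfer-learning style: the
extractor provides fixed features, only the head's fully connected weights
are learned), so the gradient is exact and hand-computable — softmax
cross-entropy over a linear layer.  Pooled features are standardised on the
training set before the head sees them.

``TrainConfig.learning_rate`` defaults to 1e-5, the rate used when adapting
a pretrained backbone; when the head is trained from scratch on frozen
random-init features (the offline test path) Adam's conventional 1e-3 is the
appropriate choice — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneSpec, FeatureExtractor, build_backbone
from .errors import ParameterError, StateError, TrainingError
from .synthetic import ImageSample

__all__ = ["TrainConfig", "ConventionalModel", "train_conventional",
           "predict_proba", "softmax"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for the softmax head."""

    learning_rate: float = 1e-5
    optimizer: str = "adam"
    loss: str = "cross-entropy"
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ParameterError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross-entropy":
            raise ParameterError(f"unsupported loss {self.loss!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _pool_stage5(extractor: FeatureExtractor, image: ImageSample | np.ndarray
                 ) -> np.ndarray:
    fm = extractor.extract(image)
    return fm.stage5.mean(axis=(0, 1))


@dataclass
class ConventionalModel:
    """Frozen extractor + trained 2-class softmax head."""

    extractor: FeatureExtractor
    W: np.ndarray | None = None          # (d, 2)
    b: np.ndarray | None = None          # (2,)
    feat_mean: np.ndarray | None = None
    feat_scale: np.ndarray | None = None
    config: TrainConfig | None = None
    loss_trace: list[float] = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return self.W is not None

    def features(self, image: ImageSample | np.ndarray) -> np.ndarray:
        f = _pool_stage5(self.extractor, image)
        if self.feat_mean is not None:
            f = (f - self.feat_mean) / self.feat_scale
        return f

    def logits(self, image: ImageSample | np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("conventional model head is not trained")
        return self.features(image) @ self.W + self.b


def _adam_update(param, grad, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad * grad
    mhat = m / (1 - beta1 ** t)
    vhat = v / (1 - beta2 ** t)
    param -= lr * mhat / (np.sqrt(vhat) + eps)


def train_conventional(dataset: list[ImageSample], spec: BackboneSpec,
                       cfg: TrainConfig | None = None,
                       extractor: FeatureExtractor | None = None
                       ) -> ConventionalModel:
    """Train the softmax head on frozen stage-5 pooled features.

    The extractor is built (seeded from ``cfg.seed``) unless one is supplied;
    mini-batch order reshuffles every epoch from the same seeded generator,
    so a fixed config gives identical loss traces and weights.
    """
    cfg = cfg or TrainConfig()
    labels = np.array([s.y for s in dataset])
    if len(dataset) < 2 or len(np.unique(labels)) < 2:
        raise TrainingError("training requires both classes present")
    ext = extractor or build_backbone(spec, init="random", seed=cfg.seed)
    feats = np.stack([_pool_stage5(ext, s) for s in dataset])
    mean = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    X = (feats - mean) / scale
    n, d = X.shape
    Y = np.zeros((n, 2))
    Y[np.arange(n), labels] = 1.0

    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((d, 2))
    b = np.zeros(2)
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros_like(b), np.zeros_like(b)
    t = 0
    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            P = softmax(X[idx] @ W + b)
            G = (P - Y[idx]) / len(idx)
            t += 1
            _adam_update(W, X[idx].T @ G, mW, vW, t, cfg.learning_rate)
            _adam_update(b, G.sum(axis=0), mb, vb, t, cfg.learning_rate)
        P = softmax(X @ W + b)
        trace.append(float(-np.mean(np.log(P[np.arange(n), labels] + 1e-12))))
    return ConventionalModel(extractor=ext, W=W, b=b, feat_mean=mean,
                             feat_scale=scale, config=cfg, loss_trace=trace)


def predict_proba(model: ConventionalModel,
                  image: ImageSample | np.ndarray) -> float:
    """P(Positive | image) from the softmax head (index 1 = Positive)."""
    if not isinstance(model, ConventionalModel) or not model.trained:
        raise StateError("predict_proba requires a trained ConventionalModel")
    return float(softmax(model.logits(image))[1])
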