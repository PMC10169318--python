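"""ANN stacking combiner: two base-model scores in, final prediction out.

The combiner is a fixed-topology feed-forward network — exactly two input
neurons (the improved-model score and the conventional-model score), one
hidden layer (default width 4, sigmoid), and a single sigmoid output neuron
representing the ground-truth label.  It is trained by full-batch gradient
descent on cross-entropy from the two base models' scores on a dedicated
stacking cohort, never on the validation cohort.

The base-model inputs are continuous scores in (0, 1) rather than hard
labels, so the network can learn a genuinely nonlinear consensus (e.g.
trusting one model only where the other is uncertain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

from .conventional import ConventionalModel, predict_proba
from .errors import ParameterError, StateError, TrainingError, ValidationError
from .synthetic import ImageSample

__all__ = ["Combiner", "StackedModel", "fit_combiner", "combine_predict"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


@dataclass
class Combiner:
    """2 -> hidden -> 1 sigmoid network."""

    W1: np.ndarray  # (2, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    loss_trace: list[float] = field(default_factory=list)

    @property
    def hidden_width(self) -> int:
        return self.W1.shape[1]

    def forward(self, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
        """Final score in [0, 1] for paired base-model scores."""
        X = np.column_stack([np.atleast_1d(s1), np.atleast_1d(s2)])
        H = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)


@dataclass
class StackedModel:
    """The two base models plus the trained combiner.

    ``improved_scorer`` maps an image to the improved-model score in (0, 1);
    it closes over the feature extractor and the fitted SVM.
    """

    improved_scorer: Callable[[ImageSample], float]
    conventional_model: ConventionalModel
    combiner: Combiner


def fit_combiner(scores_improved: np.ndarray, scores_conventional: np.ndarray,
                 labels: np.ndarray, seed: int = 0, hidden: int = 4,
                 learning_rate: float = 1.0, epochs: int = 500,
                 plateau_tol: float = 1e-10) -> Combiner:
    """Train the stacking network on paired base-model scores.

    Full-batch gradient descent on mean cross-entropy; stops early when the
    loss improvement over an epoch falls below ``plateau_tol``.  Seeded
    weight initialisation makes retraining bit-reproducible.
    """
    s1 = np.asarray(scores_improved, dtype=np.float64).ravel()
    s2 = np.asarray(scores_conventional, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if not (len(s1) == len(s2) == len(y)):
        raise ValidationError("scores and labels must have equal lengths")
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValidationError("scores contain non-finite values")
    if len(np.unique(y)) < 2:
        raise TrainingError("combiner training requires both classes present")
    if hidden < 1:
        raise ParameterError("hidden width must be >= 1")

    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0, size=(2, hidden))
    b1 = np.zeros(hidden)
    W2 = rng.normal(0.0, 1.0, size=hidden)
    b2 = 0.0
    X = np.column_stack([s1, s2])
    n = len(y)
    trace: list[float] = []
    for _ in range(epochs):
        H = _sigmoid(X @ W1 + b1)
        p = _sigmoid(H @ W2 + b2)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        # Backprop: d(loss)/d(logit) = (p - y) / n for sigmoid + CE.
        dz2 = (p - y) / n
        gW2 = H.T @ dz2
        gb2 = dz2.sum()
        dH = np.outer(dz2, W2) * H * (1 - H)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        W2 -= learning_rate * gW2
        b2 -= learning_rate * gb2
        W1 -= learning_rate * gW1
        b1 -= learning_rate * gb1
        if trace and trace[-1] - loss < plateau_tol:
            trace.append(loss)
            break
        trace.append(loss)
    return Combiner(W1=W1, b1=b1, W2=W2, b2=b2, loss_trace=trace)


def combine_predict(model: StackedModel,
                    image: ImageSample | np.ndarray) -> tuple[float, int]:
    """Run both base models on the image and combine their scores.

    Returns ``(final_score, hard_label)`` with the hard label 1 (Positive)
    when score >= 0.5.
    """
    if model.combiner is None or model.improved_scorer is None:
        raise StateError("stacked model has untrained components")
    if not model.conventional_model.trained:
        raise StateError("conventional base model is not trained")
    s1 = float(model.improved_scorer(image))
    s2 = predict_proba(model.conventional_model, image)
    score = float(model.combiner.forward(s1, s2)[0])
    return score, int(score >= 0.5)
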