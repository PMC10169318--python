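"""SVM classifier on concatenated fine/coarse backbone features.

The classifier solves the soft-margin dual

    max_a  W(a) = sum_i a_i - 1/2 sum_{i,j} a_i a_j y_i y_j K(x_i, x_j)
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C

and predicts with the kernel expansion  f(x) = sum_i a_i y_i K(x_i, x) + b.
Optimisation is delegated to scikit-learn's SMO solver; the fitted model is
re-expressed here in the dual quantities (support vectors, multipliers a_i,
bias b) and the decision function is evaluated by this module's own kernel
expansion, so the dual constraints and the objective value are directly
inspectable.

Features are standardised per dimension on the training cohort (the raw
concatenated activations span wildly different scales).  For use as an input
to the stacking combiner, the signed decision value is squashed through a
logistic link to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit
from sklearn.svm import SVC

from .errors import StateError, TrainingError, ValidationError

__all__ = ["SVMModel", "fit_svm", "svm_decision", "svm_score", "dual_objective",
           "kernel_matrix"]

KernelName = Literal["rbf", "linear", "poly"]


def kernel_matrix(a: np.ndarray, b: np.ndarray, kernel: str,
                  gamma: float = 1.0, degree: int = 3,
                  coef0: float = 0.0) -> np.ndarray:
    """K(a_i, b_j) for the supported kernel families."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if kernel == "linear":
        return a @ b.T
    if kernel == "rbf":
        sq = (np.sum(a * a, axis=1)[:, None] + np.sum(b * b, axis=1)[None, :]
              - 2.0 * (a @ b.T))
        return np.exp(-gamma * np.maximum(sq, 0.0))
    if kernel == "poly":
        return (gamma * (a @ b.T) + coef0) ** degree
    raise ValidationError(f"unsupported kernel {kernel!r}")


@dataclass
class SVMModel:
    """Fitted dual-form SVM with its feature standardiser."""

    support_vectors: np.ndarray          # (n_sv, d) in standardised space
    alpha: np.ndarray                    # (n_sv,) multipliers, 0 < a_i <= C
    sv_labels: np.ndarray                # (n_sv,) in {-1, +1}
    bias: float
    kernel: str
    gamma: float
    degree: int
    coef0: float
    C: float
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    n_features: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def dual_coef(self) -> np.ndarray:
        """a_i * y_i for each support vector."""
        return self.alpha * self.sv_labels

    def standardise(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.n_features:
            raise ValidationError(
                f"feature dimension {x.shape[1]} does not match the "
                f"{self.n_features} training dimensions")
        if self.scaler_mean is None:
            return x
        return (x - self.scaler_mean) / self.scaler_scale


def _as_pm1(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    uniq = set(np.unique(y).tolist())
    if uniq <= {0, 1}:
        y = np.where(y > 0, 1, -1)
    elif not uniq <= {-1, 1}:
        raise ValidationError(f"labels must be binary (+-1 or 0/1), got {sorted(uniq)}")
    return y.astype(np.float64)


def fit_svm(features: np.ndarray, labels: np.ndarray, C: float = 1.0,
            kernel: str = "rbf", gamma: float | str = "scale",
            degree: int = 3, coef0: float = 0.0,
            standardize: bool = True) -> SVMModel:
    """Fit the soft-margin dual on (n_samples, d) features with +-1 labels.

    ``gamma="scale"`` uses the 1 / (d * var(X)) heuristic on the
    (standardised) training matrix.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    y = _as_pm1(labels)
    if len(y) != len(X):
        raise ValidationError("features and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise TrainingError("SVM training requires both classes present")
    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        X = (X - mean) / scale
    if gamma == "scale":
        var = X.var()
        gamma_val = 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]
    else:
        gamma_val = float(gamma)
    clf = SVC(C=C, kernel=kernel, gamma=gamma_val, degree=degree, coef0=coef0)
    clf.fit(X, y)
    # SVC stores a_i * y_i; recover a_i = |dual_coef| since a_i >= 0.
    dual = clf.dual_coef_[0]
    sv = clf.support_vectors_
    sv_labels = np.sign(dual)
    alpha = np.abs(dual)
    return SVMModel(
        support_vectors=sv, alpha=alpha, sv_labels=sv_labels,
        bias=float(clf.intercept_[0]), kernel=kernel, gamma=gamma_val,
        degree=degree, coef0=coef0, C=C,
        scaler_mean=mean, scaler_scale=scale, n_features=X.shape[1],
        meta={"n_support": int(alpha.size)})


def svm_decision(model: SVMModel, features: np.ndarray) -> np.ndarray | float:
    """Signed decision value  sum_i a_i y_i K(x_i, x) + b.

    Classification is ``sign`` of the value, with the tie f(x) == 0 resolved
    as Positive (consistent with ``score >= threshold`` elsewhere).
    Accepts a single vector (returns a float) or a matrix (returns a vector).
    """
    if not isinstance(model, SVMModel):
        raise StateError("svm_decision requires a fitted SVMModel")
    single = np.asarray(features).ndim == 1
    Xs = model.standardise(features)
    K = kernel_matrix(model.support_vectors, Xs, model.kernel,
                      gamma=model.gamma, degree=model.degree, coef0=model.coef0)
    vals = model.dual_coef @ K + model.bias
    return float(vals[0]) if single else vals


def svm_score(model: SVMModel, features: np.ndarray) -> np.ndarray | float:
    """Decision value through a logistic link: score in (0, 1)."""
    d = svm_decision(model, features)
    s = expit(np.asarray(d))
    return float(s) if np.ndim(d) == 0 else s


def dual_objective(model: SVMModel) -> float:
    """W(a) evaluated at the fitted multipliers (standardised feature space)."""
    K = kernel_matrix(model.support_vectors, model.support_vectors,
                      model.kernel, gamma=model.gamma, degree=model.degree,
                      coef0=model.coef0)
    coef = model.dual_coef
    return float(model.alpha.sum() - 0.5 * coef @ K @ coef)
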