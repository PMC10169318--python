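"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own fast paths: convolution by
explicit loops, AUROC by exhaustive pair counting, the SVM dual by a generic
constrained optimiser over the multipliers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def naive_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Loop-based 'same'-padded cross-correlation of (H, W, C) by (kh, kw, C, F)."""
    kh, kw, cin, cout = w.shape
    h_in, w_in, _ = x.shape
    h_out = -(-h_in // stride)
    w_out = -(-w_in // stride)
    pad_h = max((h_out - 1) * stride + kh - h_in, 0)
    pad_w = max((w_out - 1) * stride + kw - w_in, 0)
    xp = np.pad(x, ((pad_h // 2, pad_h - pad_h // 2),
                    (pad_w // 2, pad_w - pad_w // 2), (0, 0)))
    out = np.zeros((h_out, w_out, cout))
    for i in range(h_out):
        for j in range(w_out):
            patch = xp[i * stride:i * stride + kh, j * stride:j * stride + kw]
            for f in range(cout):
                out[i, j, f] = np.sum(patch * w[:, :, :, f])
    return out


def pairwise_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Concordance statistic: P(score_pos > score_neg), ties counted half."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def qp_dual_objective(X: np.ndarray, y: np.ndarray, K: np.ndarray,
                      C: float) -> tuple[float, np.ndarray]:
    """Maximise W(a) = sum a - 1/2 a^T (yy^T * K) a over the dual box.

    Generic SLSQP over the l multipliers with the equality constraint
    sum a_i y_i = 0; suitable only for tiny problems (l <= 6).  Returns the
    optimal objective value and the multipliers.
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    best = None
    # A few feasible starts guard against local SLSQP stalls (the problem is
    # concave so any KKT point is global, but SLSQP can stop early).
    rng = np.random.default_rng(0)
    starts = [np.zeros(n), np.full(n, min(C / 2, 1.0))]
    for _ in range(3):
        a0 = rng.uniform(0, C, n)
        a0 -= y * (a0 @ y) / n  # rough projection toward the constraint
        starts.append(np.clip(a0, 0, C))
    for a0 in starts:
        res = minimize(neg_obj, a0, jac=neg_grad, method="SLSQP",
                       bounds=[(0.0, C)] * n,
                       constraints={"type": "eq", "fun": lambda a: a @ y,
                                    "jac": lambda a: y},
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x
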