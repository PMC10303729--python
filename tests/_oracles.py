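"""Independent brute-force oracles used to check the fitted estimators.

These deliberately avoid the code paths they validate: the NNLS check
enumerates a grid on the probability simplex, and the regression check
solves the normal equations by explicit matrix inversion.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def simplex_grid(k: int, step: float = 0.01) -> np.ndarray:
    """All points on the k-simplex whose coordinates are multiples of step."""
    n = round(1.0 / step)
    pts = []
    # stars and bars: compositions of n into k nonnegative parts
    for bars in combinations(range(n + k - 1), k - 1):
        prev = -1
        parts = []
        for b in bars:
            parts.append(b - prev - 1)
            prev = b
        parts.append(n + k - 2 - prev)
        pts.append(parts)
    return np.asarray(pts, dtype=float) * step


def best_simplex_objective(A: np.ndarray, b: np.ndarray, step: float = 0.01) -> float:
    """min over the simplex grid of ‖Ax − b‖₂ (the NNLS oracle bound)."""
    grid = simplex_grid(A.shape[1], step)
    resid = grid @ A.T - b
    return float(np.sqrt((resid**2).sum(axis=1).min()))


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept via explicit inversion of XᵀX."""
    D = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(D.T @ D) @ D.T @ y


def pearson_by_hand(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
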