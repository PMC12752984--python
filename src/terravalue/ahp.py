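"""Analytic hierarchy process weighting with consistency checking.

Indicator weights derive from a positive reciprocal pairwise-comparison
(judgment) matrix on Saaty's 1-9 scale: the weight vector is the principal
right-eigenvector of the matrix (power iteration), normalised to sum 1, and
the quality of the judgments is summarised by the consistency ratio
CR = CI / RI(n) with CI = (lambda_max - n) / (n - 1) and Saaty's random-index
table RI.  CR < 0.1 is the conventional acceptance gate.

The case-study pipeline defaults to the published 16-indicator weight vector
(:func:`hefei_weights`); matrix-based derivation is the general capability
for user-supplied judgments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hefei2021

#: Saaty's random consistency index RI by matrix order n (1-based; orders
#: 1 and 2 are always consistent).
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
    16: 1.60,
}

#: Conventional acceptance threshold on the consistency ratio.
CR_THRESHOLD = 0.1


def validate_judgment_matrix(m: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Validate a positive reciprocal judgment matrix, returning it as float.

    Requires a square matrix with unit diagonal, entries in [1/9, 9] and
    m[j, i] = 1 / m[i, j] within ``rtol``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"judgment matrix must be square, got shape {m.shape}")
    if not np.all(m > 0):
        raise ValueError("judgment matrix entries must be positive")
    if not np.allclose(np.diag(m), 1.0, rtol=rtol):
        raise ValueError("judgment matrix diagonal must be 1")
    if m.min() < 1 / 9 - 1e-9 or m.max() > 9 + 1e-9:
        raise ValueError("judgment matrix entries must lie in [1/9, 9]")
    if not np.allclose(m * m.T, 1.0, rtol=rtol, atol=0):
        raise ValueError("judgment matrix must be reciprocal (m[j,i] = 1/m[i,j])")
    return m


def weights_from_matrix(
    m: np.ndarray,
    ids: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[pd.Series, float]:
    """Principal-eigenvector weights and dominant eigenvalue of a judgment
    matrix.

    Power iteration runs to relative tolerance ``tol`` on the normalised
    eigenvector; the returned weights sum to 1.  Returns
    ``(weights, lambda_max)``.
    """
    m = validate_judgment_matrix(m)
    n = m.shape[0]
    if ids is None:
        ids = [f"C{i + 1}" for i in range(n)]
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        v = m @ w
        lam = float(v.sum())  # since w sums to 1, Rayleigh-like estimate
        v /= v.sum()
        if np.max(np.abs(v - w)) <= tol * np.max(np.abs(v)):
            w = v
            break
        w = v
    # dominant eigenvalue from the converged vector
    lam = float(np.mean((m @ w) / w))
    return pd.Series(w, index=ids, name="weight"), lam


def geometric_mean_weights(m: np.ndarray, ids: list[str] | None = None) -> pd.Series:
    """Row geometric-mean weights (cross-check method; exact for consistent
    matrices)."""
    m = validate_judgment_matrix(m)
    n = m.shape[0]
    if ids is None:
        ids = [f"C{i + 1}" for i in range(n)]
    g = np.exp(np.log(m).mean(axis=1))
    return pd.Series(g / g.sum(), index=ids, name="weight")


def consistency_ratio(m: np.ndarray) -> float:
    """Consistency ratio CR of a judgment matrix.

    CR = CI / RI(n), CI = (lambda_max - n)/(n - 1); defined as 0 for
    n <= 2 (2x2 reciprocal matrices are always consistent).
    """
    m = validate_judgment_matrix(m)
    n = m.shape[0]
    if n <= 2:
        return 0.0
    if n not in RANDOM_INDEX:
        raise ValueError(f"no random index available for order {n}")
    _, lam = weights_from_matrix(m)
    ci = (lam - n) / (n - 1)
    return max(ci, 0.0) / RANDOM_INDEX[n]


def is_consistent(m: np.ndarray, threshold: float = CR_THRESHOLD) -> bool:
    """Whether the matrix passes the consistency test (CR < threshold)."""
    return consistency_ratio(m) < threshold


def hefei_weights(renormalise: bool = False) -> pd.Series:
    """The published 16-indicator weight vector of the Hefei study.

    The printed values sum to 0.9999; with ``renormalise=True`` they are
    rescaled to sum exactly 1 (off by default to preserve the printed
    values).
    """
    w = pd.Series(hefei2021.INDICATOR_WEIGHTS, name="weight")
    if renormalise:
        w = w / w.sum()
    return w
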