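"""Eigenspectrum analysis of the feature correlation matrix.

The head count of the transformer is not hand-picked: it is the number
of leading principal components of the training-split feature
correlation matrix needed to reach a cumulative explained-variance
threshold ``alpha``.  The same eigenvectors and eigenvalues later seed
the attention projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EigenSpectrum",
    "HeadSelection",
    "correlation_matrix",
    "eigendecompose",
    "explained_variance_ratio",
    "select_heads",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigendecomposition of a feature correlation matrix.

    Attributes
    ----------
    eigenvalues : (d,) array, descending, clipped at zero.
    eigenvectors : (d, d) array; column ``i`` is the unit eigenvector of
        ``eigenvalues[i]`` with its largest-magnitude entry made
        positive (a fixed sign convention so downstream weight
        initialisation is backend-independent).
    evr : (d,) cumulative explained-variance ratios.
    feature_names : names of the d features, in matrix order.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    evr: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    @property
    def d(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class HeadSelection:
    """Smallest component count whose cumulative EVR reaches ``alpha``."""

    alpha: float
    h: int
    evr_at_h: float


def correlation_matrix(X_train: np.ndarray, feature_names=None) -> np.ndarray:
    """Pearson correlation matrix of a sample x feature training matrix.

    Uses the n-1 denominator on centred, unit-scaled columns.  Constant
    columns must be excluded upstream; encountering one here is an error
    naming the offending feature.
    """
    X = np.asarray(X_train, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("correlation_matrix requires a 2-D matrix with >= 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("correlation_matrix requires finite values (impute first)")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        idx = np.flatnonzero(sd == 0)
        names = (
            [feature_names[i] for i in idx]
            if feature_names is not None
            else [f"column {i}" for i in idx]
        )
        raise ValueError(f"constant feature(s) have undefined correlation: {names}")
    Z = (X - X.mean(axis=0)) / sd
    C = (Z.T @ Z) / (X.shape[0] - 1)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def eigendecompose(C: np.ndarray, feature_names=None) -> EigenSpectrum:
    """Symmetric eigendecomposition ``C = V diag(lambda) V^T``.

    Eigenvalues are returned in descending order with tiny negative
    round-off clipped to zero; each eigenvector's largest-magnitude
    component is made positive.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if np.abs(C - C.T).max() > 1e-8:
        raise ValueError("C is asymmetric beyond 1e-8")
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w.min() < -1e-6:  # genuinely indefinite input, not round-off
        raise ValueError(f"matrix is not positive semi-definite (min eigenvalue {w.min():g})")
    w = np.clip(w, 0.0, None)
    # deterministic sign: largest-|.| entry of each eigenvector positive
    flips = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flips[flips == 0] = 1.0
    V = V * flips
    names = tuple(feature_names) if feature_names is not None else tuple(f"f{i}" for i in range(C.shape[0]))
    return EigenSpectrum(w, V, explained_variance_ratio(w), names)


def explained_variance_ratio(eigenvalues: np.ndarray) -> np.ndarray:
    """Cumulative EVR_k = sum_{i<=k} lambda_i / sum_i lambda_i."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be in descending order")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero eigenspectrum")
    return np.cumsum(lam) / total


def select_heads(evr: np.ndarray, alpha: float) -> HeadSelection:
    """Head count = smallest k with cumulative EVR_k >= alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    evr = np.asarray(evr, dtype=np.float64)
    # float round-off guard: the final EVR is 1 by construction
    meets = np.flatnonzero(evr >= alpha - 1e-12)
    h = int(meets[0]) + 1 if meets.size else len(evr)
    return HeadSelection(alpha=alpha, h=h, evr_at_h=float(evr[h - 1]))


def sensitivity_sweep(
    X_train: np.ndarray,
    thresholds: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95, 0.98),
    feature_names=None,
) -> pd.DataFrame:
    """Head counts across a sweep of variance thresholds.

    Returns a DataFrame with columns ``threshold``, ``heads`` and
    ``evr_at_heads``; ``heads`` is non-decreasing in ``threshold``.
    """
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    spectrum = eigendecompose(correlation_matrix(X_train, feature_names), feature_names)
    rows = []
    for alpha in thresholds:
        sel = select_heads(spectrum.evr, alpha)
        rows.append({"threshold": alpha, "heads": sel.h, "evr_at_heads": sel.evr_at_h})
    return pd.DataFrame(rows)
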