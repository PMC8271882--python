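"""Gaussian kernels, kernel matrices and data-driven bandwidth selection.

The Gaussian (RBF) kernel

    k_sigma(a, b) = exp(-||a - b||^2 / (2 sigma^2))

is the similarity used everywhere in this package: as the spectral-clustering
affinity, inside the distribution embeddings, and (through scikit-learn) in
the SVM. ``sigma`` is a length scale in the same units as the Euclidean
distances of the space it parameterizes. The standard data-driven choice is
the *median heuristic*: sigma equals the median pairwise Euclidean distance
of the data, optionally refined over the multiplier grid
{0.5, 1, 2, 5, 10} x sigma0 by cross-validation downstream.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateDataWarning, DimensionMismatchError

#: multipliers applied to the median-heuristic bandwidth during grid search
GRID_MULTIPLIERS = (0.5, 1.0, 2.0, 5.0, 10.0)


def _as_samples(A, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2 or A.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array of samples, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite values")
    return A


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"bandwidth sigma must be a positive real, got {sigma}")
    return sigma


def squared_distances(A, B) -> np.ndarray:
    """All-pairs squared Euclidean distances via the stable expansion.

    Uses ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b with negative round-off
    clamped to 0, so downstream exponentials never see spurious negatives.
    """
    A = _as_samples(A, "A")
    B = _as_samples(B, "B")
    if A.shape[1] != B.shape[1]:
        raise DimensionMismatchError("sample dimension mismatch", A.shape[1], B.shape[1])
    sq = (A * A).sum(axis=1)[:, None] + (B * B).sum(axis=1)[None, :] - 2.0 * (A @ B.T)
    np.maximum(sq, 0.0, out=sq)
    return sq


def gaussian_kernel_matrix(A, B, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix K[i, j] = exp(-||a_i - b_j||^2 / (2 sigma^2)).

    Parameters
    ----------
    A, B : array-like, shape (n, d) and (m, d)
        Sample sets; 1-D inputs are treated as scalar samples.
    sigma : float
        Positive bandwidth.

    Returns
    -------
    ndarray of shape (n, m) with entries in (0, 1]. When ``A is B`` (or the
    arrays are equal) the matrix is symmetric with unit diagonal and PSD up
    to floating point.
    """
    sigma = _check_sigma(sigma)
    sq = squared_distances(A, B)
    return np.exp(sq / (-2.0 * sigma * sigma))


def median_heuristic_bandwidth(A) -> float:
    """Median of all distinct pairwise Euclidean distances of ``A``.

    Self-distances are excluded (strict upper triangle only); including them
    would bias the bandwidth downward. If every point coincides the median
    is 0, which is not a valid bandwidth: a fallback of 1.0 is returned with
    a :class:`DegenerateDataWarning`.
    """
    A = _as_samples(A, "A")
    n = A.shape[0]
    if n < 2:
        raise ValueError(f"median heuristic needs at least 2 samples, got {n}")
    sq = squared_distances(A, A)
    iu = np.triu_indices(n, k=1)
    med = float(np.median(np.sqrt(sq[iu])))
    if med == 0.0:
        warnings.warn(
            "all pairwise distances are zero (coincident samples); "
            "falling back to bandwidth 1.0",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return 1.0
    return med


def bandwidth_grid(sigma0: float) -> list[float]:
    """Candidate bandwidths {0.5, 1, 2, 5, 10} x sigma0, in that order."""
    sigma0 = _check_sigma(sigma0)
    return [m * sigma0 for m in GRID_MULTIPLIERS]
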