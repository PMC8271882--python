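"""PCA latent space: the second view of each codebook pose.

The joint-distribution metric pairs every primary-space pose x_n in R^V
with a latent coordinate y_n in R^Q. The latent map is ordinary PCA: the
top-Q eigenvectors of the sample covariance of the pooled (training)
codebook frames. The basis is fitted *globally* — a single basis shared by
all records — because the metric's cross term compares latent coordinates
across records, which only makes sense in one common coordinate system.

Q defaults to 3; on data of the kind targeted here three components retain
at least ~75% of the pooled variance (asserted on the synthetic generator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError


@dataclass(frozen=True)
class LatentBasis:
    """Fitted orthonormal projection: mean (V,), components (Q, V), ratios (Q,)."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).ravel()
        comps = np.atleast_2d(np.asarray(self.components, dtype=float))
        ratios = np.asarray(self.explained_variance_ratio, dtype=float).ravel()
        if comps.shape[1] != mean.shape[0]:
            raise DimensionMismatchError("components width vs mean", comps.shape[1], mean.shape[0])
        if ratios.shape[0] != comps.shape[0]:
            raise DimensionMismatchError("ratios vs components", ratios.shape[0], comps.shape[0])
        G = comps @ comps.T
        if not np.allclose(G, np.eye(comps.shape[0]), atol=1e-10):
            raise ValueError("components must be mutually orthonormal (to 1e-10)")
        if np.any(np.diff(ratios) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing")
        if ratios.sum() > 1 + 1e-12:
            raise ValueError("explained variance ratios sum exceeds 1")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "explained_variance_ratio", ratios)

    @property
    def q(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LatentBasis":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mean=np.array(payload["mean"]),
            components=np.array(payload["components"]),
            explained_variance_ratio=np.array(payload["explained_variance_ratio"]),
        )


def fit_latent_basis(frames: np.ndarray, q: int) -> LatentBasis:
    """Top-q principal components of the pooled frames.

    Deterministic sign convention: each component's largest-magnitude
    coefficient is made positive, removing the eigenvector sign ambiguity.
    Raises if the centered data rank is below ``q`` (names the achievable
    rank).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    n, V = frames.shape
    if n < 2:
        raise ValueError(f"need at least 2 frames to fit a basis, got {n}")
    if not 1 <= q <= min(n - 1, V):
        raise ValueError(f"q must satisfy 1 <= q <= min(n-1, V) = {min(n - 1, V)}, got {q}")
    mean = frames.mean(axis=0)
    X = frames - mean
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2  # proportional to covariance eigenvalues
    total = var.sum()
    if total <= 0:
        raise ValueError("frames have zero variance; achievable rank is 0")
    tol = s[0] * max(n, V) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < q:
        raise ValueError(f"input rank {rank} is below the requested q={q}")
    comps = Vt[:q]
    # sign convention: largest-magnitude coefficient of each component positive
    flip = np.sign(comps[np.arange(q), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    ratios = var[:q] / total
    return LatentBasis(mean=mean, components=comps, explained_variance_ratio=ratios)


def project_latent(frames: np.ndarray, basis: LatentBasis) -> np.ndarray:
    """(frames - mean) @ components.T — the latent coordinates y_n in R^Q."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[1] != basis.mean.shape[0]:
        raise DimensionMismatchError(
            "frame dimension vs basis", frames.shape[1], basis.mean.shape[0]
        )
    return (frames - basis.mean) @ basis.components.T


def variance_preserved(basis: LatentBasis) -> float:
    """Fraction of total input variance retained by the basis."""
    return float(basis.explained_variance_ratio.sum())
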