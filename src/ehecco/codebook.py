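"""Pose codebooks: representative frames selected by spectral clustering.

A Mocap record of T frames is summarized by N_c representative poses. The
frames (flattened, hip-normalized joint coordinates) are clustered with
normalized spectral clustering — Gaussian affinity at the median-heuristic
bandwidth, symmetric normalized Laplacian, row-normalized eigenvector
embedding, seeded k-means — and each cluster contributes its *medoid*: the
member frame minimizing the summed within-cluster Euclidean distance, so
every codebook pose is an actual recorded pose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .errors import DegenerateDataWarning
from .kernels import gaussian_kernel_matrix, median_heuristic_bandwidth, squared_distances


@dataclass(frozen=True)
class Codebook:
    """Selected frame indices and their pose vectors for one record."""

    indices: np.ndarray  # (N_c,) frame indices into the source record
    poses: np.ndarray  # (N_c, V), rows bit-identical to source frames
    n_clusters: int

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "poses", np.asarray(self.poses, dtype=float))
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("codebook frame indices must be unique")

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.poses, columns=[f"v{k}" for k in range(self.poses.shape[1])])
        df.insert(0, "frame", self.indices)
        df.to_csv(path, index=False)


def spectral_cluster(frames: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    """Normalized spectral clustering of frames; labels in [0, n_clusters).

    Affinity W is the Gaussian kernel at the median-heuristic bandwidth of
    the frames. The embedding is the bottom ``n_clusters`` eigenvectors of
    the symmetric normalized Laplacian I - D^{-1/2} W D^{-1/2}, rows scaled
    to unit norm, partitioned by k-means with the given seed.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if not np.all(np.isfinite(frames)):
        raise ValueError("frames contain non-finite values")
    T = frames.shape[0]
    if not 1 <= n_clusters <= T:
        raise ValueError(f"need 1 <= n_clusters <= T, got n_clusters={n_clusters}, T={T}")
    if n_clusters == 1:
        return np.zeros(T, dtype=int)
    if n_clusters == T:
        return np.arange(T, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDataWarning)
        sigma = median_heuristic_bandwidth(frames)
    W = gaussian_kernel_matrix(frames, frames, sigma)
    W = (W + W.T) / 2.0
    d = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(T) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=[0, n_clusters - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = vecs / norms
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(U)
    return labels.astype(int)


def build_codebook(frames: np.ndarray, n_clusters: int, seed: int) -> Codebook:
    """Cluster the frames and keep one medoid per cluster.

    Medoid ties are broken by the lowest frame index. If the record is
    shorter than ``n_clusters`` every frame is kept and the cluster count is
    reduced, with a warning.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    T = frames.shape[0]
    if T < n_clusters:
        warnings.warn(
            f"record has only {T} frames < n_clusters={n_clusters}; keeping all frames",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return Codebook(indices=np.arange(T), poses=frames.copy(), n_clusters=T)
    labels = spectral_cluster(frames, n_clusters, seed)
    sq = squared_distances(frames, frames)
    dist = np.sqrt(sq)
    indices = []
    for k in range(n_clusters):
        members = np.flatnonzero(labels == k)
        costs = dist[np.ix_(members, members)].sum(axis=1)
        # argmin returns the first minimum -> lowest frame index wins ties
        indices.append(int(members[int(np.argmin(costs))]))
    indices = np.sort(np.asarray(indices, dtype=int))
    return Codebook(indices=indices, poses=frames[indices].copy(), n_clusters=n_clusters)
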