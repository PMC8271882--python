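"""Sample estimators of RKHS distances between distributions.

Two estimators are provided. The classical maximum mean discrepancy (MMD)
compares the *marginal* laws of two sample sets X = {x_n} and Z = {z_m}
through their kernel mean embeddings:

    MMD^2 = (1/N^2) 1' Kxx 1 + (1/M^2) 1' Kzz 1 - (2/NM) 1' Kxz 1.

The joint-distribution estimator (EHECCO) compares two *joint* laws, each
represented by paired samples in a primary space R^V and a latent space R^Q
with a probability weight vector alpha. The joint law is embedded in the
tensor RKHS H (x) G via its cross-covariance operator E[phi(x) (x) psi(y)],
and the squared tensor-space distance between two such embeddings reduces,
by the kernel trick, to

    d_J^2 = a' (Kp_xx o Kl_yy) a + b' (Kp_zz o Kl_ll) b
            - 2 a' (Kp_xz o Kl_yl) b,

where o is the Hadamard (elementwise) product, Kp uses the primary-space
kernel on {x}, {z} and Kl the latent-space kernel on {y}, {l}. The Hadamard
product is exactly the tensor-product kernel evaluated on paired samples, so
the embeddings are never materialized. With an all-ones latent kernel and
uniform weights the expression collapses to the MMD, which is the main
internal consistency check (see the reduction-law tests).

Both estimators are non-negative in exact arithmetic (the kernels are PSD);
negative floating-point round-off is clamped at zero, and a raw value below
-1e-9 raises :class:`~ehecco.errors.ConsistencyError` as it can only mean a
broken kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, DimensionMismatchError
from .kernels import _check_sigma, gaussian_kernel_matrix

#: raw estimator values above this (negative) threshold are round-off
CLAMP_TOL = -1e-9


@dataclass(frozen=True)
class WeightedSampleSet:
    """Paired samples from one record: {x_n in R^V, y_n in R^Q} with weights.

    ``primary`` holds the N x V primary-space samples (here: flattened
    normalized joint coordinates), ``latent`` the N x Q latent coordinates of
    the same N items, and ``weights`` a probability vector over the items
    (uniform 1/N for the empirical joint measure).
    """

    primary: np.ndarray
    latent: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        primary = np.atleast_2d(np.asarray(self.primary, dtype=float))
        latent = np.atleast_2d(np.asarray(self.latent, dtype=float))
        if primary.shape[0] != latent.shape[0]:
            raise DimensionMismatchError(
                "primary/latent sample counts differ", primary.shape[0], latent.shape[0]
            )
        if self.weights is None:
            weights = np.full(primary.shape[0], 1.0 / primary.shape[0])
        else:
            weights = np.asarray(self.weights, dtype=float).ravel()
        if weights.shape[0] != primary.shape[0]:
            raise DimensionMismatchError(
                "weight vector length mismatch", weights.shape[0], primary.shape[0]
            )
        if np.any(weights < 0) or np.any(weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")
        object.__setattr__(self, "primary", primary)
        object.__setattr__(self, "latent", latent)
        object.__setattr__(self, "weights", weights)

    @property
    def n_samples(self) -> int:
        return self.primary.shape[0]

    @property
    def primary_dim(self) -> int:
        return self.primary.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.latent.shape[1]


def _clamp(value: float, *, clamp: bool) -> float:
    if not clamp:
        return value
    if value < CLAMP_TOL:
        raise ConsistencyError(
            f"squared distance estimator returned {value}, below the round-off "
            f"tolerance {CLAMP_TOL}; the kernel computation is inconsistent"
        )
    return max(value, 0.0)


def mmd_squared(X, Z, sigma: float, *, convention: str = "bandwidth", clamp: bool = True) -> float:
    """Squared MMD between the empirical marginal laws of ``X`` and ``Z``.

    ``sigma`` is the nominal bandwidth; the kernel matrices are evaluated at
    a doubled scale, for which two conventions exist:

    - ``"bandwidth"`` (default): effective bandwidth 2*sigma, denominator
      8 sigma^2;
    - ``"variance"``: doubled variance, effective bandwidth sqrt(2)*sigma,
      denominator 4 sigma^2;
    - ``"none"``: the kernel is evaluated at sigma itself.
    """
    sigma = _check_sigma(sigma)
    factor = {"bandwidth": 2.0, "variance": np.sqrt(2.0), "none": 1.0}.get(convention)
    if factor is None:
        raise ValueError(f"unknown convention {convention!r}")
    b = factor * sigma
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise DimensionMismatchError("X/Z dimension mismatch", X.shape[1], Z.shape[1])
    kxx = _sym(gaussian_kernel_matrix(X, X, b))
    kzz = _sym(gaussian_kernel_matrix(Z, Z, b))
    kxz = gaussian_kernel_matrix(X, Z, b)
    value = float(kxx.mean() + kzz.mean() - 2.0 * kxz.mean())
    return _clamp(value, clamp=clamp)


def _sym(K: np.ndarray) -> np.ndarray:
    # self-kernel matrices are symmetrized to suppress round-off; cross
    # matrices are never assumed symmetric
    return (K + K.T) / 2.0


def _check_pair(P: WeightedSampleSet, R: WeightedSampleSet) -> None:
    if P.primary_dim != R.primary_dim:
        raise DimensionMismatchError("primary-space dimension V mismatch", P.primary_dim, R.primary_dim)
    if P.latent_dim != R.latent_dim:
        raise DimensionMismatchError("latent-space dimension Q mismatch", P.latent_dim, R.latent_dim)


def ehecco_squared(
    P: WeightedSampleSet,
    R: WeightedSampleSet,
    sigma_phi: float,
    sigma_psi: float,
    *,
    clamp: bool = True,
) -> float:
    """Squared tensor-RKHS distance between the joint laws of ``P`` and ``R``.

    ``sigma_phi`` parameterizes the Gaussian kernel on the primary space
    (applied to both records' primary samples), ``sigma_psi`` the kernel on
    the latent space. The estimator is the weighted Hadamard-product form
    described in the module docstring; it is symmetric in (P, R) and zero
    when the two weighted sample sets are identical.
    """
    _check_pair(P, R)
    sigma_phi = _check_sigma(sigma_phi)
    sigma_psi = _check_sigma(sigma_psi)
    a, b = P.weights, R.weights
    kpp = _sym(gaussian_kernel_matrix(P.primary, P.primary, sigma_phi)) * _sym(
        gaussian_kernel_matrix(P.latent, P.latent, sigma_psi)
    )
    krr = _sym(gaussian_kernel_matrix(R.primary, R.primary, sigma_phi)) * _sym(
        gaussian_kernel_matrix(R.latent, R.latent, sigma_psi)
    )
    kpr = gaussian_kernel_matrix(P.primary, R.primary, sigma_phi) * gaussian_kernel_matrix(
        P.latent, R.latent, sigma_psi
    )
    value = float(a @ kpp @ a + b @ krr @ b - 2.0 * (a @ kpr @ b))
    return _clamp(value, clamp=clamp)


def ehecco_squared_oracle(
    P: WeightedSampleSet,
    R: WeightedSampleSet,
    sigma_phi: float,
    sigma_psi: float,
) -> float:
    """Brute-force nested-loop transcription of the estimator, for testing.

    Accumulates the three double sums one scalar kernel evaluation at a
    time, with no matrix algebra. Intended for N, M <= 100; mathematically
    identical to :func:`ehecco_squared`.
    """
    _check_pair(P, R)
    sigma_phi = _check_sigma(sigma_phi)
    sigma_psi = _check_sigma(sigma_psi)

    def kphi(u, v):
        d2 = float(np.sum((u - v) ** 2))
        return np.exp(-d2 / (2.0 * sigma_phi**2))

    def kpsi(u, v):
        d2 = float(np.sum((u - v) ** 2))
        return np.exp(-d2 / (2.0 * sigma_psi**2))

    total = 0.0
    for i in range(P.n_samples):
        for j in range(P.n_samples):
            total += (
                P.weights[i]
                * P.weights[j]
                * kphi(P.primary[i], P.primary[j])
                * kpsi(P.latent[i], P.latent[j])
            )
    for i in range(R.n_samples):
        for j in range(R.n_samples):
            total += (
                R.weights[i]
                * R.weights[j]
                * kphi(R.primary[i], R.primary[j])
                * kpsi(R.latent[i], R.latent[j])
            )
    for i in range(P.n_samples):
        for j in range(R.n_samples):
            total -= (
                2.0
                * P.weights[i]
                * R.weights[j]
                * kphi(P.primary[i], R.primary[j])
                * kpsi(P.latent[i], R.latent[j])
            )
    return max(total, 0.0)


def pairwise_distance_matrix(
    reps: list[WeightedSampleSet],
    sigma_phi: float,
    sigma_psi: float,
    *,
    squared: bool = False,
) -> np.ndarray:
    """Symmetric dissimilarity matrix of pairwise record distances.

    Entry (i, j) is sqrt(max(d_J^2(rep_i, rep_j), 0)) — the distance, not
    the squared distance, unless ``squared=True``. Only the upper triangle
    is computed, then mirrored; the diagonal is exactly zero.
    """
    n = len(reps)
    if n < 2:
        raise ValueError(f"need at least 2 representations, got {n}")
    for idx, r in enumerate(reps[1:], start=1):
        try:
            _check_pair(reps[0], r)
        except DimensionMismatchError as exc:
            raise DimensionMismatchError(
                f"representation {idx} incompatible with representation 0", exc.left, exc.right
            ) from exc
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = ehecco_squared(reps[i], reps[j], sigma_phi, sigma_psi)
            D[i, j] = D[j, i] = d2 if squared else np.sqrt(d2)
    return D


# ---------------------------------------------------------------------------
# distance-matrix serialization


def save_distance_matrix_csv(D: np.ndarray, ids: list[str], path) -> None:
    """Write ``D`` as CSV with a header row (and index column) of record ids."""
    import pandas as pd

    D = np.asarray(D, dtype=float)
    if D.shape[0] != len(ids):
        raise DimensionMismatchError("ids length vs matrix size", len(ids), D.shape[0])
    pd.DataFrame(D, index=list(ids), columns=list(ids)).to_csv(path)


def load_distance_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def save_distance_matrix_npy(D: np.ndarray, path) -> None:
    """Compact binary form; round-trips floats exactly."""
    np.save(path, np.asarray(D, dtype=float))


def load_distance_matrix_npy(path) -> np.ndarray:
    return np.load(path)
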