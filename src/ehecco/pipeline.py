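"""End-to-end Mocap recognition pipeline on the joint-embedding metric.

Stages, per record: forward kinematics -> hip normalization -> flattening
-> spectral-clustering codebook of N_c poses -> global PCA latent
projection (Q=3) -> weighted sample set {x_n in R^V, y_n in R^Q} with
uniform weights. Records are compared with the tensor-RKHS metric to give a
dissimilarity matrix D; an RBF-kernel SVM is trained in the *dissimilarity
space* (record i's feature vector is row i of D, its distances to the
training records). Evaluation is stratified 10-fold cross-validation with,
inside every training fold, a fresh latent basis and an exhaustive grid
search: bandwidth multipliers {0.5, 1, 2, 5, 10} x median heuristic for
each space, SVM penalty {1, 10, 1e2, 1e3, 1e4} and kernel precision
{0.01, 0.1, 1, 100, 1000}, scored by internal stratified CV on the
training records only (no test-fold leakage anywhere).

Visualization and interpretation reuse D directly: t-SNE in precomputed-
distance mode for 2-D scatter plots, and the anthropometric analysis
correlates each subject's mean 1-D t-SNE coordinate against the covariate
table (absolute Pearson correlation).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .codebook import build_codebook
from .errors import DegenerateDataWarning, DimensionMismatchError
from .kernels import bandwidth_grid, median_heuristic_bandwidth, squared_distances
from .latent import LatentBasis, fit_latent_basis, project_latent
from .metric import WeightedSampleSet, pairwise_distance_matrix
from .mocap import PoseSequence, flatten_poses, forward_kinematics, hip_normalize

logger = logging.getLogger("ehecco")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs; flat keys so a YAML file maps one-to-one."""

    n_clusters: int = 50
    q: int = 3
    folds: int = 10
    inner_folds: int = 3
    seed: int = 0
    perplexity: float = 5.0
    svm_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 100.0, 1000.0)
    squared_distances: bool = False
    svm_mode: str = "dissimilarity"  # or "kernel": precomputed exp(-gamma D^2)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("svm_c_grid", "svm_gamma_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        raw = asdict(self)
        raw["svm_c_grid"] = list(raw["svm_c_grid"])
        raw["svm_gamma_grid"] = list(raw["svm_gamma_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class LabeledDataset:
    """Per-record codebooks with labels and optional subject covariates.

    ``codebooks[i]`` is the (N_c, V) matrix of record i's selected poses
    (the primary-space samples); ``records`` additionally carries the
    latent view under a single global basis, for the non-cross-validated
    operations (distance matrix, t-SNE, correlation).
    """

    codebooks: list[np.ndarray]
    labels: np.ndarray
    subject_ids: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    records: list[WeightedSampleSet] | None = None
    basis: LatentBasis | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.codebooks) != len(self.labels):
            raise DimensionMismatchError(
                "codebooks vs labels", len(self.codebooks), len(self.labels)
            )
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if len(self.subject_ids) != len(self.labels):
                raise DimensionMismatchError(
                    "subject_ids vs labels", len(self.subject_ids), len(self.labels)
                )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EvaluationReport:
    """Cross-validation outcome: accuracies, pooled confusion, chosen grids."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray  # rows = true class, in ``classes`` order
    classes: np.ndarray
    chosen_hyperparameters: list[dict]

    def to_json(self, path) -> None:
        import json

        payload = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "chosen_hyperparameters": self.chosen_hyperparameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def confusion_to_csv(self, path) -> None:
        pd.DataFrame(
            self.confusion,
            index=pd.Index(self.classes, name="true"),
            columns=pd.Index(self.classes, name="predicted"),
        ).to_csv(path)


# ---------------------------------------------------------------------------
# representation


def normalized_frames(poses: PoseSequence, root_joint: str | None = None) -> np.ndarray:
    """Hip-normalize and flatten a pose sequence to a (T, 3J) frame matrix."""
    return flatten_poses(hip_normalize(poses, root_joint))


def represent_record(
    poses: PoseSequence,
    basis: LatentBasis,
    n_clusters: int,
    seed: int,
) -> WeightedSampleSet:
    """Codebook poses + their latent projection, with uniform 1/N_c weights."""
    frames = normalized_frames(poses)
    cb = build_codebook(frames, n_clusters, seed)
    X = cb.poses
    Y = project_latent(X, basis)
    return WeightedSampleSet(primary=X, latent=Y)


def build_dataset(
    pose_sequences: list[PoseSequence],
    labels,
    config: PipelineConfig,
    *,
    subject_ids=None,
    covariates: pd.DataFrame | None = None,
) -> LabeledDataset:
    """Codebooks for every record plus a global latent basis and record views.

    The latent basis here is fitted on the pooled codebook frames of *all*
    records; :func:`cross_validate` refits it per training fold and ignores
    this global one.
    """
    t0 = time.perf_counter()
    codebooks = []
    for poses in pose_sequences:
        frames = normalized_frames(poses)
        cb = build_codebook(frames, min(config.n_clusters, frames.shape[0]), config.seed)
        codebooks.append(cb.poses)
    logger.info("codebooks for %d records: %.2fs", len(codebooks), time.perf_counter() - t0)
    pooled = np.vstack(codebooks)
    basis = fit_latent_basis(pooled, config.q)
    records = [
        WeightedSampleSet(primary=X, latent=project_latent(X, basis)) for X in codebooks
    ]
    return LabeledDataset(
        codebooks=codebooks,
        labels=labels,
        subject_ids=subject_ids,
        covariates=covariates,
        records=records,
        basis=basis,
    )


def dataset_from_synthetic(synth, config: PipelineConfig) -> LabeledDataset:
    """FK + normalization + representation of a generated dataset."""
    poses = [forward_kinematics(h, m) for h, m in synth.records]
    return build_dataset(
        poses,
        synth.labels,
        config,
        subject_ids=synth.subject_ids,
        covariates=synth.covariates,
    )


# ---------------------------------------------------------------------------
# fast uniform-codebook distance computation
#
# With equal codebook sizes and uniform weights the full Lambda x Lambda
# distance matrix reduces to block sums of one stacked tensor-product kernel
# matrix; squared-distance matrices for both spaces are cached (float32) so
# every bandwidth pair in the grid costs a single exp pass.


def _stack_sqdist(stacked: np.ndarray) -> np.ndarray:
    return squared_distances(stacked, stacked).astype(np.float32)


def _distmat_uniform(
    P2: np.ndarray, L2: np.ndarray, sigma_phi: float, sigma_psi: float, lam: int, nc: int
) -> np.ndarray:
    """Lambda x Lambda squared-distance matrix from cached stacks."""
    E = P2 * np.float32(-0.5 / sigma_phi**2)
    E += L2 * np.float32(-0.5 / sigma_psi**2)
    np.exp(E, out=E)
    S = E.reshape(lam, nc, lam, nc).sum(axis=(1, 3), dtype=np.float64) / (nc * nc)
    diag = np.diag(S)
    D2 = diag[:, None] + diag[None, :] - 2.0 * S
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return (D2 + D2.T) / 2.0


def _median_from_block(sq: np.ndarray, idx: np.ndarray, nc: int) -> float:
    """Median heuristic over the pooled samples of the given records."""
    rows = np.concatenate([np.arange(i * nc, (i + 1) * nc) for i in idx])
    block = sq[np.ix_(rows, rows)]
    n = block.shape[0]
    iu = np.triu_indices(n, k=1)
    med = float(np.median(np.sqrt(block[iu], dtype=np.float64)))
    if med == 0.0:
        warnings.warn("degenerate pooled samples; bandwidth fallback 1.0", DegenerateDataWarning)
        return 1.0
    return med


def _uniform_codebook_stack(codebooks: list[np.ndarray]) -> np.ndarray:
    shapes = {cb.shape for cb in codebooks}
    if len(shapes) != 1:
        raise ValueError(
            f"cross-validation requires equal codebook sizes; got shapes {sorted(shapes)}"
        )
    return np.vstack(codebooks)


def distance_matrix(
    dataset: LabeledDataset,
    sigma_phi: float | None = None,
    sigma_psi: float | None = None,
    *,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Pairwise record distance matrix under the global latent basis.

    Bandwidths default to the median heuristic of the pooled samples of
    each space. Uses the fast uniform-codebook path when codebook sizes
    agree, the general per-pair route otherwise.
    """
    config = config or PipelineConfig()
    if dataset.records is None:
        raise ValueError("dataset has no record representations; use build_dataset")
    primary = np.vstack([r.primary for r in dataset.records])
    latent = np.vstack([r.latent for r in dataset.records])
    if sigma_phi is None:
        sigma_phi = median_heuristic_bandwidth(primary)
    if sigma_psi is None:
        sigma_psi = median_heuristic_bandwidth(latent)
    shapes = {r.primary.shape for r in dataset.records}
    uniform = len(shapes) == 1 and all(
        np.allclose(r.weights, 1.0 / r.n_samples) for r in dataset.records
    )
    if uniform:
        lam = len(dataset)
        nc = dataset.records[0].n_samples
        D2 = _distmat_uniform(
            _stack_sqdist(primary), _stack_sqdist(latent), sigma_phi, sigma_psi, lam, nc
        )
        return D2 if config.squared_distances else np.sqrt(D2)
    return pairwise_distance_matrix(
        dataset.records, sigma_phi, sigma_psi, squared=config.squared_distances
    )


# ---------------------------------------------------------------------------
# classification


class DissimilarityClassifier:
    """SVM over distance-based features.

    In ``"dissimilarity"`` mode record i's feature vector is its distances
    to the Lambda_train training records and the SVM applies an RBF kernel
    on those vectors; in ``"kernel"`` mode the distances are turned into a
    precomputed kernel exp(-gamma d^2) directly.
    """

    def __init__(self, C: float, gamma: float, mode: str = "dissimilarity"):
        if mode not in ("dissimilarity", "kernel"):
            raise ValueError(f"unknown svm_mode {mode!r}")
        self.mode = mode
        self.C = C
        self.gamma = gamma
        kernel = "rbf" if mode == "dissimilarity" else "precomputed"
        g = gamma if mode == "dissimilarity" else 1.0
        self._svc = SVC(C=C, gamma=g, kernel=kernel)
        self.n_train: int | None = None

    def fit(self, D_train: np.ndarray, labels) -> "DissimilarityClassifier":
        D_train = np.asarray(D_train, dtype=float)
        labels = np.asarray(labels)
        if D_train.shape[0] != D_train.shape[1]:
            raise ValueError(f"D_train must be square, got {D_train.shape}")
        if not np.allclose(np.diag(D_train), 0.0, atol=1e-8):
            raise ValueError("D_train must have a zero diagonal")
        if not np.allclose(D_train, D_train.T, atol=1e-8):
            raise ValueError("D_train must be symmetric")
        if len(np.unique(labels)) < 2:
            raise ValueError("training labels must span at least 2 classes")
        X = D_train if self.mode == "dissimilarity" else np.exp(-self.gamma * D_train**2)
        self._svc.fit(X, labels)
        self.n_train = D_train.shape[0]
        return self

    def predict(self, D_rows: np.ndarray) -> np.ndarray:
        """``D_rows[k]`` = distances from test record k to the training records."""
        D_rows = np.atleast_2d(np.asarray(D_rows, dtype=float))
        if D_rows.shape[1] != self.n_train:
            raise DimensionMismatchError(
                "feature length vs training size", D_rows.shape[1], self.n_train
            )
        X = D_rows if self.mode == "dissimilarity" else np.exp(-self.gamma * D_rows**2)
        return self._svc.predict(X)


def train_classifier(
    D_train: np.ndarray, labels, C: float, gamma: float, *, mode: str = "dissimilarity"
) -> DissimilarityClassifier:
    """Fit the dissimilarity-space SVM on a training distance matrix."""
    return DissimilarityClassifier(C=C, gamma=gamma, mode=mode).fit(D_train, labels)


def _inner_cv_accuracy(
    D_tr: np.ndarray, labels: np.ndarray, C: float, gamma: float, config: PipelineConfig
) -> float:
    _, counts = np.unique(labels, return_counts=True)
    n_splits = min(config.inner_folds, counts.min())
    if n_splits < 2:
        # too few per-class records for internal folds: score on training fit
        clf = train_classifier(D_tr, labels, C, gamma, mode=config.svm_mode)
        return float(np.mean(clf.predict(D_tr) == labels))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    correct = 0
    for tr, va in skf.split(np.zeros(len(labels)), labels):
        clf = train_classifier(
            D_tr[np.ix_(tr, tr)], labels[tr], C, gamma, mode=config.svm_mode
        )
        correct += int(np.sum(clf.predict(D_tr[np.ix_(va, tr)]) == labels[va]))
    return correct / len(labels)


def _grid_search_uniform(
    P2: np.ndarray,
    L2: np.ndarray,
    train_idx: np.ndarray,
    labels: np.ndarray,
    sigma0_phi: float,
    sigma0_psi: float,
    lam: int,
    nc: int,
    config: PipelineConfig,
):
    """Exhaustive 5x5x5x5 search; ties broken by smallest grid indices.

    Returns the winning (sigma_phi, sigma_psi, C, gamma) and the full
    Lambda x Lambda distance matrix at the winning bandwidths.
    """
    y_tr = labels[train_idx]
    best = None
    best_acc = -1.0
    best_D = None
    for sp in bandwidth_grid(sigma0_phi):
        for sl in bandwidth_grid(sigma0_psi):
            D2 = _distmat_uniform(P2, L2, sp, sl, lam, nc)
            D = D2 if config.squared_distances else np.sqrt(D2)
            D_tr = D[np.ix_(train_idx, train_idx)]
            for C in config.svm_c_grid:
                for gamma in config.svm_gamma_grid:
                    acc = _inner_cv_accuracy(D_tr, y_tr, C, gamma, config)
                    if acc > best_acc:
                        best_acc = acc
                        best = (sp, sl, C, gamma)
                        best_D = D
    return best, best_acc, best_D


def select_hyperparameters(
    train: LabeledDataset,
    sigma0_phi: float | None = None,
    sigma0_psi: float | None = None,
    *,
    config: PipelineConfig | None = None,
) -> tuple[float, float, float, float]:
    """Grid-search bandwidths and SVM hyperparameters on a training set.

    Candidates are the 5-point multiplier grids around the median-heuristic
    bandwidths of each space crossed with the SVM penalty/precision grids
    (625 tuples), scored by internal stratified CV accuracy; ties go to the
    smallest grid indices.
    """
    config = config or PipelineConfig()
    if train.records is None:
        raise ValueError("train dataset has no representations; use build_dataset")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    stack_p = _uniform_codebook_stack([r.primary for r in train.records])
    stack_l = np.vstack([r.latent for r in train.records])
    lam = len(train)
    nc = train.records[0].n_samples
    P2 = _stack_sqdist(stack_p)
    L2 = _stack_sqdist(stack_l)
    all_idx = np.arange(lam)
    if sigma0_phi is None:
        sigma0_phi = _median_from_block(P2, all_idx, nc)
    if sigma0_psi is None:
        sigma0_psi = _median_from_block(L2, all_idx, nc)
    best, _, _ = _grid_search_uniform(
        P2, L2, all_idx, train.labels, sigma0_phi, sigma0_psi, lam, nc, config
    )
    return best


def cross_validate(
    data: LabeledDataset, folds: int | None = None, seed: int | None = None, *,
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation with per-fold basis and grid search.

    Inside every fold the latent basis, the median-heuristic reference
    bandwidths and all hyperparameters are derived from the training
    records alone; the test block of the distance matrix is only used for
    the final prediction.
    """
    config = config or PipelineConfig()
    folds = config.folds if folds is None else folds
    seed = config.seed if seed is None else seed
    labels = np.asarray(data.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to cross-validate")
    n_splits = min(folds, counts.min())
    if n_splits < folds:
        warnings.warn(
            f"reducing folds from {folds} to {n_splits} (smallest class has "
            f"{counts.min()} records)",
            DegenerateDataWarning,
        )
    if n_splits < 2:
        raise ValueError("smallest class has fewer than 2 records")

    stack_p = _uniform_codebook_stack(data.codebooks)
    lam = len(data)
    nc = data.codebooks[0].shape[0]
    t0 = time.perf_counter()
    P2 = _stack_sqdist(stack_p)
    logger.info("primary sq-dist stack (%d x %d): %.2fs", *P2.shape, time.perf_counter() - t0)

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_accuracies = []
    chosen = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(lam), labels)):
        t0 = time.perf_counter()
        basis = fit_latent_basis(stack_p[_record_rows(train_idx, nc)], config.q)
        L2 = _stack_sqdist(project_latent(stack_p, basis))
        sigma0_phi = _median_from_block(P2, train_idx, nc)
        sigma0_psi = _median_from_block(L2, train_idx, nc)
        (sp, sl, C, gamma), inner_acc, D = _grid_search_uniform(
            P2, L2, train_idx, labels, sigma0_phi, sigma0_psi, lam, nc, config
        )
        clf = train_classifier(
            D[np.ix_(train_idx, train_idx)], labels[train_idx], C, gamma, mode=config.svm_mode
        )
        preds = clf.predict(D[np.ix_(test_idx, train_idx)])
        acc = float(np.mean(preds == labels[test_idx]))
        fold_accuracies.append(acc)
        chosen.append(
            {
                "sigma_phi": float(sp),
                "sigma_psi": float(sl),
                "C": float(C),
                "gamma": float(gamma),
                "inner_cv_accuracy": float(inner_acc),
            }
        )
        y_true_all.append(labels[test_idx])
        y_pred_all.append(preds)
        logger.info(
            "fold %d/%d: acc=%.3f (inner %.3f), %.2fs", k + 1, n_splits, acc, inner_acc,
            time.perf_counter() - t0,
        )

    confusion = confusion_matrix(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes
    )
    return EvaluationReport(
        fold_accuracies=np.asarray(fold_accuracies),
        mean_accuracy=float(np.mean(fold_accuracies)),
        confusion=confusion,
        classes=classes,
        chosen_hyperparameters=chosen,
    )


def _record_rows(idx: np.ndarray, nc: int) -> np.ndarray:
    return np.concatenate([np.arange(i * nc, (i + 1) * nc) for i in idx])


# ---------------------------------------------------------------------------
# visualization & interpretation


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    # deterministic sign: largest-magnitude coordinate positive per axis
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def tsne_embed(
    D: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    perplexity: float = 5.0,
    init: str = "mds",
    early_exaggeration: float = 4.0,
) -> np.ndarray:
    """Seeded t-SNE of a precomputed distance matrix; shape (Lambda, dims).

    By default the optimization is initialized from classical MDS of the
    distances (scaled to the usual 1e-4 spread) instead of a random start:
    informative initialization is the standard way to keep the global
    arrangement of a t-SNE embedding faithful and removes init-dependent
    folding, which matters when downstream analyses read coordinates (the
    1-D subject projections) rather than just cluster shapes. ``init=
    "random"`` restores the stochastic start. Early exaggeration is kept
    mild (4 instead of the common 12) for the same reason: strong
    exaggeration fragments the embedding into clusters and discards the
    global arrangement the initialization provides.
    """
    from sklearn.manifold import TSNE

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError(f"D must be square, got {D.shape}")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be below the record count ({n})")
    if init == "mds":
        start = _classical_mds(D, dims)
        spread = start.std()
        if spread > 0:
            start = start / spread * 1e-4
        else:
            start = None
    elif init == "random":
        start = None
    else:
        raise ValueError(f"unknown init {init!r}")
    tsne = TSNE(
        n_components=dims,
        metric="precomputed",
        init=start if start is not None else "random",
        random_state=seed,
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
    )
    return tsne.fit_transform(D)


@dataclass
class CorrelationResult:
    """Absolute Pearson correlations of covariates vs mean 1-D projection."""

    pooled: pd.Series  # |r| per covariate, pooled over all records
    matrix: pd.DataFrame  # full |r| matrix: projection + covariates
    per_class: pd.DataFrame | None = None  # class x covariate |r|
    subject_projection: pd.Series | None = None  # mean 1-D coordinate per subject


def _abs_pearson(x: np.ndarray, table: pd.DataFrame) -> pd.Series:
    out = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(x) == 0:
            warnings.warn(
                f"covariate {col!r} (or the projection) is constant; correlation undefined",
                DegenerateDataWarning,
            )
            out[col] = np.nan
        else:
            out[col] = abs(float(np.corrcoef(x, v)[0, 1]))
    return pd.Series(out, name="abs_pearson_r")


def covariate_correlation(
    D: np.ndarray,
    subject_ids,
    covariates: pd.DataFrame,
    *,
    labels=None,
    seed: int = 0,
    perplexity: float = 5.0,
) -> CorrelationResult:
    """Correlate per-subject mean 1-D t-SNE projections with covariates.

    The distance matrix is embedded into one t-SNE dimension; each
    subject's records are averaged to a single coordinate, which is then
    correlated (absolute Pearson) against every covariate column. With
    ``labels`` given, a per-class table is also produced (subject means
    within each class separately).
    """
    subject_ids = np.asarray(subject_ids)
    if D.shape[0] != len(subject_ids):
        raise DimensionMismatchError("D vs subject_ids", D.shape[0], len(subject_ids))
    missing = set(subject_ids) - set(covariates.index)
    if missing:
        raise KeyError(f"subjects without covariates: {sorted(missing)}")
    coords = tsne_embed(D, dims=1, seed=seed, perplexity=perplexity).ravel()
    frame = pd.DataFrame({"subject": subject_ids, "coord": coords})
    subj_mean = frame.groupby("subject")["coord"].mean()
    table = covariates.loc[subj_mean.index]
    pooled = _abs_pearson(subj_mean.to_numpy(), table)

    joint = table.copy()
    joint.insert(0, "mean_projection", subj_mean)
    matrix = joint.corr().abs()

    per_class = None
    if labels is not None:
        labels = np.asarray(labels)
        rows = {}
        for cls in np.unique(labels):
            mask = labels == cls
            fm = pd.DataFrame({"subject": subject_ids[mask], "coord": coords[mask]})
            sm = fm.groupby("subject")["coord"].mean()
            rows[cls] = _abs_pearson(sm.to_numpy(), covariates.loc[sm.index])
        per_class = pd.DataFrame(rows).T
    return CorrelationResult(
        pooled=pooled, matrix=matrix, per_class=per_class, subject_projection=subj_mean
    )
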