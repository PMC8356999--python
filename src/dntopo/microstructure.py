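"""Microstructure-based parcellation of the dentate nuclei.

DN voxels are clustered on their seven-metric diffusion profile
(FA, MD, AD, RD, MK, AK, RK).  The chain is: build the voxel-by-metric
feature matrix, normalise each feature to its per-subject maximum,
replace interquartile-range outliers by the column median, run fuzzy
c-means (c = 3, fuzziness m = 2 by default), harden to the most probable
cluster, and finally reduce to a two-cluster medial/lateral atlas by
merging the closest pair of cluster centroids.

Fuzzy c-means minimises

    J = sum_i sum_j u_ij^m ||x_i - c_j||^2

by alternating the membership update
u_ij = 1 / sum_k (||x_i - c_j|| / ||x_i - c_k||)^(2/(m-1)) and the
centroid update c_j = sum_i u_ij^m x_i / sum_i u_ij^m.  The objective is
non-increasing across iterations; runs restart from several random
row-stochastic membership initialisations and keep the lowest J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LabelVolume, ScalarVolume, VoxelGrid, mask_indices, require_same_grid

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "FCMConfig",
    "FuzzyPartition",
    "build_feature_matrix",
    "normalize_max",
    "replace_outliers_iqr",
    "fuzzy_cmeans",
    "assign_max_membership",
    "reduce_to_two",
    "microstructure_atlas",
]

FEATURE_NAMES = ("FA", "MD", "AD", "RD", "MK", "AK", "RK")


@dataclass
class FeatureMatrix:
    """DN-voxel x feature table with a back-map to voxel indices."""

    grid: VoxelGrid
    voxel_indices: np.ndarray  # (N, 3)
    feature_names: tuple[str, ...]
    values: np.ndarray  # (N, n_features)

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.voxel_indices), len(self.feature_names)):
            raise ValueError("values must be (n_voxels, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means settings: c clusters, fuzziness m > 1, stopping rule."""

    n_clusters: int = 3
    fuzziness: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzziness <= 1.0:
            raise ValueError("fuzziness must be > 1")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")


@dataclass
class FuzzyPartition:
    """Soft clustering result: row-stochastic memberships and centroids."""

    memberships: np.ndarray  # (N, c)
    centroids: np.ndarray  # (c, n_features)
    objective: float
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        rowsums = self.memberships.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("memberships must sum to 1 per voxel")


# ---------------------------------------------------------------------------
# Feature preparation
# ---------------------------------------------------------------------------

def build_feature_matrix(
    metrics: dict[str, ScalarVolume], dn_mask: LabelVolume
) -> FeatureMatrix:
    """Mask the seven metric maps to the DN, one row per voxel."""
    missing = [n for n in FEATURE_NAMES if n not in metrics]
    if missing:
        raise ValueError(f"missing metric volumes: {missing}")
    require_same_grid([dn_mask, *[metrics[n] for n in FEATURE_NAMES]], "metrics and mask")
    idx = mask_indices(dn_mask, 1)
    values = np.column_stack(
        [metrics[n].values[idx[:, 0], idx[:, 1], idx[:, 2]] for n in FEATURE_NAMES]
    )
    return FeatureMatrix(
        grid=dn_mask.grid, voxel_indices=idx, feature_names=FEATURE_NAMES, values=values
    )


def normalize_max(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide every feature column by its own maximum (column max becomes 1)."""
    maxima = fm.values.max(axis=0)
    if np.any(maxima <= 0):
        bad = [fm.feature_names[i] for i in np.where(maxima <= 0)[0]]
        raise ValueError(f"cannot normalise non-positive columns: {bad}")
    return FeatureMatrix(
        grid=fm.grid,
        voxel_indices=fm.voxel_indices,
        feature_names=fm.feature_names,
        values=fm.values / maxima,
    )


def replace_outliers_iqr(fm: FeatureMatrix, k: float = 1.5) -> FeatureMatrix:
    """Replace per-column IQR outliers by the column median.

    Quartiles use linear interpolation; a value outside
    [Q1 - k*IQR, Q3 + k*IQR] is replaced by the median of the column
    *before* any replacement, so the operation is idempotent.
    """
    if fm.n_voxels < 4:
        raise ValueError("need at least 4 voxels for quartile estimation")
    values = fm.values.copy()
    q1, med, q3 = np.percentile(fm.values, [25, 50, 75], axis=0)
    lo = q1 - k * (q3 - q1)
    hi = q3 + k * (q3 - q1)
    outlier = (fm.values < lo) | (fm.values > hi)
    values[outlier] = np.broadcast_to(med, values.shape)[outlier]
    return FeatureMatrix(
        grid=fm.grid,
        voxel_indices=fm.voxel_indices,
        feature_names=fm.feature_names,
        values=values,
    )


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

def _fcm_run(
    x: np.ndarray, cfg: FCMConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, _ = x.shape
    c, m = cfg.n_clusters, cfg.fuzziness
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    history = []
    prev_j = np.inf
    for _ in range(cfg.max_iter):
        um = u**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _membership_from_distances(d2, m)
        j = float((u**m * d2).sum())
        history.append(j)
        if abs(prev_j - j) < cfg.tol:
            break
        prev_j = j
    return u, centroids, np.asarray(history)


def _membership_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update; coincident points get full weight on their centroid."""
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = 0.0
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(fm: FeatureMatrix, cfg: FCMConfig = FCMConfig()) -> FuzzyPartition:
    """Run fuzzy c-means with random restarts, keeping the lowest objective.

    Restarts draw independent random row-stochastic initial memberships
    from ``cfg.seed``; within each run the alternating updates stop when
    the objective changes by less than ``cfg.tol`` or after
    ``cfg.max_iter`` iterations.
    """
    if fm.n_voxels < cfg.n_clusters:
        raise ValueError("fewer voxels than clusters")
    rng = np.random.default_rng(cfg.seed)
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(cfg.n_restarts):
        u, centroids, history = _fcm_run(fm.values, cfg, rng)
        if best is None or history[-1] < best[2][-1]:
            best = (u, centroids, history)
    u, centroids, history = best
    return FuzzyPartition(
        memberships=u,
        centroids=centroids,
        objective=float(history[-1]),
        objective_history=history,
    )


def assign_max_membership(fp: FuzzyPartition) -> np.ndarray:
    """Harden the partition: 1-based argmax label per voxel (ties -> lowest)."""
    return np.argmax(fp.memberships, axis=1) + 1


# ---------------------------------------------------------------------------
# Reduction to the two-cluster medial/lateral atlas
# ---------------------------------------------------------------------------

def reduce_to_two(
    labels: np.ndarray, fm: FeatureMatrix, dn_mask: LabelVolume
) -> LabelVolume:
    """Merge to two clusters and name them medial/lateral.

    With three nonempty input clusters the pair whose feature-space
    centroids are closest is merged (one agglomerative step).  The
    surviving cluster whose voxel centroid lies nearer the mid-sagittal
    plane (smaller |world x|) is named "medial" (label 2), the other
    "lateral" (label 1).  Requires the grid's x axis to cross the
    mid-sagittal plane at x = 0.
    """
    labels = np.asarray(labels, dtype=int)
    present = [l for l in np.unique(labels) if l > 0 and np.any(labels == l)]
    if len(present) < 2:
        raise ValueError("need at least 2 nonempty clusters")
    if len(present) > 3:
        raise ValueError("reduction defined for at most 3 clusters")

    merged = labels.copy()
    if len(present) == 3:
        cents = {l: fm.values[labels == l].mean(axis=0) for l in present}
        pairs = [
            (np.linalg.norm(cents[a] - cents[b]), a, b)
            for i, a in enumerate(present)
            for b in present[i + 1 :]
        ]
        _, a, b = min(pairs, key=lambda t: t[0])
        merged[merged == b] = a
        present = [l for l in present if l != b]

    x_world = fm.grid.world_coordinates(fm.voxel_indices)[:, 0]
    mean_abs_x = {l: float(np.abs(x_world[merged == l]).mean()) for l in present}
    medial = min(present, key=lambda l: mean_abs_x[l])
    lateral = next(l for l in present if l != medial)

    out = np.zeros(dn_mask.grid.shape, dtype=np.int32)
    idx = fm.voxel_indices
    vox_labels = np.where(merged == lateral, 1, 2)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = vox_labels
    return LabelVolume(
        grid=dn_mask.grid, labels=out, label_names={1: "lateral", 2: "medial"}
    )


def microstructure_atlas(
    metrics: dict[str, ScalarVolume],
    dn_mask: LabelVolume,
    cfg: FCMConfig = FCMConfig(),
    iqr_k: float = 1.5,
    normalize_first: bool = True,
) -> tuple[LabelVolume, FuzzyPartition]:
    """Full chain: features -> normalise -> IQR -> FCM -> harden -> 2 clusters.

    ``normalize_first`` controls whether max-normalisation precedes
    outlier replacement (the default) or follows it.
    """
    fm = build_feature_matrix(metrics, dn_mask)
    if normalize_first:
        fm = replace_outliers_iqr(normalize_max(fm), k=iqr_k)
    else:
        fm = normalize_max(replace_outliers_iqr(fm, k=iqr_k))
    fp = fuzzy_cmeans(fm, cfg)
    labels = assign_max_membership(fp)
    atlas = reduce_to_two(labels, fm, dn_mask)
    return atlas, fp
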