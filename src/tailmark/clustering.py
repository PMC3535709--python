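"""Profile clustering: restarted K-means, tail-cluster selection, correlation
hierarchical clustering and PCA.

The K-means here is a deliberate re-creation of the classic Matlab-style
algorithm: Lloyd iterations with squared-Euclidean distance, each restart
initialized by a uniform-random choice of k distinct data rows, best restart
by inertia kept, and empty clusters repaired by reseeding with the point
farthest from its current centroid. (k-means++ is *not* used; robustness
comes from the restarts.) A seeded generator makes results reproducible.

"Tail" selection formalizes what is otherwise a visual call: the tail score
of a centroid is the mean signal over the gene-body window (default +2..+8 kb
downstream of the TSS) divided by the mean over the upstream flank (default
-10..-2 kb, which avoids the promoter's bimodal peaks), plus a small epsilon
in the denominator. A flat profile scores ~1; a gene-body-marked profile
scores well above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import cdist, pdist

from .annotations import BinGeometry
from .coverage import ProfileMatrix

__all__ = [
    "KMeansConfig",
    "ClusterResult",
    "TailScoreConfig",
    "HierarchicalResult",
    "kmeans",
    "tail_score",
    "select_tail_cluster",
    "two_stage_tail_discovery",
    "hierarchical_cluster",
    "cut_tree",
    "pca",
    "PCAResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMeansConfig:
    k: int
    repeats: int = 50
    distance: str = "squared_euclidean"
    max_iter: int = 300
    tol: float = 1e-6
    seed: int | None = None
    # single-point (online) refinement after batch convergence; "auto" enables
    # it on small problems, where batch local minima are consequential and the
    # extra passes are cheap. At metaprofile scale the 50 restarts carry the
    # robustness and the phase is skipped.
    online_phase: bool | str = "auto"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.distance != "squared_euclidean":
            raise ValueError("only squared_euclidean distance is supported")


@dataclass
class ClusterResult:
    """A flat partition with centroids and fit diagnostics."""

    labels: np.ndarray            # row -> cluster index
    centroids: np.ndarray         # k x n_features
    inertia: float                # sum of squared distances to assigned centroid
    n_iter: list[int]             # Lloyd iterations per restart
    seed_used: int | None
    row_ids: list[str] | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    @property
    def assignments(self) -> dict[str, int]:
        if self.row_ids is None:
            raise ValueError("result has no row_ids")
        return {r: int(c) for r, c in zip(self.row_ids, self.labels)}

    def members(self, cluster: int) -> list[str]:
        if self.row_ids is None:
            raise ValueError("result has no row_ids")
        return [r for r, c in zip(self.row_ids, self.labels) if c == cluster]


def _as_rows(matrix) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(matrix, ProfileMatrix):
        return np.asarray(matrix.counts, float), list(matrix.row_ids)
    X = np.asarray(matrix, float)
    return X, None


def _online_refine(X: np.ndarray, labels: np.ndarray, k: int, max_sweeps: int = 50):
    """Single-point move phase (the classic Matlab-style online update).

    Moves a point to another cluster whenever the size-weighted SSE change is
    negative, until no improving move exists. Strictly lowers the objective
    and leaves every point assigned to its nearest centroid.
    """
    n = X.shape[0]
    sizes = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, X.shape[1]))
    for c in range(k):
        if sizes[c]:
            sums[c] = X[labels == c].sum(axis=0)
    for _ in range(max_sweeps * n):
        C = sums / np.maximum(sizes, 1)[:, None]
        d2 = cdist(X, C, metric="sqeuclidean")
        own = d2[np.arange(n), labels]
        sz = sizes[labels]
        # SSE change of moving point i from its cluster to cluster b; the
        # sole member of a cluster may not leave it
        movable = sz > 1
        leave = np.zeros(n)
        leave[movable] = sz[movable] / (sz[movable] - 1) * own[movable]
        join = d2 * (sizes / (sizes + 1))[None, :]
        delta = join - leave[:, None]
        delta[~movable, :] = np.inf
        delta[np.arange(n), labels] = 0.0
        i, b = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, b] >= -1e-12:
            break
        a = labels[i]
        sums[a] -= X[i]
        sizes[a] -= 1
        sums[b] += X[i]
        sizes[b] += 1
        labels[i] = b
    return labels


def _lloyd(X: np.ndarray, init_idx: np.ndarray, max_iter: int, tol: float,
           online: bool = False):
    n, _ = X.shape
    C = X[init_idx].copy()
    k = C.shape[0]
    prev = np.inf
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = cdist(X, C, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia = d2[np.arange(n), labels].sum()
        # centroid update with deterministic farthest-point repair of empties
        newC = np.empty_like(C)
        for c in range(k):
            mask = labels == c
            if mask.any():
                newC[c] = X[mask].mean(axis=0)
        empty = [c for c in range(k) if not (labels == c).any()]
        for c in empty:
            far = d2[np.arange(n), labels].argmax()
            newC[c] = X[far]
            labels[far] = c
            d2[far, :] = np.inf  # do not pick the same point twice
            d2[far, c] = 0.0
        if empty:
            for c in range(k):  # re-average after stealing points
                mask = labels == c
                if mask.any():
                    newC[c] = X[mask].mean(axis=0)
        C = newC
        if prev - inertia <= tol * max(prev, 1e-300) and not empty:
            break
        prev = inertia
    if online:
        # single-point refinement, then recompute a consistent final state
        labels = _online_refine(X, labels, k)
        C = np.array([
            X[labels == c].mean(axis=0) if (labels == c).any() else C[c]
            for c in range(k)
        ])
    d2 = cdist(X, C, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, C, inertia, it


def kmeans(matrix, cfg: KMeansConfig) -> ClusterResult:
    """Best-of-``repeats`` restarted Lloyd K-means (squared Euclidean).

    Raises if there are fewer rows than clusters or non-finite values.
    """
    X, row_ids = _as_rows(matrix)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n = X.shape[0]
    if n < cfg.k:
        raise ValueError(f"cannot form k={cfg.k} clusters from {n} rows")
    seed = cfg.seed
    rng = np.random.default_rng(seed)
    if cfg.online_phase == "auto":
        online = n * X.shape[1] <= 100_000
    else:
        online = bool(cfg.online_phase)
    best = None
    iters: list[int] = []
    for _ in range(cfg.repeats):
        init = rng.choice(n, size=cfg.k, replace=False)
        labels, C, inertia, it = _lloyd(X, init, cfg.max_iter, cfg.tol, online)
        iters.append(it)
        if best is None or inertia < best[2]:
            best = (labels, C, inertia)
    labels, C, inertia = best
    return ClusterResult(labels, C, float(inertia), iters, seed, row_ids)


# ---------------------------------------------------------------------------
# tail scoring & two-stage discovery


@dataclass(frozen=True)
class TailScoreConfig:
    """Gene-body vs upstream-flank signal ratio windows (bp relative to TSS).

    The denominator is regularized by ``epsilon`` plus ``rel_epsilon`` times
    the centroid's overall mean. The relative term keeps the score exactly
    invariant under positive rescaling of the centroid and stops
    near-empty flanks (a handful of background reads, or none at all) from
    producing unbounded ratios that would outrank a genuine tail profile.
    """

    body_from: int = 2_000
    body_to: int = 8_000
    flank_from: int = -10_000
    flank_to: int = -2_000
    epsilon: float = 1e-9
    rel_epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if not self.body_from < self.body_to:
            raise ValueError("body_from must be < body_to")
        if not self.flank_from < self.flank_to <= 0:
            raise ValueError("require flank_from < flank_to <= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.rel_epsilon < 0:
            raise ValueError("rel_epsilon must be >= 0")


def tail_score(
    centroid: np.ndarray, geometry: BinGeometry, cfg: TailScoreConfig = TailScoreConfig()
) -> float:
    """Mean gene-body signal over mean upstream-flank signal (+ epsilon)."""
    v = np.asarray(centroid, float)
    if v.shape != (geometry.n_bins,):
        raise ValueError(
            f"centroid length {v.shape} does not match geometry ({geometry.n_bins} bins)"
        )
    blo, bhi = geometry.bin_range(cfg.body_from, cfg.body_to)
    flo, fhi = geometry.bin_range(cfg.flank_from, cfg.flank_to)
    if bhi <= blo or fhi <= flo:
        raise ValueError("degenerate (0-bin) scoring region")
    body = float(v[blo:bhi].mean())
    flank = float(v[flo:fhi].mean())
    reg = cfg.epsilon + cfg.rel_epsilon * float(np.abs(v).mean())
    return body / (flank + reg)


def select_tail_cluster(
    result: ClusterResult,
    geometry: BinGeometry,
    cfg: TailScoreConfig = TailScoreConfig(),
) -> tuple[int, np.ndarray]:
    """Centroid with the highest tail score; ties to the larger, then lower-index
    cluster. Returns (index, all per-cluster scores)."""
    scores = np.array([tail_score(c, geometry, cfg) for c in result.centroids])
    if result.k == 1:
        logger.warning("select_tail_cluster on a single-cluster result")
        return 0, scores
    sizes = result.sizes
    order = sorted(
        range(result.k), key=lambda c: (-scores[c], -sizes[c], c)
    )
    return order[0], scores


def two_stage_tail_discovery(
    matrix: ProfileMatrix,
    cfg_stage1: KMeansConfig = KMeansConfig(k=7, repeats=50),
    cfg_stage2: KMeansConfig = KMeansConfig(k=4, repeats=50),
    tail_cfg: TailScoreConfig = TailScoreConfig(),
    seed: int | None = None,
) -> tuple[list[str], ClusterResult, ClusterResult]:
    """Coarse k=7 clustering, tail-cluster pick, k=4 refinement, tail pick.

    Returns the refined tail cluster's transcript ids (the gene-body-marked
    candidate set) plus both stage results. ``seed`` overrides both configs'
    seeds (stage 2 gets ``seed + 1``) for single-knob reproducibility.
    """
    if seed is not None:
        cfg_stage1 = KMeansConfig(
            cfg_stage1.k, cfg_stage1.repeats, cfg_stage1.distance,
            cfg_stage1.max_iter, cfg_stage1.tol, seed,
        )
        cfg_stage2 = KMeansConfig(
            cfg_stage2.k, cfg_stage2.repeats, cfg_stage2.distance,
            cfg_stage2.max_iter, cfg_stage2.tol, seed + 1,
        )
    geometry = matrix.geometry
    stage1 = kmeans(matrix, cfg_stage1)
    c1, scores1 = select_tail_cluster(stage1, geometry, tail_cfg)
    members = stage1.members(c1)
    logger.info(
        "stage 1: selected cluster %d (%d rows) with tail score %.3g",
        c1, len(members), scores1[c1],
    )
    sub = matrix.subset(members)
    if len(members) < cfg_stage2.k:
        # degenerate: the coarse pass isolated fewer rows than stage 2 asks
        # clusters for; refine with what is there rather than aborting
        logger.warning(
            "stage-1 tail cluster has %d rows < k=%d; reducing stage-2 k",
            len(members), cfg_stage2.k,
        )
        cfg_stage2 = KMeansConfig(
            max(1, len(members)), cfg_stage2.repeats, cfg_stage2.distance,
            cfg_stage2.max_iter, cfg_stage2.tol, cfg_stage2.seed,
        )
    stage2 = kmeans(sub, cfg_stage2)
    c2, scores2 = select_tail_cluster(stage2, geometry, tail_cfg)
    candidates = stage2.members(c2)
    logger.info(
        "stage 2: selected cluster %d -> %d candidate genes (tail score %.3g)",
        c2, len(candidates), scores2[c2],
    )
    return candidates, stage1, stage2


# ---------------------------------------------------------------------------
# hierarchical clustering (correlation distance)


@dataclass
class HierarchicalResult:
    """Agglomerative tree over rows: scipy linkage matrix + row ids."""

    linkage: np.ndarray
    row_ids: list[str] | None = None
    labels_at_k: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.linkage.shape[0] + 1


def hierarchical_cluster(
    matrix,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> HierarchicalResult:
    """Agglomerative clustering under d(x, y) = 1 - Pearson(x, y).

    Zero-variance rows have undefined correlation and are rejected by name.
    """
    if distance != "one_minus_pearson":
        raise ValueError("only one_minus_pearson distance is supported")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    X, row_ids = _as_rows(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    var = X.var(axis=1)
    if (var == 0).any():
        bad = np.flatnonzero(var == 0)
        names = [row_ids[i] if row_ids else str(i) for i in bad[:10]]
        raise ValueError(
            f"zero-variance rows have undefined correlation distance: {names}"
        )
    d = pdist(X, metric="correlation")
    # tiny negative values from roundoff
    np.clip(d, 0.0, None, out=d)
    Z = _hier.linkage(d, method=linkage)
    return HierarchicalResult(Z, row_ids)


def cut_tree(result: HierarchicalResult, k: int) -> np.ndarray:
    """Partition into k groups by removing the k-1 highest merges.

    Group indices are relabeled in order of decreasing group size (ties by
    first occurrence). Cached on the result.
    """
    if not 1 <= k <= result.n:
        raise ValueError(f"k={k} out of range [1, {result.n}]")
    if k in result.labels_at_k:
        return result.labels_at_k[k]
    raw = _hier.cut_tree(result.linkage, n_clusters=k).ravel()
    sizes = np.bincount(raw)
    order = sorted(range(len(sizes)), key=lambda g: (-sizes[g], g))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[g] for g in raw])
    result.labels_at_k[k] = labels
    return labels


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: np.ndarray                    # n x n_components
    loadings: np.ndarray                  # n_components x n_features, orthonormal rows
    explained_variance_ratio: np.ndarray  # length n_components
    mean: np.ndarray                      # column means removed before the SVD


def pca(matrix, n_components: int) -> PCAResult:
    """PCA by SVD of the column-centered matrix (no variance scaling)."""
    X, _ = _as_rows(matrix)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n, p = X.shape
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}]")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    evr = (s ** 2) / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        scores=(U * s)[:, :n_components],
        loadings=Vt[:n_components],
        explained_variance_ratio=evr[:n_components],
        mean=mu,
    )
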