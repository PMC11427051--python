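"""Mixed-type clustering validation of firing-mode structure.

This module re-creates the unbiased validation workflow used to check manual
firing-mode assignments: Gower dissimilarity over (bursting flag, firing rate,
IEI CV), agglomerative hierarchical clustering via Lance–Williams updates with
the agglomerative coefficient, PAM (k-medoids BUILD+SWAP) and k-means
comparators, and the Dunn index plus silhouette width over k = 2..6.

All algorithms here are first-party implementations; scipy/scikit-learn serve
as independent oracles in the test suite only. Gower dissimilarity is bounded
in [0, 1] and symmetric but need not satisfy the triangle inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

FEATURE_COLUMNS = ("bursting", "rate_hz", "cv")
CATEGORICAL = ("bursting",)
CONTINUOUS = ("rate_hz", "cv")


@dataclass(frozen=True)
class FeatureVector:
    """One cell's clustering features: bursting flag plus rate and CV."""

    bursting: int
    rate_hz: float
    cv: float

    def __post_init__(self) -> None:
        if self.bursting not in (0, 1):
            raise ValueError("bursting must be 0 or 1")
        if self.rate_hz <= 0 or self.cv < 0:
            raise ValueError("rate_hz must be positive and cv non-negative")


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features[list(FEATURE_COLUMNS)].astype(float)
    if len(features) and isinstance(features[0], FeatureVector):
        return pd.DataFrame(
            [(f.bursting, f.rate_hz, f.cv) for f in features], columns=list(FEATURE_COLUMNS)
        )
    arr = np.asarray(features, dtype=float)
    return pd.DataFrame(arr, columns=list(FEATURE_COLUMNS))


def gower_matrix(features, ranges: dict[str, float] | None = None) -> np.ndarray:
    """Equal-weight Gower dissimilarity over the three clustering features.

    Categorical variables contribute a 0/1 mismatch; continuous variables
    contribute |xi - xj| / range. Ranges default to the observed max - min and
    should be computed once on the full dataset when sub-analyses reuse them.
    A zero-range continuous variable contributes 0 (with a warning).
    """
    df = _as_feature_frame(features)
    if len(df) < 2:
        raise ValueError("Gower dissimilarity needs at least two feature vectors")
    n = len(df)
    d = np.zeros((n, n))
    for col in FEATURE_COLUMNS:
        x = df[col].to_numpy()
        if col in CATEGORICAL:
            part = (x[:, None] != x[None, :]).astype(float)
        else:
            rng = (
                ranges[col]
                if ranges is not None and col in ranges
                else float(x.max() - x.min())
            )
            if rng == 0:
                warnings.warn(f"zero range for {col}; variable contributes 0 to Gower")
                part = np.zeros((n, n))
            else:
                part = np.abs(x[:, None] - x[None, :]) / rng
        d += part
    d /= len(FEATURE_COLUMNS)
    np.fill_diagonal(d, 0.0)
    return d


def encode_features(features, ranges: dict[str, float] | None = None) -> np.ndarray:
    """Numeric encoding for k-means paralleling Gower's scaling.

    Bursting stays 0/1; continuous variables are range-scaled so that one unit
    of each variable carries the same weight Gower gives it.
    """
    df = _as_feature_frame(features)
    out = np.empty((len(df), len(FEATURE_COLUMNS)))
    for j, col in enumerate(FEATURE_COLUMNS):
        x = df[col].to_numpy(dtype=float)
        if col in CATEGORICAL:
            out[:, j] = x
        else:
            rng = (
                ranges[col]
                if ranges is not None and col in ranges
                else float(x.max() - x.min())
            )
            out[:, j] = (x - x.min()) / rng if rng else 0.0
    return out


class GowerTransformer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: feature table -> square Gower dissimilarity.

    ``fit`` freezes the per-variable ranges from the training table so that
    sub-cohort transforms reuse one scaling.
    """

    def fit(self, X, y=None):
        df = _as_feature_frame(X)
        self.ranges_ = {c: float(df[c].max() - df[c].min()) for c in CONTINUOUS}
        return self

    def transform(self, X) -> np.ndarray:
        return gower_matrix(X, ranges=getattr(self, "ranges_", None))


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration record: scipy-style merge table plus linkage name.

    ``merges`` has one row (id_a, id_b, height, size) per merge; original
    points are ids 0..n-1, the t-th merge creates id n+t.
    """

    merges: np.ndarray
    n_leaves: int
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[int]:
        children: dict[int, tuple[int, int]] = {
            self.n_leaves + t: (int(r[0]), int(r[1])) for t, r in enumerate(self.merges)
        }
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                stack.append(b)
                stack.append(a)
        return order

    def to_newick(self) -> str:
        """Nested-parenthesis export with merge heights as branch lengths."""
        height_of: dict[int, float] = {i: 0.0 for i in range(self.n_leaves)}

        def node_str(node: int, parent_h: float) -> str:
            if node < self.n_leaves:
                return f"L{node}:{parent_h:.6g}"
            t = node - self.n_leaves
            a, b, h, _ = self.merges[t]
            inner = f"({node_str(int(a), h)},{node_str(int(b), h)})"
            return f"{inner}:{max(parent_h - h, 0.0):.6g}"

        t = len(self.merges) - 1
        a, b, h, _ = self.merges[t]
        return f"({node_str(int(a), h)},{node_str(int(b), h)});"


_LINKAGES = ("ward", "ward_d", "average", "complete", "single")


def hierarchical_cluster(d: np.ndarray, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering on a dissimilarity matrix via Lance–Williams.

    ``ward`` applies the Ward update to squared dissimilarities (the Ward.D2
    convention, matching scipy and R hclust ward.D2 on the same input);
    ``ward_d`` applies the same coefficients to unsquared dissimilarities.
    Merge ties break toward the lowest cluster indices.
    """
    d = _check_square(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two points to cluster")
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")

    squared = linkage == "ward"
    work = d.astype(float) ** 2 if squared else d.astype(float)
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)  # current node id per active slot
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for t in range(n - 1):
        sub = np.where(active)[0]
        block = work[np.ix_(sub, sub)]
        flat = np.argmin(block)  # first minimum -> lowest-index tie break
        i_s, j_s = divmod(flat, block.shape[1])
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = sub[i_s], sub[j_s]
        dij = work[i, j]
        height = np.sqrt(dij) if squared else dij
        merges[t] = (ids[i], ids[j], height, sizes[i] + sizes[j])

        ni, nj = sizes[i], sizes[j]
        k = active.copy()
        k[i] = k[j] = False
        dk_i, dk_j = work[k, i], work[k, j]
        if linkage in ("ward", "ward_d"):
            nk = sizes[k]
            new = ((ni + nk) * dk_i + (nj + nk) * dk_j - nk * dij) / (ni + nj + nk)
        elif linkage == "average":
            new = (ni * dk_i + nj * dk_j) / (ni + nj)
        elif linkage == "complete":
            new = np.maximum(dk_i, dk_j)
        else:  # single
            new = np.minimum(dk_i, dk_j)
        work[k, i] = new
        work[i, k] = new
        sizes[i] += sizes[j]
        active[j] = False
        ids[i] = n + t
        work[j, :] = np.inf
        work[:, j] = np.inf

    return Dendrogram(merges=merges, n_leaves=n, linkage=linkage)


def agglomerative_coefficient(dend: Dendrogram) -> float:
    """AC = mean over leaves of 1 - (first-merge height / final-merge height).

    Values near 1 indicate strong clustering structure. Defined as 0 (with a
    warning) when all points are identical (final height 0).
    """
    n = dend.n_leaves
    final = float(dend.merges[-1, 2])
    if final == 0:
        warnings.warn("all merge heights zero; agglomerative coefficient set to 0")
        return 0.0
    first = np.full(n, np.nan)
    for a, b, h, _ in dend.merges:
        for node in (int(a), int(b)):
            if node < n:
                first[node] = h
    return float(np.mean(1.0 - first / final))


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    """Partition into k clusters by undoing the last k-1 merges.

    Labels are renumbered 0..k-1 by first appearance.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b, _, _ = dend.merges[t]
        new = n + t
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


class AgglomerativeGower(ClusterMixin, BaseEstimator):
    """Hierarchical clustering estimator over a feature table or dissimilarity.

    Parameters
    ----------
    n_clusters : int, default 2
    linkage : str, default "ward"
    metric : "gower" or "precomputed"

    Fitted attributes: ``dendrogram_``, ``labels_``, ``agglomerative_coefficient_``.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "ward", metric: str = "gower"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        d = np.asarray(X, float) if self.metric == "precomputed" else gower_matrix(X)
        self.dissimilarity_ = d
        self.dendrogram_ = hierarchical_cluster(d, linkage=self.linkage)
        self.agglomerative_coefficient_ = agglomerative_coefficient(self.dendrogram_)
        self.labels_ = cut_tree(self.dendrogram_, self.n_clusters)
        return self


def pam(
    d: np.ndarray, k: int, seed: int | None = None, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a dissimilarity matrix.

    The greedy BUILD initialisation plus ``n_restarts - 1`` seeded random
    medoid sets are each refined by SWAP (best improving single medoid
    exchange until a local optimum); the lowest-objective solution wins.
    SWAP alone can stall in swap-local optima, which the extra starts escape.
    Deterministic given seed; ties break toward lower indices. Returns
    (labels, medoid indices).
    """
    d = _check_square(d)
    n = d.shape[0]
    if not 1 <= k < n + 1:
        raise ValueError("k must be in [1, n]")

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    def build() -> list[int]:
        meds = [int(np.argmin(d.sum(axis=1)))]
        while len(meds) < k:
            nearest = d[:, meds].min(axis=1)
            gains = np.array(
                [
                    np.maximum(nearest - d[:, c], 0.0).sum() if c not in meds else -np.inf
                    for c in range(n)
                ]
            )
            meds.append(int(np.argmax(gains)))
        return meds

    def swap(meds: list[int]) -> tuple[list[int], float]:
        best = objective(meds)
        improved = True
        while improved:
            improved = False
            best_swap: tuple[int, int] | None = None
            best_obj = best
            for mi in range(k):
                for c in range(n):
                    if c in meds:
                        continue
                    trial = meds.copy()
                    trial[mi] = c
                    obj = objective(trial)
                    if obj < best_obj - 1e-12:
                        best_obj = obj
                        best_swap = (mi, c)
            if best_swap is not None:
                meds[best_swap[0]] = best_swap[1]
                best = best_obj
                improved = True
        return meds, best

    rng = np.random.default_rng(seed)
    starts = [build()]
    while len(starts) < max(1, n_restarts) and k < n:
        starts.append(list(rng.choice(n, size=k, replace=False)))

    best_meds, best_obj = None, np.inf
    for start in starts:
        meds, obj = swap(start)
        if obj < best_obj - 1e-12:
            best_meds, best_obj = meds, obj
    assert best_meds is not None

    medoid_arr = np.array(sorted(best_meds))
    labels = np.argmin(d[:, medoid_arr], axis=1)
    return labels, medoid_arr


class PAMClustering(ClusterMixin, BaseEstimator):
    """k-medoids estimator over Gower or precomputed dissimilarities."""

    def __init__(self, n_clusters: int = 2, metric: str = "gower", random_state: int | None = None):
        self.n_clusters = n_clusters
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        d = np.asarray(X, float) if self.metric == "precomputed" else gower_matrix(X)
        self.labels_, self.medoid_indices_ = pam(d, self.n_clusters, self.random_state)
        return self


def kmeans(
    x: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm, best of ``n_restarts`` by within-cluster sum of squares.

    Initial centroids are distinct points drawn with the seeded generator; an
    emptied cluster is re-seeded to the point farthest from its centroid.
    Returns (labels, centroids, inertia).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n]")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
        for _ in range(max_iter):
            d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            labels = np.argmin(d2, axis=1)
            new_centroids = centroids.copy()
            for j in range(k):
                members = labels == j
                if members.any():
                    new_centroids[j] = x[members].mean(axis=0)
                else:
                    far = int(np.argmax(d2.min(axis=1)))
                    new_centroids[j] = x[far]
            if np.allclose(new_centroids, centroids):
                centroids = new_centroids
                break
            centroids = new_centroids
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centroids, inertia)
    assert best is not None
    return best


class MixedKMeans(ClusterMixin, BaseEstimator):
    """k-means on Gower-parallel numeric encoding of the mixed feature table."""

    def __init__(self, n_clusters: int = 2, random_state: int | None = None, n_restarts: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        enc = encode_features(X)
        self.labels_, self.cluster_centers_, self.inertia_ = kmeans(
            enc, self.n_clusters, seed=self.random_state, n_restarts=self.n_restarts
        )
        return self


def silhouette(d: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean silhouette width and per-point s(i) on a dissimilarity matrix.

    s(i) = (b - a) / max(a, b) with a the mean within-cluster dissimilarity
    (excluding self) and b the smallest mean dissimilarity to another cluster.
    Points in singleton clusters get s(i) = 0.
    """
    d = _check_square(d)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = d.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean()), s


def dunn_index(d: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster dissimilarity over maximum cluster diameter.

    Singleton clusters have no diameter; if every cluster is a singleton the
    index is undefined and an error is raised.
    """
    d = _check_square(d)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn index requires at least two clusters")
    min_between = np.inf
    for ai, a in enumerate(uniq):
        for b in uniq[ai + 1 :]:
            min_between = min(min_between, d[np.ix_(labels == a, labels == b)].min())
    diameters = [
        d[np.ix_(labels == c, labels == c)].max()
        for c in uniq
        if (labels == c).sum() > 1
    ]
    if not diameters:
        raise ValueError("all clusters are singletons; Dunn index undefined")
    max_diam = max(diameters)
    if max_diam == 0:
        return np.inf if min_between > 0 else 0.0
    return float(min_between / max_diam)


@dataclass(frozen=True)
class ValidationEntry:
    method: str
    k: int
    labels: np.ndarray
    dunn: float
    mean_silhouette: float
    degenerate: bool = False


@dataclass(frozen=True)
class ValidationReport:
    """Internal-validation grid over clustering methods and k = 2..6."""

    entries: list[ValidationEntry]
    agglomerative_coefficient: float

    def best(self, index: str = "mean_silhouette") -> ValidationEntry:
        valid = [e for e in self.entries if not e.degenerate]
        return max(valid, key=lambda e: getattr(e, index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": e.method,
                    "k": e.k,
                    "dunn": e.dunn,
                    "mean_silhouette": e.mean_silhouette,
                    "degenerate": e.degenerate,
                }
                for e in self.entries
            ]
        )


def validation_scan(
    features,
    methods: tuple[str, ...] = ("hierarchical", "pam", "kmeans"),
    k_range: range = range(2, 7),
    linkage: str = "ward",
    seed: int | None = 0,
) -> ValidationReport:
    """Dunn index and silhouette for every (method, k) combination.

    All indices are evaluated on the one Gower dissimilarity matrix (k-means
    clusters on the parallel numeric encoding but is scored on Gower, as
    mixed-data validation toolchains do).
    """
    d = gower_matrix(features)
    dend = hierarchical_cluster(d, linkage=linkage)
    ac = agglomerative_coefficient(dend)
    enc = encode_features(features)

    entries: list[ValidationEntry] = []
    for method in methods:
        for k in k_range:
            if method == "hierarchical":
                labels = cut_tree(dend, k)
            elif method == "pam":
                labels, _ = pam(d, k, seed)
            elif method == "kmeans":
                labels, _, _ = kmeans(enc, k, seed=seed)
            else:
                raise ValueError(f"unknown method {method!r}")
            degenerate = np.unique(labels).size < k
            if degenerate:
                entries.append(ValidationEntry(method, k, labels, np.nan, np.nan, True))
                continue
            try:
                dn = dunn_index(d, labels)
            except ValueError:
                dn = np.nan
            sil, _ = silhouette(d, labels)
            entries.append(ValidationEntry(method, k, labels, dn, sil))
    return ValidationReport(entries=entries, agglomerative_coefficient=ac)
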