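"""Similarity-network-fusion affinity construction, spectral clustering, and
silhouette-based model selection.

Subjects are compared by the squared Euclidean distance between their
edge-score profiles.  Distances become affinities through a scaled
exponential kernel whose bandwidth adapts to each pair's K-nearest-neighbour
context:

    eps_ij = (mean_d(i, KNN_i) + mean_d(j, KNN_j) + d_ij) / 3
    W_ij   = exp(-d_ij / (mu * eps_ij))

``mu`` scales the kernel width; larger values make the affinity graph denser.
When several data views are available their affinities are merged by the
cross-diffusion update of similarity network fusion (SNF): each view's
full-kernel matrix P is repeatedly propagated through the other views' local
K-nearest-neighbour kernels S,

    P_v  <-  S_v . mean_{u != v}(P_u) . S_v^T,

then the fused matrix is the average of the diffused views.  With a single
view (the edge-score matrix alone) fusion reduces to the full-kernel
normalization of that view's affinity.

Clusters come from spectral clustering on the fused affinity (symmetric
normalized Laplacian, row-normalized eigenvector embedding, seeded k-means),
and the number of clusters / mu are chosen by grid search on a silhouette
index adapted to similarities: the affinity is converted to a dissimilarity
by D' = max(A) - A (zero diagonal) and the standard per-sample silhouette is
averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)


@dataclass
class SNFConfig:
    """Hyperparameters for affinity construction and model selection.

    K defaults to n_subjects / 10 (rounded) when left as None, the rule of
    thumb for the neighbour count.  The mu grid spans 0.2-0.8 in steps of
    0.1 and candidate cluster counts 2-10.
    """

    K: int | None = None
    mu: float = 0.5
    t_iterations: int = 20
    cluster_range: tuple[int, ...] = tuple(range(2, 11))
    mu_grid: tuple[float, ...] = tuple(np.round(np.arange(0.2, 0.81, 0.1), 1))
    seed: int = 0
    kmeans_restarts: int = 100
    #: affinity kernel dialect; the density-adaptive form is the reference
    #: implementation's convention and the pipeline default
    kernel: str = "density"
    #: which silhouette ranks the grid: "feature" evaluates every partition
    #: on the shared feature-space distances (comparable across mu);
    #: "affinity" uses each grid point's own affinity silhouette
    selection: str = "feature"

    def resolve_K(self, n: int) -> int:
        K = self.K if self.K is not None else int(round(n / 10))
        K = max(1, min(K, n - 1))
        return K

    def validate(self, n: int) -> None:
        K = self.resolve_K(n)
        if not 1 <= K < n:
            raise ValueError(f"K={K} out of range for n={n}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for k in self.cluster_range:
            if not 2 <= k <= n - 1:
                raise ValueError(f"cluster count {k} outside [2, n-1]")


@dataclass
class ClusteringSolution:
    """Labels plus hyperparameters and quality scores for one grid point.

    ``silhouette`` is the similarity-adapted silhouette on the grid point's
    own affinity (the quantity the clustering literature reports for fused
    networks).  ``feature_silhouette`` is the standard silhouette evaluated
    on the mu-independent feature-space distances; because it does not
    depend on the kernel bandwidth it is the score used to rank solutions
    across the grid (``rank_value``).
    """

    labels: np.ndarray
    n_clusters: int
    mu: float
    silhouette: float
    K: int = 0
    feature_silhouette: float = float("nan")

    @property
    def rank_value(self) -> float:
        if np.isfinite(self.feature_silhouette):
            return self.feature_silhouette
        return self.silhouette

    def to_dict(self) -> dict:
        return {
            "n_clusters": int(self.n_clusters),
            "mu": float(self.mu),
            "K": int(self.K),
            "silhouette": float(self.silhouette),
            "feature_silhouette": float(self.feature_silhouette),
            "labels": [int(x) for x in self.labels],
        }


# ---------------------------------------------------------------------------
# Distances and affinities
# ---------------------------------------------------------------------------

def squared_euclidean_distances(features) -> np.ndarray:
    """Pairwise squared Euclidean distances between subject rows."""
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(features, dtype=float)
    if np.isnan(X).any():
        if hasattr(features, "columns"):
            bad = [
                c for c, col in zip(features.columns, X.T) if np.isnan(col).any()
            ]
            raise ValueError(f"missing values in feature columns: {bad}")
        raise ValueError("missing values in feature matrix")
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def snf_affinity(
    D: np.ndarray, K: int, mu: float, kernel: str = "exp"
) -> np.ndarray:
    """Scaled exponential kernel with KNN-adaptive bandwidth.

    eps_ij averages each sample's mean distance to its K nearest neighbours
    (self excluded) with the pair distance itself; zero eps falls back to
    machine epsilon with a warning.

    Two kernel dialects share the adaptive bandwidth:

    * ``"exp"`` — W_ij = exp(-D_ij / (mu * eps_ij)), the original SNF
      publication's form (default for this operation);
    * ``"density"`` — the Gaussian density N(D_ij; 0, mu * eps_ij), the
      convention of the widely used Python SNF implementation.  Its
      1/(mu * eps) prefactor is density-adaptive: pairs in locally tight
      neighbourhoods get boosted affinity, which markedly improves the
      recovery of small dense clusters, so the clustering pipeline defaults
      to it.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 1 <= K < n:
        raise ValueError(f"K={K} out of range for n={n}")
    if mu <= 0:
        raise ValueError("mu must be positive")
    Dsort = np.sort(D, axis=1)
    # column 0 is the zero self-distance; K nearest neighbours are cols 1..K
    knn_mean = Dsort[:, 1 : K + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + D) / 3.0
    zero = eps <= 0
    if zero.any():
        logger.warning("%d zero-bandwidth pairs; machine epsilon substituted",
                       int(zero.sum()))
        eps[zero] = np.finfo(float).eps
    if kernel == "exp":
        W = np.exp(-D / (mu * eps))
    elif kernel == "density":
        scale = mu * eps
        W = np.exp(-(D * D) / (2.0 * scale * scale)) / (
            np.sqrt(2.0 * np.pi) * scale
        )
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    W = (W + W.T) / 2.0
    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite affinity values")
    return W


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalization P: diagonal 1/2, off-diagonal W_ij / (2 sum_{k!=i} W_ik).

    Rows sum to 1, and the half mass on the diagonal keeps the diffusion
    numerically stable (original SNF convention).
    """
    W = np.asarray(W, dtype=float)
    P = W.copy()
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized K-nearest-neighbour mask of the affinity (local kernel S)."""
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf
        nbrs = np.argpartition(w, -K)[-K:]
        S[i, nbrs] = W[i, nbrs]
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def snf_fuse(
    views: list[np.ndarray], K: int, t: int = 20
) -> np.ndarray:
    """Fuse one or more affinity matrices by cross-diffusion.

    A single view returns its full-kernel normalization unchanged.  With
    multiple views, each view's P matrix is updated for ``t`` iterations as
    S_v . mean(other P) . S_v^T, renormalized and symmetrized each step, and
    the fused affinity is the symmetrized average of the final P matrices.
    """
    if not views:
        raise ValueError("no views to fuse")
    n = views[0].shape[0]
    for V in views:
        if V.shape != (n, n):
            raise ValueError("all views must share dimensions")
    if len(views) == 1:
        P = _full_kernel(views[0])
        return (P + P.T) / 2.0
    P = [_full_kernel(V) for V in views]
    S = [_knn_kernel(V, K) for V in views]
    m = len(views)
    for _ in range(t):
        P_next = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = _full_kernel((Pv + Pv.T) / 2.0)
            P_next.append(Pv)
        P = P_next
    fused = sum(P) / m
    return (fused + fused.T) / 2.0


# ---------------------------------------------------------------------------
# Spectral clustering and silhouette
# ---------------------------------------------------------------------------

def spectral_clustering(A: np.ndarray, k: int, seed: int = 0,
                        restarts: int = 100) -> np.ndarray:
    """Cluster an affinity matrix into k groups.

    Embedding: eigenvectors of the k smallest eigenvalues of the symmetric
    normalized Laplacian I - D^{-1/2} A D^{-1/2}, rescaled by D^{-1/2} to
    the random-walk (diffusion-map) coordinates, partitioned by k-means with
    ``restarts`` seeded restarts.  The degree rescaling keeps small,
    tight clusters from being absorbed by large diffuse ones.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k < 2:
        raise ValueError("need at least 2 clusters")
    d = A.sum(axis=1)
    d[d <= 0] = np.finfo(float).eps
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -(A * inv_sqrt[:, None]) * inv_sqrt[None, :]
    L[np.diag_indices(n)] += 1.0
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    emb = vecs * inv_sqrt[:, None]
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(emb)


def similarity_silhouette_samples(
    A: np.ndarray, labels, method: str = "similarity"
) -> np.ndarray:
    """Per-sample silhouette adapted to a similarity (affinity) matrix.

    ``method="similarity"`` (default) swaps the roles of cohesion and
    separation directly on the affinities: a_i is the mean affinity of i to
    its own cluster (self excluded), b_i the largest mean affinity to any
    other cluster, and s_i = (a_i - b_i) / max(a_i, b_i).  This form is
    invariant to rescaling A -> c*A, so values are comparable across kernel
    bandwidths.  ``method="max_shift"`` converts to a dissimilarity
    D' = max_offdiag(A) - A and runs the standard silhouette;
    ``method="relative"`` uses D' = 1 - A / max_offdiag(A) (identical
    silhouettes to max_shift up to the positive scale factor).
    Singleton clusters score 0 (standard convention).
    """
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if method in ("max_shift", "relative"):
        Dp = similarity_to_dissimilarity(A, relative=(method == "relative"))
        return silhouette_samples(Dp, labels, metric="precomputed")
    if method != "similarity":
        raise ValueError(f"unknown silhouette method {method!r}")
    n = len(labels)
    clusters = np.unique(labels)
    out = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = labels == own
        same[i] = False
        if not same.any():
            continue  # singleton
        a = A[i][same].mean()
        b = max(A[i][labels == c].mean() for c in clusters if c != own)
        denom = max(a, b)
        out[i] = (a - b) / denom if denom > 0 else 0.0
    return out


def similarity_silhouette(
    A: np.ndarray, labels, method: str = "similarity"
) -> float:
    """Mean similarity-adapted silhouette over samples (see samples variant)."""
    return float(np.mean(similarity_silhouette_samples(A, labels, method)))


def similarity_to_dissimilarity(A: np.ndarray, relative: bool = False) -> np.ndarray:
    """Convert an affinity to a dissimilarity matrix with zero diagonal.

    Default is the max-shift D' = max(A) - A; ``relative=True`` uses the
    scale-free alternative 1 - A / max(A).
    """
    A = np.asarray(A, dtype=float)
    off = ~np.eye(A.shape[0], dtype=bool)
    # the reference point is the largest between-subject similarity: the
    # diagonal (self-similarity, 1/2 under the full-kernel normalization)
    # is on a different scale and is zeroed anyway
    amax = A[off].max()
    if relative:
        Dp = 1.0 - A / (amax if amax > 0 else 1.0)
    else:
        Dp = amax - A
    np.fill_diagonal(Dp, 0.0)
    np.maximum(Dp, 0.0, out=Dp)
    return (Dp + Dp.T) / 2.0


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def cluster_edge_scores(
    features, k: int, mu: float, K: int | None = None, seed: int = 0,
    t_iterations: int = 20, restarts: int = 100, kernel: str = "density",
) -> ClusteringSolution:
    """One grid point: affinity -> fusion normalization -> spectral clustering."""
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(features, float)
    n = X.shape[0]
    Kr = int(round(n / 10)) if K is None else K
    Kr = max(1, min(Kr, n - 1))
    D = squared_euclidean_distances(X)
    W = snf_affinity(D, Kr, mu, kernel=kernel)
    A = snf_fuse([W], Kr, t_iterations)
    labels = spectral_clustering(A, k, seed=seed, restarts=restarts)
    si = similarity_silhouette(A, labels)
    return ClusteringSolution(labels=labels, n_clusters=k, mu=mu,
                              silhouette=si, K=Kr)


def model_selection_grid(features, cfg: SNFConfig) -> list[ClusteringSolution]:
    """Evaluate every (mu, k) grid point at fixed K; rank by silhouette.

    Returns all solutions sorted by silhouette descending, ties broken by
    smaller k.  The caller chooses the working solution: when the top two
    silhouettes are close the smaller-SI solution may be preferred for
    interpretability, so the ranking is reported rather than auto-picked.
    """
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(features, float)
    n = X.shape[0]
    cfg.validate(n)
    if not cfg.mu_grid or not cfg.cluster_range:
        raise ValueError("empty hyperparameter grid")
    if cfg.selection not in ("feature", "affinity"):
        raise ValueError(f"unknown selection metric {cfg.selection!r}")
    K = cfg.resolve_K(n)
    D = squared_euclidean_distances(X)
    solutions: list[ClusteringSolution] = []
    for mu in cfg.mu_grid:
        W = snf_affinity(D, K, float(mu), kernel=cfg.kernel)
        A = snf_fuse([W], K, cfg.t_iterations)
        for k in cfg.cluster_range:
            try:
                labels = spectral_clustering(
                    A, k, seed=cfg.seed, restarts=cfg.kmeans_restarts
                )
                si = similarity_silhouette(A, labels)
                fsi = float(np.mean(
                    silhouette_samples(D, labels, metric="precomputed")
                )) if cfg.selection == "feature" else float("nan")
            except (ValueError, FloatingPointError) as exc:
                logger.warning("grid point (mu=%.2f, k=%d) failed: %s",
                               mu, k, exc)
                continue
            solutions.append(
                ClusteringSolution(labels=labels, n_clusters=k,
                                   mu=float(mu), silhouette=si, K=K,
                                   feature_silhouette=fsi)
            )
    if not solutions:
        raise RuntimeError("all grid points degenerate: no clustering solution")
    solutions.sort(key=lambda s: (-s.rank_value, s.n_clusters))
    return solutions


def best_per_cluster_count(
    solutions: list[ClusteringSolution],
) -> list[ClusteringSolution]:
    """Best-ranked solution for each distinct cluster count, ranked.

    This is the reporting form of the grid search: one line per candidate k,
    ranked by that k's best score over the mu grid (feature-distance
    silhouette when available, affinity silhouette otherwise).
    """
    best: dict[int, ClusteringSolution] = {}
    for s in solutions:
        cur = best.get(s.n_clusters)
        if cur is None or s.rank_value > cur.rank_value:
            best[s.n_clusters] = s
    return sorted(best.values(), key=lambda s: (-s.rank_value, s.n_clusters))


def drop_constant_columns(features: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance feature columns before distance computation."""
    constant = features.columns[features.nunique(axis=0) <= 1]
    if len(constant):
        logger.warning("dropping %d constant feature columns", len(constant))
        return features.drop(columns=list(constant))
    return features
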