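"""SC3-style consensus clustering with silhouette-driven model selection.

The scheme combines many base k-means solutions: three sample-sample
distances (Euclidean, Pearson, Spearman), two spectral transformations (PCA
and normalized graph Laplacian), and a small range of embedding dimensions
(4%–7% of the sample count).  Each solution votes on sample co-membership;
the consensus matrix of vote fractions is then cut by complete-linkage
hierarchical clustering into k groups, and the mean silhouette width under
the 1−consensus distance scores the solution.

`ConsensusCluster` fits one (k) setting; `ConsensusGrid` searches a grid of
(number of highly variable genes, k) and picks the silhouette argmax, with
an explicit override for forcing k (subtype count is sometimes fixed on
clinical rather than purely statistical grounds).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import ValidationError
from .qc import log2cpm, select_hvg

DISTANCE_METRICS = ("euclidean", "pearson", "spearman")
TRANSFORMS = ("pca", "laplacian")


def compute_distances(X, metrics=DISTANCE_METRICS) -> dict[str, np.ndarray]:
    """Sample-sample distance matrices from a samples×features matrix.

    Correlation distances are 1−r (Pearson on values or on ranks for
    Spearman); all outputs are symmetric with a zero diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to compute distances")
    out: dict[str, np.ndarray] = {}
    if any(m in metrics for m in ("pearson", "spearman")):
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)[0]
            raise ValidationError(
                f"sample at position {bad} has zero variance; correlation "
                "distance undefined")
    for m in metrics:
        if m == "euclidean":
            D = ssd.squareform(ssd.pdist(X, metric="euclidean"))
        elif m == "pearson":
            D = 1.0 - np.corrcoef(X)
        elif m == "spearman":
            ranks = scipy.stats.rankdata(X, axis=1)
            D = 1.0 - np.corrcoef(ranks)
        else:
            raise ValidationError(f"unknown distance metric {m!r}")
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        out[m] = D
    return out


def _fix_signs(E: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    E = E.copy()
    for j in range(E.shape[1]):
        i = np.argmax(np.abs(E[:, j]))
        if E[i, j] < 0:
            E[:, j] = -E[:, j]
    return E


def transform_distance(D: np.ndarray, method: str, d: int) -> np.ndarray:
    """Embed a distance matrix in d dimensions by PCA or Laplacian eigenmaps.

    PCA treats D as a samples×samples feature matrix (columns centered);
    the Laplacian route uses the symmetric normalized graph Laplacian of the
    affinity A = exp(−D / max(D)) and keeps the eigenvectors of the d
    smallest non-trivial eigenvalues (the constant top eigenvector is
    dropped).  Column signs are fixed deterministically.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= d < n:
        raise ValidationError(f"embedding dimension d={d} out of range [1, {n - 1}]")
    if method == "pca":
        if np.allclose(D, 0):
            return np.zeros((n, d))
        emb = PCA(n_components=d, svd_solver="full").fit_transform(D)
    elif method == "laplacian":
        dmax = D.max()
        A = np.exp(-D / dmax) if dmax > 0 else np.ones_like(D)
        deg = A.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(deg)
        L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
        eigvals, eigvecs = np.linalg.eigh(L)
        # drop the trivial (near-constant) smallest eigenvector: it carries
        # no partition information and degrades low-d embeddings
        emb = eigvecs[:, 1:d + 1]
    else:
        raise ValidationError(f"unknown transform {method!r}")
    return _fix_signs(emb)


def _d_range(n_samples: int, d_fracs: tuple[float, float]) -> range:
    lo = max(1, math.ceil(d_fracs[0] * n_samples))
    hi = max(lo, math.floor(d_fracs[1] * n_samples))
    hi = min(hi, n_samples - 1)
    lo = min(lo, hi)
    return range(lo, hi + 1)


def _renumber(labels: np.ndarray, sample_ids: list) -> np.ndarray:
    """Renumber cluster ids 1..k by decreasing size, ties by the
    lexicographically smallest member sample id."""
    order = []
    for c in np.unique(labels):
        members = [str(sample_ids[i]) for i in np.flatnonzero(labels == c)]
        order.append((-len(members), min(members), c))
    mapping = {c: i + 1 for i, (_, _, c) in enumerate(sorted(order))}
    return np.array([mapping[c] for c in labels])


class ConsensusCluster(ClusterMixin, BaseEstimator):
    """Consensus clustering of samples at a fixed cluster count k.

    Parameters
    ----------
    k : number of clusters.
    d_fracs : fractions of the sample count spanning the embedding
        dimensions used for the base clusterings.
    metrics, transforms : distance metrics and spectral transforms combined.
    n_init, max_iter : k-means restarts and iteration cap per base solution.
    random_state : seeds every base k-means run.

    Attributes (after ``fit``)
    --------------------------
    consensus_ : samples×samples co-clustering fraction matrix (diag 1).
    labels_ : final cluster ids in {1..k}, renumbered by decreasing size.
    silhouette_ : mean silhouette width under the 1−consensus distance.
    n_solutions_ : number of base clusterings combined.
    """

    def __init__(self, k: int = 4, d_fracs: tuple[float, float] = (0.04, 0.07),
                 metrics: tuple[str, ...] = DISTANCE_METRICS,
                 transforms: tuple[str, ...] = TRANSFORMS,
                 n_init: int = 10, max_iter: int = 300, random_state: int = 0):
        self.k = k
        self.d_fracs = d_fracs
        self.metrics = metrics
        self.transforms = transforms
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a samples×features matrix (DataFrame index = sample ids)."""
        if isinstance(X, pd.DataFrame):
            sample_ids = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            sample_ids = list(range(values.shape[0]))
        n = values.shape[0]
        if self.k < 2:
            raise ValidationError(f"k must be >=2, got {self.k}")
        if self.k > n:
            raise ValidationError(f"k={self.k} exceeds sample count {n}")

        distances = compute_distances(values, self.metrics)
        ds = list(_d_range(n, self.d_fracs))
        seeds = np.random.default_rng(self.random_state).integers(
            0, 2**31 - 1, size=len(distances) * len(self.transforms) * len(ds))

        co = np.zeros((n, n))
        n_solutions = 0
        si = 0
        for m in self.metrics:
            for tr in self.transforms:
                for d in ds:
                    emb = transform_distance(distances[m], tr, d)
                    km = KMeans(n_clusters=self.k, n_init=self.n_init,
                                max_iter=self.max_iter,
                                random_state=int(seeds[si]))
                    lab = km.fit_predict(emb)
                    co += lab[:, None] == lab[None, :]
                    n_solutions += 1
                    si += 1
        consensus = co / n_solutions
        np.fill_diagonal(consensus, 1.0)

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        link = sch.linkage(ssd.squareform(dist, checks=False), method="complete")
        raw = sch.fcluster(link, t=self.k, criterion="maxclust")
        labels = _renumber(raw, sample_ids)

        if len(np.unique(labels)) >= 2:
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        else:
            sil = -1.0  # degenerate single-cluster cut

        self.sample_ids_ = sample_ids
        self.consensus_ = consensus
        self.labels_ = labels
        self.silhouette_ = sil
        self.n_solutions_ = n_solutions
        return self

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.sample_ids_, name="cluster")


class ConsensusGrid(BaseEstimator):
    """Grid search over (number of HVGs, k) scored by mean silhouette.

    ``fit`` takes a genes×samples CPM matrix restricted to the samples to
    cluster; for each n it selects the top-n variable genes, log-transforms,
    and runs `ConsensusCluster` for each k.  The chosen point is the
    silhouette argmax unless ``force_k`` pins the cluster count.

    Attributes: ``results_`` (one row per grid point), ``best_n_``,
    ``best_k_``, ``best_model_``, ``labels_``.
    """

    def __init__(self, n_grid=(2500, 3000, 3500, 4000, 4500, 5000),
                 k_grid=tuple(range(2, 9)), d_fracs=(0.04, 0.07),
                 force_k: int | None = None, random_state: int = 0):
        self.n_grid = n_grid
        self.k_grid = k_grid
        self.d_fracs = d_fracs
        self.force_k = force_k
        self.random_state = random_state

    def fit(self, expr: pd.DataFrame, y=None):
        if len(self.n_grid) == 0 or len(self.k_grid) == 0:
            raise ValidationError("empty grid")
        if max(self.n_grid) > expr.shape[0]:
            raise ValidationError(
                f"n_grid max {max(self.n_grid)} exceeds gene count {expr.shape[0]}")
        if self.force_k is not None and self.force_k not in self.k_grid:
            raise ValidationError(
                f"force_k={self.force_k} not in k_grid {tuple(self.k_grid)}")
        rows = []
        models: dict[tuple[int, int], ConsensusCluster] = {}
        seeds = np.random.default_rng(self.random_state).integers(
            0, 2**31 - 1, size=len(self.n_grid) * len(self.k_grid))
        si = 0
        for n in self.n_grid:
            hvg = select_hvg(expr, n)
            X = log2cpm(hvg).T
            for k in self.k_grid:
                model = ConsensusCluster(k=k, d_fracs=self.d_fracs,
                                         random_state=int(seeds[si])).fit(X)
                si += 1
                models[(n, k)] = model
                sizes = pd.Series(model.labels_).value_counts().sort_index()
                rows.append({"n_hvg": n, "k": k,
                             "silhouette": model.silhouette_,
                             "cluster_sizes": "/".join(map(str, sizes))})
        results = pd.DataFrame(rows)
        pool = results if self.force_k is None else results[results["k"] == self.force_k]
        # argmax silhouette; ties resolved toward smaller k, then smaller n
        best = pool.sort_values(["silhouette", "k", "n_hvg"],
                                ascending=[False, True, True]).iloc[0]
        self.results_ = results
        self.best_n_ = int(best["n_hvg"])
        self.best_k_ = int(best["k"])
        self.best_model_ = models[(self.best_n_, self.best_k_)]
        self.labels_ = self.best_model_.labels_series()
        return self


def consensus_cluster(X, k: int, d_fracs=(0.04, 0.07), seed: int = 0) -> ConsensusCluster:
    """Functional wrapper: consensus-cluster a samples×features matrix."""
    return ConsensusCluster(k=k, d_fracs=d_fracs, random_state=seed).fit(X)


def grid_search(expr: pd.DataFrame, n_grid=(2500, 3000, 3500, 4000, 4500, 5000),
                k_grid=tuple(range(2, 9)), seed: int = 0,
                force_k: int | None = None) -> ConsensusGrid:
    """Functional wrapper: silhouette grid search on a genes×samples CPM matrix."""
    return ConsensusGrid(n_grid=n_grid, k_grid=k_grid, force_k=force_k,
                         random_state=seed).fit(expr)
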