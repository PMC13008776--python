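"""Cluster-then-binarize cell phenotyping.

Each marker is treated as an independent input: cells are clustered
unsupervised on that stain's intensity statistics plus shared morphology
(after z-scoring and PCA to 90% explained variance), then a reviewer marks
whole clusters positive or negative for the marker — with optional
hierarchical "reclassification" of a mixed cluster into subtiers ("3" ->
"3.0", "3.1", ...) and per-cell manual overrides. The fast path uses
mini-batch k-means; an alternative path fits a battery of Gaussian mixture
models on a subsample embedded with UMAP and merges their component means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

MORPHOLOGY_COLUMNS = ("area_px", "perimeter_px", "major_px", "minor_px",
                      "eccentricity")


# ---------------------------------------------------------------------------
# tiers and binarization decisions
# ---------------------------------------------------------------------------

@dataclass
class ClusterTier:
    """Hierarchical cluster assignment for one marker.

    ``paths[i]`` is cell i's deepest path, e.g. "3" or "3.2" after one
    reclassification (components are 0-based cluster labels). Child paths
    partition their parent's cells by construction.
    """

    marker: str
    paths: np.ndarray  # dtype=object/str per cell

    def __post_init__(self) -> None:
        self.paths = np.asarray(self.paths, dtype=object)

    @property
    def unique_paths(self) -> list[str]:
        return sorted(set(self.paths))

    def members(self, path: str) -> np.ndarray:
        """Indices of cells at ``path`` or any of its descendants."""
        prefix = path + "."
        return np.nonzero([p == path or str(p).startswith(prefix)
                           for p in self.paths])[0]


@dataclass
class BinarizationDecision:
    """Reviewer decision: which tier paths are positive, plus overrides."""

    marker: str
    positive_paths: set = field(default_factory=set)
    overrides: dict = field(default_factory=dict)  # cell index -> bool


# ---------------------------------------------------------------------------
# dimensionality reduction and clustering
# ---------------------------------------------------------------------------

@dataclass
class PCAReduction:
    components: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    kept_columns: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (x[:, self.kept_columns] - self.mean) / self.scale
        return z @ self.components.T


def reduce_features_pca(x: np.ndarray, var_target: float = 0.90
                        ) -> tuple[np.ndarray, PCAReduction]:
    """Z-score features, then keep principal components until the
    cumulative explained variance reaches ``var_target``.

    Zero-variance features are dropped with a warning (they carry no
    clustering signal and break z-scoring).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    std = x.std(axis=0)
    keep = np.nonzero(std > 1e-12)[0]
    if len(keep) < x.shape[1]:
        warnings.warn(f"dropping {x.shape[1] - len(keep)} zero-variance features")
    if len(keep) == 0:
        raise ValueError("all features are constant")
    xs = x[:, keep]
    mean, scale = xs.mean(axis=0), xs.std(axis=0)
    z = (xs - mean) / scale
    pca = PCA(n_components=min(z.shape[0] - 1, z.shape[1]), svd_solver="full")
    zz = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    n_comp = min(n_comp, zz.shape[1])
    red = PCAReduction(components=pca.components_[:n_comp], mean=mean,
                       scale=scale, kept_columns=keep,
                       explained_variance_ratio=pca.explained_variance_ratio_[:n_comp])
    return zz[:, :n_comp], red


def cluster_minibatch_kmeans(x: np.ndarray, k: int, seed: int = 0,
                             batch_size: int = 1024, max_iter: int = 100
                             ) -> np.ndarray:
    """Mini-batch k-means labels (0..k-1); deterministic given the seed."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k < 1 or k > x.shape[0]:
        raise ValueError(f"k={k} out of range for n={x.shape[0]}")
    if k == 1:
        return np.zeros(x.shape[0], dtype=int)
    km = MiniBatchKMeans(n_clusters=k, random_state=seed,
                         batch_size=batch_size, max_iter=max_iter,
                         n_init=3, init="k-means++")
    return km.fit_predict(x)


def initial_tier(marker: str, labels: np.ndarray) -> ClusterTier:
    return ClusterTier(marker=marker,
                       paths=np.array([str(int(l)) for l in labels],
                                      dtype=object))


def reclassify_cluster(x: np.ndarray, tier: ClusterTier, parent_path: str,
                       k_sub: int, seed: int = 0) -> ClusterTier:
    """Re-cluster one tier's cells into subtiers "parent.s".

    Only the parent's members move; every other cell keeps its path. Full
    k-means is used here — reclassification targets one (small) cluster.
    """
    idx = tier.members(parent_path)
    if len(idx) == 0:
        raise ValueError(f"tier {parent_path!r} is empty or unknown")
    if k_sub > len(idx):
        raise ValueError(f"k_sub={k_sub} exceeds {len(idx)} member cells")
    x = np.asarray(x, dtype=float)
    if k_sub == 1:
        sub = np.zeros(len(idx), dtype=int)
    else:
        km = KMeans(n_clusters=k_sub, random_state=seed, n_init=10)
        sub = km.fit_predict(x[idx])
    paths = tier.paths.copy()
    for i, s in zip(idx, sub):
        paths[i] = f"{parent_path}.{int(s)}"
    return ClusterTier(marker=tier.marker, paths=paths)


def cluster_gmm_alternative(x: np.ndarray, k_final: int, seed: int = 0,
                            n_sample: int = 50_000, max_models: int = 60,
                            umap_neighbors: int = 15,
                            umap_min_dist: float = 0.1,
                            pca_var: float = 0.90) -> np.ndarray:
    """Batched-GMM clustering for smaller cohorts.

    A random sample of up to ``n_sample`` cells is PCA-reduced, embedded in
    2-D with UMAP (pinned parameters), and split into up to ``max_models``
    batches (~833 cells each); each batch fits a ``k_final``-component GMM
    seeded from shared k-means++ centroids. All component means are pooled,
    z-scored per feature and merged by k-means into ``k_final`` final
    centroids. Unsampled cells inherit the label of their nearest sampled
    neighbour in PCA space.
    """
    import umap  # deferred: numba compilation is expensive at import time

    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < k_final:
        raise ValueError(f"k_final={k_final} exceeds n={n}")
    rng = np.random.default_rng(seed)
    if n <= n_sample:
        sample_idx = np.arange(n)
        if n < n_sample:
            warnings.warn(f"n={n} < {n_sample}: single-batch GMM path")
    else:
        sample_idx = rng.choice(n, size=n_sample, replace=False)
    zs, red = reduce_features_pca(x[sample_idx], var_target=pca_var)
    emb = umap.UMAP(n_neighbors=min(umap_neighbors, len(sample_idx) - 1),
                    min_dist=umap_min_dist, n_components=2,
                    random_state=seed).fit_transform(zs)
    n_batches = max(1, min(max_models, int(np.ceil(len(sample_idx) / 833))))
    order = rng.permutation(len(sample_idx))
    batches = np.array_split(order, n_batches)
    seed_km = KMeans(n_clusters=k_final, random_state=seed, n_init=10).fit(emb)
    means = []
    for b in batches:
        if len(b) < k_final:
            continue
        gmm = GaussianMixture(n_components=k_final, random_state=seed,
                              means_init=seed_km.cluster_centers_,
                              covariance_type="full", max_iter=100)
        gmm.fit(emb[b])
        means.append(gmm.means_)
    if not means:
        raise ValueError("no batch large enough to fit a mixture model")
    pooled = np.vstack(means)
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
    sd[sd < 1e-12] = 1.0
    merged = KMeans(n_clusters=k_final, random_state=seed, n_init=10)
    merged.fit((pooled - mu) / sd)
    centres = merged.cluster_centers_ * sd + mu
    # assign sampled cells to the nearest merged centre in embedding space
    d2 = ((emb[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    sample_labels = d2.argmin(axis=1)
    labels = np.empty(n, dtype=int)
    labels[sample_idx] = sample_labels
    unsampled = np.setdiff1d(np.arange(n), sample_idx)
    if len(unsampled):
        from scipy.spatial import cKDTree
        tree = cKDTree(zs)
        zu = red.transform(x[unsampled])
        _, nn = tree.query(zu)
        labels[unsampled] = sample_labels[nn]
    return labels


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def apply_binarization(tier: ClusterTier,
                       decision: BinarizationDecision) -> np.ndarray:
    """Per-cell boolean marker calls from tier-level decisions.

    A cell is positive iff its deepest path equals or descends from a
    positive path; a manual override on a cell takes precedence either
    way. Unknown decision paths are an error (they would silently call
    nothing positive).
    """
    known = set()
    for p in tier.paths:
        parts = str(p).split(".")
        for i in range(1, len(parts) + 1):
            known.add(".".join(parts[:i]))
    unknown = set(decision.positive_paths) - known
    if unknown:
        raise ValueError(f"unknown tier paths: {sorted(unknown)}")
    calls = np.zeros(len(tier.paths), dtype=bool)
    for path in decision.positive_paths:
        calls[tier.members(path)] = True
    for idx, val in decision.overrides.items():
        calls[int(idx)] = bool(val)
    return calls


def marker_feature_matrix(table: pd.DataFrame, stain: str
                          ) -> tuple[np.ndarray, list[str]]:
    """Feature subset for clustering one marker: that stain's intensity
    statistics plus shared morphology."""
    cols = [c for c in table.columns
            if c.startswith(f"{stain}_") or c in MORPHOLOGY_COLUMNS]
    if not cols:
        raise ValueError(f"no feature columns for stain {stain!r}")
    return table[cols].to_numpy(dtype=float), cols


def rank_paths_by_chromogen(table: pd.DataFrame, tier: ClusterTier,
                            stain: str) -> list[str]:
    """Tier paths in descending mean chromogen OD (whole-cell mean).

    This is the ranking used to sweep cluster-inclusion thresholds for
    precision-recall curves and oracle-guided binarization.
    """
    col = f"{stain}_cell_chrom_mean"
    if col not in table.columns:
        raise ValueError(f"missing column {col!r}")
    vals = table[col].to_numpy(dtype=float)
    scores = {p: float(np.nanmean(vals[tier.members(p)]))
              for p in tier.unique_paths}
    return sorted(scores, key=lambda p: -scores[p])
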