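"""Phenotypic fingerprints: feature reduction, clustering, embedding.

A fingerprint is the per-crRNA (gene) vector of median rZ values over a
shared feature registry. Feature reduction removes features that are
unstable across crLIS1 control replicates (SD >= 3 on the rZ scale) and
redundant features (squared Pearson correlation >= 0.8 with an
already-retained feature, scanned greedily in registry order).
Hierarchical clustering uses complete linkage on correlation distance
(1 - Pearson r) after per-feature min-max scaling to [0, 1]; K-means
groups genes by their mean cargo-effect vectors in Euclidean space;
UMAP provides a 2-D visualization (never used for hit calling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


class ProfilingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# feature reduction


def reduce_features(
    fingerprints: pd.DataFrame,
    lis1_profiles: pd.DataFrame,
    sd_cut: float = 3.0,
    r2_cut: float = 0.8,
):
    """Drop unstable and redundant features from the registry.

    Step 1 removes features whose SD across the crLIS1 replicate
    profiles (plate-scattered control wells, rZ scale) is >= ``sd_cut``.
    Step 2 scans the survivors in registry order and drops any feature
    whose squared Pearson correlation with an already-retained feature
    is >= ``r2_cut`` (first kept wins). Returns ``(retained, drop_log)``
    where ``drop_log`` is a DataFrame of (feature, reason).
    """
    if len(lis1_profiles) < 3:
        raise ProfilingError("need >= 3 crLIS1 replicate profiles")
    registry = list(fingerprints.columns)
    dropped = []
    sds = lis1_profiles[registry].std(ddof=1)
    survivors = []
    for feat in registry:
        if sds[feat] >= sd_cut:
            dropped.append((feat, f"crLIS1 SD {sds[feat]:.3g} >= {sd_cut}"))
        else:
            survivors.append(feat)
    retained: list = []
    if survivors:
        x = fingerprints[survivors].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
        kept_idx: list[int] = []
        for j, feat in enumerate(survivors):
            r2 = max((corr[j, i] ** 2 for i in kept_idx), default=0.0)
            if r2 >= r2_cut:
                dropped.append((feat, f"R^2 {r2:.3g} >= {r2_cut} with retained feature"))
            else:
                kept_idx.append(j)
                retained.append(feat)
    if not retained:
        raise ProfilingError("feature reduction dropped every feature")
    drop_log = pd.DataFrame(dropped, columns=["feature", "reason"])
    return retained, drop_log


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    method: str
    labels: pd.Series
    parameters: dict = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None
    leaf_order: list | None = None
    centroids: np.ndarray | None = None
    flagged: list = field(default_factory=list)


def minmax_scale_features(fingerprints: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature to [0, 1] across genes."""
    x = fingerprints.astype(float)
    rng_ = x.max() - x.min()
    rng_ = rng_.replace(0, 1.0)
    return (x - x.min()) / rng_


def correlation_distance_matrix(fingerprints: pd.DataFrame, method: str = "pearson"):
    """Pairwise 1 - correlation distances; zero-variance genes flagged."""
    x = fingerprints.astype(float)
    variances = x.var(axis=1, ddof=0)
    flagged = list(x.index[variances == 0])
    ok = x.loc[variances > 0]
    corr = ok.T.corr(method=method).to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return dist, list(ok.index), flagged


def hierarchical_cluster(
    fingerprints: pd.DataFrame,
    n_clusters: int | None = None,
    cut_height: float | None = None,
    linkage_method: str = "complete",
    corr_method: str = "pearson",
    scale: bool = True,
) -> ClusterResult:
    """Complete-linkage clustering on correlation distance.

    Genes are sorted lexicographically before linkage so tie-breaking is
    deterministic. Zero-variance fingerprints (correlation undefined)
    are flagged and placed as singleton clusters. Flat labels come from
    cutting the tree at ``cut_height`` or into ``n_clusters`` groups.
    """
    fp = fingerprints.sort_index()
    if scale:
        fp = minmax_scale_features(fp)
    dist, names, flagged = correlation_distance_matrix(fp, corr_method)
    if flagged:
        logger.warning("%d zero-variance fingerprints placed as singletons", len(flagged))
    if len(names) < 2:
        raise ProfilingError("need >= 2 fingerprints with variance to cluster")
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    if cut_height is not None:
        flat = fcluster(z, t=cut_height, criterion="distance")
    else:
        flat = fcluster(z, t=n_clusters or 2, criterion="maxclust")
    labels = pd.Series(flat, index=names, name="cluster")
    next_label = int(labels.max()) + 1 if len(labels) else 1
    for g in flagged:
        labels.loc[g] = next_label
        next_label += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        order = [names[i] for i in dendrogram(z, no_plot=True)["leaves"]]
    order += flagged
    return ClusterResult(
        method="hierarchical",
        labels=labels,
        parameters={
            "linkage": linkage_method,
            "distance": f"1 - {corr_method} r",
            "scaling": "minmax [0,1] per feature" if scale else "none",
            "n_clusters": n_clusters,
            "cut_height": cut_height,
        },
        linkage_matrix=z,
        leaf_order=order,
        flagged=flagged,
    )


def linkage_to_newick(z: np.ndarray, names: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree string."""
    n = len(names)
    # iterative post-order construction to avoid recursion limits
    reprs: dict[int, str] = {i: names[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        reprs[n + k] = f"({reprs[a]}:{la:.6g},{reprs[b]}:{lb:.6g})"
        heights[n + k] = h
    return reprs[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# K-means cargo-signature grouping


def kmeans_cargo_clusters(
    effect_vectors: pd.DataFrame,
    k: int = 14,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Group genes by mean cargo-effect vectors with K-means (Euclidean).

    ``effect_vectors`` is genes x cargoes (e.g., PEX = mean of the GFP
    and RFP localization rZ, EEA1, TGN46). Labels are 1-based. The
    default K of 14 matches the cargo-signature grouping granularity
    used for the secondary-screen visualization.
    """
    if k < 1:
        raise ProfilingError("k must be >= 1")
    if k > len(effect_vectors):
        raise ProfilingError(f"k={k} exceeds the number of genes ({len(effect_vectors)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(effect_vectors.to_numpy(dtype=float)) + 1
    return ClusterResult(
        method="kmeans",
        labels=pd.Series(labels, index=effect_vectors.index, name="cluster"),
        parameters={"k": k, "seed": seed, "n_init": n_init, "distance": "euclidean"},
        centroids=km.cluster_centers_,
    )


# ---------------------------------------------------------------------------
# UMAP embedding (visualization only)


def embed_umap(
    fingerprints: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of reduced fingerprints (fixed seed).

    ``n_neighbors`` is clamped (with a warning) when there are fewer
    genes; degenerate inputs (< 4 genes) fall back to the first two
    feature axes so a plot is still possible.
    """
    x = fingerprints.to_numpy(dtype=float)
    n = len(fingerprints)
    if n < 4:
        logger.warning("too few genes for UMAP (%d); returning raw 2-D coordinates", n)
        coords = np.zeros((n, 2))
        coords[:, : min(2, x.shape[1])] = x[:, :2] if x.shape[1] >= 2 else x[:, :1]
        return pd.DataFrame(coords, index=fingerprints.index, columns=["umap1", "umap2"])
    if n_neighbors >= n:
        logger.warning("n_neighbors %d clamped to %d", n_neighbors, n - 1)
        n_neighbors = n - 1
    import umap  # deferred: heavy numba import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
        ).fit_transform(x)
    return pd.DataFrame(emb, index=fingerprints.index, columns=["umap1", "umap2"])


# ---------------------------------------------------------------------------
# heatmap export


def export_heatmap(
    fingerprints: pd.DataFrame,
    cluster_result: ClusterResult,
    figure_path=None,
    matrix_path=None,
    cmap: str = "vlag",
):
    """Export the dendrogram-ordered, per-feature min-max-scaled matrix.

    Rows follow the dendrogram leaf order; each feature is scaled so its
    minimum maps to 0 and maximum to 1. Returns the ordered scaled
    matrix; optionally writes the figure (PNG/PDF) and the matrix (CSV).
    """
    order = cluster_result.leaf_order or list(fingerprints.index)
    scaled = minmax_scale_features(fingerprints).loc[order]
    if matrix_path is not None:
        scaled.to_csv(matrix_path, float_format="%.12g")
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.1 * scaled.shape[1]), max(3, 0.12 * scaled.shape[0]))
        )
        im = ax.pcolormesh(scaled.to_numpy(), cmap=cmap, vmin=0, vmax=1)
        ax.set_yticks(np.arange(len(order)) + 0.5, order, fontsize=5)
        ax.set_xticks([])
        ax.set_xlabel("features (registry order, grouped by marker)")
        fig.colorbar(im, ax=ax, label="min-max scaled rZ")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return scaled
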