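import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from dynscreen.profiling import (
    ProfilingError,
    correlation_distance_matrix,
    embed_umap,
    export_heatmap,
    hierarchical_cluster,
    kmeans_cargo_clusters,
    linkage_to_newick,
    minmax_scale_features,
    reduce_features,
)
from dynscreen.synth.effects import sample_module_fingerprints


def brute_force_complete_linkage(dist: np.ndarray, k: int):
    """Naive O(n^3) agglomeration oracle; returns a partition at k clusters."""
    clusters = [{i} for i in range(len(dist))]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


# -------------------------------------------------------- feature reduction


@pytest.fixture()
def lis1_profiles():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(0, 1, (8, 5)), columns=list("abcde"))


def test_duplicated_feature_keeps_first_in_registry(lis1_profiles):
    rng = np.random.default_rng(1)
    fp = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    fp["b"] = fp["a"]  # exact duplicate
    retained, log = reduce_features(fp, lis1_profiles)
    assert "a" in retained and "b" not in retained
    assert (log["feature"] == "b").any()


def test_unstable_feature_dropped_by_sd_rule(lis1_profiles):
    rng = np.random.default_rng(2)
    fp = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    lis1 = lis1_profiles.copy()
    lis1.loc[:3, "c"] = [0.0, 10.0, -10.0, 10.0]  # SD ~ 9.6 >= 3
    retained, log = reduce_features(fp, lis1)
    assert "c" not in retained
    assert log.set_index("feature").loc["c", "reason"].startswith("crLIS1 SD")


def test_independent_noise_features_mostly_retained():
    rng = np.random.default_rng(3)
    fp = pd.DataFrame(
        rng.normal(size=(500, 40)), columns=[f"f{i:02d}" for i in range(40)]
    )
    lis1 = pd.DataFrame(rng.normal(size=(8, 40)), columns=fp.columns)
    retained, _ = reduce_features(fp, lis1)
    assert len(retained) >= 0.95 * 40


def test_reduce_features_idempotent(lis1_profiles):
    rng = np.random.default_rng(4)
    fp = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    fp["e"] = fp["d"] * 2 + rng.normal(0, 0.01, 30)
    retained, _ = reduce_features(fp, lis1_profiles)
    again, log = reduce_features(fp[retained], lis1_profiles[retained])
    assert again == retained
    assert len(log) == 0


# ------------------------------------------------------------- hierarchical


def test_identical_fingerprints_merge_first():
    rng = np.random.default_rng(5)
    base = rng.normal(size=8)
    fp = pd.DataFrame(
        [base, base, rng.normal(size=8), -base],
        index=["twin1", "twin2", "noise", "anti"],
    )
    result = hierarchical_cluster(fp, n_clusters=3, scale=False)
    assert result.labels["twin1"] == result.labels["twin2"]
    first_merge = result.linkage_matrix[0]
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_fingerprints_at_distance_two():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    fp = pd.DataFrame([x, -x], index=["a", "b"])
    dist, names, _ = correlation_distance_matrix(fp)
    assert dist[0, 1] == pytest.approx(2.0)


def test_linkage_matches_brute_force_oracle_on_random_fingerprints():
    rng = np.random.default_rng(6)
    fp = pd.DataFrame(
        rng.normal(size=(12, 10)), index=[f"g{i:02d}" for i in range(12)]
    )
    dist, names, _ = correlation_distance_matrix(minmax_scale_features(fp.sort_index()))
    result = hierarchical_cluster(fp, n_clusters=4)
    for k in (2, 3, 4, 6):
        flat = fcluster(result.linkage_matrix, t=k, criterion="maxclust")
        ours = {}
        for name, lbl in zip(names, flat):
            ours.setdefault(lbl, set()).add(name)
        oracle = brute_force_complete_linkage(dist, k)
        oracle_named = {frozenset(names[i] for i in c) for c in oracle}
        assert {frozenset(c) for c in ours.values()} == oracle_named


def test_zero_variance_fingerprint_becomes_flagged_singleton():
    rng = np.random.default_rng(7)
    fp = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"g{i}" for i in range(5)])
    fp.loc["g4"] = 1.0  # constant profile: correlation undefined
    result = hierarchical_cluster(fp, n_clusters=2, scale=False)
    assert "g4" in result.flagged
    assert (result.labels == result.labels["g4"]).sum() == 1


def test_module_recovery_by_both_clustering_methods():
    rng = np.random.default_rng(8)
    fp, labels = sample_module_fingerprints(rng, separation=3.0)
    hier = hierarchical_cluster(fp, n_clusters=6)
    km = kmeans_cargo_clusters(fp, k=6, seed=0)
    assert adjusted_rand_score(labels[hier.labels.index], hier.labels) >= 0.9
    assert adjusted_rand_score(labels[km.labels.index], km.labels) >= 0.9


def test_kmeans_label_invariant_to_feature_permutation():
    rng = np.random.default_rng(9)
    fp, _ = sample_module_fingerprints(rng, n_modules=3, genes_per_module=5, n_features=12)
    a = kmeans_cargo_clusters(fp, k=3, seed=1).labels
    b = kmeans_cargo_clusters(fp[list(reversed(fp.columns))], k=3, seed=1).labels
    assert adjusted_rand_score(a, b) == 1.0


def test_kmeans_trivial_cases():
    fp = pd.DataFrame(
        [[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [4.0, 4.0]], index=list("abcd")
    )
    one = kmeans_cargo_clusters(fp, k=1, seed=0)
    assert one.labels.nunique() == 1
    np.testing.assert_allclose(one.centroids[0], fp.mean().to_numpy())
    some = kmeans_cargo_clusters(fp, k=2, seed=0)
    assert some.labels["b"] == some.labels["c"]  # duplicates co-cluster
    with pytest.raises(ProfilingError):
        kmeans_cargo_clusters(fp, k=10, seed=0)


# --------------------------------------------------------------------- UMAP


def test_umap_separates_planted_modules_and_is_deterministic():
    rng = np.random.default_rng(10)
    fp, labels = sample_module_fingerprints(
        rng, n_modules=2, genes_per_module=10, n_features=20, separation=5.0
    )
    emb1 = embed_umap(fp, seed=0, n_neighbors=5)
    emb2 = embed_umap(fp, seed=0, n_neighbors=5)
    pd.testing.assert_frame_equal(emb1, emb2)
    coords = emb1.to_numpy()
    same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    tri = np.triu(np.ones_like(same, dtype=bool), 1)
    assert dist[tri & ~same].mean() > dist[tri & same].mean()


def test_umap_degenerate_inputs_give_finite_points():
    fp = pd.DataFrame([[1.0, 2.0]], index=["only"])
    emb = embed_umap(fp, seed=0)
    assert emb.shape == (1, 2)
    assert np.isfinite(emb.to_numpy()).all()


# ------------------------------------------------------------------ heatmap


def test_heatmap_export_order_scaling_and_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    fp, _ = sample_module_fingerprints(rng, n_modules=3, genes_per_module=4, n_features=8)
    result = hierarchical_cluster(fp, n_clusters=3)
    matrix_path = tmp_path / "matrix.csv"
    scaled = export_heatmap(fp, result, matrix_path=matrix_path)
    assert list(scaled.index) == result.leaf_order
    np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)
    back = pd.read_csv(matrix_path, index_col=0)
    np.testing.assert_allclose(back.to_numpy(), scaled.to_numpy(), atol=1e-9)


def test_newick_serialization_contains_all_leaves():
    rng = np.random.default_rng(12)
    fp, _ = sample_module_fingerprints(rng, n_modules=2, genes_per_module=4, n_features=6)
    result = hierarchical_cluster(fp, n_clusters=2)
    newick = linkage_to_newick(result.linkage_matrix, sorted(fp.index))
    assert newick.endswith(";")
    for name in fp.index:
        assert name in newick
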