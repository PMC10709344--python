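import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from orgscreen import (
    DataError,
    build_feature_matrix,
    cluster_embedding,
    cluster_profiles,
    embed_tsne,
    rank_normalize,
    select_informative_pcs,
)
from orgscreen.heterogeneity import FEATURES, knn_graph, tsne_perplexity


def states_frame(n_organoids=3, n_times=6, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for oid in range(n_organoids):
        for t in range(n_times):
            rows.append({
                "plate_id": "P1", "well": "A01", "organoid_id": oid,
                "time_h": 24.0 * t, "regimen": "vehicle", "role": "treatment",
                "bf_area": rng.lognormal(7, 0.3), "inv_area": rng.lognormal(4, 0.5),
                "fa": rng.uniform(0, 1), "inv_fraction": rng.uniform(0, 0.5),
                "brightness": rng.normal(100, 10), "texture": rng.normal(10, 2),
            })
    return pd.DataFrame(rows)


class TestFeatureMatrix:
    def test_one_row_per_organoid_timepoint(self):
        fm = build_feature_matrix(states_frame(3, 6))
        assert fm.X.shape == (18, 6)
        assert fm.features == FEATURES
        np.testing.assert_allclose(fm.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fm.X.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_dropped(self):
        df = states_frame(4, 6)
        df["texture"] = 5.0
        fm = build_feature_matrix(df)
        assert fm.dropped_constant == ["texture"]
        assert fm.X.shape[1] == 5

    def test_missing_rows_dropped_and_counted(self):
        df = states_frame(4, 6)
        df.loc[:2, "texture"] = np.nan
        fm = build_feature_matrix(df)
        assert fm.n_dropped_missing == 3
        assert len(fm.meta) == 21


class TestPCSelection:
    def test_pure_noise_retains_nothing(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(500, 6))
        scores, table = select_informative_pcs(X, n_perm=200, seed=1)
        assert scores.shape == (500, 0)
        assert not table["retained"].any()

    def test_two_planted_components_retained(self):
        rng = np.random.default_rng(7)
        n = 500
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack(
            [z1 + 0.1 * rng.normal(size=n) for _ in range(3)]
            + [z2 + 0.1 * rng.normal(size=n) for _ in range(3)]
        )
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        scores, table = select_informative_pcs(X, n_perm=200, seed=1)
        assert int(table["retained"].sum()) == 2
        assert scores.shape == (500, 2)

    def test_pvalues_respect_permutation_resolution(self):
        rng = np.random.default_rng(3)
        _, table = select_informative_pcs(rng.normal(size=(60, 4)), n_perm=199, seed=0)
        assert (table["p_perm"] >= 1 / 200).all()
        assert (table["p_perm"] <= 1.0).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            select_informative_pcs(np.zeros((5, 6)), n_perm=100)


class TestTSNE:
    @pytest.mark.parametrize("n,expected", [(10000, 100.0), (29371, 171.0), (400, 20.0)])
    def test_perplexity_square_root_rule(self, n, expected):
        perp, lowered = tsne_perplexity(n)
        assert perp == expected
        assert not lowered

    def test_small_n_lowers_perplexity(self):
        perp, lowered = tsne_perplexity(20)  # floor(sqrt) = 4 but 20 < 3*4 is False
        assert perp == 4.0 and not lowered
        perp, lowered = tsne_perplexity(8)  # floor(sqrt)=2, 8 >= 6 ok
        assert perp == 2.0
        perp, lowered = tsne_perplexity(5)  # 5 < 3*2 -> floor(4/3) = 1
        assert (perp, lowered) == (1.0, True)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        a = embed_tsne(X, seed=5)
        b = embed_tsne(X, seed=5)
        np.testing.assert_array_equal(a, b)


class TestClustering:
    def test_two_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(loc=(0, 0), scale=1.0, size=(200, 2))
        b = rng.normal(loc=(20, 0), scale=1.0, size=(200, 2))
        coords = np.vstack([a, b])
        truth = np.array([0] * 200 + [1] * 200)
        labels = cluster_embedding(coords, k=1000, seed=0)  # capped at n-1
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_k_capped_at_n_minus_one(self):
        coords = np.random.default_rng(1).normal(size=(5, 2))
        graph = knn_graph(coords, k=1000)
        assert all(graph.degree(i) == 4 for i in graph.nodes)

    def test_duplicated_points_form_single_community(self):
        coords = np.zeros((10, 2))
        labels = cluster_embedding(coords, k=5, seed=0)
        assert len(np.unique(labels)) == 1

    def test_edge_weights_are_complement_distances(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        graph = knn_graph(coords, k=2)
        weights = nx.get_edge_attributes(graph, "weight")
        assert all(0.0 <= w <= 1.0 for w in weights.values())
        assert weights[(0, 1)] == pytest.approx(1 - 1 / 3)
        assert weights[(0, 2)] == pytest.approx(0.0)  # the farthest realized edge

    def test_partition_beats_trivial_partitions_on_modularity(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([
            rng.normal(loc=(0, 0), size=(100, 2)),
            rng.normal(loc=(15, 0), size=(100, 2)),
        ])
        graph = knn_graph(coords, k=20)
        labels = cluster_embedding(coords, k=20, seed=0)
        parts = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        q = nx.community.modularity(graph, parts, weight="weight")
        q_single = nx.community.modularity(graph, [set(graph.nodes)], weight="weight")
        q_singletons = nx.community.modularity(
            graph, [{i} for i in graph.nodes], weight="weight")
        assert q >= q_single
        assert q >= q_singletons


class TestRankNormalize:
    @pytest.mark.parametrize("values,expected", [
        ([5, 1, 3], [1.0, 1 / 3, 2 / 3]),
        ([2, 2], [0.75, 0.75]),
        ([7], [1.0]),
    ])
    def test_values(self, values, expected):
        np.testing.assert_allclose(rank_normalize(values), expected)


class TestClusterProfiles:
    def test_enrichment_and_baseline_cluster(self):
        df = states_frame(10, 3)
        fm = build_feature_matrix(df)
        # put all baseline (t=0) rows in cluster 1, the rest in cluster 2
        labels = np.where(fm.meta["time_h"] == 0.0, 1, 2)
        profiles, enrichment, baseline = cluster_profiles(labels, fm)
        assert baseline == 1
        t0 = enrichment[(enrichment["variable"] == "time_h") & (enrichment["level"] == 0.0)]
        assert t0.set_index("cluster")["enrichment"][1] == pytest.approx(3.0)  # 1 / (1/3)
        assert t0.set_index("cluster")["enrichment"][2] == 0.0

    def test_enrichment_averages_to_one_weighted_by_cluster_size(self):
        df = states_frame(12, 4, rng=np.random.default_rng(5))
        fm = build_feature_matrix(df)
        labels = np.random.default_rng(1).integers(1, 4, size=len(fm.meta))
        _, enrichment, _ = cluster_profiles(labels, fm)
        sizes = pd.Series(labels).value_counts(normalize=True)
        for (_, level), grp in enrichment.groupby(["variable", "level"]):
            weighted = (grp.set_index("cluster")["enrichment"] * sizes).sum()
            assert weighted == pytest.approx(1.0)
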