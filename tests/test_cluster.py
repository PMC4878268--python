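import numpy as np
import pandas as pd
import pytest

from calclust import (
    DistanceMatrix,
    classical_mds,
    gmm_bic_select,
    hierarchical_cluster,
    label_clusters,
    rank_dims_by_silhouette,
    responder_proportion,
    spearman_distance,
)
from calclust.cluster import NON_OSCILLATING, NON_RESPONDER, OSCILLATING

from conftest import make_dataset


class TestSpearmanDistance:
    def test_monotone_transform_gives_zero_distance(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
        ds = make_dataset([x, np.exp(3 * x)], np.arange(5.0))
        d = spearman_distance(ds)
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_give_unit_distance(self):
        ds = make_dataset([[1, 2, 3, 4], [4, 3, 2, 1]], np.arange(4.0))
        assert spearman_distance(ds).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        # rho([1,2,3,4],[1,3,2,4]) = 1 - 6*2/(4*15) = 0.8 -> d = 0.1
        ds = make_dataset([[1, 2, 3, 4], [1, 3, 2, 4]], np.arange(4.0))
        assert spearman_distance(ds).matrix[0, 1] == pytest.approx(0.1)

    def test_constant_trace_treated_as_uncorrelated(self):
        ds = make_dataset([[1, 2, 3, 4], [2, 2, 2, 2]], np.arange(4.0))
        with pytest.warns(UserWarning, match="constant"):
            d = spearman_distance(ds)
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_invariant_under_per_cell_monotone_transforms(self, preset_run):
        kept = preset_run["kept"]
        sub = kept.subset(kept.cell_ids[:20])
        base = spearman_distance(sub).matrix
        warped = make_dataset(np.exp(sub.values) + 3.0, sub.times)
        np.testing.assert_allclose(spearman_distance(warped).matrix, base, atol=1e-12)


class TestClassicalMDS:
    def test_three_equidistant_cells_embed_as_equilateral_triangle(self):
        d = DistanceMatrix(ids=["a", "b", "c"], matrix=0.5 * (1 - np.eye(3)))
        coords = classical_mds(d, n_dims=2)
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        off = dists[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, off[0], atol=1e-9)

    def test_planar_distances_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 0.3, size=(12, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = DistanceMatrix(ids=[str(i) for i in range(12)], matrix=dist)
        coords = classical_mds(d, n_dims=2)
        re_dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(re_dist, dist, atol=1e-6)

    def test_duplicate_cells_get_identical_coordinates(self):
        m = np.array([[0, 0, 0.4], [0, 0, 0.4], [0.4, 0.4, 0]])
        coords = classical_mds(DistanceMatrix(ids=list("abc"), matrix=m), n_dims=1)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-9)

    def test_dimension_bound(self):
        d = DistanceMatrix(ids=list("abc"), matrix=0.5 * (1 - np.eye(3)))
        with pytest.raises(ValueError):
            classical_mds(d, n_dims=3)

    def test_embedding_is_deterministic(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 0.3, size=(8, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = DistanceMatrix(ids=[str(i) for i in range(8)], matrix=dist)
        np.testing.assert_array_equal(classical_mds(d, 3), classical_mds(d, 3))


class TestSilhouetteRanking:
    def test_separating_dimension_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 200
        fields = ["f1"] * (n // 2) + ["f2"] * (n // 2)
        sep = np.r_[rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)]
        noise = rng.normal(size=n)
        ranked = rank_dims_by_silhouette(np.c_[noise, sep], fields, top_k=2)
        assert ranked["dimension"].iloc[0] == 1
        assert ranked["mean_silhouette_width"].iloc[0] > 0.8

    def test_interleaved_dimension_scores_near_zero(self):
        rng = np.random.default_rng(1)
        n = 200
        fields = rng.choice(["f1", "f2"], size=n).tolist()
        ranked = rank_dims_by_silhouette(rng.normal(size=(n, 1)), fields, top_k=1)
        assert abs(ranked["mean_silhouette_width"].iloc[0]) < 0.1

    def test_top_k_clipped_with_warning(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(40, 2))
        fields = ["f1"] * 20 + ["f2"] * 20
        with pytest.warns(UserWarning, match="top_k"):
            ranked = rank_dims_by_silhouette(coords, fields, top_k=9)
        assert len(ranked) == 2

    def test_single_field_rejected(self):
        with pytest.raises(ValueError):
            rank_dims_by_silhouette(np.zeros((5, 2)), ["f1"] * 5)


class TestHierarchical:
    @staticmethod
    def _blob_table(rng, centers, n_per, spread=0.05):
        rows = []
        for c, (x, y) in enumerate(centers):
            rows.append(
                np.c_[rng.normal(x, spread, n_per), rng.normal(y, spread, n_per)]
            )
        data = np.vstack(rows)
        return (
            pd.DataFrame(data, columns=["high_glucose_response", "high_glucose_oscillation"]),
            np.repeat(np.arange(len(centers)), n_per),
        )

    def test_identical_feature_columns_merge_first(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        model = hierarchical_cluster(table, axis="features")
        first = sorted(model.linkage_matrix[0, :2].astype(int))
        assert [model.ids[i] for i in first] == ["a", "b"]
        assert model.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_well_separated_groups_recovered_at_k3(self):
        rng = np.random.default_rng(1)
        table, truth = self._blob_table(rng, [(0, 0), (5, 0), (0, 5)], 30)
        model = hierarchical_cluster(table, axis="cells", n_clusters=3)
        # planted partition recovered exactly up to label permutation
        df = pd.DataFrame({"truth": truth, "got": model.assignments})
        assert (df.groupby("truth")["got"].nunique() == 1).all()
        assert df["got"].nunique() == 3

    def test_cutting_at_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        table, _ = self._blob_table(rng, [(0, 0)], 6)
        model = hierarchical_cluster(table, axis="cells", n_clusters=6)
        assert sorted(model.assignments) == [1, 2, 3, 4, 5, 6]

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            model = hierarchical_cluster(table, axis="cells", n_clusters=2)
        assert model.columns == ("a",)


class TestGMMSelection:
    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.normal(size=(500, 2)),
            columns=["high_glucose_response", "high_glucose_oscillation"],
        )
        model = gmm_bic_select(table, seed=0, k_range=range(1, 5))
        assert model.n_clusters == 1

    def test_three_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        means = np.array([(0, 0), (6, 0), (0, 6)])
        truth = np.repeat([0, 1, 2], 100)
        pts = means[truth] + rng.normal(size=(300, 2))
        table = pd.DataFrame(
            pts, columns=["high_glucose_response", "high_glucose_oscillation"]
        )
        model = gmm_bic_select(table, seed=1)
        assert model.n_clusters == 3
        df = pd.DataFrame({"truth": truth, "got": model.assignments})
        best = df.groupby(["truth", "got"]).size().groupby("truth").max().sum()
        assert best / 300 >= 0.98

    def test_k_range_of_one_is_trivial(self, preset_run):
        model = gmm_bic_select(preset_run["features"], k_range=(1,), seed=0)
        assert model.n_clusters == 1

    def test_selection_is_reproducible_for_fixed_seed(self, preset_run):
        a = gmm_bic_select(preset_run["features"], seed=42)
        b = gmm_bic_select(preset_run["features"], seed=42)
        assert a.n_clusters == b.n_clusters and a.covariance_family == b.covariance_family
        np.testing.assert_array_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.bic_table, b.bic_table)

    def test_bic_reported_for_every_candidate(self, preset_run):
        model = gmm_bic_select(preset_run["features"], k_range=range(1, 4), seed=0)
        assert len(model.bic_table) == 3 * 4  # K x covariance families
        assert model.responsibilities.shape == (len(model.ids), model.n_clusters)
        np.testing.assert_allclose(model.responsibilities.sum(axis=1), 1.0)


class TestLabelling:
    def test_planted_types_receive_matching_labels(self, preset_run):
        table = preset_run["features"]
        model = gmm_bic_select(table, seed=1)
        assert model.n_clusters == 3
        label_clusters(model, table)
        pred = np.array([model.labels[a] for a in model.assignments])
        assert (pred == preset_run["truth_kept"]).mean() >= 0.95

    def test_non_three_component_models_get_generic_labels(self, preset_run):
        model = gmm_bic_select(preset_run["features"], k_range=(2,), seed=0)
        labels = label_clusters(model, preset_run["features"])
        assert labels == {1: "cluster_1", 2: "cluster_2"}

    def test_responder_proportion_counts_both_responder_labels(self):
        from calclust.cluster import ClusterModel

        model = ClusterModel(
            method="gmm",
            ids=[str(i) for i in range(10)],
            n_clusters=3,
            assignments=np.array([1] * 5 + [2] * 3 + [3] * 2),
        )
        model.labels = {1: OSCILLATING, 2: NON_OSCILLATING, 3: NON_RESPONDER}
        assert responder_proportion(model) == pytest.approx(0.8)
        model.labels = {}
        with pytest.raises(ValueError):
            responder_proportion(model)
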