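"""Two-pass decomposition, annotation, ranking, proportions and ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

from hepaflow.celltyping import (
    Clustering,
    MarkerPanelSet,
    annotate_clusters,
    anova_rank_display_genes,
    cell_type_proportions,
    count_coexpressing_cells,
    embed_tsne,
    go_overrepresentation,
    hierarchical_cluster,
    oneway_f,
    rank_genes_by_pca,
    two_pass_decomposition,
)

from conftest import toy_matrix


def blobs_matrix(rng, n_a=15, n_b=15, n_genes=40):
    """Two well-separated expression blobs."""
    a = rng.gamma(4, 1, size=(n_genes, n_a))
    b = rng.gamma(4, 1, size=(n_genes, n_b))
    a[n_genes // 2 :] += 60.0
    b[: n_genes // 2] += 60.0
    vals = np.hstack([a, b])
    return toy_matrix(vals), ["A"] * n_a + ["B"] * n_b


class TestPcaRanking:
    def test_saturation_returns_all_genes(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.gamma(2, 2, size=(10, 12)))
        assert len(rank_genes_by_pca(m, k=50)) == 10

    def test_dominant_variance_gene_ranked_first(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 0.1, size=(5, 30)).clip(min=0)
        vals[2] = rng.uniform(0, 200, 30)  # 100x the variance of the rest
        m = toy_matrix(vals)
        assert rank_genes_by_pca(m, k=5)[0] == "g2"

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 5, size=(20, 25))
        m = toy_matrix(vals)
        perm = rng.permutation(25)
        m2 = toy_matrix(vals[:, perm], cells=[f"c{j}" for j in perm])
        assert rank_genes_by_pca(m, k=10) == rank_genes_by_pca(m2, k=10)

    def test_exclusion_list_applied(self):
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.gamma(2, 5, size=(6, 10)))
        ranked = rank_genes_by_pca(m, k=6, exclusion=["g0", "g1"])
        assert "g0" not in ranked and "g1" not in ranked


class TestHierarchicalCluster:
    def test_two_separable_blobs(self):
        m, truth = blobs_matrix(np.random.default_rng(4))
        cl = hierarchical_cluster(m, list(m.genes), 2)
        assert adjusted_rand_score(truth, cl.labels.tolist()) == 1.0

    def test_six_type_simulation_recovers_ground_truth(self, default_sim):
        _, matrix, _, truth = default_sim
        genes = rank_genes_by_pca(matrix, k=400)
        cl = hierarchical_cluster(matrix, genes, 6)
        ari = adjusted_rand_score(
            truth.cells["type"], cl.labels.loc[truth.cells.index].tolist()
        )
        assert ari >= 0.9

    def test_replicating_cells_leaves_assignments_unchanged(self):
        m, _ = blobs_matrix(np.random.default_rng(5), n_a=8, n_b=8)
        cl = hierarchical_cluster(m, list(m.genes), 2)
        dup_vals = np.hstack([m.values.to_numpy(), m.values.to_numpy()])
        dup = toy_matrix(dup_vals, genes=list(m.genes),
                         cells=[f"c{j}" for j in range(32)])
        cl2 = hierarchical_cluster(dup, list(m.genes), 2)
        orig = cl.labels
        dup_orig = cl2.labels.iloc[:16]
        assert adjusted_rand_score(orig.tolist(), dup_orig.tolist()) == 1.0

    def test_bad_cluster_count_rejected(self):
        m, _ = blobs_matrix(np.random.default_rng(6), n_a=3, n_b=3)
        with pytest.raises(ValueError):
            hierarchical_cluster(m, list(m.genes), 1)


class TestAnnotateClusters:
    def panels(self):
        return MarkerPanelSet(
            panels={"alpha": ["g0", "g1"], "beta": ["g2", "g3"]}, exclusion=[]
        )

    def test_pure_cluster_gets_its_panel_label(self):
        vals = np.array([
            [9.0, 9, 0, 0], [8, 8, 0, 0], [0, 0, 9, 9], [0, 0, 8, 8],
        ])
        m = toy_matrix(vals)
        labels = pd.Series(["x", "x", "y", "y"], index=m.cells, name="cluster")
        out = annotate_clusters(m, Clustering(labels=labels), self.panels())
        assert out.types == {"x": "alpha", "y": "beta"}

    def test_scores_match_brute_force(self):
        rng = np.random.default_rng(7)
        vals = rng.gamma(3, 3, size=(4, 9))
        m = toy_matrix(vals)
        labels = pd.Series(list("aaabbbccc"), index=m.cells, name="cluster")
        out = annotate_clusters(m, Clustering(labels=labels), self.panels())
        logv = np.log2(vals + 1)
        cmeans = np.stack(
            [logv[:, labels.to_numpy() == c].mean(axis=1) for c in ["a", "b", "c"]],
            axis=1,
        )
        z = (cmeans - cmeans.mean(axis=1, keepdims=True)) / cmeans.std(axis=1, keepdims=True)
        expect_alpha = z[[0, 1]].mean(axis=0)
        assert np.allclose(out.scores["alpha"].to_numpy(), expect_alpha)

    def test_exact_tie_is_unassigned(self):
        vals = np.array([[4.0, 4], [4, 4], [4, 4], [4, 4]])
        m = toy_matrix(vals)
        labels = pd.Series(["x", "y"], index=m.cells, name="cluster")
        out = annotate_clusters(m, Clustering(labels=labels), self.panels())
        assert set(out.types.values()) == {"unassigned"}


class TestTwoPass:
    def test_default_simulation_six_groups_high_ari(self, default_sim):
        _, matrix, _, truth = default_sim
        cl = two_pass_decomposition(matrix)
        types = cl.cell_types()
        assert types.nunique() == 6
        ari = adjusted_rand_score(truth.cells["type"], types.loc[truth.cells.index])
        assert ari >= 0.9

    def test_macrophage_style_merge_is_exercised(self, default_sim):
        """Six non-hepatoblast clusters collapse onto five types, so at
        least two second-pass clusters shared a top panel and merged."""
        _, matrix, _, _ = default_sim
        cl = two_pass_decomposition(matrix)
        non_hep = {c: t for c, t in cl.types.items() if t != "hepatoblast"}
        assert len(non_hep) == 5  # 6 second-pass clusters merged into 5

    def test_pure_hepatoblast_population_skips_second_pass(self, default_sim):
        _, matrix, _, truth = default_sim
        hep = truth.cells.index[truth.cells["type"] == "hepatoblast"]
        cl = two_pass_decomposition(matrix.subset_cells(list(hep)))
        assert set(cl.cell_types()) == {"hepatoblast"}
        assert "skipped" in cl.status

    def test_hepatoblast_panel_required(self, default_sim):
        _, matrix, _, _ = default_sim
        panels = MarkerPanelSet(panels={"mesenchymal": ["Vim"]}, exclusion=[])
        with pytest.raises(ValueError, match="hepatoblast"):
            two_pass_decomposition(matrix, panels)


class TestAnovaRanking:
    def test_flat_gene_ranked_last(self):
        vals = np.array([[5.0] * 6, [1, 2, 3, 7, 8, 9]])
        m = toy_matrix(vals)
        labels = pd.Series(list("aaabbb"), index=m.cells)
        assert anova_rank_display_genes(m, labels, k=2)[-1] == "g0"

    def test_f_statistic_worked_example(self):
        """Groups (1,3), (2,4), (3,5) give F = 1 exactly."""
        groups = [np.array([[1.0, 3.0]]), np.array([[2.0, 4.0]]), np.array([[3.0, 5.0]])]
        F, p = oneway_f(groups)
        assert F[0] == pytest.approx(1.0)
        sp_f, sp_p = stats.f_oneway([1, 3], [2, 4], [3, 5])
        assert F[0] == pytest.approx(sp_f)
        assert p[0] == pytest.approx(sp_p)

    def test_zero_within_variance_distinct_means_ranked_first(self):
        vals = np.array([
            2.0 ** np.array([1, 1, 1, 3, 3, 3]) - 1,  # no within-group noise
            [1, 5, 2, 6, 1, 8],
        ])
        m = toy_matrix(vals)
        labels = pd.Series(list("aaabbb"), index=m.cells)
        assert anova_rank_display_genes(m, labels, k=2)[0] == "g0"

    def test_small_label_dropped_with_warning(self):
        vals = np.random.default_rng(1).gamma(2, 2, (5, 5))
        m = toy_matrix(vals)
        labels = pd.Series(["a", "a", "b", "b", "c"], index=m.cells)
        with pytest.warns(UserWarning, match="dropped"):
            anova_rank_display_genes(m, labels, k=5)


class TestEmbedding:
    def test_same_seed_identical_coordinates(self, default_sim):
        _, matrix, _, truth = default_sim
        sub = matrix.subset_cells(list(matrix.cells[:60]))
        genes = list(matrix.genes[:100])
        c1 = embed_tsne(sub, genes, seed=11)
        c2 = embed_tsne(sub, genes, seed=11)
        pd.testing.assert_frame_equal(c1, c2)
        assert len(c1) == 60

    def test_types_separate_in_embedding(self, default_sim):
        _, matrix, _, truth = default_sim
        genes = rank_genes_by_pca(matrix, k=200)
        coords = embed_tsne(matrix, genes, seed=1)
        sil = silhouette_score(coords.to_numpy(), truth.cells["type"])
        assert sil > 0

    def test_perplexity_reduced_for_tiny_inputs(self):
        m = toy_matrix(np.random.default_rng(2).gamma(2, 2, (10, 8)))
        with pytest.warns(UserWarning, match="perplexity"):
            coords = embed_tsne(m, list(m.genes), seed=0)
        assert coords.shape == (8, 2)


class TestProportions:
    def test_single_type_stage(self):
        labels = pd.Series(["hep"] * 3, index=["c0", "c1", "c2"])
        stages = pd.Series(["E11.5"] * 3, index=["c0", "c1", "c2"])
        out = cell_type_proportions(labels, stages)
        assert out.loc["E11.5", "hep"] == 1.0

    def test_hand_counted_toy(self):
        labels = pd.Series(list("aabbb") + list("aaabb"), index=[f"c{i}" for i in range(10)])
        stages = pd.Series(["s1"] * 5 + ["s2"] * 5, index=[f"c{i}" for i in range(10)])
        out = cell_type_proportions(labels, stages)
        assert out.loc["s1", "a"] == pytest.approx(0.4)
        assert out.loc["s2", "b"] == pytest.approx(0.4)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_mesenchymal_fraction_decreases_with_development(self, default_sim):
        """The configured stepwise mesenchymal decline is recovered."""
        cfg, _, annot, truth = default_sim
        out = cell_type_proportions(truth.cells["type"], annot["stage"])
        series = out.loc[list(cfg.stages), "mesenchymal"]
        assert series.iloc[0] > series.iloc[-1]
        assert stats.spearmanr(np.arange(len(series)), series)[0] < -0.8


class TestCoexpression:
    def test_absent_expression_counts_zero(self):
        m = toy_matrix([[5.0, 5], [0, 0]])
        n, cells = count_coexpressing_cells(m, ["g0"], ["g1"])
        assert n == 0 and cells == []

    def test_manual_quadrant_count(self):
        vals = np.array([
            [5.0, 5, 0, 5, 0, 2],
            [3.0, 0, 3, 3, 0, 0.5],
        ])
        m = toy_matrix(vals)
        n, cells = count_coexpressing_cells(m, ["g0"], ["g1"])
        assert n == 2 and cells == ["c0", "c3"]

    def test_exactly_four_double_positive_cells(self):
        """Hepatocyte x cholangiocyte keratin co-expression fixture."""
        rng = np.random.default_rng(9)
        n = 60
        vals = pd.DataFrame(
            {
                "Krt8": rng.uniform(5, 50, n),
                "Krt18": rng.uniform(5, 50, n),
                "Krt7": np.zeros(n),
                "Krt19": np.zeros(n),
            }
        ).T
        vals.loc["Krt7", [3, 17, 30, 41]] = 8.0  # four co-expressing cells
        vals.columns = [f"c{i}" for i in range(n)]
        m = toy_matrix(vals.to_numpy(), genes=list(vals.index), cells=list(vals.columns))
        count, _ = count_coexpressing_cells(m, ["Krt8", "Krt18"], ["Krt7", "Krt19"])
        assert count == 4

    def test_unknown_gene_named_in_error(self):
        m = toy_matrix([[1.0]])
        with pytest.raises(KeyError, match="Nope1"):
            count_coexpressing_cells(m, ["g0"], ["Nope1"])


class TestOverrepresentation:
    def test_zero_overlap_gives_p_one(self):
        out = go_overrepresentation(
            {"a", "b"}, {"a", "b", "c", "d"}, {"t": {"c", "d"}}
        )
        assert out.loc["t", "p_raw"] == pytest.approx(1.0)

    def test_hypergeometric_worked_example(self):
        """Universe 20, term 5, query 5, overlap 4: tail ~4.9e-3."""
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}
        out = go_overrepresentation(query, universe, {"t": term})
        expect = (5 * 15 + 1) / 15504  # C(5,4)C(15,1)+C(5,5) over C(20,5)
        assert out.loc["t", "p_raw"] == pytest.approx(expect)

    def test_single_term_bonferroni_identity(self):
        universe = {f"g{i}" for i in range(10)}
        out = go_overrepresentation({"g0", "g1"}, universe, {"t": {"g0", "g1", "g2"}})
        assert out.loc["t", "p_adj"] == out.loc["t", "p_raw"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            go_overrepresentation({"zz"}, {"a"}, {"t": {"a"}})

    def test_hepatoblast_markers_enrich_synthetic_liver_term(self, default_sim):
        """Marker-derived query hits a liver-function gene set."""
        _, matrix, _, truth = default_sim
        universe = set(matrix.biological().genes)
        hep_markers = set(
            truth.genes.index[truth.genes["marker_type"] == "hepatoblast"]
        )
        annotation = {
            "liver_function": hep_markers,
            "unrelated": {f"Gene{i:05d}" for i in range(1, 40)},
        }
        query = set(list(hep_markers)[:10]) | {"Gene01000"}
        out = go_overrepresentation(query, universe, annotation)
        assert out.loc["liver_function", "p_adj"] < 0.05
        assert out.loc["unrelated", "p_adj"] > 0.05
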