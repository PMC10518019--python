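"""Two-stage z-scoring, cosine clustering and co-expression selection."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from scmst import expression as expr


def make_adata(x, embryo=None, stage=None, genes=None):
    x = np.asarray(x, float)
    n, g = x.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["embryo"] = embryo if embryo is not None else 0
    obs["stage"] = stage if stage is not None else "HH5"
    var = pd.DataFrame(index=genes or [f"g{j}" for j in range(g)])
    return ad.AnnData(X=x, obs=obs, var=var)


class TestZscoreWithinEmbryo:
    def test_hand_computed_four_cell_column(self):
        adata = make_adata(np.array([[0.0], [1.0], [2.0], [3.0]]))
        z = expr.zscore_within_embryo(adata)
        sd = np.std([0, 1, 2, 3], ddof=1)
        expected = (np.array([0, 1, 2, 3]) - 1.5) / sd
        assert np.allclose(np.asarray(z.X).ravel(), expected)

    def test_constant_gene_maps_to_zero(self):
        adata = make_adata(np.column_stack([np.full(5, 4.0), np.arange(5.0)]))
        z = expr.zscore_within_embryo(adata)
        assert np.allclose(np.asarray(z.X)[:, 0], 0.0)

    def test_per_embryo_column_means_zero(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, (40, 6)).astype(float)
        adata = make_adata(x, embryo=np.repeat([0, 1], 20))
        z = expr.zscore_within_embryo(adata)
        for e in (0, 1):
            sub = np.asarray(z.X)[np.asarray(adata.obs["embryo"]) == e]
            assert np.abs(sub.mean(axis=0)).max() < 1e-12

    def test_single_cell_embryo_rejected(self):
        adata = make_adata(np.ones((3, 2)), embryo=[0, 0, 1])
        with pytest.raises(ValueError, match="single cell"):
            expr.zscore_within_embryo(adata)

    def test_missing_embryo_metadata_rejected(self):
        adata = make_adata(np.ones((3, 2)))
        del adata.obs["embryo"]
        with pytest.raises(ValueError, match="embryo"):
            expr.zscore_within_embryo(adata)


class TestZscorePooled:
    def test_single_embryo_is_restandardization(self):
        rng = np.random.default_rng(1)
        adata = make_adata(rng.poisson(6, (30, 4)).astype(float))
        z = expr.zscore_pooled(expr.zscore_within_embryo(adata))
        x = np.asarray(z.X)
        assert np.abs(x.mean(axis=0)).max() < 1e-9
        assert np.abs(x.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_two_embryo_matches_bruteforce_two_pass(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(5, (24, 3)).astype(float)
        embryo = np.repeat([0, 1], 12)
        adata = make_adata(x, embryo=embryo)
        z = expr.zscore_pooled(expr.zscore_within_embryo(adata))

        brute = np.empty_like(x)
        for e in (0, 1):
            sub = x[embryo == e]
            brute[embryo == e] = (sub - sub.mean(0)) / sub.std(0, ddof=1)
        brute = (brute - brute.mean(0)) / brute.std(0, ddof=1)
        assert np.allclose(np.asarray(z.X), brute)

    def test_provenance_recorded(self):
        adata = make_adata(np.random.default_rng(3).poisson(4, (10, 2)).astype(float))
        z = expr.zscore_pooled(expr.zscore_within_embryo(adata))
        assert z.uns["mode"] == "pooled_stage"
        assert z.uns["provenance"]["first_pass"] == "within_embryo"


class TestZscoreCrossStage:
    def test_duplicated_stage_symmetric(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(5, (20, 3)).astype(float)
        x2 = np.vstack([x, x])
        adata = make_adata(x2, embryo=np.repeat([0, 1], 20),
                           stage=np.repeat(["A", "B"], 20))
        z = np.asarray(expr.zscore_cross_stage(adata).X)
        assert np.allclose(z[:20], z[20:])

    def test_high_stage_gets_positive_scores(self):
        a = np.full((10, 1), 50.0) + np.arange(10)[:, None]
        b = np.full((10, 1), 2.0) + np.arange(10)[:, None]
        adata = make_adata(np.vstack([a, b]), embryo=np.repeat([0, 1], 10),
                           stage=np.repeat(["hi", "lo"], 10))
        z = np.asarray(expr.zscore_cross_stage(adata).X)
        assert (z[:10] > 0).all()
        assert (z[10:] < 0).all()

    def test_single_stage_rejected(self):
        adata = make_adata(np.ones((4, 2)) + np.arange(4)[:, None])
        with pytest.raises(ValueError, match="two stages"):
            expr.zscore_cross_stage(adata)

    def test_column_normalization_invariant(self):
        rng = np.random.default_rng(5)
        adata = make_adata(rng.poisson(6, (30, 4)).astype(float),
                           embryo=np.repeat([0, 1, 2], 10),
                           stage=np.repeat(["A", "B", "C"], 10))
        z = np.asarray(expr.zscore_cross_stage(adata).X)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-9


def brute_force_average_linkage(d):
    """Naive agglomerative clustering with average linkage on a square
    distance matrix; returns the merge sequence as (frozenset, frozenset,
    height) triples."""
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((clusters[a], clusters[b], dist))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


class TestHCluster:
    def test_duplicate_rows_merge_first_at_zero_height(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, 0.0, 1.0],
                      [0.0, 4.0, 2.0]])
        res = expr.hcluster(x, k=2, cluster_genes=False)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_sequence_matches_bruteforce_on_six_points(self):
        rng = np.random.default_rng(6)
        for trial in range(3):
            x = rng.normal(size=(6, 4))
            d = np.zeros((6, 6))
            cond = expr.cosine_distances(x)
            from scipy.spatial.distance import squareform

            d = squareform(cond)
            merges = brute_force_average_linkage(d)
            lk = linkage(cond, method="average")
            # rebuild membership sets from the scipy linkage matrix
            members = {i: frozenset([i]) for i in range(6)}
            for step, (ia, ib, height, _) in enumerate(lk):
                sa, sb = members[int(ia)], members[int(ib)]
                ba, bb, bh = merges[step]
                assert {sa, sb} == {ba, bb}
                assert height == pytest.approx(bh)
                members[6 + step] = sa | sb

    def test_recovers_planted_subpopulations(self):
        rng = np.random.default_rng(7)
        profiles = np.eye(4).repeat(3, axis=1) * 5
        labels_true = rng.integers(0, 4, 80)
        x = rng.poisson(profiles[labels_true] + 0.2).astype(float)
        z = (x - x.mean(0)) / np.maximum(x.std(0, ddof=1), 1e-9)
        res = expr.hcluster(z, k=4, cluster_genes=False)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels_true, res.labels) >= 0.8

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            expr.hcluster(np.eye(3), k=5)

    def test_leaf_order_is_permutation(self):
        x = np.random.default_rng(8).normal(size=(12, 5))
        res = expr.hcluster(x, k=3, cluster_genes=True)
        assert sorted(res.leaf_order) == list(range(12))
        assert sorted(res.gene_leaf_order) == list(range(5))

    def test_cluster_labels_contiguous(self):
        x = np.random.default_rng(9).normal(size=(15, 4))
        res = expr.hcluster(x, k=4, cluster_genes=False)
        assert set(res.labels) == {1, 2, 3, 4}


class TestCosineDistances:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(10, 6))
        from scipy.spatial.distance import squareform

        d = squareform(expr.cosine_distances(x))
        for i in range(10):
            for j in range(10):
                u, v = x[i], x[j]
                expected = 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_zero_vector_convention(self):
        x = np.array([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])
        from scipy.spatial.distance import squareform

        d = squareform(expr.cosine_distances(x))
        assert d[0, 1] == 1.0  # zero vector
        assert d[0, 2] == pytest.approx(2.0)
        assert (d >= 0).all() and (d <= 2).all()


class TestSelection:
    def test_strict_boundary_on_single_gene(self):
        z = make_adata(np.array([[-1.0], [0.0], [0.2], [2.0]]))
        sel = expr.select_coexpressing(z, ["g0"])
        assert sel.cell_ids == ["c2", "c3"]

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(11)
        z = make_adata(rng.normal(size=(10, 5)))
        genes = ["g0", "g2", "g4"]
        sel = expr.select_coexpressing(z, genes)
        x = np.asarray(z.X)
        brute = set()
        for i in range(10):
            if all(x[i, z.var_names.get_loc(g)] > 0 for g in genes):
                brute.add(f"c{i}")
        assert set(sel.cell_ids) == brute

    def test_monotone_in_gene_set(self):
        rng = np.random.default_rng(12)
        z = make_adata(rng.normal(size=(30, 6)))
        small = expr.select_coexpressing(z, ["g0", "g1"])
        big = expr.select_coexpressing(z, ["g0", "g1", "g2"])
        assert set(big.cell_ids) <= set(small.cell_ids)

    def test_empty_and_unknown_gene_rejected(self):
        z = make_adata(np.ones((3, 2)))
        with pytest.raises(ValueError, match="empty"):
            expr.select_coexpressing(z, [])
        with pytest.raises(ValueError, match="not in the panel"):
            expr.select_coexpressing(z, ["nope"])


class TestOverlapAndComposition:
    def _sel(self, ids):
        return expr.Selection(gene_set=["g"], cell_ids=list(ids),
                              mask=np.array([]))

    def test_identical_selections(self):
        out = expr.overlap_stats(self._sel(["a", "b"]), self._sel(["a", "b"]))
        assert out["frac_of_a"] == 1.0 and out["frac_of_b"] == 1.0

    def test_disjoint_selections(self):
        out = expr.overlap_stats(self._sel(["a"]), self._sel(["b"]))
        assert out["frac_of_a"] == 0.0 and out["frac_of_b"] == 0.0

    def test_partial_overlap_hand_counted(self):
        out = expr.overlap_stats(self._sel(["a", "b", "c", "d"]),
                                 self._sel(["c", "d", "e"]))
        assert out["n_intersection"] == 2
        assert out["frac_of_a"] == pytest.approx(0.5)
        assert out["frac_of_b"] == pytest.approx(2 / 3)

    def test_empty_side_reported_missing(self):
        out = expr.overlap_stats(self._sel([]), self._sel(["a"]))
        assert np.isnan(out["frac_of_a"])

    def test_stage_composition_tabulation(self):
        stages = pd.Series(["X"] * 10 + ["Y"] * 5,
                           index=[f"c{i}" for i in range(15)])
        sel = self._sel(["c0", "c1", "c12"])
        table = expr.stage_composition(sel, stages).set_index("stage")
        assert table.loc["X", "n_selected"] == 2
        assert table.loc["X", "pct_of_stage"] == 20.0
        assert table.loc["Y", "pct_of_selection"] == pytest.approx(33.3)
        assert table["n_selected"].sum() == 3
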