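import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from syncytx.expression import (
    ExpressionMatrix,
    cluster_graph,
    cluster_hierarchical,
    detected_gene_overlap,
    feature_contrast_limits,
    filter_annotated_genes,
    filter_samples_by_depth,
    log2_tpm_threshold,
    lognormalize,
    module_score,
    pca,
    rank_markers,
    scale_with_regression,
    tpm_from_counts,
    wilcoxon_rank_sum,
)

from conftest import make_matrix


def tpm_oracle(counts, lengths):
    """Independently coded two-pass TPM reference."""
    counts = np.asarray(counts, dtype=float)
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        rates = [counts[i, j] / lengths[i] for i in range(counts.shape[0])]
        total = sum(rates)
        for i in range(counts.shape[0]):
            out[i, j] = rates[i] / total * 1e6
    return out


class TestExpressionMatrix:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionMatrix(
                values=np.zeros((3, 2)),
                layer="counts",
                gene_ids=["a", "b"],
                sample_ids=["s1", "s2"],
            )

    def test_counts_meta_autofilled(self):
        m = make_matrix([[0, 2], [3, 0], [1, 1]])
        np.testing.assert_array_equal(m.sample_meta["total"], [4, 3])
        np.testing.assert_array_equal(m.sample_meta["n_genes_detected"], [2, 2])

    def test_unknown_layer(self):
        with pytest.raises(ValueError, match="layer"):
            make_matrix([[1]], layer="weird")


class TestTPM:
    def test_equal_counts_equal_lengths(self):
        m = make_matrix([[10, 4], [10, 4]])
        t = tpm_from_counts(m, [100, 100])
        np.testing.assert_allclose(t.dense(), 500_000.0)

    def test_length_doubling_halves_weight(self):
        m = make_matrix([[10], [10]])
        t = tpm_from_counts(m, [100, 200])
        col = t.dense()[:, 0]
        assert col[0] == pytest.approx(2 * col[1])
        assert col.sum() == pytest.approx(1e6, rel=1e-3)

    def test_matches_two_pass_oracle(self, rng):
        counts = rng.integers(0, 50, size=(50, 10))
        counts[0, :] += 1  # avoid zero-total columns
        lengths = rng.integers(100, 5000, size=50).astype(float)
        m = make_matrix(counts)
        t = tpm_from_counts(m, lengths)
        np.testing.assert_allclose(t.dense(), tpm_oracle(counts, lengths), rtol=1e-6)

    def test_zero_total_sample_named(self):
        m = make_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            tpm_from_counts(m, [100, 100])

    def test_columns_sum_to_million(self, rng):
        counts = rng.integers(1, 100, size=(30, 6))
        t = tpm_from_counts(make_matrix(counts), rng.integers(200, 2000, 30).astype(float))
        np.testing.assert_allclose(t.dense().sum(axis=0), 1e6, rtol=1e-3)


class TestLog2TPMThreshold:
    def test_examples(self):
        m = make_matrix([[8.0], [0.5], [1.0]], layer="TPM")
        out = log2_tpm_threshold(m).dense()[:, 0]
        np.testing.assert_allclose(out, [3.0, 0.0, 0.0])

    def test_wrong_layer(self):
        with pytest.raises(ValueError):
            log2_tpm_threshold(make_matrix([[1]], layer="counts"))

    def test_monotone_and_zero_maps_to_zero(self, rng):
        v = np.sort(rng.uniform(0, 100, size=20))[:, None]
        out = log2_tpm_threshold(make_matrix(v, layer="TPM")).dense()[:, 0]
        assert (np.diff(out) >= 0).all()
        assert log2_tpm_threshold(make_matrix([[0.0]], layer="TPM")).dense()[0, 0] == 0.0


class TestLognormalize:
    def test_closed_form(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 100
        counts[1, 0] = 9900  # total 10,000
        out = lognormalize(make_matrix(counts)).dense()
        assert out[0, 0] == pytest.approx(np.log(101.0))

    def test_zero_maps_to_zero(self):
        out = lognormalize(make_matrix([[0, 1], [5, 1]])).dense()
        assert out[0, 0] == 0.0

    def test_monotone_within_column(self, rng):
        counts = rng.integers(0, 100, size=(30, 1))
        counts[0, 0] = 1
        out = lognormalize(make_matrix(counts)).dense()[:, 0]
        order = np.argsort(counts[:, 0])
        assert (np.diff(out[order]) >= 0).all()

    def test_zero_total_column(self):
        with pytest.raises(ValueError, match="s1"):
            lognormalize(make_matrix([[1, 0], [1, 0]]))


class TestDepthFilter:
    def test_grid_min_rule(self):
        m = make_matrix(
            [[150_000, 250_000]],
            meta={"specimen": ["SM1", "SM1"]},
        )
        out = filter_samples_by_depth(m, {"SM1": (200_000, None)})
        assert list(out.sample_ids) == ["s1"]

    def test_nucleus_max_rule(self):
        m = make_matrix([[3500, 2000]])
        out = filter_samples_by_depth(m, (None, 3000))
        assert list(out.sample_ids) == ["s1"]

    def test_amoeba_range_rule(self):
        m = make_matrix([[5000, 7000, 30_000]])
        out = filter_samples_by_depth(m, (6000, 25_000))
        assert list(out.sample_ids) == ["s1"]

    def test_unknown_specimen(self):
        m = make_matrix([[1]], meta={"specimen": ["SM1"]})
        with pytest.raises(KeyError, match="SM9"):
            filter_samples_by_depth(m, {"SM9": (0, None)})


class TestAnnotationFilter:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {
                "transcript_id": ["g0", "g1", "g2", "g3"],
                "uniprot_id": ["P1", "", "", ""],
                "description": ["", "a kinase", "", ""],
            }
        )

    def test_rules(self, annotation):
        m = make_matrix(np.arange(10).reshape(5, 2), gene_ids=[f"g{i}" for i in range(5)])
        out = filter_annotated_genes(m, annotation)
        # g0 uniprot only, g1 description only; g2/g3 empty; g4 absent
        assert list(out.gene_ids) == ["g0", "g1"]

    def test_order_preserved(self, annotation):
        annotation2 = annotation.copy()
        annotation2.loc[2, "uniprot_id"] = "P2"
        m = make_matrix(np.ones((4, 1)), gene_ids=["g2", "g0", "g3", "g1"])
        out = filter_annotated_genes(m, annotation2)
        assert list(out.gene_ids) == ["g2", "g0", "g1"]


class TestScaleRegression:
    def _lognorm(self, values, meta):
        return make_matrix(values, layer="lognorm", meta=meta)

    def test_perfectly_linear_gene_zeroed(self, rng):
        total = rng.uniform(1, 10, size=12)
        values = np.vstack([3 * total + 1, rng.normal(size=12)])
        m = self._lognorm(values, {"total": total, "n_genes_detected": np.ones(12)})
        out = scale_with_regression(m, covariates=pd.DataFrame({"total": total}))
        np.testing.assert_allclose(out.dense()[0], 0.0, atol=1e-8)

    def test_equal_covariates_reduce_to_zscore(self, rng):
        values = rng.normal(size=(5, 10))
        cov = pd.DataFrame({"c": np.ones(10)})
        m = self._lognorm(values, None)
        out = scale_with_regression(m, covariates=cov).dense()
        expected = (values - values.mean(1, keepdims=True)) / values.std(
            1, ddof=1, keepdims=True
        )
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        values = rng.normal(size=(100, 30))
        C = rng.normal(size=(30, 2))
        m = self._lognorm(values, None)
        out = scale_with_regression(m, covariates=pd.DataFrame(C)).dense()
        X = np.column_stack([np.ones(30), C])
        XtX_inv = np.linalg.inv(X.T @ X)  # normal equations
        for i in range(0, 100, 13):
            beta = XtX_inv @ X.T @ values[i]
            res = values[i] - X @ beta
            z = (res - res.mean()) / res.std(ddof=1)
            np.testing.assert_allclose(out[i], z, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        values = rng.normal(size=(20, 15))
        C = rng.normal(size=(15, 2))
        m = self._lognorm(values, None)
        out = scale_with_regression(m, covariates=pd.DataFrame(C)).dense()
        for j in range(2):
            c = C[:, j] - C[:, j].mean()
            c /= np.linalg.norm(c)
            dots = out @ c / np.maximum(np.linalg.norm(out, axis=1), 1e-12)
            assert np.abs(dots).max() < 1e-6

    def test_constant_gene_zeroed(self):
        m = self._lognorm(np.vstack([np.full(6, 2.0), np.arange(6.0)]), None)
        out = scale_with_regression(m, covariates=pd.DataFrame({"c": np.arange(6.0) ** 2}))
        np.testing.assert_array_equal(out.dense()[0], 0.0)

    def test_clipping(self, rng):
        values = rng.normal(size=(4, 8))
        m = self._lognorm(values, None)
        out = scale_with_regression(m, covariates=pd.DataFrame({"c": np.ones(8)}), clip=0.5)
        assert np.abs(out.dense()).max() <= 0.5


class TestPCA:
    def test_line_explains_everything(self, rng):
        t = rng.normal(size=20)
        direction = rng.normal(size=5)
        values = np.outer(direction, t)  # genes x samples on a line
        m = make_matrix(values, layer="scaled")
        _, evr, _ = pca(m, n_pcs=3)
        assert evr[0] >= 0.999

    def test_deterministic_across_runs(self, rng):
        values = rng.normal(size=(30, 12))
        m = make_matrix(values, layer="scaled")
        s1, _, _ = pca(m, n_pcs=4)
        s2, _, _ = pca(m, n_pcs=4)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-6)

    def test_two_cluster_auc(self, rng):
        a = rng.normal(0, 0.2, size=(10, 15))
        b = rng.normal(4, 0.2, size=(10, 15))
        values = np.concatenate([a, b], axis=1)
        m = make_matrix(values, layer="scaled")
        scores, _, _ = pca(m, n_pcs=2)
        pc1 = scores["PC1"].to_numpy()
        labels = np.array([0] * 15 + [1] * 15)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(labels, pc1)
        assert max(auc, 1 - auc) == 1.0

    def test_n_pcs_too_large(self):
        m = make_matrix(np.ones((3, 3)), layer="scaled")
        with pytest.raises(ValueError):
            pca(m, n_pcs=4)


class TestGraphClustering:
    def test_two_blobs_ari_one(self, rng):
        a = rng.normal(0, 0.3, size=(20, 3))
        b = rng.normal(5, 0.3, size=(20, 3))
        scores = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(40)])
        assign = cluster_graph(scores, k_neighbors=10, resolution=1.0, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0
        assert assign.labels.nunique() == 2

    def test_resolution_zero_single_cluster(self, rng):
        scores = pd.DataFrame(rng.normal(size=(30, 3)))
        assign = cluster_graph(scores, k_neighbors=10, resolution=0.0, seed=0)
        assert assign.labels.nunique() == 1

    def test_duplicated_dataset_symmetry(self, rng):
        a = rng.normal(0, 0.3, size=(15, 3))
        b = rng.normal(5, 0.3, size=(15, 3))
        X = np.vstack([a, b])
        scores = pd.DataFrame(
            np.vstack([X, X]), index=[f"s{i}" for i in range(60)]
        )
        assign = cluster_graph(scores, k_neighbors=10, resolution=1.0, seed=0)
        lab = assign.labels.to_numpy()
        assert adjusted_rand_score(lab[:30], lab[30:]) == 1.0

    def test_determinism(self, rng):
        scores = pd.DataFrame(rng.normal(size=(40, 4)))
        a1 = cluster_graph(scores, k_neighbors=8, resolution=0.8, seed=3)
        a2 = cluster_graph(scores, k_neighbors=8, resolution=0.8, seed=3)
        assert a1.labels.equals(a2.labels)

    def test_k_too_large(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            cluster_graph(scores, k_neighbors=5)


class TestHierarchicalClustering:
    def test_identical_samples_merge_first(self):
        X = np.array([[1.0, 2, 3], [1.0, 2, 3], [9, 1, 5]])
        assign = cluster_hierarchical(X, k=2)
        Z = assign.linkage
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        X = np.array([[1.0, 2, 3], [3.0, 2, 1]])
        assign = cluster_hierarchical(X, k=2)
        # ward height of the sole merge equals the pairwise distance of 2
        assert assign.linkage[0, 2] == pytest.approx(2.0)

    def test_three_block_recovery(self, rng):
        base = rng.normal(size=(3, 30))
        rows = []
        truth = []
        for b in range(3):
            for _ in range(6):
                rows.append(base[b] + rng.normal(0, 0.05, 30))
                truth.append(b)
        assign = cluster_hierarchical(np.array(rows), k=3)
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(12, 20))
        ids = [f"s{i}" for i in range(12)]
        a1 = cluster_hierarchical(pd.DataFrame(X, index=ids), k=3)
        perm = rng.permutation(12)
        a2 = cluster_hierarchical(pd.DataFrame(X[perm], index=np.array(ids)[perm]), k=3)
        merged = pd.concat([a1.labels.rename("a"), a2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(merged["a"], merged["b"]) == 1.0

    def test_zero_variance_sample_named(self):
        X = np.array([[1.0, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="s0"):
            cluster_hierarchical(pd.DataFrame(X, index=["s0", "s1"]))

    def test_auto_k_by_height_gap(self, rng):
        a = rng.normal(0, 0.05, size=(6, 10))
        b = rng.normal(8, 0.05, size=(6, 10)) * np.linspace(1, 2, 10)
        assign = cluster_hierarchical(np.vstack([a, b]))
        assert assign.params["k"] == 2


class TestWilcoxon:
    def test_exact_matches_scipy(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(1.0, size=8)
        _, p = wilcoxon_rank_sum(x, y, method="exact")
        ref = mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_close_to_exact(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(2.0, size=8)
        _, p_asym = wilcoxon_rank_sum(x, y, method="asymptotic")
        _, p_exact = wilcoxon_rank_sum(x, y, method="exact")
        assert abs(p_asym - p_exact) < 0.02

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 5, size=25).astype(float)
        _, p = wilcoxon_rank_sum(x, y, method="asymptotic")
        ref = mannwhitneyu(
            x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestRankMarkers:
    def test_constant_gene_not_reported(self):
        values = np.vstack([np.full(10, 2.0), np.r_[np.zeros(5), np.ones(5) * 3]])
        m = make_matrix(values, layer="lognorm")
        mt = rank_markers(m, np.array([0] * 5 + [1] * 5))
        assert "g0" not in set(mt.table["gene"])

    def test_planted_marker_recovery(self):
        import dataclasses

        from syncytx.expression import lognormalize
        from syncytx.simulate import SimulationConfig, simulate_spatial_grids

        hits, totals = 0, 0
        for seed in range(3):
            cfg = SimulationConfig(n_genes=400, seed=seed, oat_size=0)
            matrix, _, truth = simulate_spatial_grids(cfg)
            log = lognormalize(matrix)
            regions = pd.Series(
                [truth.region_of_grid[g] for g in matrix.sample_ids], index=matrix.sample_ids
            )
            mt = rank_markers(log, regions)
            top = set(mt.top_genes("fan", n=50))
            planted = set(truth.program_genes["fan"])
            hits += len(top & planted)
            totals += len(planted)
        assert hits >= 0.9 * totals

    def test_single_sample_cluster_warns(self):
        values = np.random.default_rng(0).normal(2, 1, size=(5, 6))
        m = make_matrix(np.abs(values), layer="lognorm")
        with pytest.warns(UserWarning, match="single sample"):
            rank_markers(m, np.array([0] + [1] * 5), min_pct=0.0, logfc_min=0.0)

    def test_padj_at_least_p(self, rng):
        values = np.abs(rng.normal(1, 1, size=(40, 20)))
        m = make_matrix(values, layer="lognorm")
        mt = rank_markers(m, rng.integers(0, 2, 20), min_pct=0.0, logfc_min=0.0)
        assert (mt.table["p_adj"] >= mt.table["p"] - 1e-15).all()
        assert mt.table["p_adj"].between(0, 1).all()
        assert mt.table[["pct_in", "pct_out"]].to_numpy().min() >= 0
        assert mt.table[["pct_in", "pct_out"]].to_numpy().max() <= 1


class TestModuleScore:
    def test_self_control_near_zero(self, rng):
        values = np.abs(rng.normal(1.0, 0.01, size=(200, 30)))
        m = make_matrix(values, layer="lognorm")
        s = module_score(m, [f"g{i}" for i in range(0, 200, 10)], seed=0)
        assert abs(s.mean()) < 0.01

    def test_shift_invariance(self, rng):
        values = np.abs(rng.normal(1.0, 0.5, size=(100, 10)))
        m1 = make_matrix(values, layer="lognorm")
        m2 = make_matrix(values + 7.0, layer="lognorm")
        genes = [f"g{i}" for i in range(5)]
        s1 = module_score(m1, genes, seed=1)
        s2 = module_score(m2, genes, seed=1)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_missing_genes_listed(self, rng):
        m = make_matrix(np.ones((5, 3)), layer="lognorm")
        with pytest.raises(ValueError, match="gX"):
            module_score(m, ["g0", "gX"])

    def test_empty_set(self, rng):
        m = make_matrix(np.ones((5, 3)), layer="lognorm")
        with pytest.raises(ValueError, match="empty"):
            module_score(m, [])


class TestDetectedGeneOverlap:
    def test_identical_matrices(self, rng):
        values = rng.integers(0, 20, size=(50, 4))
        a = make_matrix(values)
        b = make_matrix(values.copy())
        res = detected_gene_overlap({"a": a, "b": b})
        assert res["detected"]["a"] == res["detected"]["b"]
        assert res["venn"][("a", "b")] == len(res["detected"]["a"])

    def test_cutoff_zero_all_nonzero(self):
        values = np.array([[0, 0], [1, 0], [5, 5]])
        m1, m2 = make_matrix(values), make_matrix(values)
        res = detected_gene_overlap({"a": m1, "b": m2}, quantile_cutoff=0.0)
        assert res["detected"]["a"] == {"g1", "g2"}

    def test_bottom_decile_removed(self):
        totals = np.arange(1, 101, dtype=float)
        values = totals[:, None]
        m = make_matrix(values)
        res = detected_gene_overlap({"a": m, "b": make_matrix(values)}, quantile_cutoff=0.10)
        detected = res["detected"]["a"]
        assert len(detected) == 90
        assert "g9" not in detected and "g10" in detected

    def test_disjoint_universes(self):
        a = make_matrix(np.ones((2, 2)), gene_ids=["a1", "a2"])
        b = make_matrix(np.ones((2, 2)), gene_ids=["b1", "b2"])
        with pytest.raises(ValueError, match="no genes"):
            detected_gene_overlap({"a": a, "b": b})


class TestFeatureContrast:
    def test_hand_quantiles(self):
        lo, hi = feature_contrast_limits(np.arange(1, 11, dtype=float))
        assert lo == pytest.approx(1.9)
        assert hi == pytest.approx(9.1)

    def test_constant_nonzero(self):
        assert feature_contrast_limits([4.0, 4.0, 4.0]) == (4.0, 4.0)

    def test_zeros_excluded(self):
        assert feature_contrast_limits([0.0, 0.0, 5.0]) == (5.0, 5.0)

    def test_all_zero(self):
        with pytest.raises(ValueError):
            feature_contrast_limits([0.0, 0.0])

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_limits_within_range(self, values):
        lo, hi = feature_contrast_limits(values)
        assert min(values) <= lo <= hi <= max(values)
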