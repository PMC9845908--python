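"""Coexpression network: adjacency/TOM closed forms, module cuts, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

import provisio as pv
from provisio import network
from conftest import block_expression


class TestGoodGenes:
    def test_constant_gene_dropped_varying_kept(self):
        expr = pd.DataFrame({"const": [1.0] * 5, "vary": [1, 2, 3, 4, 5.0]})
        kept = pv.good_genes_filter(expr)
        assert list(kept) == ["vary"]

    def test_planted_constant_and_missing_genes_dropped(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((10, 8)),
                            columns=[f"g{i}" for i in range(8)])
        for g in ("g0", "g1", "g2"):
            expr[g] = 7.0
        for g in ("g3", "g4"):
            expr.loc[expr.index[:5], g] = np.nan
        kept = pv.good_genes_filter(expr, max_missing_frac=0.4)
        assert set(expr.columns) - set(kept) == {"g0", "g1", "g2", "g3", "g4"}


class TestSampleOutliers:
    def test_identical_samples_unflagged(self):
        expr = pd.DataFrame(np.ones((5, 10)), index=[f"s{i}" for i in range(5)])
        assert pv.detect_sample_outliers(expr) == []

    def test_extreme_shift_flagged(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.standard_normal((8, 50)),
                            index=[f"s{i}" for i in range(8)])
        expr.loc["s3"] += 100.0
        assert pv.detect_sample_outliers(expr) == ["s3"]

    def test_planted_outlier_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.standard_normal((10, 40)),
                                index=[f"s{i}" for i in range(10)])
            expr.loc["s7"] += 15.0
            hits += pv.detect_sample_outliers(expr) == ["s7"]
        assert hits == 20


class TestScaleFree:
    def test_perfect_correlation_gives_complete_graph_connectivity(self):
        n = 12
        base = np.linspace(-1, 1, 8)
        expr = pd.DataFrame(np.tile(base[:, None], (1, n)),
                            columns=[f"g{i}" for i in range(n)])
        scan = pv.scale_free_scan(expr, betas=[1, 4])
        assert np.allclose(scan["mean_connectivity"], n - 1)

    def test_mean_connectivity_non_increasing_in_beta(self, oocyte_logcpm):
        logcpm, _ = oocyte_logcpm
        scan = pv.scale_free_scan(logcpm.iloc[:150].T, betas=range(1, 11))
        k = scan["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-9).all()

    def test_table_matches_direct_recomputation(self):
        expr, _ = block_expression([30, 30], n_samples=20, n_background=40, seed=2)
        scan = pv.scale_free_scan(expr, betas=[2, 6], n_bins=10)
        cor = np.abs(np.corrcoef(expr.to_numpy().T))
        for _, row in scan.iterrows():
            a = cor ** row["beta"]
            np.fill_diagonal(a, 0.0)
            k = a.sum(axis=1)
            assert row["mean_connectivity"] == pytest.approx(k.mean(), rel=1e-12)


class TestTOM:
    def test_two_gene_closed_form(self):
        x = 0.37
        adj = np.array([[1.0, x], [x, 1.0]])
        tom = pv.tom_similarity(adj)
        assert tom[0, 1] == pytest.approx(x, abs=1e-12)

    def test_identity_adjacency_gives_identity(self):
        tom = pv.tom_similarity(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_matches_scalar_formula_on_toy(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, size=(4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = pv.tom_similarity(a)
        k = a.sum(axis=0) - 1.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(4) if u not in (i, j))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry(self, oocyte_logcpm):
        logcpm, _ = oocyte_logcpm
        adj = pv.adjacency(logcpm.iloc[:100].T, beta=4)
        tom = pv.tom_similarity(adj)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)
        assert np.allclose(pv.adjacency(logcpm.iloc[:50].T, beta=1),
                           np.abs(np.corrcoef(logcpm.iloc[:50])), atol=1e-12)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError):
            pv.tom_similarity(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestCutModules:
    def test_two_separated_blocks_recovered_exactly(self):
        expr, truth = block_expression([40, 40], seed=3, noise_sd=0.2)
        tom = pv.tom_similarity(pv.adjacency(expr, beta=4))
        part = pv.cut_modules(tom, genes=expr.columns)
        assert part.labels.max() == 2
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_block_below_min_size_stays_unassigned(self):
        expr, truth = block_expression([10], n_background=60, seed=4)
        tom = pv.tom_similarity(pv.adjacency(expr, beta=4))
        part = pv.cut_modules(tom, genes=expr.columns)
        assert (part.labels[truth == 1] == 0).all()

    def test_fewer_genes_than_min_size_all_unassigned(self):
        expr, _ = block_expression([10], seed=5)
        tom = pv.tom_similarity(pv.adjacency(expr, beta=4))
        part = pv.cut_modules(tom, genes=expr.columns)
        assert (part.labels == 0).all()

    def test_partition_permutation_equivariant(self):
        expr, _ = block_expression([35, 45], n_background=30, seed=6)
        tom = pv.tom_similarity(pv.adjacency(expr, beta=4))
        part1 = pv.cut_modules(tom, genes=expr.columns)
        perm = np.random.default_rng(0).permutation(expr.shape[1])
        expr_p = expr.iloc[:, perm]
        tom_p = pv.tom_similarity(pv.adjacency(expr_p, beta=4))
        part2 = pv.cut_modules(tom_p, genes=expr_p.columns)
        # same induced partition: compare as ARI = 1 on the shared gene order
        assert adjusted_rand_score(part1.labels[expr.columns],
                                   part2.labels[expr.columns]) == 1.0


class TestEigengene:
    def test_single_gene_module_is_its_zscore(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame({"g0": rng.standard_normal(12)})
        labels = pd.Series({"g0": 1})
        eig = pv.module_eigengene(expr, labels)["ME1"]
        z = (expr["g0"] - expr["g0"].mean()) / expr["g0"].std(ddof=1)
        assert np.corrcoef(eig, z)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_correlated_module_eigengene_correlates_one(self):
        base = np.linspace(0, 1, 15)
        expr = pd.DataFrame({f"g{i}": 2 * base + i for i in range(6)})
        labels = pd.Series(1, index=expr.columns)
        eig = pv.module_eigengene(expr, labels)["ME1"]
        for g in expr.columns:
            assert np.corrcoef(eig, expr[g])[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_pca(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal(20)
        expr = pd.DataFrame(
            {f"g{i}": f + 0.3 * rng.standard_normal(20) for i in range(20)}
        )
        labels = pd.Series(1, index=expr.columns)
        eig = pv.module_eigengene(expr, labels)["ME1"]
        z = (expr - expr.mean()) / expr.std(ddof=1)
        pc1 = PCA(n_components=1).fit_transform(z.to_numpy())[:, 0]
        assert abs(np.corrcoef(eig, pc1)[0, 1]) >= 1 - 1e-8


class TestMergeModules:
    def test_same_latent_factor_modules_merge(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal(20)
        expr = pd.DataFrame(
            {f"g{i}": f + 0.2 * rng.standard_normal(20) for i in range(20)}
        )
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.columns)
        merged = pv.merge_similar_modules(pv.ModulePartition(labels), expr)
        assert merged.labels.nunique() == 1

    def test_orthogonal_modules_unchanged(self):
        expr, truth = block_expression([20, 20], seed=10, noise_sd=0.2)
        merged = pv.merge_similar_modules(pv.ModulePartition(truth.copy()), expr)
        assert adjusted_rand_score(truth, merged.labels) == 1.0

    def test_transitive_chain_merges_to_fixed_point(self):
        # three modules driven by overlapping factors; post-condition audit:
        # no remaining eigengene pair correlates above 1 - cut_height
        rng = np.random.default_rng(11)
        f1, f2 = rng.standard_normal(30), rng.standard_normal(30)
        groups = {
            1: f1,
            2: 0.85 * f1 + 0.55 * f2,
            3: 0.55 * f1 + 0.85 * f2,
        }
        cols, data, labs = [], [], []
        for lab, f in groups.items():
            for j in range(10):
                cols.append(f"m{lab}_g{j}")
                data.append(f + 0.1 * rng.standard_normal(30))
                labs.append(lab)
        expr = pd.DataFrame(np.array(data).T, columns=cols)
        merged = pv.merge_similar_modules(
            pv.ModulePartition(pd.Series(labs, index=cols)), expr, cut_height=0.25
        )
        if merged.labels.nunique() > 1:
            cor = merged.eigengenes.corr().to_numpy()
            np.fill_diagonal(cor, 0.0)
            assert cor.max() <= 0.75 + 1e-9


class TestModuleTrait:
    def test_trait_equal_to_eigengene_gives_r_one(self):
        season = pd.Series([0] * 6 + [1] * 6, index=[f"s{i}" for i in range(12)])
        eig = pd.DataFrame({"ME1": (season - season.mean()) / season.std(ddof=1)})
        out = pv.module_trait_correlation(eig, pd.DataFrame({"season": season}))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_hand_computed_r_matches_t_transform(self):
        from scipy import stats
        eig = pd.DataFrame({"ME1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        trait = pd.DataFrame({"t": [1, 0, 1, 0, 1, 0]})
        out = pv.module_trait_correlation(eig, trait)
        r = out["r"].iloc[0]
        n = 6
        t = abs(r) * np.sqrt((n - 2) / (1 - r ** 2))
        expected_p = 2 * stats.t.sf(t, n - 2)
        assert out["p"].iloc[0] == pytest.approx(expected_p, abs=1e-10)

    def test_constant_trait_reported_missing(self):
        eig = pd.DataFrame({"ME1": np.arange(5.0)})
        out = pv.module_trait_correlation(eig, pd.DataFrame({"t": [1] * 5}))
        assert np.isnan(out["r"].iloc[0]) and not out["significant"].iloc[0]
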