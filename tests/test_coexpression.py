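import numpy as np
import pandas as pd
import pytest

from gmtrepurpose import coexpression
from gmtrepurpose.core_io import ExpressionMatrix

from conftest import make_expr, two_block_expr
from oracles import tom_brute


def zipf_module_expr(n_genes=200, n_factors=12, n_samples=100, seed=3) -> ExpressionMatrix:
    """Genes load on factors with Zipf popularity: heavy-tailed connectivity."""
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_factors, n_samples))
    p = 1.0 / np.arange(1, n_factors + 1)
    assign = rng.choice(n_factors, size=n_genes, p=p / p.sum())
    lam = rng.uniform(0.8, 1.6, n_genes)
    X = lam[:, None] * factors[assign] + rng.standard_normal((n_genes, n_samples))
    return make_expr(X, genes=[f"G{i:03d}" for i in range(n_genes)])


class TestSoftThreshold:
    def test_structured_data_reaches_target_by_twelve(self):
        report = coexpression.pick_soft_threshold(zipf_module_expr())
        assert report.reached_target
        assert report.selected_beta <= 12
        sel = report.table.loc[report.table.beta == report.selected_beta, "r2"].iloc[0]
        assert sel >= 0.8

    def test_unreachable_target_takes_warning_path_with_argmax(self, rng):
        expr = make_expr(rng.standard_normal((100, 200)))
        report = coexpression.pick_soft_threshold(expr, betas=range(1, 7),
                                                  target_r2=0.999)
        assert not report.reached_target
        best = report.table.loc[report.table.r2.idxmax()]
        assert report.selected_beta == best.beta

    def test_constant_gene_rejected(self, rng):
        X = rng.standard_normal((25, 10))
        X[3] = 1.0
        with pytest.raises(ValueError, match="G4"):
            coexpression.pick_soft_threshold(make_expr(X))

    def test_perfectly_correlated_genes_have_unit_adjacency(self):
        base = np.arange(10.0)
        expr = make_expr(np.vstack([base, 2 * base + 1, -3 * base]))
        for beta in (1.0, 6.0, 12.0):
            a = coexpression.compute_adjacency(expr, beta)
            assert np.allclose(a, 1.0, atol=1e-10)


class TestTom:
    def test_matches_triple_loop_oracle(self, rng):
        X = rng.standard_normal((20, 15))
        expected = tom_brute(X, 6.0)
        got = coexpression.compute_tom(make_expr(X), 6.0).to_numpy()
        assert np.allclose(got, expected, atol=1e-10)

    def test_three_perfectly_correlated_genes(self):
        base = np.arange(8.0)
        expr = make_expr(np.vstack([base, 2 * base, base + 5]))
        tom = coexpression.compute_tom(expr, 7.0).to_numpy()
        assert np.allclose(tom, 1.0, atol=1e-10)  # (1+1)/(2+1-1)

    def test_symmetric_and_bounded_on_random_data(self, rng):
        tom = coexpression.compute_tom(make_expr(rng.standard_normal((15, 12))), 6.0)
        arr = tom.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert arr.min() >= 0.0 and arr.max() <= 1.0 + 1e-12

    def test_isolated_gene_has_near_zero_overlap(self, rng):
        expr = two_block_expr(n_per=10, n_bg=1, n_samples=80, seed=1)
        tom = coexpression.compute_tom(expr, 6.0)
        bg = tom.loc["BG_000"].drop("BG_000")
        assert bg.max() < 0.05


class TestModules:
    def test_two_planted_blocks_recovered(self):
        for seed in range(3):
            expr = two_block_expr(seed=seed)
            tom = coexpression.compute_tom(expr, 6.0)
            mods = coexpression.detect_modules(1 - tom, min_module_size=30)
            assert len(mods.module_ids) == 2
            for b in range(2):
                planted = {g for g in expr.gene_ids if g.startswith(f"B{b}_")}
                best = max(
                    len(planted & set(mods.genes_in(m))) / len(planted | set(mods.genes_in(m)))
                    for m in mods.module_ids
                )
                assert best >= 0.9

    def test_iid_data_yields_no_modules(self, rng):
        expr = make_expr(rng.standard_normal((100, 60)))
        tom = coexpression.compute_tom(expr, 6.0)
        mods = coexpression.detect_modules(1 - tom, min_module_size=30)
        assert mods.module_ids == []
        assert (mods.labels == 0).all()

    def test_min_size_above_gene_count_unassigns_everything(self):
        expr = two_block_expr(n_per=20, n_samples=40)
        tom = coexpression.compute_tom(expr, 6.0)
        mods = coexpression.detect_modules(1 - tom, min_module_size=100)
        assert (mods.labels == 0).all()

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.4], [0.5, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            coexpression.detect_modules(d)


class TestEigengenes:
    def _assignment(self, expr, blocks):
        labels = pd.Series(0, index=expr.gene_ids)
        for i, genes in enumerate(blocks, start=1):
            labels[genes] = i
        return coexpression.ModuleAssignment(labels)

    def test_identical_genes_give_standardized_profile(self):
        profile = np.array([3.0, -1.0, 2.0, 0.0, 4.0, -2.0])
        expr = make_expr(np.vstack([profile, profile, profile, -profile]))
        assign = self._assignment(expr, [["G1", "G2", "G3"]])
        eig = coexpression.module_eigengenes(expr, assign).data.loc[1]
        expected = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig, expected, atol=1e-8)

    def test_sign_orientation_invariant_to_member_flips(self):
        expr = two_block_expr(n_per=10, n_samples=30, seed=4)
        genes = [g for g in expr.gene_ids if g.startswith("B0_")]
        assign = self._assignment(expr, [genes])
        eig1 = coexpression.module_eigengenes(expr, assign).data.loc[1]
        flipped = ExpressionMatrix(expr.data.copy())
        flipped.data.loc[genes] *= -1
        eig2 = coexpression.module_eigengenes(flipped, assign).data.loc[1]
        assert np.allclose(np.abs(eig1), np.abs(eig2), atol=1e-8)

    def test_eigengene_explains_most_variance(self):
        expr = two_block_expr(n_per=15, n_samples=50, seed=5)
        genes = [g for g in expr.gene_ids if g.startswith("B1_")]
        assign = self._assignment(expr, [genes])
        eig = coexpression.module_eigengenes(expr, assign).data.loc[1].to_numpy()
        block = expr.data.loc[genes].to_numpy()
        z = (block - block.mean(1, keepdims=True)) / block.std(1, ddof=1, keepdims=True)

        def explained(v):
            v = (v - v.mean()) / np.linalg.norm(v - v.mean())
            return float(np.sum((z @ v) ** 2))

        assert explained(eig) >= max(explained(row) for row in z) - 1e-8


class TestMergeAndTraits:
    def test_highly_correlated_modules_merge(self, rng):
        # two modules driven by the same factor (eigengene cor ~0.9+), one independent
        f1, f2 = rng.standard_normal((2, 60))
        b1 = 2 * f1 + 0.3 * rng.standard_normal((10, 60))
        b2 = 2 * f1 + 0.3 * rng.standard_normal((10, 60))
        b3 = 2 * f2 + 0.3 * rng.standard_normal((10, 60))
        expr = make_expr(np.vstack([b1, b2, b3]))
        labels = pd.Series([1] * 10 + [2] * 10 + [3] * 10, index=expr.gene_ids)
        merged, eig = coexpression.merge_modules(
            expr, coexpression.ModuleAssignment(labels), merge_height=0.25)
        assert len(merged.module_ids) == 2
        again, _ = coexpression.merge_modules(expr, merged, merge_height=0.25)
        assert (again.labels == merged.labels).all()

    def test_uncorrelated_modules_not_merged(self):
        expr = two_block_expr(n_per=10, n_samples=60, seed=6)
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.gene_ids)
        merged, _ = coexpression.merge_modules(
            expr, coexpression.ModuleAssignment(labels), merge_height=0.25)
        assert len(merged.module_ids) == 2

    def test_merge_monotone_in_height(self, rng):
        expr = two_block_expr(n_per=10, n_samples=40, seed=7)
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.gene_ids)
        assign = coexpression.ModuleAssignment(labels)
        counts = [len(coexpression.merge_modules(expr, assign, merge_height=h)[0].module_ids)
                  for h in (0.05, 0.5, 1.2, 1.9)]
        assert counts == sorted(counts, reverse=True)

    def test_trait_equal_to_eigengene_has_unit_correlation(self):
        expr = two_block_expr(n_per=10, n_samples=40, seed=8)
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.gene_ids)
        eig = coexpression.module_eigengenes(expr, coexpression.ModuleAssignment(labels))
        traits = pd.DataFrame({"t": eig.data.loc[1]})
        table = coexpression.module_trait_correlation(eig, traits)
        row = table[(table.module == 1) & (table.trait == "t")].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-10)
        assert row.p < 1e-12
        assert coexpression.top_module_for_trait(table, "t") == 1

    def test_null_trait_uncorrelated(self, rng):
        expr = two_block_expr(n_per=10, n_samples=100, seed=9)
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.gene_ids)
        eig = coexpression.module_eigengenes(expr, coexpression.ModuleAssignment(labels))
        traits = pd.DataFrame({"noise": rng.standard_normal(100)},
                              index=eig.data.columns)
        table = coexpression.module_trait_correlation(eig, traits)
        assert table.r.abs().max() < 0.35
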