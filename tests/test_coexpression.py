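"""Signed adjacency, TOM, module detection and eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hccfusion.coexpression import (
    CoexpressionParams,
    ModuleAssignment,
    detect_modules,
    filter_variable_genes,
    module_eigengenes,
    module_trait_correlation,
    signed_adjacency,
    tom_similarity,
)


def expr_frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


def planted_blocks(rng, n_blocks=2, block=50, samples=100, loading=None):
    """Block-correlated genes: shared factor per block plus noise."""
    loading = loading if loading is not None else np.sqrt(0.8)
    rows = []
    for _b in range(n_blocks):
        factor = rng.normal(size=samples)
        noise = rng.normal(size=(block, samples))
        rows.append(loading * factor + np.sqrt(1 - loading**2) * noise)
    return expr_frame(np.vstack(rows))


class TestSignedAdjacency:
    def test_closed_form_correlation_endpoints(self):
        x = np.arange(10, dtype=float)
        expr = expr_frame([x, 2 * x + 3, -x + 1, np.cos(x)])
        a = signed_adjacency(expr, CoexpressionParams(beta=8))
        assert a.iloc[0, 1] == pytest.approx(1.0)  # cor +1
        assert a.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor -1

    def test_zero_correlation_gives_half_to_the_beta(self, rng):
        n = 20000
        x = rng.normal(size=n)
        expr = expr_frame([x, rng.normal(size=n)])
        a = signed_adjacency(expr, CoexpressionParams(beta=8))
        assert a.iloc[0, 1] == pytest.approx(0.5**8, abs=2e-3)

    def test_zero_variance_gene_rejected(self):
        expr = expr_frame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            signed_adjacency(expr)

    def test_affine_rescaling_and_sample_order_invariance(self, rng):
        expr = expr_frame(rng.normal(size=(6, 30)))
        a = signed_adjacency(expr).to_numpy()
        rescaled = expr.copy()
        rescaled.iloc[2] = 5.0 * rescaled.iloc[2] + 7.0
        perm = rng.permutation(30)
        b = signed_adjacency(rescaled.iloc[:, perm]).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestTOM:
    def test_three_gene_closed_form(self):
        a = pd.DataFrame(np.full((3, 3), 0.5) + np.eye(3) * 0.5)
        tom = tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx((0.25 + 0.5) / (1.0 + 1.0 - 0.5))

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = tom_similarity(pd.DataFrame(np.eye(5)))
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_symmetric_unit_diagonal_and_bounded(self, rng):
        A = rng.random((15, 15))
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        A = np.eye(4)
        A[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame(A))


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self, rng):
        expr = planted_blocks(rng, n_blocks=2, block=50, samples=100)
        params = CoexpressionParams(min_module_size=30)
        tom = tom_similarity(signed_adjacency(expr, params))
        mods = detect_modules(tom, params)
        assert len(mods.modules) == 2
        first_block = set(expr.index[:50])
        recovered = {frozenset(g) for g in mods.modules.values()}
        assert frozenset(first_block) in recovered
        assert (mods.labels != "grey").all()

    def test_iid_noise_goes_grey(self):
        grey_runs = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            expr = expr_frame(rng.normal(size=(120, 100)))
            params = CoexpressionParams(min_module_size=30)
            tom = tom_similarity(signed_adjacency(expr, params))
            mods = detect_modules(tom, params)
            grey_runs += len(mods.modules) == 0
        assert grey_runs >= int(0.9 * n_seeds)

    def test_small_block_below_min_size_goes_grey(self, rng):
        expr = planted_blocks(rng, n_blocks=1, block=10, samples=100)
        params = CoexpressionParams(min_module_size=30)
        tom = tom_similarity(signed_adjacency(expr, params))
        mods = detect_modules(tom, params)
        assert (mods.labels == "grey").all()

    def test_variable_gene_filter_keeps_top_mad(self, rng):
        arr = rng.normal(size=(20, 30))
        arr[:5] *= 10.0
        expr = expr_frame(arr)
        kept = filter_variable_genes(expr, 5)
        assert set(kept.index) == set(expr.index[:5])


class TestEigengenes:
    def test_perfectly_correlated_module(self):
        x = np.linspace(0, 1, 40)
        expr = expr_frame([x, 2 * x, 3 * x + 1])
        eig, ve = module_eigengenes(expr, {"M1": list(expr.index)})
        assert ve["M1"] == pytest.approx(1.0)
        for g in expr.index:
            r = np.corrcoef(eig.loc["M1"], expr.loc[g])[0, 1]
            assert abs(r) == pytest.approx(1.0)
        assert eig.loc["M1"].std(ddof=0) == pytest.approx(1.0)

    def test_factor_model_variance_explained(self, rng):
        # one-factor module with loadings 0.8: variance explained ~ 0.64
        expr = planted_blocks(rng, n_blocks=1, block=60, samples=200, loading=0.8)
        eig, ve = module_eigengenes(expr, {"M1": list(expr.index)})
        assert ve["M1"] == pytest.approx(0.64, abs=0.1)

    def test_sign_orientation_equivariance(self, rng):
        expr = planted_blocks(rng, n_blocks=1, block=20, samples=50)
        eig, _ = module_eigengenes(expr, {"M1": list(expr.index)})
        neg, _ = module_eigengenes(-expr, {"M1": list(expr.index)})
        np.testing.assert_allclose(
            neg.loc["M1"].to_numpy(), -eig.loc["M1"].to_numpy(), atol=1e-10
        )

    def test_single_gene_module_is_standardized_gene(self, rng):
        expr = expr_frame(rng.normal(size=(3, 25)))
        eig, ve = module_eigengenes(expr, {"M1": [expr.index[0]]})
        g = expr.iloc[0].to_numpy()
        z = (g - g.mean()) / g.std()
        np.testing.assert_allclose(np.abs(eig.loc["M1"].to_numpy()), np.abs(z), atol=1e-10)
        assert ve["M1"] == 1.0


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, rng):
        expr = planted_blocks(rng, n_blocks=1, block=20, samples=60)
        eig, _ = module_eigengenes(expr, {"M1": list(expr.index)})
        traits = pd.DataFrame({"t": eig.loc["M1"].to_numpy()}, index=eig.columns)
        table = module_trait_correlation(eig, traits)
        assert table.loc[0, "r"] == pytest.approx(1.0)
        assert table.loc[0, "p"] < 1e-20

    def test_complementary_indicators_mirror_correlation(self, rng):
        expr = planted_blocks(rng, n_blocks=1, block=20, samples=60)
        eig, _ = module_eigengenes(expr, {"M1": list(expr.index)})
        ind = (rng.random(60) < 0.5).astype(float)
        traits = pd.DataFrame({"s1": ind, "s2": 1.0 - ind}, index=eig.columns)
        table = module_trait_correlation(eig, traits).set_index("trait")
        assert table.loc["s1", "r"] == pytest.approx(-table.loc["s2", "r"])

    def test_constant_trait_rejected(self, rng):
        expr = planted_blocks(rng, n_blocks=1, block=20, samples=30)
        eig, _ = module_eigengenes(expr, {"M1": list(expr.index)})
        traits = pd.DataFrame({"t": np.ones(30)}, index=eig.columns)
        with pytest.raises(ValueError):
            module_trait_correlation(eig, traits)


class TestDendrogramExport:
    def test_newick_contains_every_gene_once(self, rng):
        from hccfusion.coexpression import dendrogram_newick

        expr = planted_blocks(rng, n_blocks=2, block=10, samples=40)
        tom = tom_similarity(signed_adjacency(expr, CoexpressionParams()))
        newick = dendrogram_newick(tom)
        assert newick.endswith(";")
        for gene in expr.index:
            assert newick.count(f"{gene}:") == 1
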