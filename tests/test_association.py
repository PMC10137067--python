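"""PRF cascade, module filtering, pathway-feature pairs and the network."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hccfusion import association, synthetic
from hccfusion.association import (
    build_association_network,
    filter_prf_modules,
    identify_prfs,
    pathway_feature_pairs,
    prf_related_genes,
    prf_values,
    write_network,
)
from hccfusion.expression import GeneSetCollection
from hccfusion.radiomics.registry import MultiViewFeatureTable
from hccfusion.survival import SurvivalData


def small_feature_table(rng, n=30, planted_shift=0.0, subtype=None):
    from hccfusion.radiomics.registry import feature_registry
    from hccfusion.radiomics.voi import VIEW_TYPES

    columns = pd.MultiIndex.from_tuples(
        [(v, c, f) for v in VIEW_TYPES for c, f in feature_registry()],
        names=["view_type", "class", "feature"],
    )
    X = rng.standard_normal((n, len(columns)))
    if planted_shift and subtype is not None:
        X[subtype == 2, 0] += planted_shift
    data = pd.DataFrame(
        X, index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        columns=columns,
    )
    return MultiViewFeatureTable(data).zscore()


class TestIdentifyPrfs:
    def test_constant_feature_excluded(self, rng):
        table = small_feature_table(rng, n=20)
        data = table.data.copy()
        data.iloc[:, 5] = 0.0
        table = MultiViewFeatureTable(data, standardized=True)
        subs = np.array(["FIFS1", "FIFS2"] * 10)
        surv = SurvivalData(rng.exponential(100, 20) + 1, np.ones(20))
        out = identify_prfs(table, subs, surv)
        excluded = table.data.columns[5]
        assert f"{excluded[0]}:{excluded[1]}:{excluded[2]}" not in set(out["feature_id"])

    def test_planted_feature_retained_with_correct_direction(self):
        kept = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            subtype = np.array([1] * 15 + [2] * 15)
            table = small_feature_table(rng, planted_shift=2.0, subtype=subtype)
            col = table.data.columns[0]
            fid = f"{col[0]}:{col[1]}:{col[2]}"
            # hazard rises with the planted feature (log-HR 1 per SD)
            z = table.data.iloc[:, 0].to_numpy()
            lam = 0.002 * np.exp(z)
            surv = SurvivalData(rng.exponential(1 / lam), np.ones(30))
            out = identify_prfs(table, subtype.astype(str), surv)
            row = out[out["feature_id"] == fid]
            if len(row) and row.iloc[0]["HR"] > 1.0:
                kept += 1
        assert kept >= int(0.8 * n_seeds)

    def test_null_survival_calibration_of_stage_two(self):
        # with survival independent of everything, ~5% of stage-1
        # survivors should pass the Cox stage
        pass_fracs = []
        for seed in range(8):
            rng = np.random.default_rng(200 + seed)
            subtype = np.array([1] * 15 + [2] * 15)
            table = small_feature_table(rng)
            surv = SurvivalData(rng.exponential(500, 30) + 1, np.ones(30))
            out = identify_prfs(table, subtype.astype(str), surv)
            stage1 = 0
            X = table.data
            from scipy import stats as st

            for column in X.columns:
                v = X[column].to_numpy()
                _t, p = st.ttest_ind(v[:15], v[15:], equal_var=True)
                stage1 += p < 0.05
            if stage1:
                pass_fracs.append(len(out) / stage1)
        assert np.mean(pass_fracs) < 0.15

    def test_column_order_stability(self, rng):
        subtype = np.array([1] * 15 + [2] * 15)
        table = small_feature_table(rng, planted_shift=2.0, subtype=subtype)
        surv = SurvivalData(rng.exponential(300, 30) + 1, np.ones(30))
        out1 = identify_prfs(table, subtype.astype(str), surv)
        shuffled = MultiViewFeatureTable(
            table.data.iloc[:, rng.permutation(table.data.shape[1])],
            standardized=True,
        )
        out2 = identify_prfs(shuffled, subtype.astype(str), surv)
        assert set(out1["feature_id"]) == set(out2["feature_id"])


class TestFilterPrfModules:
    def _setup(self, rng, n=40):
        subtype = np.array([1] * (n // 2) + [2] * (n - n // 2))
        prf = (subtype == 2) * 1.5 + rng.normal(size=n)
        prfs = pd.DataFrame({"prf1": prf}, index=[f"P{i}" for i in range(n)])
        lam = 0.002 * np.exp(prf)
        surv = SurvivalData(rng.exponential(1 / lam), np.ones(n))
        return subtype, prfs, surv

    def test_copy_of_prognostic_prf_passes_all_filters(self, rng):
        subtype, prfs, surv = self._setup(rng)
        eig = pd.DataFrame(
            [prfs["prf1"].to_numpy()], index=["M1"], columns=prfs.index
        )
        out = filter_prf_modules(eig, subtype.astype(str), surv, prfs)
        assert bool(out.loc[0, "selected"])

    def test_noise_module_fails_subtype_and_cox(self):
        fails = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            subtype, prfs, surv = self._setup(rng)
            eig = pd.DataFrame(
                [rng.normal(size=40)], index=["M1"], columns=prfs.index
            )
            out = filter_prf_modules(eig, subtype.astype(str), surv, prfs)
            fails += not (out.loc[0, "passes_subtype"] and out.loc[0, "passes_cox"])
        assert fails >= int(0.9 * n_seeds)

    def test_orthogonalized_module_excluded_by_prf_criterion(self, rng):
        subtype, prfs, surv = self._setup(rng, n=200)
        # eigengene tracking subtype but residualized against the PRF
        raw = (subtype == 2) * 2.0 + rng.normal(size=200) * 0.3
        raw = raw - raw.mean()
        v = prfs["prf1"].to_numpy()
        vc = v - v.mean()
        resid = raw - np.dot(raw, vc) / np.dot(vc, vc) * vc
        eig = pd.DataFrame([resid], index=["M1"], columns=prfs.index)
        out = filter_prf_modules(eig, subtype.astype(str), surv, prfs)
        assert not bool(out.loc[0, "passes_prf"])

    def test_empty_module_set_rejected(self, rng):
        subtype, prfs, surv = self._setup(rng)
        with pytest.raises(ValueError):
            filter_prf_modules(
                pd.DataFrame(columns=prfs.index), subtype.astype(str), surv, prfs
            )


class TestPathwayFeaturePairs:
    def test_identical_vectors_retained_with_unit_correlation(self, rng):
        v = rng.normal(size=30)
        scores = pd.DataFrame([v], index=["path1"], columns=[f"P{i}" for i in range(30)])
        prfs = pd.DataFrame({"prf1": v}, index=scores.columns)
        pairs = pathway_feature_pairs(scores, prfs)
        assert len(pairs) == 1
        assert pairs.loc[0, "r"] == pytest.approx(1.0)
        assert pairs.loc[0, "q"] < 1e-20

    def test_fdr_calibration_under_independence(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(
                rng.normal(size=(50, 30)),
                index=[f"path{i}" for i in range(50)],
                columns=[f"P{i}" for i in range(30)],
            )
            prfs = pd.DataFrame(
                rng.normal(size=(30, 10)),
                index=scores.columns,
                columns=[f"prf{i}" for i in range(10)],
            )
            pairs = pathway_feature_pairs(scores, prfs)
            fracs.append(len(pairs) / 500.0)
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 2 * max(se, 0.01)

    def test_single_pair_bh_equals_raw_p(self, rng):
        v = rng.normal(size=25)
        w = v + rng.normal(size=25) * 0.5
        scores = pd.DataFrame([v], index=["p1"], columns=[f"P{i}" for i in range(25)])
        prfs = pd.DataFrame({"f1": w}, index=scores.columns)
        pairs = pathway_feature_pairs(scores, prfs, fdr=1.1)
        assert pairs.loc[0, "q"] == pytest.approx(pairs.loc[0, "p"])


class TestAssociationNetwork:
    def _pairs(self, n_per_prf=7):
        rows = []
        for i in range(n_per_prf):
            rows.append(
                {"module": "M1", "pathway": f"path{i}", "prf": "prf1",
                 "r": 0.9 - i * 0.05, "p": 1e-4, "q": 1e-3}
            )
        return pd.DataFrame(rows)

    def test_truncation_to_top_five(self):
        G = build_association_network(self._pairs(7), top_n=5)
        assert G.degree("prf1") == 5
        assert "path6" not in G

    def test_no_truncation_keeps_all_edges(self):
        pairs = self._pairs(7)
        G = build_association_network(pairs, top_n=None)
        assert G.number_of_edges() == len(pairs)

    def test_graphml_round_trip(self, tmp_path):
        G = build_association_network(self._pairs(4), top_n=5)
        path = tmp_path / "net.graphml"
        write_network(G, graphml_path=path)
        H = nx.read_graphml(path)
        assert {frozenset(e) for e in H.edges()} == {
            frozenset(e) for e in G.edges()
        }


class TestPrfRelatedGenes:
    def test_gene_equal_to_prf_reported_with_unit_r(self, rng):
        samples = [f"P{i}" for i in range(25)]
        v = rng.normal(size=25)
        expr = pd.DataFrame(
            np.vstack([v, rng.normal(size=(4, 25))]),
            index=["gA", "g1", "g2", "g3", "g4"],
            columns=samples,
        )
        prfs = pd.DataFrame({"prf1": v}, index=samples)
        pairs = pd.DataFrame(
            [{"module": "M1", "pathway": "path1", "prf": "prf1",
              "r": 0.9, "p": 1e-5, "q": 1e-4}]
        )
        sets = GeneSetCollection({"path1": ["gA", "g1", "g2"]})
        out = prf_related_genes(expr, pairs, prfs, sets, modules={"gA": "M1"})
        assert out.loc[0, "gene"] == "gA"
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert list(out.columns) == ["gene", "prf", "pathway", "module", "r", "p"]

    def test_planted_correlation_recovered_within_sampling_error(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = [f"P{i}" for i in range(30)]
            v = rng.normal(size=30)
            g = 0.6 * v + np.sqrt(1 - 0.36) * rng.normal(size=30)
            expr = pd.DataFrame([g], index=["gA"], columns=samples)
            prfs = pd.DataFrame({"prf1": v}, index=samples)
            pairs = pd.DataFrame(
                [{"module": "M1", "pathway": "p1", "prf": "prf1",
                  "r": 0.5, "p": 1e-3, "q": 1e-2}]
            )
            sets = GeneSetCollection({"p1": ["gA"]})
            out = prf_related_genes(expr, pairs, prfs, sets)
            if len(out):
                rs.append(out.loc[0, "r"])
        assert abs(np.median(rs) - 0.6) < 0.25


class TestEndToEndCascade(object):
    def test_cohort_prf_values_align(self, default_cohort):
        c = default_cohort
        table = c.features.zscore()
        subs = np.where(c.subtype_labels == 1, "FIFS1", "FIFS2")
        out = identify_prfs(table, subs, c.survival)
        assert len(out) > 0
        vals = prf_values(table, out)
        assert vals.shape == (30, len(out))
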