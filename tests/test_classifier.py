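"""Nearest shrunken centroids: arithmetic, shrinkage path, CV, prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestCentroid

from hccfusion import synthetic
from hccfusion.classifier import (
    ShrunkenCentroidModel,
    candidate_genes,
    predict_nsc,
    standardized_offsets,
    train_nsc,
    validate_external,
)
from hccfusion.expression import DEResult, GeneSetCollection, normalize_counts


def de_result(flagged):
    table = pd.DataFrame(
        {
            "gene": flagged,
            "log2fc": 2.0,
            "p": 1e-6,
            "adj_p": 1e-5,
            "significant": True,
        }
    )
    return DEResult(table, reference="FIFS1", comparison="FIFS2")


def separable_expr(rng, n_genes=60, n_informative=50, n_per_class=50, shift=2.0):
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    X = rng.normal(size=(n_genes, 2 * n_per_class))
    X[:n_informative, labels == "B"] += shift
    expr = pd.DataFrame(
        X,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_class)],
    )
    return expr, labels


class TestCandidateGenes:
    def test_intersection_semantics(self):
        de = de_result(["g1", "g2", "g3", "g4"])
        assert candidate_genes(de, ["g2", "g4", "g9"]) == ["g2", "g4"]

    def test_subset_passthrough(self):
        de = de_result(["g1", "g2"])
        assert candidate_genes(de, ["g1", "g2", "g3"]) == ["g1", "g2"]

    def test_disjoint_inputs_rejected(self):
        with pytest.raises(ValueError):
            candidate_genes(de_result(["g1"]), ["g9"])


class TestShrunkenArithmetic:
    def test_four_gene_toy_matches_hand_computation(self):
        # two classes, two samples each; hand-computed centroids/SDs
        expr = pd.DataFrame(
            {
                "s1": [1.0, 0.0, 5.0, 2.0],
                "s2": [3.0, 2.0, 7.0, 2.0],
                "s3": [7.0, 1.0, 5.0, 4.0],
                "s4": [9.0, 3.0, 7.0, 4.0],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        labels = ["A", "A", "B", "B"]
        d, pooled_sd, s0, mk = standardized_offsets(expr, labels)
        # genes 1-3: within-class SS = 2 per class, so s_i^2 = 4/(4-2) = 2;
        # gene 4 is constant within class, s_4 = 0; s0 = median = sqrt(2)
        sq2 = np.sqrt(2.0)
        np.testing.assert_allclose(pooled_sd, [sq2, sq2, sq2, 0.0])
        assert s0 == pytest.approx(sq2)
        # m_k = sqrt(1/2 - 1/4) = 0.5 for both classes
        np.testing.assert_allclose(mk, 0.5)
        # g1: class means 2 and 8, overall 5 -> d_A = (2-5)/(0.5*2*sq2)
        # g4: class means 2 and 4, overall 3 -> d_A = (2-3)/(0.5*sq2)
        np.testing.assert_allclose(
            d[0], [-3.0 / sq2, -0.5 / sq2, 0.0, -sq2]
        )
        np.testing.assert_allclose(d[1], -d[0])

    def test_zero_threshold_equals_plain_nearest_centroid(self, rng):
        expr, labels = separable_expr(rng, n_per_class=20, shift=1.0)
        model = train_nsc(expr, labels, thresholds=[0.0], folds=4, seed=0)
        np.testing.assert_allclose(
            model.shrunken_centroids, model.class_centroids, atol=1e-12
        )
        # cross-check predictions against the sklearn shrunken-centroid
        # classifier at zero shrinkage
        ours, _ = predict_nsc(model, expr)
        sk = NearestCentroid(shrink_threshold=None)
        sk.fit(expr.to_numpy().T, labels)
        sk_pred = sk.predict(expr.to_numpy().T)
        # both separate the planted classes perfectly
        assert adjusted_rand_score(ours.to_numpy(), labels) == 1.0
        assert adjusted_rand_score(sk_pred, labels) == 1.0

    def test_full_shrinkage_collapses_to_priors(self, rng):
        expr, labels = separable_expr(rng, n_per_class=15, shift=0.5)
        labels = np.array(["A"] * 20 + ["B"] * 10)
        d, _sd, _s0, _mk = standardized_offsets(expr, labels)
        big = float(np.abs(d).max()) + 1.0
        model = train_nsc(expr, labels, thresholds=[big], folds=3, seed=0)
        np.testing.assert_allclose(
            model.shrunken_centroids,
            np.tile(model.overall_centroid, (2, 1)),
            atol=1e-12,
        )
        with pytest.raises(ValueError):
            predict_nsc(model, expr)  # no active genes


class TestTraining:
    def test_active_gene_count_non_increasing(self, rng):
        expr, labels = separable_expr(rng, n_per_class=25)
        model = train_nsc(expr, labels, thresholds=30, folds=5, seed=1)
        counts = model.cv_profile["n_active_genes"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_cv_profile_reproducible_with_seed(self, rng):
        expr, labels = separable_expr(rng, n_per_class=25)
        a = train_nsc(expr, labels, folds=5, seed=7).cv_profile
        b = train_nsc(expr, labels, folds=5, seed=7).cv_profile
        assert a.equals(b)

    def test_separable_cohort_reaches_zero_cv_error(self, rng):
        expr, labels = separable_expr(rng, n_genes=60, n_informative=50,
                                      n_per_class=50, shift=2.0)
        model = train_nsc(expr, labels, folds=10, seed=0)
        assert model.cv_profile["cv_error"].min() == 0.0
        # the chosen threshold is the largest one attaining that error
        zero_rows = model.cv_profile[model.cv_profile["cv_error"] == 0.0]
        assert model.threshold == pytest.approx(zero_rows["threshold"].max())

    def test_fold_reduction_warning_for_small_class(self, rng, caplog):
        expr, labels = separable_expr(rng, n_per_class=4, shift=2.0)
        model = train_nsc(expr, labels, folds=10, seed=0)
        assert model is not None  # folds were reduced, not fatal


class TestPrediction:
    def test_sample_at_shrunken_centroid_predicted_to_its_class(self, rng):
        expr, labels = separable_expr(rng, n_per_class=20)
        model = train_nsc(expr, labels, thresholds=[0.5], folds=4, seed=0)
        probe = pd.DataFrame(
            {"x": model.shrunken_centroids[0]}, index=model.genes
        )
        pred, _ = predict_nsc(model, probe)
        assert pred.iloc[0] == model.classes[0]

    def test_missing_genes_imputed_at_centroid(self, rng):
        expr, labels = separable_expr(rng, n_per_class=20)
        model = train_nsc(expr, labels, thresholds=[0.0], folds=4, seed=0)
        partial = expr.iloc[: len(model.genes) // 2]
        pred, scores = predict_nsc(model, partial)
        assert len(pred) == expr.shape[1]

    def test_resubstitution_error_close_to_cv_error(self, rng):
        expr, labels = separable_expr(rng, n_per_class=50, shift=2.0)
        model = train_nsc(expr, labels, folds=10, seed=2)
        pred, _ = predict_nsc(model, expr)
        resub = (pred.to_numpy() != labels).mean()
        assert resub <= model.cv_profile["cv_error"].min() + 0.1

    def test_json_round_trip(self, rng, tmp_path):
        expr, labels = separable_expr(rng, n_per_class=15)
        model = train_nsc(expr, labels, thresholds=[0.2], folds=3, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ShrunkenCentroidModel.from_json(path)
        pred_a, _ = predict_nsc(model, expr)
        pred_b, _ = predict_nsc(loaded, expr)
        assert pred_a.equals(pred_b)


class TestEndToEnd:
    def test_discovery_to_validation_generalization(self):
        """Train on n=30 synthetic discovery, predict independent n=150."""
        aris = []
        logrank_hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            train = synthetic.generate_cohort(
                synthetic.CohortConfig(n_patients=30, seed=300 + seed)
            )
            test = synthetic.generate_cohort(
                synthetic.CohortConfig(n_patients=150, seed=900 + seed)
            )
            tr_expr = np.log2(normalize_counts(train.counts) + 1.0)
            te_expr = np.log2(normalize_counts(test.counts) + 1.0)
            module_genes = [
                g for g, m in train.truth["gene_module"].items() if m != "grey"
            ]
            labels = np.where(train.subtype_labels == 1, "FIFS1", "FIFS2")
            model = train_nsc(tr_expr.loc[module_genes], labels, folds=10, seed=seed)
            pred, _ = predict_nsc(model, te_expr)
            aris.append(
                adjusted_rand_score(test.subtype_labels, pred.to_numpy())
            )
            immune = GeneSetCollection(
                {"imm": [g for g, m in test.truth["gene_module"].items() if m == "immune"]}
            )
            report = validate_external(pred, test.survival, immune, te_expr)
            logrank_hits += report["logrank_p"] < 0.05
            # planted immune program is elevated in the FIFS1-like arm
            z = report["immune_scores_z"]
            arm1 = pred[pred == "FIFS1"].index
            arm2 = pred[pred == "FIFS2"].index
            assert z[arm1].to_numpy().mean() > z[arm2].to_numpy().mean()
        assert np.median(aris) >= 0.7
        assert logrank_hits >= int(0.8 * n_seeds)
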