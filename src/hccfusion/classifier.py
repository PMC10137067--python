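"""Gene-expression subtype classifier: nearest shrunken centroids.

Candidate genes are the overlap of the differentially expressed genes with
the membership of the PRF-related co-expression modules.  The classifier
standardizes class-centroid offsets as
``d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0))`` with
``m_k = sqrt(1/n_k - 1/n)``, pooled within-class SD ``s_i`` and fudge
``s0 = median(s_i)``, soft-thresholds the offsets at Delta and rebuilds
shrunken centroids.  Delta is chosen by stratified 10-fold cross-validation
as the largest threshold attaining the minimal misclassification error
(fewest active genes at the lowest error).  Prediction minimizes the
squared standardized distance to each shrunken centroid penalized by
``-2 log(prior_k)``; discriminant ties break to the lexicographically
first class and are flagged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.model_selection import StratifiedKFold

from .expression import DEResult, GeneSetCollection, ssgsea_scores
from .survival import SurvivalData, km_estimate, logrank_test

logger = logging.getLogger(__name__)


def candidate_genes(de: DEResult, module_genes: Iterable[str]) -> list[str]:
    """Flagged DE genes that also belong to a PRF-related module."""
    module_genes = set(module_genes)
    overlap = [g for g in de.significant_genes if g in module_genes]
    if not overlap:
        raise ValueError(
            "no overlap between DE genes and module genes; "
            "consider looser DE thresholds or larger modules"
        )
    return overlap


@dataclasses.dataclass
class ShrunkenCentroidModel:
    """Fitted nearest-shrunken-centroid classifier."""

    genes: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # raw, (K, p)
    shrunken_centroids: np.ndarray  # (K, p), at the chosen threshold
    pooled_sd: np.ndarray  # s_i, (p,)
    s0: float
    mk: np.ndarray  # (K,)
    priors: np.ndarray  # (K,)
    threshold: float
    cv_profile: pd.DataFrame | None = None  # threshold, cv_error, n_active_genes

    @property
    def active_genes(self) -> list[str]:
        offsets = self.shrunken_centroids - self.overall_centroid
        active = np.any(np.abs(offsets) > 0, axis=0)
        return [g for g, a in zip(self.genes, active) if a]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "mk": self.mk.tolist(),
            "priors": self.priors.tolist(),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "ShrunkenCentroidModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"],
            classes=d["classes"],
            overall_centroid=np.asarray(d["overall_centroid"]),
            class_centroids=np.asarray(d["class_centroids"]),
            shrunken_centroids=np.asarray(d["shrunken_centroids"]),
            pooled_sd=np.asarray(d["pooled_sd"]),
            s0=float(d["s0"]),
            mk=np.asarray(d["mk"]),
            priors=np.asarray(d["priors"]),
            threshold=float(d["threshold"]),
        )


def _centroid_stats(X: np.ndarray, y: np.ndarray, classes: Sequence[str]):
    """Overall/class centroids, pooled SD, s0 and m_k for (n x p) data."""
    n, p = X.shape
    K = len(classes)
    overall = X.mean(axis=0)
    centroids = np.zeros((K, p))
    ss = np.zeros(p)
    nk = np.zeros(K)
    for ki, c in enumerate(classes):
        sel = y == c
        nk[ki] = sel.sum()
        centroids[ki] = X[sel].mean(axis=0)
        ss += ((X[sel] - centroids[ki]) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(ss / (n - K))
    s0 = float(np.median(pooled_sd))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    return overall, centroids, pooled_sd, s0, mk, nk


def _shrink(overall, centroids, pooled_sd, s0, mk, threshold):
    """Soft-threshold the standardized offsets and rebuild centroids."""
    scale = mk[:, None] * (pooled_sd + s0)[None, :]
    d = (centroids - overall) / scale
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - threshold, 0.0)
    return overall + scale * d_shrunk, d, d_shrunk


def _discriminant(X, shrunken, pooled_sd, s0, priors):
    denom = (pooled_sd + s0) ** 2
    scores = np.empty((X.shape[0], shrunken.shape[0]))
    for ki in range(shrunken.shape[0]):
        scores[:, ki] = ((X - shrunken[ki]) ** 2 / denom).sum(axis=1)
    return scores - 2.0 * np.log(priors)[None, :]


def standardized_offsets(
    expr: pd.DataFrame, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """(d_ik matrix (K x p), pooled SD, s0, m_k) for inspection/testing."""
    X = expr.to_numpy(dtype=float).T
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    overall, centroids, pooled_sd, s0, mk, _nk = _centroid_stats(X, y, classes)
    _shrunken, d, _ds = _shrink(overall, centroids, pooled_sd, s0, mk, 0.0)
    return d, pooled_sd, s0, mk


def train_nsc(
    expr: pd.DataFrame,
    labels: Sequence[str],
    thresholds: Sequence[float] | int = 30,
    folds: int = 10,
    seed: int = 0,
) -> ShrunkenCentroidModel:
    """Fit an NSC model with threshold selection by stratified CV.

    expr : genes x samples expression (candidate genes only).
    thresholds : explicit grid, or a count for an even grid on
        [0, max |d_ik|].
    folds : CV folds; reduced with a warning if the smallest class is
        smaller than ``folds``.
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    y = np.asarray([str(l) for l in labels])
    if X.shape[0] != y.size:
        raise ValueError("labels must align with expression columns")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    nk = np.array([(y == c).sum() for c in classes])
    priors = nk / nk.sum()
    min_class = int(nk.min())
    if min_class < folds:
        logger.warning("smallest class has %d members; folds reduced", min_class)
        folds = max(2, min_class)

    overall, centroids, pooled_sd, s0, mk, _ = _centroid_stats(X, y, classes)
    _, d, _ = _shrink(overall, centroids, pooled_sd, s0, mk, 0.0)
    if np.isscalar(thresholds):
        grid = np.linspace(0.0, float(np.abs(d).max()), int(thresholds))
    else:
        grid = np.asarray(sorted(thresholds), dtype=float)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
    errors = np.zeros(grid.size)
    for train_idx, test_idx in skf.split(X, y):
        ytr = y[train_idx]
        if np.unique(ytr).size < len(classes):
            raise ValueError("a CV fold lost a class; reduce folds")
        _overall, fold_centroids, fold_psd, fold_s0, fold_mk, fold_nk = _centroid_stats(
            X[train_idx], ytr, classes
        )
        fold_priors = fold_nk / fold_nk.sum()
        for gi, t in enumerate(grid):
            shrunk, _d1, _d2 = _shrink(
                _overall, fold_centroids, fold_psd, fold_s0, fold_mk, t
            )
            scores = _discriminant(X[test_idx], shrunk, fold_psd, fold_s0, fold_priors)
            pred = np.asarray(classes)[scores.argmin(axis=1)]
            errors[gi] += (pred != y[test_idx]).sum()
    errors = errors / X.shape[0]

    n_active = np.array(
        [
            int(np.any(np.abs(_shrink(overall, centroids, pooled_sd, s0, mk, t)[2]) > 0, axis=0).sum())
            for t in grid
        ]
    )
    best_error = errors.min()
    # largest threshold at the minimal error: fewest genes at lowest error
    chosen = float(grid[np.where(errors == best_error)[0].max()])
    shrunken, _d, _ds = _shrink(overall, centroids, pooled_sd, s0, mk, chosen)
    profile = pd.DataFrame(
        {"threshold": grid, "cv_error": errors, "n_active_genes": n_active}
    )
    return ShrunkenCentroidModel(
        genes=list(expr.index),
        classes=classes,
        overall_centroid=overall,
        class_centroids=centroids,
        shrunken_centroids=shrunken,
        pooled_sd=pooled_sd,
        s0=s0,
        mk=mk,
        priors=priors,
        threshold=chosen,
        cv_profile=profile,
    )


def predict_nsc(
    model: ShrunkenCentroidModel, expr: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Predict classes for a genes x samples matrix.

    Missing model genes are imputed at the overall centroid (with a
    warning).  Returns (labels, per-class discriminant scores); ties are
    resolved to the lexicographically first class and flagged.
    """
    if not model.active_genes:
        raise ValueError("model has no active genes")
    present = [g for g in model.genes if g in expr.index]
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        logger.warning("%d model gene(s) missing; imputed at centroid", len(missing))
    X = np.tile(model.overall_centroid, (expr.shape[1], 1))
    idx = {g: i for i, g in enumerate(model.genes)}
    for g in present:
        X[:, idx[g]] = expr.loc[g].to_numpy(dtype=float)
    scores = _discriminant(
        X, model.shrunken_centroids, model.pooled_sd, model.s0, model.priors
    )
    ties = np.isclose(scores, scores.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning("%d tied discriminant(s); first class chosen", int(ties.sum()))
    labels = pd.Series(
        np.asarray(model.classes)[scores.argmin(axis=1)],
        index=expr.columns,
        name="predicted_subtype",
    )
    score_df = pd.DataFrame(scores, index=expr.columns, columns=model.classes)
    return labels, score_df


def validate_external(
    predicted: pd.Series,
    survival: SurvivalData,
    immune_sets: GeneSetCollection,
    expr: pd.DataFrame,
) -> dict:
    """External-cohort validation report for predicted subtypes.

    Returns KM curves per arm, the log-rank p between arms, and the
    immune-pathway score matrix (row-z-scored, rows ordered by
    average-linkage hierarchical clustering).  The better-prognosis arm is
    reported as 'FIFS1'.  If one arm is empty the report degenerates to
    descriptive output with a warning.
    """
    labels = predicted.to_numpy()
    uniq = np.unique(labels)
    report: dict = {"n_per_class": {c: int((labels == c).sum()) for c in uniq}}
    scores = ssgsea_scores(expr, immune_sets)
    z = scores.sub(scores.mean(axis=1), axis=0)
    sd = scores.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    if len(z) > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(z.to_numpy(), method="average")
        )
        z = z.iloc[order]
    report["immune_scores_z"] = z

    if uniq.size < 2:
        logger.warning("only one predicted class; survival comparison skipped")
        report["logrank_p"] = None
        return report
    _stat, _df, p = logrank_test(survival, labels)
    report["logrank_p"] = p
    curves = {}
    final_surv = {}
    for c in uniq:
        curve = km_estimate(survival.subset(labels == c))
        curves[c] = curve
        final_surv[c] = float(curve["survival"].iloc[-1])
    report["km_curves"] = curves
    better = max(final_surv, key=final_surv.get)
    report["better_prognosis_arm"] = str(better)
    report["arm_names"] = {
        str(better): "FIFS1",
        **{str(c): "FIFS2" for c in uniq if c != better},
    }
    return report
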