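"""Prognostic radiomics features (PRFs) and the radiogenomics network.

The PRF cascade filters the z-scored multi-view feature table in two
stages: (1) a two-sample t-test between subtypes retains features with
p < 0.05; (2) a univariate Cox fit on each surviving feature's z-scored
eigenvalue retains features with p < 0.05.  PRF-related co-expression
modules must correlate with subtype, carry prognostic eigengenes, and
correlate with at least one PRF.  Pathway-feature pairs are Pearson
correlations between module-pathway enrichment scores and PRF eigenvalues
with one BH correction across the full grid, and the association network
keeps the top pairs per PRF.  Finally, for each retained pair the member
gene most correlated with the PRF is reported.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import ModuleAssignment
from .expression import GeneSetCollection
from .radiomics.registry import MultiViewFeatureTable, annotate_feature
from .survival import SurvivalData, SurvivalError, cox_fit

logger = logging.getLogger(__name__)

P_DIFFERENTIAL = 0.05
P_COX = 0.05


def _feature_label(column: tuple[str, str, str]) -> str:
    view, cls, feat = column
    return f"{view}:{cls}:{feat}"


def identify_prfs(
    features: MultiViewFeatureTable,
    subtypes: Sequence[str],
    survival: SurvivalData,
) -> pd.DataFrame:
    """Two-stage PRF cascade: differential t-test then univariate Cox.

    Returns one row per retained feature with view/phase/region/class
    annotation, the subtype with the higher mean eigenvalue, the Cox HR
    with Wald 95% CI and p, and the stage-1 t-test p.
    """
    subtypes = np.asarray(subtypes)
    data = features.data
    labels = sorted(np.unique(subtypes).tolist())
    if len(labels) != 2:
        raise ValueError("PRF cascade expects exactly two subtypes")
    mask_a = subtypes == labels[0]
    mask_b = subtypes == labels[1]

    rows = []
    for column in data.columns:
        values = data[column].to_numpy(dtype=float)
        if np.std(values) == 0:
            logger.info("constant feature %s excluded", _feature_label(column))
            continue
        t, p_diff = stats.ttest_ind(values[mask_a], values[mask_b], equal_var=True)
        if not (p_diff < P_DIFFERENTIAL):
            continue
        z = (values - values.mean()) / values.std()
        try:
            fit = cox_fit(survival, z[:, None], names=["feature"])
        except SurvivalError as exc:
            logger.info("Cox failed for %s: %s", _feature_label(column), exc)
            continue
        p_cox = float(fit.p[0])
        if not (p_cox < P_COX):
            continue
        higher = labels[0] if values[mask_a].mean() > values[mask_b].mean() else labels[1]
        meta = annotate_feature(column)
        rows.append(
            {
                "feature_id": _feature_label(column),
                "feature": meta["feature"],
                "view_type": meta["view_type"],
                "phase": meta["phase"],
                "region": meta["region"],
                "class": meta["class"],
                "higher_subtype": higher,
                "HR": float(fit.hr[0]),
                "CI95_lower": float(fit.ci_lower[0]),
                "CI95_upper": float(fit.ci_upper[0]),
                "cox_p": p_cox,
                "differential_p": float(p_diff),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "feature",
            "view_type",
            "phase",
            "region",
            "class",
            "higher_subtype",
            "HR",
            "CI95_lower",
            "CI95_upper",
            "cox_p",
            "differential_p",
        ],
    )
    return table.reset_index(drop=True)


def prf_values(features: MultiViewFeatureTable, prf_table: pd.DataFrame) -> pd.DataFrame:
    """Patients x PRF matrix of (z-scored) eigenvalues for retained PRFs."""
    cols = []
    for fid in prf_table["feature_id"]:
        view, cls, feat = fid.split(":")
        cols.append((view, cls, feat))
    sub = features.data[cols].copy()
    sub.columns = list(prf_table["feature_id"])
    return sub


def filter_prf_modules(
    eigengenes: pd.DataFrame,
    subtypes: Sequence[str],
    survival: SurvivalData,
    prfs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filter modules to those linked to subtype, prognosis and >= 1 PRF.

    ``prfs`` is the patients x PRF value matrix.  A module passes when
    (a) its eigengene correlates with the 0-1 subtype indicator (p < alpha),
    (b) its eigengene is prognostic in a univariate Cox fit (p < alpha),
    (c) it correlates with at least one PRF (Pearson p < alpha).
    Returns per-module flags and the pass/fail verdict.
    """
    if eigengenes.empty:
        raise ValueError("no modules to filter")
    subtypes = np.asarray(subtypes)
    labels = sorted(np.unique(subtypes).tolist())
    indicator = (subtypes == labels[-1]).astype(float)
    rows = []
    for module in eigengenes.index:
        eig = eigengenes.loc[module].to_numpy(dtype=float)
        _r, p_subtype = stats.pearsonr(eig, indicator)
        try:
            fit = cox_fit(survival, eig[:, None], names=["eigengene"])
            p_cox = float(fit.p[0])
        except SurvivalError:
            p_cox = 1.0
        p_prf_min = 1.0
        for prf in prfs.columns:
            _r2, p2 = stats.pearsonr(eig, prfs[prf].to_numpy(dtype=float))
            p_prf_min = min(p_prf_min, p2)
        passes = (p_subtype < alpha) and (p_cox < alpha) and (p_prf_min < alpha)
        rows.append(
            {
                "module": module,
                "subtype_p": float(p_subtype),
                "cox_p": p_cox,
                "min_prf_p": float(p_prf_min),
                "passes_subtype": p_subtype < alpha,
                "passes_cox": p_cox < alpha,
                "passes_prf": p_prf_min < alpha,
                "selected": passes,
            }
        )
    return pd.DataFrame(rows)


def pathway_feature_pairs(
    pathway_scores: pd.DataFrame,
    prfs: pd.DataFrame,
    pathway_modules: Mapping[str, str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pearson-correlate each pathway score with each PRF; keep q < fdr.

    ``pathway_scores`` is pathways x patients (restricted to pathways of
    the PRF-related modules); ``prfs`` is patients x PRFs.  BH correction
    is applied once across the full pathway x PRF grid.
    """
    rows = []
    for pathway in pathway_scores.index:
        s = pathway_scores.loc[pathway].to_numpy(dtype=float)
        if np.std(s) == 0:
            logger.warning("constant score vector for %r: skipped", pathway)
            continue
        for prf in prfs.columns:
            v = prfs[prf].to_numpy(dtype=float)
            r, p = stats.pearsonr(s, v)
            rows.append(
                {
                    "module": (pathway_modules or {}).get(pathway, ""),
                    "pathway": pathway,
                    "prf": prf,
                    "r": float(r),
                    "p": float(p),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["module", "pathway", "prf", "r", "p", "q"])
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table[table["q"] < fdr].reset_index(drop=True)


def build_association_network(pairs: pd.DataFrame, top_n: int | None = 5) -> nx.Graph:
    """Bipartite PRF-pathway graph from retained pairs.

    Per PRF only the ``top_n`` pairs by |r| are kept (ties broken by
    pathway name); edge weight is |r| and pathway nodes carry their module
    colour attribute.
    """
    G = nx.Graph()
    if pairs.empty:
        return G
    for prf, group in pairs.groupby("prf"):
        ranked = group.assign(abs_r=group["r"].abs()).sort_values(
            ["abs_r", "pathway"], ascending=[False, True]
        )
        if top_n is not None:
            ranked = ranked.head(top_n)
        for _, row in ranked.iterrows():
            G.add_node(row["prf"], bipartite="prf")
            G.add_node(row["pathway"], bipartite="pathway", module=row["module"])
            G.add_edge(row["prf"], row["pathway"], weight=abs(row["r"]), r=row["r"])
    return G


def write_network(G: nx.Graph, graphml_path=None, sif_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(G, str(graphml_path))
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v in G.edges():
                fh.write(f"{u}\tcorrelates\t{v}\n")


def prf_related_genes(
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    prfs: pd.DataFrame,
    gene_sets: GeneSetCollection,
    modules: ModuleAssignment | Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top correlated member gene per PRF across its retained pathways.

    For every retained (pathway, PRF) pair, each measured member gene of
    the pathway is Pearson-correlated with the PRF eigenvalue; the gene
    with the largest |r| and p < alpha is reported per PRF, together with
    its pathway and module.
    """
    if isinstance(modules, ModuleAssignment):
        gene_module = modules.labels.to_dict()
    else:
        gene_module = dict(modules or {})
    sets = gene_sets.restrict(expr.index)
    best: dict[str, dict] = {}
    for _, row in pairs.iterrows():
        pathway, prf = row["pathway"], row["prf"]
        if pathway not in sets.sets:
            logger.warning("pathway %r has no measured genes: skipped", pathway)
            continue
        v = prfs[prf].to_numpy(dtype=float)
        for gene in sets.sets[pathway]:
            g = expr.loc[gene].to_numpy(dtype=float)
            if np.std(g) == 0:
                continue
            r, p = stats.pearsonr(g, v)
            if p >= alpha:
                continue
            cur = best.get(prf)
            if cur is None or abs(r) > abs(cur["r"]):
                best[prf] = {
                    "gene": gene,
                    "prf": prf,
                    "pathway": pathway,
                    "module": gene_module.get(gene, row.get("module", "")),
                    "r": float(r),
                    "p": float(p),
                }
    return pd.DataFrame(
        list(best.values()), columns=["gene", "prf", "pathway", "module", "r", "p"]
    ).reset_index(drop=True)
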