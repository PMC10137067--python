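"""Signed weighted co-expression networks, modules and eigengenes.

The network follows the signed weighted-correlation construction:
adjacency a_ij = ((1 + cor(g_i, g_j)) / 2)^beta with beta = 8 by default,
smoothed into the topological overlap measure (TOM).  Modules are branches
of average-linkage hierarchical clustering on 1 - TOM, cut at a static
height, with branches below the minimum module size sent to "grey"
(a deterministic simplification of dynamic-hybrid tree cutting; module
boundaries are not the analysis claim — module-feature correlations are).
Each module is summarized by its eigengene, the first principal component
of the standardized member-gene expression, sign-oriented so that the
average correlation with member genes is positive.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

GREY = "grey"


@dataclasses.dataclass
class CoexpressionParams:
    """Network construction settings.

    beta : soft-threshold power (default 8, chosen for scale-free topology).
    min_module_size : smallest retained module (default 30 genes).
    cut_height : static tree-cut height on the 1 - TOM dendrogram.
    top_variable_genes : optional pre-filter to the most variable genes by
        median absolute deviation (None disables).
    """

    beta: float = 8.0
    min_module_size: int = 30
    cut_height: float = 0.98
    signed: bool = True
    top_variable_genes: int | None = 5000

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")


def filter_variable_genes(expr: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Keep the ``top_n`` genes with the largest median absolute deviation."""
    if top_n is None or len(expr) <= top_n:
        return expr
    mad = stats.median_abs_deviation(expr.to_numpy(dtype=float), axis=1)
    keep = np.argsort(-mad, kind="stable")[:top_n]
    return expr.iloc[np.sort(keep)]


def signed_adjacency(
    expr: pd.DataFrame, params: CoexpressionParams | None = None
) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta, unit diagonal."""
    params = params or CoexpressionParams()
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sds = X.std(axis=1)
    if (sds == 0).any():
        offenders = list(expr.index[sds == 0][:10])
        raise ValueError(f"zero-variance gene(s): {offenders}")
    cor = np.corrcoef(X)
    a = np.clip((1.0 + cor) / 2.0, 0.0, 1.0) ** params.beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbour adjacency a_iu a_uj over u != i, j and
    k_i is the connectivity sum_{u != i} a_iu; TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = np.clip(A, 0.0, 1.0)
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    L = Ad @ Ad  # l_ij plus no diagonal terms since Ad has zero diagonal
    kmin = np.minimum(k[:, None], k[None, :])
    tom = (L + Ad) / (kmin + 1.0 - Ad)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclasses.dataclass
class ModuleAssignment:
    """gene -> module label; 'grey' collects unassigned genes."""

    labels: pd.Series
    min_module_size: int

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, label in self.labels.items():
            if label != GREY:
                out.setdefault(label, []).append(gene)
        return out

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels != GREY].value_counts()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.labels.index, "module": self.labels.values})


def detect_modules(
    tom: pd.DataFrame, params: CoexpressionParams | None = None
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Branches with fewer than ``min_module_size`` genes are assigned to
    grey.  Retained modules are named M1, M2, ... in decreasing size.
    """
    params = params or CoexpressionParams()
    genes = list(tom.index)
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(linkage, t=params.cut_height, criterion="distance")
    labels = pd.Series(index=pd.Index(genes, name="gene"), dtype=object)
    counts = pd.Series(raw).value_counts()
    kept = counts[counts >= params.min_module_size].sort_values(ascending=False)
    name_map = {cluster: f"M{i + 1}" for i, cluster in enumerate(kept.index)}
    for gene, cluster in zip(genes, raw):
        labels[gene] = name_map.get(cluster, GREY)
    if (labels == GREY).all():
        logger.warning("all genes assigned to grey: no module detected")
    return ModuleAssignment(labels, params.min_module_size)


def dendrogram_newick(tom: pd.DataFrame) -> str:
    """Average-linkage dendrogram on 1 - TOM in Newick format, for inspection."""
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = hierarchy.to_tree(linkage)
    labels = [str(g) for g in tom.index]

    # iterative post-order rendering (trees can be deeper than the
    # recursion limit for large gene sets)
    rendered: dict[int, str] = {}
    stack = [tree]
    while stack:
        node = stack[-1]
        if node.is_leaf():
            rendered[node.id] = labels[node.id]
            stack.pop()
            continue
        left, right = node.get_left(), node.get_right()
        if left.id in rendered and right.id in rendered:
            rendered[node.id] = (
                f"({rendered[left.id]}:{node.dist / 2:.6g},"
                f"{rendered[right.id]}:{node.dist / 2:.6g})"
            )
            stack.pop()
        else:
            stack.extend([left, right])
    return rendered[tree.id] + ";"


def module_eigengenes(
    expr: pd.DataFrame, modules: ModuleAssignment | Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component eigengene per module.

    Returns (eigengenes: modules x samples with unit variance, variance
    explained per module).  The eigengene sign is oriented so its average
    correlation with member genes is positive; a single-gene module's
    eigengene is that gene standardized.
    """
    mods = modules.modules if isinstance(modules, ModuleAssignment) else dict(modules)
    if not mods:
        raise ValueError("no modules supplied")
    rows, var_expl = {}, {}
    for name, genes in mods.items():
        sub = expr.loc[list(genes)].to_numpy(dtype=float)
        sds = sub.std(axis=1, ddof=0)
        sds[sds == 0] = 1.0
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
        if Z.shape[0] == 1:
            eig = Z[0]
            var_expl[name] = 1.0
        else:
            u, s, vt = np.linalg.svd(Z, full_matrices=False)
            eig = vt[0]
            var_expl[name] = float(s[0] ** 2 / (s**2).sum())
        sd = eig.std(ddof=0)
        eig = eig / (sd if sd > 0 else 1.0)
        mean_cor = np.mean([np.corrcoef(eig, z)[0, 1] for z in Z])
        if mean_cor < 0:
            eig = -eig
        rows[name] = eig
    eigengenes = pd.DataFrame(rows, index=expr.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(var_expl, name="variance_explained")


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait column.

    Traits may include 0-1 subtype indicator columns.  Constant traits are
    rejected.  Returns (module, trait, r, p) rows.
    """
    if list(eigengenes.columns) != list(traits.index):
        traits = traits.loc[eigengenes.columns]
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.std(t) == 0:
            raise ValueError(f"constant trait {trait!r}")
        for module in eigengenes.index:
            r, p = stats.pearsonr(eigengenes.loc[module].to_numpy(), t)
            rows.append({"module": module, "trait": trait, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
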