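"""Count normalization, differential expression, gene-set scoring, ORA.

Differential expression uses median-of-ratios size factors followed by a
Welch t-test on log2(normalized + 1), with Benjamini-Hochberg adjustment
and the significance rule |log2FC| > 1 and adjusted p < 0.05.  This is a
deliberately simple, desk-verifiable test: the pipeline's contribution is
the thresholds and the downstream cascade, not the count model, and the
procedure is documented as non-identical to shrinkage-based NB estimators.

Single-sample gene-set scores use the rank-based running-sum statistic
(ssGSEA-style, weight 0.25).  The same scorer applied to user-supplied
immune/stromal gene sets yields ESTIMATE-style infiltration scores; there
is no separate code path for those.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LOG2FC_THRESHOLD = 1.0
ADJ_P_THRESHOLD = 0.05


class ExpressionError(ValueError):
    pass


def check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples count matrix."""
    if counts.index.duplicated().any():
        raise ExpressionError("duplicate gene ids")
    if (counts.to_numpy() < 0).any():
        raise ExpressionError("negative counts")
    return counts


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets, e.g. parsed from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        self.sets = {name: list(genes) for name, genes in self.sets.items()}

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect each set with the measured universe; drop empty sets."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            overlap = [g for g in genes if g in uni]
            if overlap:
                kept[name] = overlap
            else:
                logger.warning("gene set %r dropped: no measured genes", name)
        return GeneSetCollection(kept, source=self.source)

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Read a GMT file (set name, description, then gene ids, tab-separated)."""
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ExpressionError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets, source=str(path))

    def to_gmt(self, path) -> None:
        lines = [
            "\t".join([name, ""] + genes) for name, genes in self.sets.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    factor_j = median over genes g (nonzero in every sample) of
    count_gj / geometric-mean_g(count_g.).  A single sample gets factor 1.
    """
    check_counts(counts)
    X = counts.to_numpy(dtype=float)
    if X.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        raise ExpressionError(
            "no gene with nonzero counts in all samples; add a pseudocount first"
        )
    ref = X[all_nonzero]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo_mean
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


@dataclasses.dataclass
class DEResult:
    """Per-gene differential expression between two groups."""

    table: pd.DataFrame  # gene, log2fc, p, adj_p, significant
    reference: str
    comparison: str

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])


def differential_expression(
    counts: pd.DataFrame,
    group_labels: Sequence,
    reference=None,
) -> DEResult:
    """Welch t-test DE on log2(median-of-ratios normalized counts + 1).

    Significance requires |log2FC| > 1 and BH-adjusted p < 0.05.  log2FC
    is comparison-vs-reference on normalized means with pseudocount 1;
    the reference defaults to the lexicographically first group label
    (the pipeline fixes FIFS1 as reference and records it here).
    """
    labels = np.asarray(group_labels)
    uniq = sorted(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise ExpressionError("exactly two groups required")
    reference = uniq[0] if reference is None else reference
    comparison = [u for u in uniq if u != reference][0]
    if (labels == reference).sum() < 2 or (labels == comparison).sum() < 2:
        raise ExpressionError("each group needs at least 2 samples")

    norm = normalize_counts(counts).to_numpy(dtype=float)
    log_norm = np.log2(norm + 1.0)
    a = log_norm[:, labels == comparison]
    b = log_norm[:, labels == reference]
    mean_a = norm[:, labels == comparison].mean(axis=1)
    mean_b = norm[:, labels == reference].mean(axis=1)
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        _t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes are untestable
    adj_p = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(log2fc) > LOG2FC_THRESHOLD) & (adj_p < ADJ_P_THRESHOLD)
    table = pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
        }
    ).reset_index(drop=True)
    return DEResult(table, reference=str(reference), comparison=str(comparison))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    weight: float = 0.25,
    rescale: bool = True,
) -> pd.DataFrame:
    """Rank-based single-sample enrichment scores (gene sets x samples).

    Per sample, genes are ranked by expression (average ranks on ties);
    the score is the sum over the ranked list of the difference between
    the weighted in-set ECDF and the out-of-set ECDF.  Scores are
    optionally rescaled by the global (max - min).  The statistic depends
    only on ranks, hence is invariant to any monotone transform of a
    sample's expression values.
    """
    sets = sets.restrict(expr.index)
    if len(sets) == 0:
        raise ExpressionError("all gene sets empty after restriction")
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    # average ranks, higher expression -> higher rank value
    ranks = stats.rankdata(X, axis=0)
    scores = np.zeros((len(sets), n_samples))
    membership = np.zeros((len(sets.sets), n_genes), dtype=bool)
    for si, genes_in in enumerate(sets.sets.values()):
        membership[si, [gene_pos[g] for g in genes_in]] = True
    for j in range(n_samples):
        order = np.argsort(-ranks[:, j], kind="stable")  # descending
        r_sorted = ranks[order, j]
        for si in range(membership.shape[0]):
            in_set = membership[si, order]
            w = np.where(in_set, np.abs(r_sorted) ** weight, 0.0)
            denom_in = w.sum()
            n_out = n_genes - in_set.sum()
            ecdf_in = np.cumsum(w) / denom_in
            ecdf_out = np.cumsum(~in_set) / n_out if n_out else np.zeros(n_genes)
            scores[si, j] = float((ecdf_in - ecdf_out).sum())
    if rescale:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return pd.DataFrame(scores, index=list(sets.sets), columns=expr.columns)


def overrepresentation_test(
    hits: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    p = P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|set|, n=|hits|),
    BH-adjusted across sets.
    """
    universe = set(universe)
    hits = set(hits)
    if not hits:
        raise ExpressionError("empty hit list")
    if not hits <= universe:
        raise ExpressionError("hits must be a subset of the universe")
    sets = sets.restrict(universe)
    rows = []
    N, n = len(universe), len(hits)
    for name, genes in sets.sets.items():
        K = len(genes)
        overlap = len(hits & set(genes))
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": overlap, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
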