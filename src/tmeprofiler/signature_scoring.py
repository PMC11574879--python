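"""Single-sample gene-set scoring (rank-weighted running sum) and the
anchor-gene correlation / tertile workflows.

Per cell, genes are ranked by expression (mid-ranks for ties), the ranked
list is walked from the highest-expressed gene down, and set members
accumulate weight rank^alpha against a uniform accumulation over
non-members; the score is the sum of the running-sum difference.  Only
ranks enter the statistic, so any strictly increasing per-cell transform
of expression leaves scores exactly unchanged.  With alpha = 0 the
weighting reduces to the unweighted Kolmogorov-Smirnov-style statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel_io import GeneSet
from .errors import DataError, DegenerateInputError, SchemaError
from .group_stats import adjust_pvalues, mann_whitney_pratt, spearman_rho
from .survival import dichotomize

DEFAULT_ALPHA = 0.25


@dataclass
class ScoreVector:
    """Per-cell enrichment scores for one named gene set."""

    gene_set: str
    scores: pd.Series
    alpha: float
    normalized: bool


def _validate_expr(expr: pd.DataFrame) -> None:
    if expr.shape[1] < 2:
        raise SchemaError("expression matrix needs >= 2 genes")
    if expr.columns.duplicated().any():
        raise SchemaError("gene symbols must be unique")
    if (expr.to_numpy() < 0).any():
        raise DataError("expression values must be non-negative")


def ssgsea(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> ScoreVector:
    """Score every cell (row) of ``expr`` against ``gene_set``.

    Genes of the set absent from the matrix are dropped with a warning; a
    set fully disjoint from the matrix is an error, as is a set covering
    every gene (no miss population to walk against).
    """
    _validate_expr(expr)
    genes = list(expr.columns)
    members = [g for g in gene_set.genes if g in expr.columns]
    absent = [g for g in gene_set.genes if g not in expr.columns]
    if not members:
        raise SchemaError(
            f"gene set {gene_set.name!r} shares no genes with the matrix")
    if absent:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(absent)} gene(s) absent from the "
            f"matrix: {', '.join(absent[:10])}{'...' if len(absent) > 10 else ''}",
            stacklevel=2)
    n_genes = len(genes)
    n_miss = n_genes - len(members)
    if n_miss == 0:
        raise SchemaError("gene set covers the whole matrix; no miss population")

    x = expr.to_numpy(dtype=float)
    hit = np.isin(np.arange(n_genes), [genes.index(g) for g in members])

    # mid-ranks within each cell (ascending: highest expression = rank G)
    ranks = sps.rankdata(x, axis=1)
    weights = ranks ** alpha

    # walk genes in descending expression; ties broken by column order so the
    # walk order (hence the score) is deterministic and rank-invariant
    order = np.argsort(-x, axis=1, kind="stable")
    hit_ord = hit[order]  # cells x genes booleans in walk order
    w_ord = np.take_along_axis(weights, order, axis=1)

    w_hit = np.where(hit_ord, w_ord, 0.0)
    hit_total = w_hit.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(w_hit, axis=1) / hit_total
    p_miss = np.cumsum(~hit_ord, axis=1) / float(n_miss)
    scores = (p_hit - p_miss).sum(axis=1)

    s = pd.Series(scores, index=expr.index, name=gene_set.name)
    if normalize:
        rng = s.max() - s.min()
        if rng > 0:
            s = (s - s.min()) / rng
    return ScoreVector(gene_set=gene_set.name, scores=s, alpha=alpha,
                       normalized=normalize)


def anchor_correlation(
    expr: pd.DataFrame,
    anchor_gene: str,
    scores: ScoreVector | pd.Series,
) -> tuple[float, float]:
    """Spearman correlation between an anchor gene's expression and scores."""
    if anchor_gene not in expr.columns:
        raise SchemaError(f"anchor gene {anchor_gene!r} absent from the matrix")
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    anchor = expr[anchor_gene].reindex(s.index)
    return spearman_rho(anchor.to_numpy(), s.to_numpy())


@dataclass
class TertileComparison:
    summary: pd.DataFrame  # tertile, n, mean, median
    tests: pd.DataFrame    # pair, p_raw, p_holm


def tertile_compare(
    anchor_values: pd.Series | np.ndarray,
    scores: ScoreVector | pd.Series,
) -> TertileComparison:
    """Split cells into anchor-expression tertiles and compare their scores.

    Pairwise two-sided rank tests between tertiles are Holm-adjusted.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    a = np.asarray(anchor_values, dtype=float)
    sv = np.asarray(s, dtype=float)
    if a.size != sv.size:
        raise DataError("anchor values and scores must align")
    if a.size < 3:
        raise DataError("tertile comparison needs >= 3 cells")
    if np.ptp(a) == 0:
        raise DegenerateInputError("constant anchor expression")
    tert = dichotomize(a, rule="tertiles")

    summary_rows = []
    for t in ("T1", "T2", "T3"):
        vals = sv[tert == t]
        summary_rows.append({"tertile": t, "n": int(vals.size),
                             "mean": float(vals.mean()) if vals.size else np.nan,
                             "median": float(np.median(vals)) if vals.size else np.nan})
    pairs = [("T1", "T2"), ("T1", "T3"), ("T2", "T3")]
    pvals = []
    for ta, tb in pairs:
        res = mann_whitney_pratt(sv[tert == ta], sv[tert == tb])
        pvals.append(res.p_raw)
    tests = pd.DataFrame({"pair": [f"{a_}-{b_}" for a_, b_ in pairs],
                          "p_raw": pvals,
                          "p_holm": adjust_pvalues(pvals, "holm")})
    return TertileComparison(summary=pd.DataFrame(summary_rows), tests=tests)
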