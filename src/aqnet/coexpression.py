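"""Mutual-rank gene co-expression neighborhoods.

The co-expression substrate is a gene-by-condition matrix of nonnegative
abundances (RPKM scale).  Replicate samples are averaged on the raw scale,
values are log2(v+1)-transformed, Pearson correlations are computed across
conditions, and each gene pair receives a mutual-rank score

    MR(a, b) = sqrt(rank_a(b) * rank_b(a)),

where rank_a(b) is the 1-based position of b when all genes other than a
are sorted by descending correlation with a (ties broken by lexicographic
gene id).  MR is symmetric, >= 1, and equals 1 exactly for reciprocal best
partners.  The neighborhood of a guide gene is the k genes with smallest
MR to the guide (default k=300), in ascending MR order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutualRankEdge",
    "Neighborhood",
    "average_replicates",
    "log_transform",
    "pcc_matrix",
    "mutual_rank",
    "guide_neighborhood",
]


@dataclass(frozen=True)
class MutualRankEdge:
    """A gene pair with its Pearson correlation and mutual-rank score."""

    gene_a: str
    gene_b: str
    pcc: float
    mr: float


@dataclass
class Neighborhood:
    """Ordered mutual-rank neighborhood of a guide gene.

    ``entries`` is a DataFrame with columns (gene, pcc, mr, rank), sorted by
    ascending mr (ties by gene id); the guide itself is excluded.
    """

    guide: str
    entries: pd.DataFrame
    k: int = 300

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene"])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.entries)


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample/condition ids: {dups[:5]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")


def average_replicates(matrix: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Average biological replicates per condition on the raw (pre-log) scale.

    Parameters
    ----------
    matrix:
        Genes x samples abundance matrix.
    sample_map:
        Two columns ``sample_id`` and ``condition_id``; every matrix column
        must appear exactly once.

    Returns a genes x conditions matrix; condition order follows first
    appearance among the matrix columns.
    """
    _validate_matrix(matrix)
    mapping = dict(zip(sample_map["sample_id"], sample_map["condition_id"]))
    missing = [c for c in matrix.columns if c not in mapping]
    if missing:
        raise ValueError(f"sample columns missing from sample map: {missing[:5]}")
    conditions: list[str] = []
    groups: dict[str, list[str]] = {}
    for col in matrix.columns:
        cond = mapping[col]
        if cond not in groups:
            groups[cond] = []
            conditions.append(cond)
        groups[cond].append(col)
    out = pd.DataFrame(
        {cond: matrix[groups[cond]].mean(axis=1) for cond in conditions},
        index=matrix.index,
    )
    out.columns.name = matrix.columns.name
    return out


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace every value v by log2(v + 1); values must be >= 0."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns)


def pcc_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between genes (rows) across conditions.

    Genes with zero variance across conditions have undefined correlation;
    they are excluded from the result with a logged warning.  Requires at
    least 3 conditions.
    """
    if matrix.shape[1] < 3:
        raise ValueError(f"need >= 3 conditions, got {matrix.shape[1]}")
    _validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = matrix.index[~keep].tolist()
        logger.warning(
            "excluding %d zero-variance gene(s) from correlation ranking: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    kept = matrix.index[keep]
    corr = np.corrcoef(values[keep])
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=kept, columns=kept)


def _rank_within(corr: pd.DataFrame, anchor: str, other: str) -> int:
    """1-based rank of `other` among all genes != anchor, sorted by
    descending correlation with `anchor`, ties by lexicographic gene id."""
    col = corr[anchor].drop(anchor)
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return order.index(other) + 1


def mutual_rank(corr: pd.DataFrame, gene_a: str, gene_b: str) -> MutualRankEdge:
    """Mutual-rank score sqrt(rank_a(b) * rank_b(a)) for one gene pair."""
    for g in (gene_a, gene_b):
        if g not in corr.index:
            raise ValueError(f"gene {g!r} absent or correlation-undefined")
    if gene_a == gene_b:
        raise ValueError("mutual rank is defined for distinct genes")
    ra = _rank_within(corr, gene_a, gene_b)
    rb = _rank_within(corr, gene_b, gene_a)
    return MutualRankEdge(gene_a, gene_b, float(corr.loc[gene_a, gene_b]), math.sqrt(ra * rb))


def _guide_mr_vector(corr: pd.DataFrame, guide: str) -> pd.DataFrame:
    """MR of every gene to the guide, computed from rank vectors only.

    rank_guide(g) comes from the guide's own correlation vector;
    rank_g(guide) is, for each column g, one plus the number of genes h
    (h != g, h != guide) that beat the guide on corr with g (ties broken
    by lexicographic id).
    """
    genes = corr.index.to_numpy()
    gi = int(np.where(genes == guide)[0][0])
    C = corr.to_numpy(dtype=float)
    n = len(genes)

    # rank_guide(g): sort genes != guide by (-corr with guide, id)
    col = C[:, gi]
    others = np.delete(np.arange(n), gi)
    order = others[np.lexsort((genes[others], -col[others]))]
    rank_guide = np.empty(n, dtype=np.int64)
    rank_guide[order] = np.arange(1, n)

    # rank_g(guide) per column, vectorized over rows
    id_less = np.array([g < guide for g in genes])  # h beats guide on ties
    cg = C[gi, :]  # corr(guide, g) for each column g
    beats = (C > cg[None, :]) | ((C == cg[None, :]) & id_less[:, None])
    counts = beats.sum(axis=0)
    # remove self-row contribution (h == g) and the guide's own row
    diag = np.diagonal(C)
    self_contrib = (diag > cg) | ((diag == cg) & id_less)
    counts = counts - self_contrib.astype(np.int64) - beats[gi, :].astype(np.int64)
    rank_of_guide = counts + 1

    mask = np.arange(n) != gi
    mr = np.sqrt(rank_guide[mask].astype(float) * rank_of_guide[mask].astype(float))
    return pd.DataFrame({"gene": genes[mask], "pcc": cg[mask], "mr": mr})


def guide_neighborhood(corr: pd.DataFrame, guide: str, k: int = 300) -> Neighborhood:
    """The k genes with smallest mutual rank to the guide, ascending by MR.

    Ties are resolved by lexicographic gene id.  Fewer than k entries are
    returned when the rankable universe is smaller.
    """
    if guide not in corr.index:
        raise ValueError(f"guide gene {guide!r} not in correlation matrix")
    if k <= 0:
        raise ValueError("k must be positive")
    table = _guide_mr_vector(corr, guide)
    table = table.sort_values(["mr", "gene"], kind="mergesort").head(k).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return Neighborhood(guide=guide, entries=table, k=k)
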