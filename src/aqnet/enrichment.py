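"""Over-representation statistics for motifs and functional categories.

Given a study set of n genes drawn from a background of N genes, of which
K carry a feature (a motif in the promoter, a functional category) and k
of the study genes carry it, the enrichment p-value is the upper
hypergeometric tail P(X >= k).  The same table tested with a one-sided
Fisher exact test (alternative: over-representation) gives the identical
p-value; both routes are exposed and cross-checked.  Multiple testing is
corrected with the Benjamini-Hochberg step-up FDR, with significance
flagged at the strict (0.01) and loose (0.05) thresholds.

Combinatorials are evaluated in log space (log-gamma) so backgrounds of
~30,000 genes do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificanceConfig",
    "hypergeom_tail",
    "fisher_one_sided",
    "bh_fdr",
    "enrich_motifs",
    "enrich_categories",
]


@dataclass(frozen=True)
class SignificanceConfig:
    fdr_strict: float = 0.01
    fdr_loose: float = 0.05

    def __post_init__(self):
        if not 0 < self.fdr_strict <= self.fdr_loose < 1:
            raise ValueError("require 0 < fdr_strict <= fdr_loose < 1")


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    if N <= 0:
        raise ValueError(f"background size N={N} must be positive")
    if not 0 <= n <= N:
        raise ValueError(f"study size n={n} outside [0, N={N}]")
    if not 0 <= K <= N:
        raise ValueError(f"feature count K={K} outside [0, N={N}]")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"hit count k={k} outside [0, min(n={n}, K={K})]")


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Exact summation of the pmf in log space over i = k .. min(n, K).
    """
    _validate_counts(k, n, K, N)
    if k <= max(0, n + K - N):
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_pmf = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def fisher_one_sided(k: int, n: int, K: int, N: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table

        [[k, n-k], [K-k, (N-n)-(K-k)]]

    Mathematically identical to :func:`hypergeom_tail`; computed through
    an independent route.
    """
    _validate_counts(k, n, K, N)
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    return float(fisher_exact(table, alternative="greater")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_i = min_{j >= i}(m * p_(j) / j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        bad = p[~((p > 0) & (p <= 1))]
        raise ValueError(f"p-values outside (0, 1]: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def _enrichment_frame(rows: list[dict], config: SignificanceConfig) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=["id", "k", "n", "K", "N", "p_value"])
    table["fdr"] = bh_fdr(table["p_value"]) if len(table) else []
    table["significant_at_0.05"] = table["fdr"] < config.fdr_loose
    table["significant_at_0.01"] = table["fdr"] < config.fdr_strict
    return table.sort_values(["fdr", "p_value", "id"], kind="mergesort").reset_index(drop=True)


def enrich_motifs(
    presence,
    study_set: set[str],
    background: set[str],
    config: SignificanceConfig | None = None,
    unit: str = "gene",
    promoter_length: int | None = None,
) -> pd.DataFrame:
    """Motif over-representation of a study set against a background.

    With the default ``unit='gene'`` a gene counts once regardless of how
    many occurrences its promoter holds: k = genes of the study set with
    the motif, K = background genes with it, n/N the set sizes, p from the
    hypergeometric upper tail, FDR across all motifs of the run.

    ``unit='occurrence'`` instead tests occurrence counts against the
    number of scannable promoter positions (requires ``promoter_length``).
    """
    config = config or SignificanceConfig()
    study_set, background = set(study_set), set(background)
    missing = sorted(study_set - background)
    if missing:
        raise ValueError(f"study genes missing from background: {missing[:10]}")
    rows = []
    if unit == "gene":
        n, N = len(study_set), len(background)
        for motif in presence.motifs:
            present = presence.presence(motif)
            k = len(present & study_set)
            K = len(present & background)
            rows.append(dict(id=motif, k=k, n=n, K=K, N=N,
                             p_value=hypergeom_tail(k, n, K, N)))
    elif unit == "occurrence":
        if promoter_length is None:
            raise ValueError("occurrence unit requires promoter_length")
        n = promoter_length * len(study_set)
        N = promoter_length * len(background)
        for motif in presence.motifs:
            counts = presence.occurrence_counts(motif)
            k = sum(c for g, c in counts.items() if g in study_set)
            K = sum(c for g, c in counts.items() if g in background)
            rows.append(dict(id=motif, k=k, n=n, K=K, N=N,
                             p_value=hypergeom_tail(k, n, K, N)))
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return _enrichment_frame(rows, config)


def enrich_categories(
    annotation: pd.DataFrame,
    study_set: set[str],
    background: set[str],
    config: SignificanceConfig | None = None,
) -> pd.DataFrame:
    """Functional-category over-representation via one-sided Fisher tests.

    ``annotation`` has columns (gene_id, category); a gene may carry
    several categories and contributes to each independently.  Genes of
    the background absent from the annotation count as category-negative.
    """
    config = config or SignificanceConfig()
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty annotation table")
    study_set, background = set(study_set), set(background)
    missing = sorted(study_set - background)
    if missing:
        raise ValueError(f"study genes missing from background: {missing[:10]}")
    ann = annotation[annotation["gene_id"].isin(background)]
    n, N = len(study_set), len(background)
    rows = []
    for category, sub in ann.groupby("category"):
        members = set(sub["gene_id"])
        k = len(members & study_set)
        K = len(members)
        rows.append(dict(id=category, k=k, n=n, K=K, N=N,
                         p_value=fisher_one_sided(k, n, K, N)))
    return _enrichment_frame(rows, config)


def write_enrichment(table: pd.DataFrame, path) -> None:
    """Write an enrichment table sorted by ascending fdr then p."""
    table.to_csv(path, sep="\t", index=False)
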