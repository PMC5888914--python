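"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle restates the definition of an operation in the most direct
form available (exact integer combinatorics, exhaustive sorting, naive
sliding windows) and never shares code with the implementation it checks.
"""

import math
from fractions import Fraction

import numpy as np


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via integer binomials."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def hypergeom_pmf_table(n: int, K: int, N: int) -> dict[int, Fraction]:
    """Exact pmf over the full support for one (n, K, N)."""
    total = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    return {i: Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
            for i in range(lo, hi + 1)}


def mutual_rank_bruteforce(corr, gene_a: str, gene_b: str) -> float:
    """MR by literal sort-and-index, ties by lexicographic id."""

    def rank(anchor, other):
        col = corr[anchor].drop(anchor)
        order = sorted(col.index, key=lambda g: (-col[g], g))
        return order.index(other) + 1

    return math.sqrt(rank(gene_a, gene_b) * rank(gene_b, gene_a))


def scan_naive(sequence: str, expanded: set[str], motif_len: int) -> list[int]:
    """1-based offsets of every window contained in the expansion set."""
    sequence = sequence.upper()
    return [i + 1 for i in range(len(sequence) - motif_len + 1)
            if sequence[i: i + motif_len] in expanded]


def interval_overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Overlap length of two half-open intervals by direct enumeration."""
    return len(set(range(s1, e1)) & set(range(s2, e2)))


def random_count_tuple(rng: np.random.Generator, n_max: int = 2000):
    """A random valid (k, n, K, N) hypergeometric count tuple."""
    N = int(rng.integers(1, n_max + 1))
    n = int(rng.integers(0, N + 1))
    K = int(rng.integers(0, N + 1))
    lo, hi = max(0, n + K - N), min(n, K)
    k = int(rng.integers(lo, hi + 1))
    return k, n, K, N
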