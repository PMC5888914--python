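"""Transcription-factor target inference from DAP-seq peak tables.

Each peak set (one TF experiment) carries a FRiP (fraction of reads in
peaks) quality score; sets with FRiP >= 0.05 (inclusive) are retained by
default.  A gene is called a target of the TF when at least one retained
peak overlaps its promoter window (1.5 kb upstream of the TSS,
strand-aware, half-open genomic coordinates) by >= 1 bp.  Per-gene signal
is the maximum over its overlapping peaks; the "top N" list (default 350)
ranks genes by descending signal, ties broken by lexicographic gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "promoter_windows",
    "filter_peak_sets",
    "assign_targets",
    "top_targets",
]

PEAK_COLUMNS = ["seq_id", "start", "end", "peak_id", "signal", "strand"]


@dataclass
class PeakSet:
    """One DAP-seq experiment: peaks plus experiment-level metadata.

    ``peaks`` columns: seq_id, start, end (half-open, 0-based), peak_id,
    signal, strand.
    """

    set_id: str
    tf_name: str
    frip: float
    peaks: pd.DataFrame

    def __post_init__(self):
        if not 0 <= self.frip <= 1:
            raise ValueError(f"frip {self.frip} outside [0, 1] for set {self.set_id!r}")
        if len(self.peaks):
            if (self.peaks["start"] >= self.peaks["end"]).any():
                raise ValueError(f"peak with start >= end in set {self.set_id!r}")
            if self.peaks["peak_id"].duplicated().any():
                raise ValueError(f"duplicate peak ids in set {self.set_id!r}")


def filter_peak_sets(
    sets: list[PeakSet],
    min_frip: float = 0.05,
    mode: str = "per_set",
) -> list[PeakSet]:
    """Retain peak sets (or peaks) passing the FRiP quality filter.

    ``mode='per_set'`` (default, the standard reading: FRiP is an
    experiment-level score) keeps sets with frip >= min_frip, inclusive.
    ``mode='per_peak'`` instead keeps every set but drops individual peaks
    whose ``frip`` column falls below the threshold (peaks must then carry
    a per-peak ``frip`` column).
    """
    if mode == "per_set":
        kept = [s for s in sets if s.frip >= min_frip]
        for s in sets:
            if s.frip < min_frip:
                logger.warning("excluding peak set %s (FRiP %.3f < %.3f)",
                               s.set_id, s.frip, min_frip)
    elif mode == "per_peak":
        kept = []
        for s in sets:
            if "frip" not in s.peaks.columns:
                raise ValueError(f"per-peak FRiP filtering needs a 'frip' peak column "
                                 f"(set {s.set_id!r})")
            peaks = s.peaks[s.peaks["frip"] >= min_frip].reset_index(drop=True)
            kept.append(PeakSet(s.set_id, s.tf_name, s.frip, peaks))
    else:
        raise ValueError(f"unknown FRiP filter mode {mode!r}")
    if not kept:
        logger.warning("no peak sets retained at min_frip=%.3f", min_frip)
    return kept


def promoter_windows(tss_table: pd.DataFrame, window: int = 1500) -> pd.DataFrame:
    """Half-open 0-based genomic promoter intervals per gene.

    + strand: [tss-1-window, tss-1); - strand: [tss, tss+window); clipped
    at zero on the left (contig ends are the caller's concern: peak
    coordinates share the same system).
    """
    rows = []
    for rec in tss_table.itertuples(index=False):
        tss = int(rec.tss)
        if rec.strand == "+":
            start, end = max(0, tss - 1 - window), tss - 1
        elif rec.strand == "-":
            start, end = tss, tss + window
        else:
            raise ValueError(f"strand of gene {rec.gene_id!r} must be '+' or '-'")
        if start < end:
            rows.append((rec.gene_id, rec.seq_id, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "seq_id", "start", "end"])


def assign_targets(
    peak_set: PeakSet,
    tss_table: pd.DataFrame,
    window: int = 1500,
) -> pd.DataFrame:
    """Call (peak, gene) target pairs by >= 1 bp promoter overlap.

    Returns one row per overlapping pair with columns
    (tf_name, gene_id, peak_id, signal, overlap_bp).  Peaks on contigs
    absent from the TSS table are skipped with a warning.
    """
    windows = promoter_windows(tss_table, window=window)
    known_seqs = set(windows["seq_id"])
    rows = []
    skipped = 0
    for seq_id, peaks in peak_set.peaks.groupby("seq_id"):
        if seq_id not in known_seqs:
            skipped += len(peaks)
            continue
        win = windows[windows["seq_id"] == seq_id]
        ws = win["start"].to_numpy()
        we = win["end"].to_numpy()
        genes = win["gene_id"].to_numpy()
        for p in peaks.itertuples(index=False):
            overlap = np.minimum(we, p.end) - np.maximum(ws, p.start)
            hit = overlap >= 1
            for g, o in zip(genes[hit], overlap[hit]):
                rows.append((peak_set.tf_name, g, p.peak_id, float(p.signal), int(o)))
    if skipped:
        logger.warning("skipped %d peak(s) on contigs absent from the TSS table", skipped)
    calls = pd.DataFrame(rows, columns=["tf_name", "gene_id", "peak_id", "signal", "overlap_bp"])
    return calls.sort_values(["gene_id", "peak_id"], kind="mergesort").reset_index(drop=True)


def top_targets(calls: pd.DataFrame, n: int = 350) -> pd.DataFrame:
    """Top-n target genes by descending per-gene max signal.

    Ties broken by lexicographic gene id; fewer rows returned when the
    target universe is smaller.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(calls) == 0:
        raise ValueError("no target calls to rank")
    per_gene = (
        calls.groupby("gene_id", as_index=False)["signal"].max()
        .sort_values(["signal", "gene_id"], ascending=[False, True], kind="mergesort")
        .head(n)
        .reset_index(drop=True)
    )
    per_gene["rank"] = np.arange(1, len(per_gene) + 1)
    return per_gene
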