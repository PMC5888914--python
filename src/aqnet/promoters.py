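"""Strand-aware promoter extraction and degenerate IUPAC motif scanning.

Promoters are the 1,500 nt (default) immediately upstream of a gene's
transcription start site (TSS), reported 5'->3' on the gene's sense
strand: for a + strand gene with a 1-based TSS t this is the genomic
interval [t-length, t-1]; for a - strand gene it is [t+1, t+length]
reverse-complemented.  The TSS base itself is excluded.

Motifs are degenerate IUPAC strings (e.g. AKATTCY; K=G/T, Y=C/T).
Scanning is single-stranded on the promoter sense strand: the two
orientations of a palindromic-by-complement pair (AKATTCY / RGAATMT) are
supplied as separate motifs.  A sequence base 'N' matches no motif letter,
including motif 'N'.  Overlapping occurrences are all reported; presence
is binary per gene for enrichment purposes.

Also houses the small sequence utilities backing worked examples: strict
ORF translation and global-alignment percent identity.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_CODES",
    "PromoterSet",
    "PresenceTable",
    "extract_promoters",
    "expand_iupac",
    "revcomp_pattern",
    "degeneracy",
    "expected_hit_rate",
    "scan",
    "translate_orf",
    "pairwise_identity",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass
class PromoterSet:
    """gene_id -> promoter sequence (ACGTN, sense strand, 5'->3')."""

    sequences: dict[str, str]
    window_length: int = 1500

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def items(self):
        return self.sequences.items()


@dataclass
class PresenceTable:
    """Per-(gene, motif) motif occurrences over a scanned gene universe.

    ``hits`` columns: gene, motif, offset (1-based on the promoter sense
    strand), matched_seq.  ``universe`` is the full set of scanned genes,
    including those with no hit.
    """

    hits: pd.DataFrame
    universe: set[str] = field(default_factory=set)

    def presence(self, motif: str) -> set[str]:
        sub = self.hits[self.hits["motif"] == motif]
        return set(sub["gene"])

    def occurrence_counts(self, motif: str) -> dict[str, int]:
        sub = self.hits[self.hits["motif"] == motif]
        return sub.groupby("gene").size().to_dict()

    @property
    def motifs(self) -> list[str]:
        return sorted(self.hits["motif"].unique())


def _clean_pattern(iupac: str) -> str:
    pattern = iupac.strip().upper()
    if not pattern:
        raise ValueError("empty motif pattern")
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC character {ch!r} in pattern {iupac!r}")
    return pattern


def expand_iupac(iupac: str) -> set[str]:
    """All concrete ACGT strings matching a degenerate pattern.

    Cardinality equals the product of per-letter degeneracies (lowercase
    accepted, e.g. GnATATnC -> 16 sequences).
    """
    pattern = _clean_pattern(iupac)
    return {"".join(p) for p in itertools.product(*(IUPAC_CODES[c] for c in pattern))}


def degeneracy(iupac: str) -> int:
    """Product of per-letter expansion sizes."""
    pattern = _clean_pattern(iupac)
    out = 1
    for c in pattern:
        out *= len(IUPAC_CODES[c])
    return out


def revcomp_pattern(iupac: str) -> str:
    """Reverse complement under IUPAC complementation (AKATTCY -> RGAATMT)."""
    pattern = _clean_pattern(iupac)
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def expected_hit_rate(iupac: str, gc_content: float) -> float:
    """Per-position match probability for i.i.d. bases at a GC fraction.

    Base probabilities are (1-gc)/2 for A/T and gc/2 for C/G; each motif
    letter contributes the summed probability of its expansion set.
    """
    pattern = _clean_pattern(iupac)
    base_p = {"A": (1 - gc_content) / 2, "T": (1 - gc_content) / 2,
              "C": gc_content / 2, "G": gc_content / 2}
    rate = 1.0
    for c in pattern:
        rate *= sum(base_p[b] for b in IUPAC_CODES[c])
    return rate


def extract_promoters(
    genome: dict[str, str],
    tss_table: pd.DataFrame,
    length: int = 1500,
) -> PromoterSet:
    """Extract upstream promoter windows, sense-strand oriented.

    ``tss_table`` columns: gene_id, seq_id, tss (1-based), strand (+/-).
    Windows truncated at contig boundaries are returned shorter, with a
    logged warning.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    sequences: dict[str, str] = {}
    for rec in tss_table.itertuples(index=False):
        if rec.seq_id not in genome:
            raise ValueError(f"unknown seq_id {rec.seq_id!r} for gene {rec.gene_id!r}")
        contig = genome[rec.seq_id]
        tss = int(rec.tss)
        if not 1 <= tss <= len(contig):
            raise ValueError(
                f"tss {tss} of gene {rec.gene_id!r} outside contig "
                f"{rec.seq_id!r} (length {len(contig)})"
            )
        if rec.strand == "+":
            start = tss - 1 - length  # 0-based half-open [start, tss-1)
            if start < 0:
                logger.warning(
                    "promoter of %s truncated at contig start (%d bp)", rec.gene_id, tss - 1
                )
                start = 0
            seq = contig[start : tss - 1]
        elif rec.strand == "-":
            end = tss + length  # 0-based half-open [tss, end)
            if end > len(contig):
                logger.warning(
                    "promoter of %s truncated at contig end (%d bp)",
                    rec.gene_id, len(contig) - tss,
                )
                end = len(contig)
            seq = str(Seq(contig[tss:end]).reverse_complement())
        else:
            raise ValueError(f"strand of gene {rec.gene_id!r} must be '+' or '-'")
        sequences[rec.gene_id] = seq.upper()
    return PromoterSet(sequences=sequences, window_length=length)


def _motif_regex(iupac: str) -> re.Pattern:
    # Character classes list concrete bases only, so a sequence 'N' never
    # matches (including against motif letter N).  Lookahead captures
    # overlapping occurrences.
    pattern = _clean_pattern(iupac)
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan(promoters: PromoterSet, motifs: dict[str, str]) -> PresenceTable:
    """Scan promoter sense strands for each named IUPAC motif.

    ``motifs`` maps motif name -> IUPAC string.  Returns all (overlapping)
    occurrences with 1-based offsets.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    compiled = {name: _motif_regex(pat) for name, pat in motifs.items()}
    rows = []
    for gene, seq in sorted(promoters.items()):
        seq = seq.upper()
        for name in sorted(compiled):
            for m in compiled[name].finditer(seq):
                rows.append((gene, name, m.start() + 1, m.group(1)))
    hits = pd.DataFrame(rows, columns=["gene", "motif", "offset", "matched_seq"])
    return PresenceTable(hits=hits, universe=set(promoters.sequences))


def translate_orf(dna: str) -> str:
    """Translate a strict ORF (ATG start, single terminal stop) to protein.

    The terminal stop is excluded: a valid 1,071 bp ORF yields a
    356-residue protein.
    """
    dna = dna.strip().upper().replace("U", "T")
    if len(dna) == 0 or len(dna) % 3 != 0:
        raise ValueError(f"ORF length {len(dna)} is not a positive multiple of 3")
    if not dna.startswith("ATG"):
        raise ValueError("ORF must begin with ATG")
    protein = str(Seq(dna).translate(table=1))
    if not protein.endswith("*"):
        raise ValueError("ORF must end with a stop codon")
    body = protein[:-1]
    if "*" in body:
        raise ValueError("ORF contains an internal stop codon")
    return body


def pairwise_identity(protein_a: str, protein_b: str) -> float:
    """Global-alignment percent identity, one decimal place.

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1; identity is
    100 * matching columns / alignment columns (gapped columns count in the
    denominator).  Two 356-residue sequences differing at 3 positions give
    353/356 = 99.2.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    alignment = aligner.align(protein_a, protein_b)[0]
    counts = alignment.counts()
    return round(100.0 * counts.identities / alignment.length, 1)
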