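"""Readers and writers for the pipeline's plain-text exchange formats.

All intermediate artifacts are auditable text: TSV tables, multi-record
FASTA, minimal single-feature GFF3, and a truth/manifest JSON.  Column
layouts match the documented external interfaces of each stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TSS_COLUMNS = ["gene_id", "seq_id", "tss", "strand"]
PEAK_COLUMNS = ["seq_id", "start", "end", "peak_id", "signal", "strand"]


# ---------------------------------------------------------------- expression

def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_map(sample_map: pd.DataFrame, path) -> None:
    sample_map.to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------- sequences

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ TSS/GFF3

def write_tss_tsv(tss: pd.DataFrame, path) -> None:
    tss[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tss_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq_id": str,
                                               "tss": int, "strand": str})
    return table[TSS_COLUMNS]


def write_gff3(tss: pd.DataFrame, contig_lengths: dict[str, int], path) -> None:
    """Minimal GFF3 of gene features; 1-based, strand in column 7.

    For a + strand gene the feature runs from the TSS to the contig end;
    for a - strand gene from the contig start to the TSS, so the TSS is
    the feature start (+) / end (-).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id, length in contig_lengths.items():
            fh.write(f"##sequence-region {seq_id} 1 {length}\n")
        for rec in tss.itertuples(index=False):
            tss_pos = int(rec.tss)
            length = contig_lengths[rec.seq_id]
            if rec.strand == "+":
                start, end = tss_pos, length
            else:
                start, end = 1, tss_pos
            fh.write(f"{rec.seq_id}\taqnet\tgene\t{start}\t{end}\t.\t"
                     f"{rec.strand}\t.\tID={rec.gene_id}\n")


def read_gff3_tss(path) -> pd.DataFrame:
    """TSS records from gene features: GFF3 start (+) / end (-)."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["seq_id", "source", "type", "start", "end",
                               "score", "strand", "phase", "attributes"])
    table = table[table["type"] == "gene"]
    gene_ids = table["attributes"].str.extract(r"ID=([^;]+)")[0]
    tss = table["start"].where(table["strand"] == "+", table["end"])
    return pd.DataFrame({"gene_id": gene_ids, "seq_id": table["seq_id"],
                         "tss": tss.astype(int), "strand": table["strand"]}
                        ).reset_index(drop=True)


# --------------------------------------------------------------------- peaks

def write_peak_sets(sets, peaks_path, meta_path) -> None:
    meta = pd.DataFrame([(s.set_id, s.tf_name, s.frip) for s in sets],
                        columns=["set_id", "tf_name", "frip"])
    frames = []
    for s in sets:
        table = s.peaks[PEAK_COLUMNS].copy()
        table.insert(0, "set_id", s.set_id)
        frames.append(table)
    peaks = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["set_id"] + PEAK_COLUMNS))
    peaks.to_csv(peaks_path, sep="\t", index=False)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_peak_sets(peaks_path, meta_path):
    from .dapseq import PeakSet

    meta = pd.read_csv(meta_path, sep="\t", dtype={"set_id": str, "tf_name": str})
    peaks = pd.read_csv(peaks_path, sep="\t", dtype={"set_id": str, "seq_id": str,
                                                     "peak_id": str, "strand": str})
    sets = []
    for rec in meta.itertuples(index=False):
        sub = peaks[peaks["set_id"] == rec.set_id][PEAK_COLUMNS].reset_index(drop=True)
        sets.append(PeakSet(set_id=rec.set_id, tf_name=rec.tf_name,
                            frip=float(rec.frip), peaks=sub))
    return sets


# -------------------------------------------------------------------- tables

def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_motifs(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table["name"], table["iupac"]))


def write_motifs(motifs: dict[str, str], path) -> None:
    pd.DataFrame({"name": list(motifs), "iupac": list(motifs.values())}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
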