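"""Seeded synthetic inputs with ground truth for every pipeline stage.

The generator emulates, at desk scale, the statistical structure each
stage assumes: an RPKM-like expression matrix (default 2,000 genes x 60
conditions x 3 replicates, a scaled stand-in for a ~30,000-gene,
235-condition compendium averaged from ~650 samples) with one planted
co-expression module around a guide gene; per-gene promoter sequences on
both strands with motif instances planted at separate foreground and
background probabilities; DAP-seq-like peak sets with known
promoter-overlap truth; a differential-expression table with a planted
up/down gene set; and a partial one-to-one orthology map to a second
species.

Expression is log-normal by construction: module genes follow a latent
condition factor f_c with loading a (x_i = a*f_c + sqrt(1-a^2)*eps, so
the expected within-module Pearson correlation is a^2); background genes
form co-expression blocks of their own, independent of the module, and
log2 values are exponentiated onto the RPKM scale.
One global seed drives a per-component seed sequence, so each component
regenerates independently and identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .dapseq import PeakSet, promoter_windows
from .promoters import IUPAC_CODES, PresenceTable, expand_iupac

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "gen_expression",
    "gen_promoters",
    "gen_peaks",
    "gen_de_table",
    "gen_orthology",
    "generate_all",
    "simulate_presence",
    "gen_orf",
    "gen_protein_pair",
]

DEFAULT_MOTIFS: dict[str, str] = {
    "AKATTCY": "AKATTCY",
    "RGAATMT": "RGAATMT",
    "P1BS": "GNATATNC",
}

_COMPONENTS = ("expression", "promoters", "peaks", "de", "orthology")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic-data generator; the seed fixes everything."""

    seed: int = 0
    n_genes: int = 2000
    n_conditions: int = 60
    n_replicates_per_condition: int = 3
    module_size: int = 30
    module_correlation: float = 0.9  # latent-factor loading in [0, 1]
    guide_id: str | None = None  # default: first gene id
    promoter_length: int = 1500
    gc_content: float = 0.4
    motif_list: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    p_fg: float = 0.6
    p_bg: float = 0.2
    n_peak_sets: int = 3
    peaks_per_set: int = 100
    frip_values: tuple[float, ...] = (0.12, 0.08, 0.03)
    de_effect_sd: float = 0.5
    # secondary knobs
    background_block_size: int = 50
    background_block_loading: float = 0.8
    replicate_log_sd: float = 0.2
    n_genes_species2: int = 500
    de_fraction: float = 0.1
    targets_per_set: int = 50
    peak_width: int = 60
    n_orthologs: int = 150

    def __post_init__(self):
        counts = dict(n_genes=self.n_genes, n_conditions=self.n_conditions,
                      n_replicates_per_condition=self.n_replicates_per_condition,
                      module_size=self.module_size, promoter_length=self.promoter_length,
                      n_peak_sets=self.n_peak_sets, peaks_per_set=self.peaks_per_set,
                      n_genes_species2=self.n_genes_species2, peak_width=self.peak_width)
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.module_size >= self.n_genes:
            raise ValueError(
                f"module_size ({self.module_size}) must be < n_genes ({self.n_genes})")
        if not 0 <= self.p_bg <= self.p_fg <= 1:
            raise ValueError(f"require 0 <= p_bg ({self.p_bg}) <= p_fg ({self.p_fg}) <= 1")
        if not 0 <= self.module_correlation <= 1:
            raise ValueError("module_correlation must lie in [0, 1]")
        if not 0 <= self.background_block_loading <= 1:
            raise ValueError("background_block_loading must lie in [0, 1]")
        if self.background_block_size <= 0:
            raise ValueError("background_block_size must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if any(not 0 <= f <= 1 for f in self.frip_values):
            raise ValueError(f"frip_values outside [0, 1]: {self.frip_values}")
        for name, pattern in self.motif_list.items():
            if len(pattern) > self.promoter_length:
                raise ValueError(f"motif {name!r} longer than the promoter window")
            for ch in pattern.upper():
                if ch not in IUPAC_CODES:
                    raise ValueError(f"illegal IUPAC character {ch!r} in motif {name!r}")
        if self.peak_width >= self.promoter_length or self.peak_width > 100:
            raise ValueError("peak_width must fit inside promoter and flank regions")
        if self.targets_per_set > min(self.peaks_per_set, self.n_genes):
            raise ValueError("targets_per_set exceeds peaks_per_set or gene count")

    # -- derived id universes ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def species2_gene_ids(self) -> list[str]:
        return [f"at{i + 1:05d}" for i in range(self.n_genes_species2)]

    @property
    def guide(self) -> str:
        return self.guide_id if self.guide_id is not None else self.gene_ids[0]

    @property
    def module_members(self) -> list[str]:
        guide = self.guide
        others = [g for g in self.gene_ids if g != guide]
        return [guide] + others[: self.module_size - 1]

    def component_rng(self, component: str) -> np.random.Generator:
        """Independent generator per pipeline component, derived from the seed."""
        index = _COMPONENTS.index(component)
        child = np.random.SeedSequence(self.seed).spawn(len(_COMPONENTS))[index]
        return np.random.default_rng(child)


@dataclass
class GroundTruth:
    """Planted-structure records, verifiable against the emitted files."""

    module_members: list[str] = field(default_factory=list)
    planted_motif_sites: list[dict] = field(default_factory=list)
    true_targets: list[dict] = field(default_factory=list)
    true_de: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "module_members": sorted(self.module_members),
            "planted_motif_sites": sorted(
                self.planted_motif_sites,
                key=lambda s: (s["gene"], s["motif"], s["offset"])),
            "true_targets": sorted(self.true_targets,
                                   key=lambda t: (t["set_id"], t["gene"])),
            "true_de": sorted(self.true_de, key=lambda d: d["gene"]),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        return cls(module_members=list(data.get("module_members", [])),
                   planted_motif_sites=list(data.get("planted_motif_sites", [])),
                   true_targets=list(data.get("true_targets", [])),
                   true_de=list(data.get("true_de", [])))

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            module_members=self.module_members or other.module_members,
            planted_motif_sites=self.planted_motif_sites + other.planted_motif_sites,
            true_targets=self.true_targets + other.true_targets,
            true_de=self.true_de + other.true_de,
        )


# ------------------------------------------------------------------ expression

def gen_expression(config: SyntheticConfig):
    """Expression matrix (genes x samples), sample map, and module truth."""
    rng = config.component_rng("expression")
    genes = config.gene_ids
    module = config.module_members
    if config.guide not in genes:
        raise ValueError(f"guide_id {config.guide!r} not among generated gene ids")
    module_idx = [genes.index(g) for g in module]

    a = config.module_correlation
    noise_sd = float(np.sqrt(max(0.0, 1.0 - a * a)))
    f = rng.standard_normal(config.n_conditions)
    x = rng.standard_normal((config.n_genes, config.n_conditions))
    x[module_idx, :] = (a * f[None, :]
                        + noise_sd * rng.standard_normal((len(module_idx),
                                                          config.n_conditions)))
    # Background co-expression blocks, independent of the planted module and
    # of each other: real compendia are pervasively structured, and without
    # this the mutual-rank metric degenerates (an unstructured gene whose
    # strongest chance correlation points at the guide becomes a reciprocal
    # near-best partner and contaminates any guide neighborhood).
    b = config.background_block_loading
    if b > 0:
        b_sd = float(np.sqrt(max(0.0, 1.0 - b * b)))
        background_idx = [i for i in range(config.n_genes) if i not in set(module_idx)]
        for lo in range(0, len(background_idx), config.background_block_size):
            block = background_idx[lo: lo + config.background_block_size]
            g = rng.standard_normal(config.n_conditions)
            x[block, :] = (b * g[None, :]
                           + b_sd * rng.standard_normal((len(block),
                                                         config.n_conditions)))
    baseline = rng.uniform(2.0, 8.0, size=config.n_genes)
    log_cond = baseline[:, None] + x

    condition_ids = [f"c{c + 1:03d}" for c in range(config.n_conditions)]
    sample_ids, sample_conditions = [], []
    columns = []
    for c, cond in enumerate(condition_ids):
        for r in range(config.n_replicates_per_condition):
            sample_ids.append(f"{cond}_r{r + 1}")
            sample_conditions.append(cond)
            columns.append(log_cond[:, c]
                           + rng.normal(0.0, config.replicate_log_sd,
                                        size=config.n_genes))
    values = np.power(2.0, np.column_stack(columns))
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=sample_ids)
    sample_map = pd.DataFrame({"sample_id": sample_ids,
                               "condition_id": sample_conditions})
    truth = GroundTruth(module_members=list(module))
    return matrix, sample_map, truth


# ------------------------------------------------------------------- promoters

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(["A", "C", "G", "T"]), size=n, p=probs)


def gen_promoters(config: SyntheticConfig, foreground: set[str]):
    """Synthetic genome (one contig per gene), TSS table, and planted sites.

    Each gene sits on its own contig of length promoter_length + 100, with
    alternating orientation: + strand genes have their promoter at the
    contig start (TSS = promoter_length + 1), - strand genes carry it
    reverse-complemented after a 100 bp flank (TSS = 100).  Foreground
    genes receive one planted instance of each motif with probability
    p_fg, background genes with p_bg; instances are drawn uniformly from
    the motif's IUPAC expansion at uniform non-overlapping offsets.
    """
    foreground = set(foreground)
    unknown = foreground - set(config.gene_ids)
    if unknown:
        raise ValueError(f"foreground genes outside the generated universe: "
                         f"{sorted(unknown)[:5]}")
    rng = config.component_rng("promoters")
    L = config.promoter_length
    flank = 100
    expansions = {name: sorted(expand_iupac(pat))
                  for name, pat in sorted(config.motif_list.items())}

    genome: dict[str, str] = {}
    tss_rows = []
    sites = []
    for idx, gene in enumerate(config.gene_ids):
        promoter = _random_bases(rng, L, config.gc_content)
        occupied: list[tuple[int, int]] = []
        p_plant = config.p_fg if gene in foreground else config.p_bg
        for name, concrete in expansions.items():
            if rng.random() >= p_plant:
                continue
            instance = concrete[rng.integers(len(concrete))]
            m = len(instance)
            for _ in range(200):  # rejection-sample a non-overlapping offset
                offset = int(rng.integers(1, L - m + 2))  # 1-based
                span = (offset, offset + m)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    promoter[offset - 1: offset - 1 + m] = list(instance)
                    sites.append(dict(gene=gene, motif=name, offset=offset,
                                      instance=instance))
                    break
        promoter_seq = "".join(promoter)
        seq_id = f"ctg_{gene}"
        flank_seq = "".join(_random_bases(rng, flank, config.gc_content))
        if idx % 2 == 0:  # + strand: promoter occupies contig[0:L], TSS at L+1
            contig = promoter_seq + flank_seq
            tss, strand = L + 1, "+"
        else:  # - strand: promoter = revcomp(contig[100:100+L]), TSS at 100
            contig = flank_seq + str(Seq(promoter_seq).reverse_complement())
            tss, strand = flank, "-"
        genome[seq_id] = contig
        tss_rows.append((gene, seq_id, tss, strand))

    tss_table = pd.DataFrame(tss_rows, columns=["gene_id", "seq_id", "tss", "strand"])
    return genome, tss_table, GroundTruth(planted_motif_sites=sites)


# ----------------------------------------------------------------------- peaks

def gen_peaks(config: SyntheticConfig, tss_table: pd.DataFrame):
    """DAP-seq-like peak sets with known promoter-overlap truth.

    True-target peaks fall entirely inside the gene's promoter window;
    background peaks sit in the contig flank outside it.  FRiP values are
    taken from ``config.frip_values`` (cycled across sets).
    """
    rng = config.component_rng("peaks")
    windows = promoter_windows(tss_table, window=config.promoter_length)
    windows = windows.set_index("gene_id")
    genes = list(tss_table["gene_id"])
    seq_of = dict(zip(tss_table["gene_id"], tss_table["seq_id"]))
    strand_of = dict(zip(tss_table["gene_id"], tss_table["strand"]))
    L, w, flank = config.promoter_length, config.peak_width, 100

    sets = []
    truth = GroundTruth()
    for s in range(config.n_peak_sets):
        set_id, tf_name = f"set{s + 1}", f"TF{s + 1}"
        frip = config.frip_values[s % len(config.frip_values)]
        chosen = rng.choice(len(genes), size=config.targets_per_set, replace=False)
        target_genes = [genes[i] for i in sorted(chosen)]
        rows = []
        for i, gene in enumerate(target_genes):
            win = windows.loc[gene]
            start = int(rng.integers(win["start"], win["end"] - w + 1))
            rows.append((seq_of[gene], start, start + w, f"{set_id}_p{i + 1:04d}",
                         float(np.round(rng.uniform(10.0, 100.0), 3)), "."))
            truth.true_targets.append(dict(set_id=set_id, gene=gene))
        n_bg = config.peaks_per_set - config.targets_per_set
        bg_genes = rng.choice(len(genes), size=n_bg, replace=True)
        for j, gi in enumerate(bg_genes):
            gene = genes[gi]
            # flank region outside the promoter window on the same contig
            if strand_of[gene] == "+":
                lo, hi = L, L + flank - w  # window is [0, L)
            else:
                lo, hi = 0, flank - w  # window is [flank, flank + L)
            start = int(rng.integers(lo, hi + 1))
            rows.append((seq_of[gene], start, start + w,
                         f"{set_id}_bg{j + 1:04d}",
                         float(np.round(rng.uniform(1.0, 100.0), 3)), "."))
        peaks = pd.DataFrame(rows, columns=["seq_id", "start", "end",
                                            "peak_id", "signal", "strand"])
        sets.append(PeakSet(set_id=set_id, tf_name=tf_name, frip=float(frip),
                            peaks=peaks))
    return sets, truth


# -------------------------------------------------------------------------- DE

def gen_de_table(config: SyntheticConfig):
    """Species-2 differential-expression table with planted up/down truth.

    log2FC is a mixture: null genes ~ N(0, 0.1); true DE genes
    ~ +/- N(2, de_effect_sd).  p-values come from a two-sided z-test on
    log2FC (se 0.25) for DE genes and are uniform for nulls; the fdr
    column is the Benjamini-Hochberg adjustment.
    """
    from scipy.stats import norm

    from .enrichment import bh_fdr

    rng = config.component_rng("de")
    genes = config.species2_gene_ids
    n = len(genes)
    n_de = int(round(config.de_fraction * n))
    de_idx = set(int(i) for i in rng.choice(n, size=n_de, replace=False))

    log2fc = rng.normal(0.0, 0.1, size=n)
    p = rng.uniform(0.0, 1.0, size=n)
    p = np.maximum(p, 1e-12)
    truth = GroundTruth()
    for i in sorted(de_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2fc[i] = sign * abs(rng.normal(2.0, config.de_effect_sd))
        p[i] = max(2.0 * norm.sf(abs(log2fc[i]) / 0.25), 1e-300)
        truth.true_de.append(dict(gene=genes[i],
                                  direction="up" if sign > 0 else "down"))
    table = pd.DataFrame({
        "gene_id": genes,
        "log2fc": np.round(log2fc, 6),
        "p_value": p,
        "fdr": bh_fdr(p),
        "contrast": "stress_vs_nonstress",
    })
    return table, truth


# ------------------------------------------------------------------- orthology

def gen_orthology(config: SyntheticConfig) -> pd.DataFrame:
    """Partial one-to-one orthology map between the two species' ids.

    Module members are always mapped (so the planted neighborhood can be
    bridged into the species-2 subnetwork); additional random pairs are
    added up to ``n_orthologs`` total, without reusing genes on either
    side.
    """
    rng = config.component_rng("orthology")
    sp1 = list(config.module_members)
    remaining1 = [g for g in config.gene_ids if g not in set(sp1)]
    n_extra = max(0, min(config.n_orthologs - len(sp1), len(remaining1)))
    extra = rng.choice(len(remaining1), size=n_extra, replace=False)
    sp1 += [remaining1[i] for i in sorted(extra)]

    sp2_pool = list(config.species2_gene_ids)
    if len(sp1) > len(sp2_pool):
        sp1 = sp1[: len(sp2_pool)]
    chosen2 = rng.choice(len(sp2_pool), size=len(sp1), replace=False)
    sp2 = [sp2_pool[i] for i in chosen2]
    confidence = np.round(rng.uniform(0.7, 1.0, size=len(sp1)), 4)
    return pd.DataFrame({"gene_species_1": sp1, "gene_species_2": sp2,
                         "confidence": confidence})


# ------------------------------------------------------------------ aggregates

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    expression: pd.DataFrame
    sample_map: pd.DataFrame
    genome: dict[str, str]
    tss_table: pd.DataFrame
    peak_sets: list
    de_table: pd.DataFrame
    orthology: pd.DataFrame
    truth: GroundTruth


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every synthetic input; foreground = the planted module."""
    expression, sample_map, t_expr = gen_expression(config)
    genome, tss_table, t_prom = gen_promoters(config, set(config.module_members))
    peak_sets, t_peaks = gen_peaks(config, tss_table)
    de_table, t_de = gen_de_table(config)
    orthology = gen_orthology(config)
    truth = t_expr.merge(t_prom).merge(t_peaks).merge(t_de)
    return SyntheticDataset(config=config, expression=expression,
                            sample_map=sample_map, genome=genome,
                            tss_table=tss_table, peak_sets=peak_sets,
                            de_table=de_table, orthology=orthology, truth=truth)


# -------------------------------------------------- direct presence simulation

def simulate_presence(
    seed: int,
    motifs: list[str],
    study_genes: list[str],
    background_genes: list[str],
    p_fg: float,
    p_bg: float,
) -> PresenceTable:
    """Bernoulli presence/absence table for calibration and power studies.

    Study genes carry each motif with probability p_fg, the remaining
    background genes with p_bg, independently across motifs -- the
    gene-level summary the promoter generator produces, without
    materializing sequences.  Study genes must be a subset of the
    background.
    """
    if not set(study_genes) <= set(background_genes):
        raise ValueError("study genes must be a subset of the background")
    rng = np.random.default_rng(seed)
    study = set(study_genes)
    genes = np.asarray(background_genes)
    p_vec = np.where(np.isin(genes, list(study)), p_fg, p_bg)
    draws = rng.random((len(motifs), len(genes))) < p_vec[None, :]
    motif_idx, gene_idx = np.nonzero(draws)
    hits = pd.DataFrame({"gene": genes[gene_idx],
                         "motif": np.asarray(motifs)[motif_idx],
                         "offset": 1, "matched_seq": ""})
    return PresenceTable(hits=hits, universe=set(background_genes))


# ------------------------------------------------------- sequence fixture gen

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


def gen_orf(seed: int, length_bp: int = 1071) -> str:
    """A random valid ORF: ATG start, no internal stop, one terminal stop.

    length_bp must be a positive multiple of 3 (>= 6); the encoded protein
    has length_bp/3 - 1 residues.
    """
    if length_bp % 3 != 0 or length_bp < 6:
        raise ValueError("ORF length must be a multiple of 3, at least 6")
    rng = np.random.default_rng(seed)
    n_internal = length_bp // 3 - 2
    body = [_SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS),
                                                   size=n_internal)]
    stop = sorted(_STOPS)[rng.integers(3)]
    return "ATG" + "".join(body) + stop


def gen_protein_pair(seed: int, length: int = 356, n_diffs: int = 3) -> tuple[str, str]:
    """Synthetic stand-in protein pair: equal length, n_diffs substitutions.

    Used for worked examples of percent-identity arithmetic (e.g. 356
    residues differing at 3 positions -> 353/356 = 99.2%).  These are
    random sequences, not any real protein.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rng = np.random.default_rng(seed)
    base = ["M"] + [alphabet[i] for i in rng.integers(len(alphabet), size=length - 1)]
    variant = list(base)
    positions = rng.choice(np.arange(1, length), size=n_diffs, replace=False)
    for pos in positions:
        old = variant[pos]
        choices = [c for c in alphabet if c != old]
        variant[pos] = choices[rng.integers(len(choices))]
    return "".join(base), "".join(variant)
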