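"""End-to-end orchestration: simulate -> coexpress -> promoters/scan ->
enrich -> dapseq -> integrate, from a single flat configuration.

Every stage reads and writes documented plain-text artifacts, so any
stage can be re-run or audited standalone.  A run manifest records the
parameters, per-stage output paths (relative to the run directory) and
SHA-256 checksums; identical configuration and inputs give byte-identical
outputs and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, coexpression, dapseq, enrichment, io, network, promoters
from .synthetic import SyntheticConfig, generate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]

STAGES = ("simulate", "coexpress", "promoters", "enrich", "dapseq", "integrate")


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration (YAML on disk).

    When ``simulate`` is true the synthetic generator produces all inputs
    under the run directory; otherwise the ``*_path`` entries must point
    at existing files.
    """

    seed: int = 0
    simulate: bool = True
    guide: str | None = None
    k_neighborhood: int = 300
    promoter_length: int = 1500
    min_frip: float = 0.05
    top_n_targets: int = 350
    fdr_strict: float = 0.01
    fdr_loose: float = 0.05
    species1_prefix: str = "Vv"
    species2_prefix: str = "At"
    stages: tuple[str, ...] = STAGES
    # synthetic-generator knobs (used when simulate is true)
    n_genes: int = 2000
    n_conditions: int = 60
    n_replicates_per_condition: int = 3
    module_size: int = 30
    module_correlation: float = 0.9
    # input paths (used when simulate is false)
    expression_path: str | None = None
    sample_map_path: str | None = None
    genome_path: str | None = None
    tss_path: str | None = None
    motifs_path: str | None = None
    peaks_path: str | None = None
    peaks_meta_path: str | None = None
    de_path: str | None = None
    orthology_path: str | None = None

    def __post_init__(self):
        if self.k_neighborhood <= 0 or self.top_n_targets <= 0:
            raise ValueError("k_neighborhood and top_n_targets must be positive")
        if not 0 < self.fdr_strict <= self.fdr_loose < 1:
            raise ValueError("require 0 < fdr_strict <= fdr_loose < 1")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {unknown}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed,
            n_genes=self.n_genes,
            n_conditions=self.n_conditions,
            n_replicates_per_condition=self.n_replicates_per_condition,
            module_size=self.module_size,
            module_correlation=self.module_correlation,
            guide_id=self.guide,
            promoter_length=self.promoter_length,
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages and write ``manifest.json``.

    Returns the manifest dictionary.  A stage failure raises, leaving the
    partial outputs of completed stages on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest: dict = {
        "version": __version__,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        }

    # ------------------------------------------------------------- simulate
    if "simulate" in config.stages and config.simulate:
        logger.info("stage simulate: generating synthetic inputs")
        dataset = generate_all(config.synthetic_config())
        sim = outdir / "inputs"
        sim.mkdir(exist_ok=True)
        io.write_expression(dataset.expression, sim / "expression.tsv")
        io.write_sample_map(dataset.sample_map, sim / "sample_map.tsv")
        io.write_fasta(dataset.genome, sim / "genome.fasta")
        io.write_tss_tsv(dataset.tss_table, sim / "tss.tsv")
        io.write_gff3(dataset.tss_table,
                      {k: len(v) for k, v in dataset.genome.items()},
                      sim / "genes.gff3")
        io.write_motifs(dataset.config.motif_list, sim / "motifs.tsv")
        io.write_peak_sets(dataset.peak_sets, sim / "peaks.tsv", sim / "peaks_meta.tsv")
        io.write_table(dataset.de_table, sim / "de.tsv")
        io.write_table(dataset.orthology, sim / "orthology.tsv")
        io.write_json(dataset.truth.to_dict(), sim / "truth.json")
        paths.update(expression=sim / "expression.tsv",
                     sample_map=sim / "sample_map.tsv",
                     genome=sim / "genome.fasta", tss=sim / "tss.tsv",
                     motifs=sim / "motifs.tsv", peaks=sim / "peaks.tsv",
                     peaks_meta=sim / "peaks_meta.tsv", de=sim / "de.tsv",
                     orthology=sim / "orthology.tsv", truth=sim / "truth.json")
        record("simulate", {k: v for k, v in paths.items()})
        guide = dataset.config.guide
    else:
        for key, attr in [("expression", "expression_path"),
                          ("sample_map", "sample_map_path"),
                          ("genome", "genome_path"), ("tss", "tss_path"),
                          ("motifs", "motifs_path"), ("peaks", "peaks_path"),
                          ("peaks_meta", "peaks_meta_path"), ("de", "de_path"),
                          ("orthology", "orthology_path")]:
            value = getattr(config, attr)
            if value is not None:
                paths[key] = Path(value)
        if config.guide is None:
            raise ValueError("guide gene id is required when simulate is disabled")
        guide = config.guide

    # ------------------------------------------------------------ coexpress
    neighborhood = None
    if "coexpress" in config.stages:
        logger.info("stage coexpress: mutual-rank neighborhood of %s", guide)
        matrix = io.read_expression(paths["expression"])
        sample_map = io.read_sample_map(paths["sample_map"])
        averaged = coexpression.average_replicates(matrix, sample_map)
        logged = coexpression.log_transform(averaged)
        corr = coexpression.pcc_matrix(logged)
        neighborhood = coexpression.guide_neighborhood(corr, guide,
                                                      k=config.k_neighborhood)
        out = outdir / "neighborhood.tsv"
        io.write_table(neighborhood.entries, out)
        record("coexpress", {"neighborhood": out})

    # ------------------------------------------------------------ promoters
    presence = None
    promoter_set = None
    if "promoters" in config.stages:
        logger.info("stage promoters: extraction and motif scan")
        genome = io.read_fasta(paths["genome"])
        tss = io.read_tss_tsv(paths["tss"])
        motifs = io.read_motifs(paths["motifs"])
        promoter_set = promoters.extract_promoters(genome, tss,
                                                   length=config.promoter_length)
        io.write_fasta(promoter_set.sequences, outdir / "promoters.fasta")
        presence = promoters.scan(promoter_set, motifs)
        io.write_table(presence.hits, outdir / "motif_hits.tsv")
        presence_rows = presence.hits.groupby(["motif", "gene"]).size().reset_index(
            name="occurrences")
        io.write_table(presence_rows, outdir / "motif_presence.tsv")
        record("promoters", {"promoters": outdir / "promoters.fasta",
                             "hits": outdir / "motif_hits.tsv",
                             "presence": outdir / "motif_presence.tsv"})

    # --------------------------------------------------------------- enrich
    if "enrich" in config.stages:
        if presence is None or neighborhood is None:
            raise ValueError("enrich stage needs the coexpress and promoters stages")
        logger.info("stage enrich: motif over-representation in the neighborhood")
        study = set(neighborhood.genes) & presence.universe
        sig = enrichment.SignificanceConfig(fdr_strict=config.fdr_strict,
                                            fdr_loose=config.fdr_loose)
        table = enrichment.enrich_motifs(presence, study, presence.universe,
                                         config=sig)
        out = outdir / "motif_enrichment.tsv"
        enrichment.write_enrichment(table, out)
        record("enrich", {"motif_enrichment": out})

    # --------------------------------------------------------------- dapseq
    target_calls = None
    if "dapseq" in config.stages:
        logger.info("stage dapseq: FRiP filter and promoter target assignment")
        sets = io.read_peak_sets(paths["peaks"], paths["peaks_meta"])
        tss = io.read_tss_tsv(paths["tss"])
        kept = dapseq.filter_peak_sets(sets, min_frip=config.min_frip)
        import pandas as pd

        calls = [dapseq.assign_targets(s, tss, window=config.promoter_length)
                 for s in kept]
        target_calls = (pd.concat(calls, ignore_index=True) if calls
                        else pd.DataFrame(columns=["tf_name", "gene_id",
                                                   "peak_id", "signal",
                                                   "overlap_bp"]))
        io.write_table(target_calls, outdir / "targets.tsv")
        outputs = {"targets": outdir / "targets.tsv"}
        if len(target_calls):
            top = dapseq.top_targets(target_calls, n=config.top_n_targets)
            io.write_table(top, outdir / "top_targets.tsv")
            outputs["top_targets"] = outdir / "top_targets.tsv"
        record("dapseq", outputs)

    # ------------------------------------------------------------ integrate
    if "integrate" in config.stages:
        if neighborhood is None:
            raise ValueError("integrate stage needs the coexpress stage")
        logger.info("stage integrate: interspecies network assembly")
        de_table = io.read_table(paths["de"]) if "de" in paths else None
        orthology = io.read_table(paths["orthology"]) if "orthology" in paths else None
        net = network.build_network(neighborhood, presence, de_table, orthology,
                                    target_calls,
                                    species1_prefix=config.species1_prefix,
                                    species2_prefix=config.species2_prefix,
                                    de_fdr_max=config.fdr_loose)
        files = network.export_network(net, outdir / "network")
        record("integrate", files)

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
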