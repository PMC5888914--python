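"""Interspecies regulatory-network assembly and Cytoscape-ready export.

The network joins (i) the guide gene's co-expression neighborhood in
species 1 (edges weighted by Pearson correlation, nodes annotated with
the cis-elements found in their promoters), (ii) orthology links to
species 2, (iii) differential-expression status under the stress
contrast in species 2 (a "cold" hub node connects to significantly
regulated genes with up/down edge labels), and (iv) DAP-seq target
membership for the species-2 TFs.  Gene ids are namespaced by species
prefix ("Vv:...", "At:...") so the two id systems cannot collide.

Also houses two presentation statistics: per-row Z-score scaling of an
expression matrix (for heatmaps) and the 2^-ddCt relative qPCR fold
change.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "export_network",
    "import_network",
    "zscore_matrix",
    "ddct_fold",
]

COLD_HUB = "cold"
EDGE_TYPES = ("coexpression", "orthology", "cold_regulation", "tf_target")


def build_network(
    neighborhood,
    presence,
    de_table: pd.DataFrame | None,
    orthology: pd.DataFrame | None,
    target_calls: pd.DataFrame | None,
    species1_prefix: str = "Vv",
    species2_prefix: str = "At",
    de_fdr_max: float = 0.05,
) -> nx.MultiDiGraph:
    """Assemble the typed interspecies network.

    Parameters
    ----------
    neighborhood:
        :class:`aqnet.coexpression.Neighborhood` of the species-1 guide.
    presence:
        :class:`aqnet.promoters.PresenceTable` over species-1 promoters.
    de_table:
        Species-2 table with columns (gene_id, log2fc, p_value, fdr,
        contrast); genes with fdr < ``de_fdr_max`` are cold-regulated.
    orthology:
        Columns (gene_species_1, gene_species_2, confidence).
    target_calls:
        DAP-seq calls with columns (tf_name, gene_id, ...), species-2 ids.

    Node inclusion is explicit rather than hard-coded: species-2 genes
    enter when they are orthologs of retained species-1 nodes or pass the
    DE filter; the FDR threshold is a parameter.
    """
    if species1_prefix == species2_prefix:
        raise ValueError("species prefixes must differ to keep id namespaces resolvable")
    p1, p2 = species1_prefix, species2_prefix
    net = nx.MultiDiGraph()

    guide_node = f"{p1}:{neighborhood.guide}"
    net.add_node(guide_node, species=p1, node_kind="gene", is_guide=True)
    motif_of = {}
    if presence is not None and len(presence.hits):
        for motif in presence.motifs:
            for gene in presence.presence(motif):
                motif_of.setdefault(gene, []).append(motif)
    for rec in neighborhood.entries.itertuples(index=False):
        node = f"{p1}:{rec.gene}"
        net.add_node(node, species=p1, node_kind="gene",
                     motif_presence=sorted(motif_of.get(rec.gene, [])))
        net.add_edge(guide_node, node, key="coexpression",
                     edge_type="coexpression", weight=float(rec.pcc), mr=float(rec.mr))

    de_sig: dict[str, pd.Series] = {}
    if de_table is not None and len(de_table):
        for rec in de_table.itertuples(index=False):
            if rec.fdr < de_fdr_max:
                de_sig[rec.gene_id] = rec

    targets_of: dict[str, list[str]] = {}
    tf_names: set[str] = set()
    if target_calls is not None and len(target_calls):
        for rec in target_calls.itertuples(index=False):
            targets_of.setdefault(rec.gene_id, []).append(rec.tf_name)
            tf_names.add(rec.tf_name)

    species2_genes: set[str] = set(de_sig)
    ortho_pairs: list[tuple[str, str, float]] = []
    if orthology is not None and len(orthology):
        for rec in orthology.itertuples(index=False):
            g1 = f"{p1}:{rec.gene_species_1}"
            if g1 in net:
                species2_genes.add(rec.gene_species_2)
                ortho_pairs.append((g1, rec.gene_species_2, float(rec.confidence)))

    for gene in sorted(species2_genes):
        node = f"{p2}:{gene}"
        attrs = dict(species=p2, node_kind="gene",
                     tf_target_of=sorted(set(targets_of.get(gene, []))))
        if gene in de_sig:
            rec = de_sig[gene]
            attrs["log2fc"] = float(rec.log2fc)
            attrs["cold_direction"] = "up" if rec.log2fc > 0 else "down"
        net.add_node(node, **attrs)

    for g1, g2, conf in ortho_pairs:
        net.add_edge(g1, f"{p2}:{g2}", key="orthology",
                     edge_type="orthology", weight=conf)

    if de_sig:
        net.add_node(COLD_HUB, species=p2, node_kind="condition-hub")
        for gene in sorted(de_sig):
            rec = de_sig[gene]
            direction = "up" if rec.log2fc > 0 else "down"
            net.add_edge(COLD_HUB, f"{p2}:{gene}", key="cold_regulation",
                         edge_type="cold_regulation",
                         weight=float(rec.log2fc), direction=direction)

    for tf in sorted(tf_names):
        tf_node = f"{p2}:{tf}"
        if tf_node not in net:
            net.add_node(tf_node, species=p2, node_kind="gene", is_tf=True)
    for gene, tfs in targets_of.items():
        node = f"{p2}:{gene}"
        if node not in net:
            continue
        for tf in sorted(set(tfs)):
            net.add_edge(f"{p2}:{tf}", node, key="tf_target",
                         edge_type="tf_target", weight=1.0)

    return net


def _edge_rows(net: nx.MultiDiGraph) -> pd.DataFrame:
    rows = []
    for u, v, key, data in net.edges(keys=True, data=True):
        rows.append(dict(source=u, edge_type=data.get("edge_type", key), target=v,
                         weight=data.get("weight", ""),
                         mr=data.get("mr", ""),
                         direction=data.get("direction", "")))
    table = pd.DataFrame(rows, columns=["source", "edge_type", "target",
                                        "weight", "mr", "direction"])
    return table.sort_values(["source", "edge_type", "target"],
                             kind="mergesort").reset_index(drop=True)


def _node_rows(net: nx.MultiDiGraph) -> pd.DataFrame:
    rows = []
    for node, data in net.nodes(data=True):
        rows.append(dict(
            id=node,
            species=data.get("species", ""),
            node_kind=data.get("node_kind", ""),
            is_guide=bool(data.get("is_guide", False)),
            is_tf=bool(data.get("is_tf", False)),
            log2fc=data.get("log2fc", ""),
            cold_direction=data.get("cold_direction", ""),
            motif_presence=",".join(data.get("motif_presence", [])),
            tf_target_of=",".join(data.get("tf_target_of", [])),
        ))
    table = pd.DataFrame(rows, columns=["id", "species", "node_kind", "is_guide",
                                        "is_tf", "log2fc", "cold_direction",
                                        "motif_presence", "tf_target_of"])
    return table.sort_values("id", kind="mergesort").reset_index(drop=True)


def export_network(net: nx.MultiDiGraph, out_prefix: str | Path) -> dict[str, Path]:
    """Write Cytoscape-loadable SIF plus node/edge attribute tables.

    Produces ``<prefix>.sif`` (source<TAB>edge_type<TAB>target),
    ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``, all in
    lexicographic row order, so identical networks export byte-identically.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = _edge_rows(net)
    nodes = _node_rows(net)
    sif_path = out_prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for rec in edges.itertuples(index=False):
            fh.write(f"{rec.source}\t{rec.edge_type}\t{rec.target}\n")
        connected = set(edges["source"]) | set(edges["target"])
        for node in nodes["id"]:
            if node not in connected:
                fh.write(f"{node}\n")
    nodes_path = Path(str(out_prefix) + ".nodes.tsv")
    edges_path = Path(str(out_prefix) + ".edges.tsv")
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}


def import_network(out_prefix: str | Path) -> nx.MultiDiGraph:
    """Rebuild a network from its exported attribute tables (round-trip)."""
    out_prefix = Path(out_prefix)
    nodes = pd.read_csv(Path(str(out_prefix) + ".nodes.tsv"), sep="\t",
                        keep_default_na=False)
    edges = pd.read_csv(Path(str(out_prefix) + ".edges.tsv"), sep="\t",
                        keep_default_na=False)
    net = nx.MultiDiGraph()
    for rec in nodes.itertuples(index=False):
        attrs = dict(species=rec.species, node_kind=rec.node_kind)
        if rec.is_guide:
            attrs["is_guide"] = True
        if rec.is_tf:
            attrs["is_tf"] = True
        if rec.log2fc != "":
            attrs["log2fc"] = float(rec.log2fc)
        if rec.cold_direction != "":
            attrs["cold_direction"] = rec.cold_direction
        if rec.motif_presence != "":
            attrs["motif_presence"] = rec.motif_presence.split(",")
        elif rec.species and rec.node_kind == "gene":
            pass
        if rec.tf_target_of != "":
            attrs["tf_target_of"] = rec.tf_target_of.split(",")
        net.add_node(rec.id, **attrs)
    for rec in edges.itertuples(index=False):
        attrs = dict(edge_type=rec.edge_type)
        if rec.weight != "":
            attrs["weight"] = float(rec.weight)
        if rec.mr != "":
            attrs["mr"] = float(rec.mr)
        if rec.direction != "":
            attrs["direction"] = rec.direction
        net.add_edge(rec.source, rec.target, key=rec.edge_type, **attrs)
    return net


def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (row) Z-score scaling: (v - row mean) / row sd (ddof=1).

    Rows with zero standard deviation map to all zeros with a warning.
    Requires at least two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-score scaling needs >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant row(s) mapped to zeros in Z-score matrix", flat.sum())
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def ddct_fold(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); fold = 2^-ddCt.
    """
    cts = [ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control]
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
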