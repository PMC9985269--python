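"""GO-term overlap network: gated nodes, gene-sharing edges, export.

Nodes are GO terms that, in at least one diet contrast, move enough and are
significant enough (|log2FC| ≥ 0.5 and GSR p ≤ 0.1 by default; boundary
values kept).  Two node terms are connected when both contain at least 10
genes, they share at least half of the smaller term's genes, and both pass a
stricter edge gate (|log2FC| ≥ 0.2 and p ≤ 0.05) in at least one common
contrast.  Node fill and border carry the two contrasts' fold changes, as in
a two-ring Cytoscape rendering; the exported GraphML/TSVs are viewer-ready.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass
class GONetworkConfig:
    node_abs_fc_min: float = 0.5
    node_p_max: float = 0.1
    edge_min_genes: int = 10
    edge_share_frac: float = 0.5
    edge_fc_min: float = 0.2
    edge_p_max: float = 0.05
    share_reference: str = "smaller"  # or "either"

    def validate(self) -> None:
        if not 0 < self.edge_share_frac <= 1:
            raise ValueError("edge_share_frac must lie in (0, 1]")
        for name in ("node_abs_fc_min", "node_p_max", "edge_fc_min", "edge_p_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_min_genes < 1:
            raise ValueError("edge_min_genes must be >= 1")
        if self.share_reference not in ("smaller", "either"):
            raise ValueError("share_reference must be 'smaller' or 'either'")


def _passes(fc: float, p: float, fc_min: float, p_max: float) -> bool:
    return abs(fc) >= fc_min and p <= p_max


def select_nodes(results: dict, cfg: GONetworkConfig) -> list:
    """Terms passing the node gate in at least one contrast.

    ``results`` maps contrast name → DataFrame indexed by term with columns
    ``log2FC`` and ``gsr_p``; the contrasts must share a term universe.
    """
    cfg.validate()
    universes = {frozenset(df.index) for df in results.values()}
    if len(universes) != 1:
        raise ValueError("contrast result tables must share a term universe")
    kept = []
    for term in next(iter(results.values())).index:
        for df in results.values():
            if _passes(df.at[term, "log2FC"], df.at[term, "gsr_p"],
                       cfg.node_abs_fc_min, cfg.node_p_max):
                kept.append(term)
                break
    return kept


@dataclass
class GONetwork:
    graph: nx.Graph

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [tuple(sorted(e)) for e in self.graph.edges]


def build_go_edges(
    nodes, ann: dict, results: dict, cfg: GONetworkConfig
) -> GONetwork:
    """Connect node terms by gene sharing.

    Edge (A, B) requires: both terms hold ≥ ``edge_min_genes`` genes; the
    overlap covers ≥ ``edge_share_frac`` of the smaller term (or of either
    term with ``share_reference='either'``); and both endpoints pass the
    edge-level |FC|/p gate in at least one common contrast.
    """
    cfg.validate()
    missing = [t for t in nodes if t not in ann]
    if missing:
        raise ValueError(f"nodes absent from annotation: {missing[:5]}")
    contrasts = list(results)
    g = nx.Graph()
    for term in nodes:
        attrs = {"n_genes": len(ann[term])}
        for i, c in enumerate(contrasts):
            attrs[f"fc_{c}"] = float(results[c].at[term, "log2FC"])
            attrs[f"p_{c}"] = float(results[c].at[term, "gsr_p"])
        # fill = first contrast, border = second, matching the figure styling
        attrs["fill_fc"] = attrs[f"fc_{contrasts[0]}"]
        if len(contrasts) > 1:
            attrs["border_fc"] = attrs[f"fc_{contrasts[1]}"]
        g.add_node(term, **attrs)

    gene_sets = {t: set(ann[t]) for t in nodes}
    for a, b in combinations(nodes, 2):
        sa, sb = gene_sets[a], gene_sets[b]
        if len(sa) < cfg.edge_min_genes or len(sb) < cfg.edge_min_genes:
            continue
        shared = len(sa & sb)
        ref = min(len(sa), len(sb))
        share_ok = shared >= cfg.edge_share_frac * ref
        if cfg.share_reference == "either":
            share_ok = (shared >= cfg.edge_share_frac * len(sa)
                        or shared >= cfg.edge_share_frac * len(sb))
        if not share_ok:
            continue
        common = [
            c for c in contrasts
            if _passes(results[c].at[a, "log2FC"], results[c].at[a, "gsr_p"],
                       cfg.edge_fc_min, cfg.edge_p_max)
            and _passes(results[c].at[b, "log2FC"], results[c].at[b, "gsr_p"],
                        cfg.edge_fc_min, cfg.edge_p_max)
        ]
        if not common:
            continue
        g.add_edge(a, b, shared=shared, share_frac=shared / ref,
                   contrasts=",".join(common))
    return GONetwork(g)


def export_network(net: GONetwork, path, fmt: str = "graphml") -> list:
    """Write the network as GraphML or as Cytoscape-importable TSV pair.

    Returns the list of files written.  The GraphML round-trips exactly
    (numeric attributes included) through :func:`networkx.read_graphml`.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
        return [path]
    if fmt == "tsv":
        edge_rows = [
            {"source": a, "target": b, **net.graph.edges[a, b]}
            for a, b in net.graph.edges
        ]
        node_rows = [{"term": t, **net.graph.nodes[t]} for t in net.graph.nodes]
        edge_path = path.with_suffix(".edges.tsv")
        node_path = path.with_suffix(".nodes.tsv")
        pd.DataFrame(edge_rows, columns=None if edge_rows else ["source", "target"]).to_csv(
            edge_path, sep="\t", index=False)
        pd.DataFrame(node_rows, columns=None if node_rows else ["term"]).to_csv(
            node_path, sep="\t", index=False)
        return [edge_path, node_path]
    raise ValueError("fmt must be 'graphml' or 'tsv'")
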