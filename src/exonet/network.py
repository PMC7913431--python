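"""Confidence-filtered bipartite miRNA-mRNA network assembly and export.

Predicted interactions between the key miRNAs and key mRNAs are filtered
to a minimum confidence class on the ordered scale
low < medium < high < "very high" (default: >= high), deduplicated keeping
the best confidence, and assembled into a strictly bipartite undirected
network.  Degree statistics flag high-connectivity nodes: miRNAs linked
to more than half of the network's mRNAs, and mRNAs at or above a
configurable degree cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import FormatError, InputError
from .screen import normalize_mirna_id, validate_target_table

CONFIDENCE_ORDER = {"low": 0, "medium": 1, "high": 2, "very high": 3}


def _conf_rank(label: str) -> int:
    key = str(label).strip().lower().replace("_", " ")
    if key not in CONFIDENCE_ORDER:
        raise FormatError(f"unknown confidence class {label!r}; "
                          f"expected one of {sorted(CONFIDENCE_ORDER)}")
    return CONFIDENCE_ORDER[key]


def filter_interactions(table: pd.DataFrame, key_mirnas: set[str], key_mrnas: set[str],
                        min_class: str = "high", strip_arm: bool = False,
                        ) -> set[tuple[str, str, str]]:
    """Key x key interactions at or above the minimum confidence class.

    Duplicate (miRNA, mRNA) pairs collapse to their maximum confidence.
    """
    validate_target_table(table)
    if "confidence" not in table.columns:
        raise FormatError("target table is missing required column 'confidence'")
    min_rank = _conf_rank(min_class)
    best: dict[tuple[str, str], str] = {}
    for _, row in table.iterrows():
        mi = normalize_mirna_id(row["mirna"], strip_arm)
        mr = row["mrna"]
        rank = _conf_rank(row["confidence"])
        if mi not in key_mirnas or mr not in key_mrnas:
            continue
        prev = best.get((mi, mr))
        if prev is None or rank > _conf_rank(prev):
            best[(mi, mr)] = str(row["confidence"]).strip().lower().replace("_", " ")
    return {(mi, mr, conf) for (mi, mr), conf in best.items()
            if _conf_rank(conf) >= min_rank}


@dataclass
class BipartiteNetwork:
    """Undirected bipartite network of miRNA and mRNA nodes."""

    mirna_nodes: set[str] = field(default_factory=set)
    mrna_nodes: set[str] = field(default_factory=set)
    edges: set = field(default_factory=set)   # {(mirna, mrna, confidence)}
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    def degree(self, node: str) -> int:
        return int(self.graph.degree(node))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(edges) -> BipartiteNetwork:
    """Assemble the network from (miRNA, mRNA, confidence) triples.

    Node sets are the endpoints of surviving edges, so zero-degree nodes
    never appear.  An identifier used on both sides violates bipartiteness
    and is rejected.
    """
    edges = set(edges)
    mirnas = {e[0] for e in edges}
    mrnas = {e[1] for e in edges}
    overlap = mirnas & mrnas
    if overlap:
        raise InputError(f"identifier(s) used as both miRNA and mRNA: {sorted(overlap)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(mirnas, node_type="mirna")
    g.add_nodes_from(mrnas, node_type="mrna")
    for mi, mr, conf in edges:
        _conf_rank(conf)
        g.add_edge(mi, mr, confidence=conf)
    return BipartiteNetwork(mirna_nodes=mirnas, mrna_nodes=mrnas, edges=edges, graph=g)


def degree_report(net: BipartiteNetwork, mrna_hub_cutoff: int = 3) -> pd.DataFrame:
    """Nodes ranked by degree within each side, with hub flags.

    A miRNA is flagged when it targets strictly more than half of the
    network's mRNAs; an mRNA when its degree >= ``mrna_hub_cutoff``.
    Ties rank lexicographically by node ID for a stable report.
    """
    if not net.edges:
        raise InputError("degree report requires a non-empty network")
    rows = []
    half = len(net.mrna_nodes) / 2.0
    for node in sorted(net.mirna_nodes):
        d = net.degree(node)
        rows.append(("mirna", node, d, d > half))
    for node in sorted(net.mrna_nodes):
        d = net.degree(node)
        rows.append(("mrna", node, d, d >= mrna_hub_cutoff))
    report = pd.DataFrame(rows, columns=["node_type", "node", "degree", "hub_flag"])
    return (report.sort_values(["node_type", "degree", "node"],
                               ascending=[True, False, True])
            .reset_index(drop=True))


def write_sif(net: BipartiteNetwork, path: str | Path) -> None:
    """Cytoscape SIF edge list: ``mirna <TAB> targets <TAB> mrna``."""
    with open(path, "w") as fh:
        for mi, mr, _ in sorted(net.edges):
            fh.write(f"{mi}\ttargets\t{mr}\n")


def read_sif(path: str | Path) -> set[tuple[str, str]]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] != "targets":
                raise FormatError(f"malformed SIF line: {line!r}")
            pairs.add((parts[0], parts[2]))
    return pairs


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def read_graphml(path: str | Path) -> BipartiteNetwork:
    g = nx.read_graphml(str(path))
    edges = set()
    for u, v, data in g.edges(data=True):
        if g.nodes[u].get("node_type") == "mirna":
            mi, mr = u, v
        else:
            mi, mr = v, u
        edges.add((mi, mr, data.get("confidence", "high")))
    return build_network(edges)
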