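"""Build the combined pairwise/mediation network and write Cytoscape files.

Visual vocabulary: OTUs are violet octagons, environmental factors green
rectangles, and each mediated triplet is rendered through a gray triangle hub
connected to X and Y by solid edges (red for a positive, blue for a negative
pair correlation) and to the mediator Z by a wavy edge (red when the
association strengthens at high Z, types A and D; blue when at low Z, types
B and C).  Since plain SIF cannot carry a "wavy" line style, the style is
emitted as edge attributes in the TSV tables and the GraphML file, to be
mapped in Cytoscape.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx

from .data_io import ENVIRONMENT, OTU, FactorClassTable

NODE_STYLE = {
    "otu": ("octagon", "violet"),
    "environment": ("rectangle", "green"),
    "la_hub": ("triangle", "gray"),
}


@dataclass(frozen=True)
class Node:
    node_id: str
    node_kind: str          # otu | environment | la_hub
    label: str


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    edge_kind: str          # ls_edge | la_mediation
    sign: str               # + | -
    weight: float
    line_style: str         # solid | wavy


@dataclass
class AssociationNetwork:
    nodes: list[Node]
    edges: list[Edge]


def hub_id(x_id: str, y_id: str, z_id: str) -> str:
    a, b = sorted((x_id, y_id))
    return f"LA:{a}|{b}|{z_id}"


def _factor_kind(fid: str, classes: FactorClassTable | None) -> str:
    cls = classes.get(fid) if classes is not None else OTU
    return "environment" if cls == ENVIRONMENT else "otu"


def build_network(pairs, triplets, classes: FactorClassTable | None = None) -> AssociationNetwork:
    """Assemble factor nodes, pair edges and one triangle hub per triplet.

    Every hub has degree exactly three: solid edges to X and Y carrying the
    pair's LS sign, and one wavy edge to Z whose sign is "+" for the
    high-Z-enhancing types (A, D) and "-" for the low-Z-enhancing types
    (B, C).  Triplets must refer to screened pairs.
    """
    screened = {frozenset((p.x_id, p.y_id)) for p in pairs}
    nodes: dict[str, Node] = {}
    edges: list[Edge] = []

    def add_factor(fid: str) -> None:
        if fid not in nodes:
            nodes[fid] = Node(fid, _factor_kind(fid, classes), fid)

    for p in pairs:
        add_factor(p.x_id)
        add_factor(p.y_id)
        edges.append(Edge(p.x_id, p.y_id, "ls_edge", p.sign, abs(p.ls), "solid"))

    for t in triplets:
        if frozenset((t.x_id, t.y_id)) not in screened:
            raise ValueError(
                f"triplet ({t.x_id}, {t.y_id}, {t.z_id}) refers to a pair "
                "that was not screened"
            )
        if t.la_type not in ("A", "B", "C", "D"):
            raise ValueError(f"triplet has no valid type: {t.la_type!r}")
        add_factor(t.x_id)
        add_factor(t.y_id)
        add_factor(t.z_id)
        hid = hub_id(t.x_id, t.y_id, t.z_id)
        if hid in nodes:
            raise ValueError(f"duplicate triplet hub {hid!r}")
        nodes[hid] = Node(hid, "la_hub", hid)
        mediation_sign = "+" if t.la_type in ("A", "D") else "-"
        edges.append(Edge(hid, t.x_id, "ls_edge", t.pair_ls_sign, abs(t.la), "solid"))
        edges.append(Edge(hid, t.y_id, "ls_edge", t.pair_ls_sign, abs(t.la), "solid"))
        edges.append(Edge(hid, t.z_id, "la_mediation", mediation_sign, abs(t.la), "wavy"))

    return AssociationNetwork(nodes=list(nodes.values()), edges=edges)


def to_graph(network: AssociationNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in network.nodes:
        shape, color = NODE_STYLE[node.node_kind]
        g.add_node(node.node_id, node_kind=node.node_kind, label=node.label,
                   suggested_shape=shape, suggested_color=color)
    for e in network.edges:
        color = "red" if e.sign == "+" else "blue"
        g.add_edge(e.source, e.target, edge_kind=e.edge_kind, sign=e.sign,
                   weight=float(e.weight), line_style=e.line_style,
                   suggested_color=color)
    return g


def write_cytoscape(network: AssociationNetwork, outdir, sif: bool = False) -> dict[str, str]:
    """Write edge/node attribute TSVs and a GraphML file into ``outdir``.

    Output is byte-deterministic for identical networks.  Returns the paths
    written, keyed by kind.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "edges": os.path.join(outdir, "edges.tsv"),
        "nodes": os.path.join(outdir, "nodes.tsv"),
        "graphml": os.path.join(outdir, "network.graphml"),
    }
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinteraction\tsign\tweight\tline_style\n")
        for e in network.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.edge_kind}\t{e.sign}"
                     f"\t{e.weight:.6g}\t{e.line_style}\n")
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        fh.write("node_id\tnode_kind\tsuggested_shape\tsuggested_color\n")
        for node in network.nodes:
            shape, color = NODE_STYLE[node.node_kind]
            fh.write(f"{node.node_id}\t{node.node_kind}\t{shape}\t{color}\n")
    g = to_graph(network)
    nx.write_graphml_xml(g, paths["graphml"])
    if sif:
        paths["sif"] = os.path.join(outdir, "network.sif")
        with open(paths["sif"], "w", encoding="utf-8") as fh:
            for e in network.edges:
                fh.write(f"{e.source}\t{e.edge_kind}\t{e.target}\n")
    return paths
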