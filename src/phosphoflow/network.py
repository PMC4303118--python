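"""Provenance-annotated interaction networks over class-specific proteins.

Mouse edges apply directly; human edges are translated through a mouse-human
orthologue map before inducing the subgraph on the protein set.  An edge
supported by both sources gets provenance "both".  Kinase->substrate edges
are kept as a directed overlay and by default do not count toward hub
degree.  Node identity is the case-folded gene symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .tables_io import EdgeRecord

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass
class OrthologueMap:
    """Case-insensitive mouse -> human symbol map with an unmapped ledger."""

    mapping: dict[str, str]  # upper-cased mouse -> upper-cased human

    @classmethod
    def from_table(cls, table: Mapping[str, str]) -> "OrthologueMap":
        up: dict[str, str] = {}
        for m, h in table.items():
            mu, hu = m.upper(), h.upper()
            if mu in up and up[mu] != hu:
                raise NetworkError(f"mouse gene {m!r} maps to multiple human genes")
            up[mu] = hu
        return cls(up)

    def lookup(self, mouse_gene: str) -> str | None:
        return self.mapping.get(mouse_gene.upper())

    def reverse(self) -> dict[str, str]:
        rev: dict[str, str] = {}
        for m, h in self.mapping.items():
            rev.setdefault(h, m)
        return rev


def map_orthologues(
    mouse_genes: Iterable[str], table: Mapping[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Map mouse symbols through the orthologue table.

    Returns (mapped mouse->human pairs, unmapped mouse genes).  Unmapped
    genes are reported, never silently dropped.
    """
    omap = OrthologueMap.from_table(table)
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for g in mouse_genes:
        h = omap.lookup(g)
        if h is None:
            unmapped.append(g)
        else:
            mapped[g] = h
    if unmapped:
        logger.info("map_orthologues: %d unmapped gene(s): %s",
                    len(unmapped), unmapped[:10])
    return mapped, unmapped


@dataclass
class AnnotatedNetwork:
    """Undirected provenance-annotated graph plus a directed kinase overlay."""

    graph: nx.Graph
    kinase_edges: nx.DiGraph
    unmapped: list[str] = field(default_factory=list)

    def degree_of(self, node: str, include_kinase_edges: bool = False) -> int:
        d = self.graph.degree(node) if node in self.graph else 0
        if include_kinase_edges and node in self.kinase_edges:
            d += self.kinase_edges.degree(node)
        return d

    def provenance_counts(self) -> dict[str, int]:
        counts = {"mouse": 0, "human": 0, "both": 0}
        for _, _, data in self.graph.edges(data=True):
            counts[data["provenance"]] += 1
        return counts


def build_network(
    proteins: Iterable[str],
    mouse_edges: Sequence[EdgeRecord],
    human_edges: Sequence[EdgeRecord],
    orthologues: Mapping[str, str] | None = None,
    kinase_substrate_edges: Sequence[EdgeRecord] = (),
    node_attrs: Mapping[str, Mapping] | None = None,
) -> AnnotatedNetwork:
    """Induce the annotated interaction subgraph on ``proteins``.

    Human edges only contribute where both endpoints back-map into the
    protein set through the orthologue table; without a table the human
    evidence is unusable and provenance reduces to {mouse}.
    """
    nodes = {p.upper() for p in proteins}
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))

    def canon(a: str, b: str) -> tuple[str, str] | None:
        a, b = a.upper(), b.upper()
        if a in nodes and b in nodes and a != b:
            return tuple(sorted((a, b)))
        return None

    mouse_pairs = set()
    for e in mouse_edges:
        pair = canon(e.node_a, e.node_b)
        if pair:
            mouse_pairs.add(pair)

    human_pairs = set()
    unmapped: list[str] = []
    if orthologues is not None:
        omap = OrthologueMap.from_table(orthologues)
        rev = omap.reverse()
        # translate node set to human symbols for matching human evidence
        node_to_human = {}
        for nd in nodes:
            h = omap.lookup(nd)
            if h is None:
                unmapped.append(nd)
            else:
                node_to_human[nd] = h
        human_of = {h: m for m, h in node_to_human.items()}
        for e in human_edges:
            a, b = e.node_a.upper(), e.node_b.upper()
            if a in human_of and b in human_of and a != b:
                human_pairs.add(tuple(sorted((human_of[a], human_of[b]))))

    for pair in sorted(mouse_pairs | human_pairs):
        if pair in mouse_pairs and pair in human_pairs:
            prov = "both"
        elif pair in mouse_pairs:
            prov = "mouse"
        else:
            prov = "human"
        g.add_edge(*pair, provenance=prov)

    kg = nx.DiGraph()
    kg.add_nodes_from(sorted(nodes))
    for e in kinase_substrate_edges:
        a, b = e.node_a.upper(), e.node_b.upper()
        if a in nodes and b in nodes and a != b:
            kg.add_edge(a, b)

    if node_attrs:
        for nd, attrs in node_attrs.items():
            ndu = nd.upper()
            if ndu in g:
                g.nodes[ndu].update(attrs)

    logger.info(
        "build_network: %d nodes, %d undirected edges (%s), %d kinase edges",
        g.number_of_nodes(), g.number_of_edges(),
        AnnotatedNetwork(g, kg).provenance_counts(), kg.number_of_edges(),
    )
    return AnnotatedNetwork(graph=g, kinase_edges=kg, unmapped=unmapped)


def rank_hubs(
    network: AnnotatedNetwork, top_n: int | None = None,
    include_kinase_edges: bool = False,
) -> list[tuple[str, int]]:
    """Nodes ordered by degree descending, then node id ascending."""
    ranked = sorted(
        (
            (nd, network.degree_of(nd, include_kinase_edges))
            for nd in network.graph.nodes
        ),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:top_n] if top_n is not None else ranked


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_edge_list(network: AnnotatedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tprovenance\tdirected\n")
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['provenance']}\tfalse\n")
        for a, b in sorted(network.kinase_edges.edges):
            fh.write(f"{a}\t{b}\tkinase_substrate\ttrue\n")


def write_graphml(network: AnnotatedNetwork, path: str | Path) -> None:
    merged = nx.MultiDiGraph()
    for nd, data in network.graph.nodes(data=True):
        merged.add_node(nd, **data)
    for a, b, data in network.graph.edges(data=True):
        merged.add_edge(a, b, provenance=data["provenance"], directed="false")
    for a, b in network.kinase_edges.edges:
        merged.add_edge(a, b, provenance="kinase_substrate", directed="true")
    nx.write_graphml(merged, path)
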