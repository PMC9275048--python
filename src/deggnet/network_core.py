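"""Curated gene-gene interaction networks and repository merging.

The curated network is an undirected simple graph over gene symbols.  Each
edge carries a *provenance* set recording which source repositories reported
the interaction (e.g. a pathway database, a microRNA-target table, a
transcription-factor target list).  Directed source relations are stored
undirected because the downstream edge statistics treat the pair
symmetrically up to a fixed orientation convention.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING, Iterable, Iterator

import networkx as nx

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in lexicographic order."""
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """Undirected simple graph of curated gene-gene interactions.

    Invariants: no self-loops; every edge endpoint is a node; edges are
    reported in canonical (lexicographic) order; every edge has a non-empty
    provenance set of repository tags.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "InteractionNetwork":
        """Build from (gene_a, provenance_tag, gene_b) records.

        Self-loops are dropped (count logged); parallel records for the same
        unordered pair merge their provenance tags.
        """
        net = cls()
        n_loops = 0
        for a, tag, b in records:
            a, b = a.upper(), b.upper()
            if a == b:
                n_loops += 1
                continue
            net.add_edge(a, b, {tag})
        if n_loops:
            logger.warning("dropped %d self-loop interaction(s)", n_loops)
        return net

    def add_edge(self, a: str, b: str, provenance: set[str]) -> None:
        if a == b:
            raise ValidationError(f"self-loop on gene {a!r} not permitted")
        u, v = canonical_edge(a, b)
        if self.graph.has_edge(u, v):
            self.graph.edges[u, v]["provenance"] |= set(provenance)
        else:
            self.graph.add_edge(u, v, provenance=set(provenance))

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    def provenance(self, edge: Edge) -> set[str]:
        u, v = canonical_edge(*edge)
        return set(self.graph.edges[u, v]["provenance"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(self.provenance(e) == other.provenance(e) for e in self.edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self.edges))

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())


def merge_networks(networks: list[InteractionNetwork]) -> InteractionNetwork:
    """Union of node and edge sets; provenance sets merged per edge.

    Idempotent: ``merge_networks([n, n]) == n``.
    """
    if not networks:
        raise ValidationError("merge_networks requires at least one network")
    merged = InteractionNetwork()
    for net in networks:
        for gene in net.nodes:
            merged.add_node(gene)
        for edge in net.edges:
            merged.add_edge(*edge, net.provenance(edge))
    return merged


def restrict_to_measured(network: InteractionNetwork, expr: "ExpressionMatrix") -> InteractionNetwork:
    """Drop nodes (and incident edges) whose gene is absent from the matrix."""
    measured = set(expr.gene_ids)
    keep = network.nodes & measured
    dropped_nodes = network.n_nodes - len(keep)
    sub = InteractionNetwork(nx.Graph(network.graph.subgraph(keep)))
    dropped_edges = network.n_edges - sub.n_edges
    if dropped_nodes:
        logger.info(
            "restrict_to_measured: dropped %d node(s) and %d edge(s) not in the expression matrix",
            dropped_nodes,
            dropped_edges,
        )
    if sub.n_nodes == 0:
        logger.warning("restrict_to_measured: no network gene is measured; empty network")
    return sub
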