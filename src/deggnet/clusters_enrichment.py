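"""Community detection on specific networks and gene-set enrichment.

Clusters are greedy modularity-maximization communities (deterministic for
a fixed, lexicographic node order).  Enrichment of a cluster in a gene set
is summarized two ways: the *coverage percentage* 100 * |cluster & term| /
|cluster| rounded half-up to one decimal (the headline number reported per
cluster), and an upper-tail hypergeometric p-value against the gene
universe, BH-adjusted across terms within the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
from scipy.stats import hypergeom

from .diff_interaction import adjust_bh
from .exceptions import ValidationError
from .io_formats import GeneSetCollection
from .subgroup_networks import SpecificNetwork

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ClusterEnrichment:
    """Enrichment of one cluster in one gene set."""

    cluster_id: str
    cluster_genes: list[str]
    term: str
    n_in_term: int
    cluster_size: int
    percentage: float
    p_hyper: float
    p_adj: float

    def as_record(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "genes": ";".join(self.cluster_genes),
            "term": self.term,
            "n_in_term": self.n_in_term,
            "cluster_size": self.cluster_size,
            "percentage": self.percentage,
            "p_hyper": self.p_hyper,
            "p_adj": self.p_adj,
        }


def coverage_percentage(n_in_term: int, cluster_size: int) -> float:
    """100 * n_in_term / cluster_size, rounded half-up to one decimal."""
    if not 0 <= n_in_term <= cluster_size:
        raise ValidationError("need 0 <= n_in_term <= cluster_size")
    frac = Decimal(100 * n_in_term) / Decimal(cluster_size)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def detect_clusters(
    network: SpecificNetwork, min_size: int = 3
) -> list[tuple[str, list[str]]]:
    """Greedy-modularity communities of a specific network.

    Deterministic for a fixed graph: nodes and edges are inserted in
    canonical lexicographic order before clustering.  Communities smaller
    than ``min_size`` are pooled into a single ``unassigned`` bucket.
    Cluster ids C1, C2, ... are assigned by decreasing size, ties broken by
    the lexicographically first member gene.
    """
    if network.network.n_edges == 0:
        raise ValidationError("detect_clusters on an empty network")
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes))
    g.add_edges_from(sorted(network.edges))
    communities = nx.community.greedy_modularity_communities(g)
    kept, unassigned = [], []
    for comm in communities:
        genes = sorted(comm)
        if len(genes) >= min_size:
            kept.append(genes)
        else:
            unassigned.extend(genes)
    kept.sort(key=lambda genes: (-len(genes), genes[0]))
    out = [(f"C{i + 1}", genes) for i, genes in enumerate(kept)]
    if unassigned:
        out.append((UNASSIGNED, sorted(unassigned)))
    return out


def enrich(
    cluster_genes: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> list[ClusterEnrichment]:
    """Hypergeometric enrichment of one cluster against every gene set.

    For a universe of N genes, a term covering K of them and a cluster of
    size n containing k term genes, ``p_hyper`` is the upper-tail
    probability P(X >= k) for X ~ Hypergeom(N, K, n).  Terms with no
    universe overlap are skipped; BH adjustment runs across the tested
    terms.  Results are sorted by raw p, so the first entry is the
    cluster's label term.
    """
    universe_set = set(g.upper() for g in universe)
    if not universe_set:
        raise ValidationError("empty gene universe")
    cluster = [g.upper() for g in cluster_genes]
    outside = set(cluster) - universe_set
    if outside:
        raise ValidationError(f"cluster gene(s) outside the universe: {sorted(outside)[:5]}")
    n = len(cluster)
    N = len(universe_set)
    out = []
    for term in sets.terms():
        term_genes = set(sets.genes(term)) & universe_set
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(set(cluster) & term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        out.append(
            ClusterEnrichment(
                cluster_id="",
                cluster_genes=list(cluster),
                term=term,
                n_in_term=k,
                cluster_size=n,
                percentage=coverage_percentage(k, n),
                p_hyper=min(p, 1.0),
                p_adj=float("nan"),
            )
        )
    if out:
        adj = adjust_bh([e.p_hyper for e in out])
        for e, q in zip(out, adj):
            e.p_adj = float(q)
    out.sort(key=lambda e: (e.p_hyper, e.term))
    return out


def enrich_clusters(
    clusters: list[tuple[str, list[str]]],
    sets: GeneSetCollection,
    universe: list[str],
) -> list[ClusterEnrichment]:
    """Enrichment for every detected cluster (unassigned bucket skipped)."""
    out = []
    for cluster_id, genes in clusters:
        if cluster_id == UNASSIGNED:
            continue
        for e in enrich(genes, sets, universe):
            e.cluster_id = cluster_id
            out.append(e)
    return out
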