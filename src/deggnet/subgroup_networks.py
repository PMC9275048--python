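"""Subgroup node weighting, percolation thresholding and specific edge sets.

The curated network is replicated once per sample subgroup and every node is
weighted by the gene's mean log-expression over that subgroup's samples.
Low-weight nodes are then removed: the removal threshold is a percentile of
the subgroup's node-weight distribution, and a percolation scan over a
percentile grid tracks how the giant connected component (GCC) shrinks and
fragments as the threshold rises, locating the fragmentation transition.
Finally, edges present in two or more filtered subgroup networks are
discarded, leaving pairwise-disjoint subgroup-specific edge sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .io_formats import ExpressionMatrix, SampleAnnotation
from .network_core import Edge, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 75.0
DEFAULT_GRID = tuple(float(p) for p in range(0, 100, 5))


@dataclass
class WeightedSubgroupNetwork:
    """A curated network with per-node mean log-expression weights for one subgroup."""

    subgroup: str
    network: InteractionNetwork
    node_weight: dict[str, float]

    def __post_init__(self) -> None:
        missing = self.network.nodes - set(self.node_weight)
        if missing:
            raise ValidationError(f"no weight for node(s): {sorted(missing)[:5]}")
        bad = [g for g, w in self.node_weight.items() if not np.isfinite(w)]
        if bad:
            raise ValidationError(f"non-finite weight for node(s): {bad[:5]}")


@dataclass
class PercolationProfile:
    """Connectivity of the weight-filtered network along a percentile grid.

    ``gcc_fraction`` is giant-component size over retained nodes (the
    percolation order parameter); ``second_component_size`` peaks near the
    fragmentation transition and is reported as a diagnostic.
    """

    subgroup: str
    percentile_grid: list[float]
    threshold_values: list[float]
    nodes_retained: list[int]
    gcc_fraction: list[float]
    second_component_size: list[int]
    selected_percentile: float
    transition_percentile: float = field(default=float("nan"))


@dataclass
class SpecificNetwork:
    """Edges unique to one subgroup after weight filtering and overlap removal."""

    subgroup: str
    network: InteractionNetwork

    @property
    def edges(self) -> set[Edge]:
        return self.network.edges

    @property
    def nodes(self) -> set[str]:
        return self.network.nodes


def compute_weights(
    expr: ExpressionMatrix,
    annot: SampleAnnotation,
    network: InteractionNetwork,
) -> list[WeightedSubgroupNetwork]:
    """One weighted copy of ``network`` per subgroup.

    weight(gene, subgroup) = arithmetic mean of the gene's log-expression
    over the subgroup's samples.  Every subgroup needs >= 2 samples.
    """
    genes = sorted(network.nodes)
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(
            f"network gene(s) not measured: {missing[:5]}; restrict the network first"
        )
    out = []
    for label in annot.subgroup_levels:
        samples = annot.samples_in_subgroup(label)
        if len(samples) < 2:
            raise ValidationError(f"subgroup {label!r} has {len(samples)} sample(s); need >= 2")
        sub = expr.frame.loc[genes, samples]
        weights = dict(zip(genes, sub.mean(axis=1).to_numpy(dtype=float)))
        out.append(WeightedSubgroupNetwork(label, network.copy(), weights))
    return out


def _component_sizes(graph: nx.Graph) -> list[int]:
    return sorted((len(c) for c in nx.connected_components(graph)), reverse=True)


def _threshold_subgraph(wnet: WeightedSubgroupNetwork, percentile: float) -> nx.Graph:
    """Induced subgraph on nodes with weight >= the percentile threshold.

    The threshold is the linear-interpolation percentile of all node weights;
    nodes strictly below it are removed, so ties at the threshold survive.
    """
    weights = np.array([wnet.node_weight[g] for g in wnet.network.nodes])
    thr = float(np.percentile(weights, percentile, method="linear"))
    keep = [g for g in wnet.network.nodes if wnet.node_weight[g] >= thr]
    return nx.Graph(wnet.network.graph.subgraph(keep))


def percolation_scan(
    wnet: WeightedSubgroupNetwork,
    percentile_grid: tuple[float, ...] = DEFAULT_GRID,
    gcc_fraction_min: float = 0.5,
) -> PercolationProfile:
    """Scan weight-removal percentiles and track giant-component collapse.

    ``selected_percentile`` is the largest grid value whose retained network
    keeps a giant component of at least ``gcc_fraction_min`` of retained
    nodes (falls back to the smallest grid value if none qualifies).  The
    argmax of the second-largest component size is reported separately as
    the percolation-transition diagnostic.
    """
    grid = [float(p) for p in percentile_grid]
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("percentile grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] >= 100:
        raise ValidationError("percentile grid values must lie in [0, 100)")
    if wnet.network.n_nodes == 0:
        raise ValidationError("percolation_scan on an empty network")

    weights = np.array([wnet.node_weight[g] for g in wnet.network.nodes])
    thresholds, retained, gcc_frac, second = [], [], [], []
    for p in grid:
        thresholds.append(float(np.percentile(weights, p, method="linear")))
        sub = _threshold_subgraph(wnet, p)
        n = sub.number_of_nodes()
        retained.append(n)
        sizes = _component_sizes(sub)
        gcc_frac.append(sizes[0] / n if n else 0.0)
        second.append(sizes[1] if len(sizes) > 1 else 0)

    eligible = [p for p, f in zip(grid, gcc_frac) if f >= gcc_fraction_min]
    selected = max(eligible) if eligible else grid[0]
    transition = grid[int(np.argmax(second))]
    return PercolationProfile(
        subgroup=wnet.subgroup,
        percentile_grid=grid,
        threshold_values=thresholds,
        nodes_retained=retained,
        gcc_fraction=gcc_frac,
        second_component_size=second,
        selected_percentile=selected,
        transition_percentile=transition,
    )


def filter_by_weight(wnet: WeightedSubgroupNetwork, percentile: float) -> InteractionNetwork:
    """Remove nodes below the percentile threshold; drop isolated nodes."""
    if not 0 <= percentile < 100:
        raise ValidationError("percentile must lie in [0, 100)")
    sub = _threshold_subgraph(wnet, percentile)
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return InteractionNetwork(sub)


def extract_specific(filtered: dict[str, InteractionNetwork]) -> list[SpecificNetwork]:
    """Keep each edge only if it appears in exactly one subgroup's network.

    Edges present in two or more filtered networks are discarded from all,
    so the resulting subgroup-specific edge sets are pairwise disjoint.
    """
    if len(filtered) < 2:
        raise ValidationError("extract_specific requires >= 2 subgroups")
    membership: dict[Edge, list[str]] = {}
    for label, net in filtered.items():
        for edge in net.edges:
            membership.setdefault(edge, []).append(label)
    out = []
    for label, net in filtered.items():
        specific = InteractionNetwork()
        for edge in net.edges:
            if len(membership[edge]) == 1:
                specific.add_edge(*edge, net.provenance(edge))
        out.append(SpecificNetwork(label, specific))
    n_discarded = sum(1 for owners in membership.values() if len(owners) > 1)
    logger.info(
        "extract_specific: %d overlapping edge(s) discarded across %d subgroups",
        n_discarded,
        len(filtered),
    )
    return out
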