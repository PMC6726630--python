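"""Cross-method consensus and filtering of detected cluster sets.

Consensus integration builds a k-partite graph (one part per detection
method; one node per cluster) with an edge between clusters of different
methods whenever their Jaccard index exceeds the overlap threshold phi.
Every maximal clique strictly larger than the cutoff psi represents a group
of clusters reported — with some alterations — by several methods; the
integrated cluster set is the per-clique union or intersection. Defaults
are phi = 0.5 and psi = k/2. With phi = 1 only identical clusters are
linked, so union and intersection coincide.

Three result filters mirror the options a benchmark front end offers: a
size window, a query-protein filter, and a reliability filter keeping
clusters detected (up to Jaccard > phi) by at least beta methods.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx

from .overlap import ClusterSet, jcc_score

__all__ = [
    "IntegrationConfig",
    "ReliabilityConfig",
    "build_kpartite",
    "enumerate_consensus_cliques",
    "integrate",
    "filter_size",
    "filter_protein",
    "filter_reliability",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Consensus parameters.

    ``phi`` is the strict Jaccard threshold for linking clusters of
    different methods; ``psi`` the strict minimum clique size (``None``
    means the default k/2); ``mode`` selects union or intersection of each
    clique's member clusters.
    """

    phi: float = 0.5
    psi: float | None = None
    mode: str = "union"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.mode not in ("union", "intersection"):
            raise ValueError(f"mode must be 'union' or 'intersection', got {self.mode!r}")


@dataclass(frozen=True)
class ReliabilityConfig:
    """Reliability-filter parameters: minimum method count ``beta`` and the
    Jaccard threshold ``phi`` reused for "same cluster" identification."""

    beta: int = 1
    phi: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")


def build_kpartite(cluster_sets: list[ClusterSet], phi: float) -> nx.Graph:
    """Build the k-partite consensus graph.

    Nodes are ``(part index, cluster index)``; an edge links clusters of
    different methods whose Jaccard index is strictly greater than ``phi``,
    so ``phi = 1`` links only identical clusters. Never creates intra-part
    edges, hence every clique has at most one node per part.
    """
    if len(cluster_sets) < 2:
        raise ValueError("integration needs >= 2 methods")
    graph = nx.Graph()
    for part, cs in enumerate(cluster_sets):
        for idx, cluster in enumerate(cs.clusters):
            graph.add_node((part, idx), cluster=cluster, method=cs.name)
    for pa, ca in enumerate(cluster_sets):
        for pb in range(pa + 1, len(cluster_sets)):
            cb = cluster_sets[pb]
            for ia, A in enumerate(ca.clusters):
                for ib, B in enumerate(cb.clusters):
                    # strict "> phi", except identical clusters (JCC = 1) are
                    # always linked so that phi = 1 selects exact consensus
                    s = jcc_score(A, B)
                    if s > phi or s == 1.0:
                        graph.add_edge((pa, ia), (pb, ib))
    return graph


def enumerate_consensus_cliques(graph: nx.Graph, psi: float) -> list[tuple]:
    """All maximal cliques of the k-partite graph with size strictly > ``psi``.

    Output order is deterministic: cliques sorted by their sorted member
    node lists.
    """
    cliques = [
        tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) > psi
    ]
    return sorted(cliques)


def integrate(
    cluster_sets: list[ClusterSet], config: IntegrationConfig | None = None
) -> ClusterSet:
    """Consensus cluster set across k methods.

    Each surviving clique contributes the union (``mode='union'``) or
    intersection (``mode='intersection'``) of its member clusters.
    Exact-duplicate integrated clusters collapse to one; empty
    intersections are dropped.
    """
    config = config or IntegrationConfig()
    k = len(cluster_sets)
    psi = config.psi if config.psi is not None else k / 2.0
    graph = build_kpartite(cluster_sets, config.phi)
    merged: list[frozenset] = []
    seen: set[frozenset] = set()
    for clique in enumerate_consensus_cliques(graph, psi):
        members = [graph.nodes[node]["cluster"] for node in clique]
        if config.mode == "union":
            combined = frozenset().union(*members)
        else:
            combined = frozenset.intersection(*members)
        if combined and combined not in seen:
            seen.add(combined)
            merged.append(combined)
    name = f"integration({config.mode},phi={config.phi:g},psi={psi:g})"
    return ClusterSet(name=name, clusters=merged)


def filter_size(clusters: ClusterSet, min_size: int, max_size: int) -> ClusterSet:
    """Keep clusters with ``min_size <= |C| <= max_size``; order preserved."""
    if not 1 <= min_size <= max_size:
        raise ValueError(
            f"need 1 <= min_size <= max_size, got {min_size}..{max_size}"
        )
    kept = [c for c in clusters.clusters if min_size <= len(c) <= max_size]
    return ClusterSet(name=clusters.name, clusters=kept)


def filter_protein(
    cluster_sets: list[ClusterSet], protein: str
) -> dict[str, list[frozenset]]:
    """Per method, the clusters containing ``protein`` (exact string match).

    An absent protein yields empty lists, not an error.
    """
    return {
        cs.name: [c for c in cs.clusters if protein in c] for cs in cluster_sets
    }


def filter_reliability(
    target: ClusterSet,
    panel: list[ClusterSet],
    config: ReliabilityConfig | None = None,
) -> ClusterSet:
    """Keep target clusters detected by at least ``beta`` methods.

    A method "detects" cluster ``c`` if it holds some cluster with
    ``JCC(c, c') > phi``; the target method itself is counted (for
    ``phi < 1`` a cluster always matches itself), so ``beta = 1`` is the
    identity. ``beta`` larger than the number of methods yields an empty
    result with a warning.
    """
    config = config or ReliabilityConfig()
    n_methods = len(panel) + 1
    if config.beta > n_methods:
        warnings.warn(
            f"beta={config.beta} exceeds the {n_methods} supplied methods; "
            "result is empty",
            stacklevel=2,
        )
        return ClusterSet(name=target.name, clusters=[])
    methods = [target] + list(panel)
    kept = []
    for c in target.clusters:
        count = sum(
            any(jcc_score(c, other) > config.phi for other in method.clusters)
            for method in methods
        )
        if count >= config.beta:
            kept.append(c)
    return ClusterSet(name=target.name, clusters=kept)
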