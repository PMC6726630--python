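"""Reading and writing cluster-set, gold-standard and weighted edge-list files.

The canonical on-disk format is the de-facto standard of MCL / ClusterONE
outputs: plain text, one cluster per line, whitespace-separated protein IDs,
``#`` comment lines. Protein IDs are opaque case-sensitive strings.

Weighted protein-protein interaction networks (PPINs) are three-column
whitespace-separated edge lists ``idA idB weight``; self-interactions are
dropped and the undirected edge ``(a, b)`` is kept once (first occurrence
wins), so a loaded network never contains a self-edge or an isolated protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

from .overlap import ClusterSet, GoldStandard

__all__ = [
    "ClusterFileDialect",
    "PPINetwork",
    "ClusterFileError",
    "read_cluster_set",
    "read_gold_standard",
    "write_cluster_set",
    "read_weighted_edgelist",
    "write_weighted_edgelist",
]


class ClusterFileError(ValueError):
    """Malformed or empty cluster/edge-list input."""


@dataclass(frozen=True)
class ClusterFileDialect:
    """Parsing rules for cluster files.

    ``field_separator=None`` means "any run of whitespace" (``str.split``
    semantics). Duplicate IDs within a line collapse to one set member;
    comment and blank lines are skipped. Clusters smaller than
    ``min_cluster_size_on_read`` are dropped on read (default 1: no silent
    filtering).
    """

    comment_prefix: str = "#"
    min_cluster_size_on_read: int = 1

    def __post_init__(self) -> None:
        if self.min_cluster_size_on_read < 1:
            raise ValueError("min_cluster_size_on_read must be >= 1")


DEFAULT_DIALECT = ClusterFileDialect()


def _parse_cluster_lines(
    source: IO[str] | Iterable[str], dialect: ClusterFileDialect
) -> list[frozenset]:
    clusters = []
    for line in source:
        line = line.strip()
        if not line or line.startswith(dialect.comment_prefix):
            continue
        members = frozenset(line.split())
        if len(members) >= dialect.min_cluster_size_on_read:
            clusters.append(members)
    return clusters


def read_cluster_set(
    source: IO[str] | Iterable[str],
    dialect: ClusterFileDialect = DEFAULT_DIALECT,
    name: str = "clusters",
) -> ClusterSet:
    """Read a detected-cluster file: one cluster per non-comment line.

    Original line order is preserved as cluster indices.

    Raises
    ------
    ClusterFileError
        If no clusters remain after filtering.
    """
    clusters = _parse_cluster_lines(source, dialect)
    if not clusters:
        raise ClusterFileError(f"no clusters in input for {name!r}")
    return ClusterSet(name=name, clusters=clusters)


def read_gold_standard(
    source: IO[str] | Iterable[str],
    dialect: ClusterFileDialect = DEFAULT_DIALECT,
    name: str = "gold",
) -> GoldStandard:
    """Read a gold-standard complex file (same dialect as cluster files)."""
    complexes = _parse_cluster_lines(source, dialect)
    if not complexes:
        raise ClusterFileError(f"no complexes in input for {name!r}")
    return GoldStandard(name=name, complexes=complexes)


def write_cluster_set(clusters: ClusterSet | GoldStandard, sink: IO[str]) -> None:
    """Write clusters one per line, members in lexicographic order.

    ``read(write(X))`` has the same clusters as ``X`` (as sets, same order).
    """
    groups = clusters.clusters if isinstance(clusters, ClusterSet) else clusters.complexes
    for group in groups:
        sink.write(" ".join(sorted(group)) + "\n")


@dataclass
class PPINetwork:
    """A weighted, undirected protein-protein interaction network.

    ``edges`` holds ``(idA, idB, weight)`` triples with ``idA != idB`` and
    positive weights; ``proteins`` contains exactly the edge endpoints, so
    there are no isolated proteins.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def proteins(self) -> frozenset:
        return frozenset(p for a, b, _ in self.edges for p in (a, b))


def read_weighted_edgelist(source: IO[str] | Iterable[str]) -> PPINetwork:
    """Read a three-column ``idA idB weight`` edge list.

    Self-interactions are dropped; duplicate undirected edges keep the first
    occurrence; non-positive weights are rejected with their line number.

    Raises
    ------
    ClusterFileError
        On a malformed or non-positive-weight line (message carries the
        1-based line number).
    """
    edges: list[tuple[str, str, float]] = []
    seen: set[frozenset] = set()
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ClusterFileError(
                f"line {lineno}: expected 'idA idB weight', got {len(parts)} fields"
            )
        a, b, wtext = parts
        try:
            w = float(wtext)
        except ValueError:
            raise ClusterFileError(
                f"line {lineno}: non-numeric weight {wtext!r}"
            ) from None
        if not w > 0:
            raise ClusterFileError(f"line {lineno}: weight must be positive, got {w}")
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((a, b, w))
    return PPINetwork(edges=edges)


def write_weighted_edgelist(network: PPINetwork, sink: IO[str]) -> None:
    """Write the edge list in the three-column format read by this module."""
    for a, b, w in network.edges:
        sink.write(f"{a} {b} {w:g}\n")
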