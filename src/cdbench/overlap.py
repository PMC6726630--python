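"""Bipartite overlap model between gold-standard complexes and detected clusters.

A complex-detection benchmark compares a set of detected clusters (protein-ID
sets output by some algorithm) with a gold standard of curated reference
complexes. All criteria in this package are functions of the bipartite
overlap structure: the intersection counts ``t[i, j] = |P_i & C_j|`` between
reference complex ``P_i`` and detected cluster ``C_j``, together with two
pairwise similarity scores,

* the neighborhood affinity score ``NA(P, C) = |P & C|^2 / (|P| |C|)``, and
* the Jaccard index ``JCC(P, C) = |P & C| / |P | C|``.

:class:`OverlapTable` precomputes all three matrices in one pass so that
every downstream criterion works from identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterSet",
    "GoldStandard",
    "OverlapTable",
    "EmptyEvaluationError",
    "na_score",
    "jcc_score",
    "build_overlap",
]


class EmptyEvaluationError(ValueError):
    """Raised when an evaluation is requested on an empty collection."""


def _check_sets(groups, kind: str) -> list[frozenset]:
    out = []
    for g in groups:
        fs = frozenset(g)
        if not fs:
            raise ValueError(f"empty {kind} is not allowed")
        out.append(fs)
    return out


@dataclass
class ClusterSet:
    """An ordered collection of detected clusters attributed to one method.

    Parameters
    ----------
    name
        Label of the detection method that produced the clusters.
    clusters
        Ordered list of protein-ID sets; every cluster must be non-empty.
    """

    name: str
    clusters: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.clusters = _check_sets(self.clusters, "cluster")

    @property
    def m(self) -> int:
        """Number of clusters."""
        return len(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def proteins(self) -> frozenset:
        """Union of all member proteins."""
        return frozenset().union(*self.clusters) if self.clusters else frozenset()


@dataclass
class GoldStandard:
    """A collection of reference complexes; overlap between complexes is allowed."""

    name: str
    complexes: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = _check_sets(self.complexes, "complex")

    @property
    def n(self) -> int:
        """Number of reference complexes."""
        return len(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def proteins(self) -> frozenset:
        return frozenset().union(*self.complexes) if self.complexes else frozenset()


def na_score(P: frozenset | set, C: frozenset | set) -> float:
    """Neighborhood affinity score ``|P & C|^2 / (|P| |C|)``.

    Symmetric, in ``[0, 1]``; equals 1 iff ``P == C`` and 0 iff the sets are
    disjoint.

    Raises
    ------
    ValueError
        If either set is empty.
    """
    if not P or not C:
        raise ValueError("neighborhood affinity is undefined for empty sets")
    inter = len(set(P) & set(C))
    return inter * inter / (len(P) * len(C))


def jcc_score(P: frozenset | set, C: frozenset | set) -> float:
    """Jaccard index ``|P & C| / |P | C|``.

    Symmetric, in ``[0, 1]``; equals 1 iff ``P == C`` and 0 iff disjoint.

    Raises
    ------
    ValueError
        If either set is empty.
    """
    if not P or not C:
        raise ValueError("Jaccard index is undefined for empty sets")
    P, C = set(P), set(C)
    return len(P & C) / len(P | C)


@dataclass
class OverlapTable:
    """Complex-by-cluster overlap model.

    Attributes
    ----------
    t
        ``(n, m)`` integer matrix of intersection counts ``|P_i & C_j|``.
    n_sizes
        Reference complex sizes ``n_i``.
    m_sizes
        Detected cluster sizes ``m_j``.
    na
        ``(n, m)`` matrix of neighborhood affinity scores.
    jcc
        ``(n, m)`` matrix of Jaccard indices.
    """

    t: np.ndarray
    n_sizes: np.ndarray
    m_sizes: np.ndarray
    na: np.ndarray
    jcc: np.ndarray
    gold_name: str = ""
    cluster_name: str = ""

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def m(self) -> int:
        return self.t.shape[1]


def build_overlap(gold: GoldStandard, clusters: ClusterSet) -> OverlapTable:
    """Compute the full overlap table between a gold standard and a cluster set.

    Raises
    ------
    EmptyEvaluationError
        If either collection is empty.
    """
    n, m = gold.n, clusters.m
    if n == 0 or m == 0:
        raise EmptyEvaluationError(
            "empty evaluation: need at least one reference complex and one cluster"
        )
    t = np.zeros((n, m), dtype=np.int64)
    for i, P in enumerate(gold.complexes):
        for j, C in enumerate(clusters.clusters):
            t[i, j] = len(P & C)
    n_sizes = np.array([len(P) for P in gold.complexes], dtype=np.int64)
    m_sizes = np.array([len(C) for C in clusters.clusters], dtype=np.int64)
    tf = t.astype(float)
    na = tf**2 / np.outer(n_sizes, m_sizes)
    # |P | C| = n_i + m_j - t_ij
    jcc = tf / (n_sizes[:, None] + m_sizes[None, :] - tf)
    return OverlapTable(
        t=t,
        n_sizes=n_sizes,
        m_sizes=m_sizes,
        na=na,
        jcc=jcc,
        gold_name=gold.name,
        cluster_name=clusters.name,
    )
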