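"""Matching-based criteria: MMR, Precision/Recall/F and the ⁺ family.

All criteria here operate on the bipartite graph whose edges link reference
complex ``P_i`` to detected cluster ``C_j`` whenever the neighborhood
affinity score reaches a threshold (``NA >= theta``) and the pair actually
shares proteins (``t_ij > 0``; zero-overlap pairs are never edges, even at
``theta = 0``).

* MMR (maximal matching ratio): the total weight of a maximum-weight
  matching on this graph, divided by the number of reference complexes. It
  is blind to duplicated clusters — copies cannot enlarge a matching.
* Precision / Recall / F: the fraction of complexes (resp. clusters) with at
  least one qualifying counterpart. Note the naming follows the complex
  detection literature — "Precision" is over complexes and "Recall" over
  clusters, the reverse of the usual information-retrieval convention.
* Precision⁺ / Recall⁺ / F⁺: the fractions covered by a maximum-cardinality
  one-to-one matching, so duplicated clusters lower Recall⁺.
* The composite MMR + F⁺ is the headline score: it reaches its maximum 2
  exactly when the detected clusters reproduce the gold standard one-to-one.

Matching uses the exact rectangular linear assignment solver; correctness is
pinned against brute-force enumeration in the test suite, not by algorithm
choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .overlap import EmptyEvaluationError, OverlapTable
from .set_metrics import MetricTriple, harmonic_mean

__all__ = [
    "ThresholdedGraph",
    "MatchResult",
    "threshold_graph",
    "mmr",
    "pr_metrics",
    "match_set",
    "plus_metrics",
    "composite_mmr_fplus",
]


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")


@dataclass(frozen=True)
class ThresholdedGraph:
    """Edges ``(i, j, na_ij)`` with ``na_ij >= theta`` and ``t_ij > 0``."""

    theta: float
    edges: frozenset
    score_kind: str = "NA"


def threshold_graph(table: OverlapTable, theta: float) -> ThresholdedGraph:
    """Build the NA-thresholded bipartite graph of an overlap table."""
    _check_theta(theta)
    mask = _edge_mask(table, theta)
    ii, jj = np.nonzero(mask)
    edges = frozenset(
        (int(i), int(j), float(table.na[i, j])) for i, j in zip(ii, jj)
    )
    return ThresholdedGraph(theta=theta, edges=edges)


def _edge_mask(table: OverlapTable, theta: float) -> np.ndarray:
    return (table.na >= theta) & (table.t > 0)


def mmr(table: OverlapTable, theta: float) -> float:
    """Maximal matching ratio at NA threshold ``theta``.

    Maximum-weight bipartite matching on the thresholded graph; the matched
    NA weights are summed and normalized by the number of reference
    complexes. The value is deterministic even when several optimal
    matchings exist.
    """
    _check_theta(theta)
    if table.n == 0:
        raise EmptyEvaluationError("empty evaluation")
    # Non-edges get weight 0: with all weights >= 0 a maximum-weight full
    # assignment on the padded matrix has the same total as the maximum-weight
    # matching on the edge set.
    w = np.where(_edge_mask(table, theta), table.na, 0.0)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum()) / table.n


def pr_metrics(table: OverlapTable, theta: float) -> MetricTriple:
    """Precision, Recall and F at NA threshold ``theta``.

    Precision is the fraction of reference complexes with at least one
    qualifying cluster; Recall the fraction of clusters with at least one
    qualifying complex (the field's own, unconventional naming).
    """
    _check_theta(theta)
    mask = _edge_mask(table, theta)
    n_p = int(mask.any(axis=1).sum())
    n_c = int(mask.any(axis=0).sum())
    precision = n_p / table.n
    recall = n_c / table.m
    return MetricTriple(
        precision, recall, harmonic_mean(precision, recall),
        ("Precision", "Recall", "F"),
    )


@dataclass(frozen=True)
class MatchResult:
    """A one-to-one matching between complexes and clusters.

    ``pairs`` is sorted by ``(complex index, cluster index)``; no index
    repeats on either side, so the number of matched complexes and matched
    clusters both equal ``cardinality``.
    """

    pairs: tuple
    total_weight: float
    cardinality: int

    @property
    def n_p_plus(self) -> int:
        return self.cardinality

    @property
    def n_c_plus(self) -> int:
        return self.cardinality


def match_set(table: OverlapTable, theta: float) -> MatchResult:
    """Maximum-cardinality matching on the unweighted thresholded graph.

    Among maximum-cardinality matchings the one of maximum total NA weight
    is reported (the cardinality — hence every ⁺ criterion — is
    tie-invariant; the pair list is deterministic and sorted for
    reproducible downstream inspection).
    """
    _check_theta(theta)
    mask = _edge_mask(table, theta)
    # A per-edge bonus larger than any achievable NA total makes cardinality
    # dominate; NA weights break ties among equal-cardinality matchings.
    bonus = float(min(table.n, table.m)) + 1.0
    w = np.where(mask, bonus + table.na, 0.0)
    rows, cols = linear_sum_assignment(w, maximize=True)
    pairs = sorted(
        (int(i), int(j)) for i, j in zip(rows, cols) if mask[i, j]
    )
    total = float(sum(table.na[i, j] for i, j in pairs))
    return MatchResult(pairs=tuple(pairs), total_weight=total, cardinality=len(pairs))


def plus_metrics(table: OverlapTable, theta: float) -> MetricTriple:
    """Precision⁺, Recall⁺ and F⁺ at NA threshold ``theta``.

    Both numerators equal the maximum-cardinality matching size, so every
    cluster can validate at most one complex and vice versa.
    """
    match = match_set(table, theta)
    precision = match.cardinality / table.n
    recall = match.cardinality / table.m
    return MetricTriple(
        precision, recall, harmonic_mean(precision, recall),
        ("Precision+", "Recall+", "F+"),
    )


def composite_mmr_fplus(table: OverlapTable, theta: float) -> float:
    """The composite criterion MMR + F⁺, in ``[0, 2]``.

    Takes its maximum value 2 exactly when the detected clusters are the
    gold-standard complexes (one-to-one and spanning).
    """
    return mmr(table, theta) + plus_metrics(table, theta).combined
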