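"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's matching/clique code paths:
matchings are maximized by bitmask dynamic programming over explicit edge
lists, and maximal cliques by exhaustive subset enumeration. They are only
feasible on tiny instances, which is what pins the production
implementations.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from cdbench import (
    ClusterSet,
    GoldStandard,
    GoldSpec,
    PerturbationSpec,
    build_overlap,
    make_gold,
    perturb,
)


@pytest.fixture
def w1():
    """The worked instance used throughout: two complexes, three clusters.

    t = [[3,0,0],[0,2,0]]; NA_11 = 0.75, NA_22 = 4/9; JCC_11 = 0.75,
    JCC_22 = 0.5.
    """
    gold = GoldStandard("gold", [frozenset("abcd"), frozenset("def")])
    clusters = ClusterSet(
        "method", [frozenset("abc"), frozenset("efg"), frozenset("xy")]
    )
    return build_overlap(gold, clusters)


@pytest.fixture
def w1_sets():
    gold = GoldStandard("gold", [frozenset("abcd"), frozenset("def")])
    clusters = ClusterSet(
        "method", [frozenset("abc"), frozenset("efg"), frozenset("xy")]
    )
    return gold, clusters


def oracle_matching(edges: list[tuple[int, int, float]], n: int, m: int,
                    weighted: bool) -> float:
    """Exact optimum over all matchings via bitmask DP over complexes.

    Returns the maximum total weight (``weighted=True``) or the maximum
    cardinality (``weighted=False``).
    """
    by_complex: dict[int, list[tuple[int, float]]] = {}
    for i, j, w in edges:
        by_complex.setdefault(i, []).append((j, w))

    @lru_cache(maxsize=None)
    def rec(i: int, used_mask: int) -> float:
        if i == n:
            return 0.0
        best = rec(i + 1, used_mask)  # leave complex i unmatched
        for j, w in by_complex.get(i, ()):
            if not used_mask >> j & 1:
                gain = w if weighted else 1.0
                best = max(best, gain + rec(i + 1, used_mask | 1 << j))
        return best

    return rec(0, 0)


def oracle_maximal_cliques(nodes: list, adjacency: dict) -> set[frozenset]:
    """All maximal cliques by exhaustive subset enumeration (<= 12 nodes)."""
    node_list = list(nodes)
    cliques = []
    for r in range(1, len(node_list) + 1):
        for subset in itertools.combinations(node_list, r):
            if all(b in adjacency[a] for a, b in itertools.combinations(subset, 2)):
                cliques.append(frozenset(subset))
    maximal = set()
    for c in cliques:
        if not any(c < other for other in cliques):
            maximal.add(c)
    return maximal


def random_instance(seed: int, max_n: int = 6, max_m: int = 6):
    """A small random gold/cluster pair over a shared protein pool."""
    rng = np.random.default_rng(seed)
    pool = [f"x{k}" for k in range(12)]
    n = int(rng.integers(1, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    complexes = [
        frozenset(rng.choice(pool, size=rng.integers(2, 6), replace=False).tolist())
        for _ in range(n)
    ]
    clusters = [
        frozenset(rng.choice(pool, size=rng.integers(2, 6), replace=False).tolist())
        for _ in range(m)
    ]
    return (
        GoldStandard(f"gold{seed}", complexes),
        ClusterSet(f"clusters{seed}", clusters),
    )


def noisy_fixture(seed: int):
    """A seeded gold standard plus a moderately perturbed detection of it."""
    rng = np.random.default_rng(seed)
    gold = make_gold(GoldSpec(
        n_complexes=int(rng.integers(3, 7)),
        size_range=(3, 7),
        overlap_fraction=float(rng.uniform(0, 0.5)),
        shared_count=2,
        seed=seed,
    ))
    clusters = perturb(gold, PerturbationSpec(
        drop_protein_rate=float(rng.uniform(0, 0.3)),
        add_noise_protein_rate=float(rng.uniform(0, 0.3)),
        duplicate_clusters=int(rng.integers(0, 3)),
        spurious_pairs=int(rng.integers(0, 3)),
        drop_cluster_rate=float(rng.uniform(0, 0.2)),
        seed=seed + 1,
    ))
    if clusters.m == 0:  # pathological seed wiped every cluster
        clusters = perturb(gold, PerturbationSpec(seed=seed + 1))
    return gold, clusters
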