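"""Seeded generators for gold standards, perturbed cluster sets and PPINs.

Everything the benchmark consumes can be generated deterministically from a
seed, so the full metric surface is testable without downloading any
reference data.

* :func:`make_gold` emulates a curated complex catalogue: a configurable
  number of complexes with sizes drawn uniformly from a range, optionally
  with shared proteins between consecutive complexes (real catalogues
  overlap).
* :func:`perturb` turns a gold standard into a synthetic "detected" cluster
  set by applying, in a fixed order, the classic pathologies of
  complex-detection output: missed complexes (false negatives), per-protein
  drop-out and contamination, exact duplicate clusters, spurious small
  within-complex clusters, and a giant cluster spanning every reference
  protein. With an all-zero spec the output is a perfect detection.
* :func:`make_ppin` plants the complexes in a weighted interaction network:
  complexes are dense subgraphs (intra-complex edge probability ``p_in``
  exceeds inter-complex ``p_out``) with higher reliability weights inside.

Protein IDs live in a ``P######`` namespace; contamination proteins come
from a disjoint ``N######`` namespace so noise is traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import PPINetwork
from .overlap import ClusterSet, GoldStandard

__all__ = [
    "GoldSpec",
    "PerturbationSpec",
    "PlantedPPINSpec",
    "make_gold",
    "perturb",
    "make_ppin",
]


@dataclass(frozen=True)
class GoldSpec:
    """Parameters of a synthetic gold standard.

    ``overlap_fraction`` of the consecutive complex pairs share
    ``shared_count`` proteins; ``shared_count`` must stay below the minimum
    complex size so complexes remain distinct.
    """

    n_complexes: int = 5
    size_range: tuple[int, int] = (3, 8)
    overlap_fraction: float = 0.0
    shared_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if self.n_complexes < 1 or lo < 1 or hi < lo:
            raise ValueError("invalid gold-standard spec")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.overlap_fraction > 0 and self.shared_count >= lo:
            raise ValueError(
                f"shared_count ({self.shared_count}) must be smaller than the "
                f"minimum complex size ({lo})"
            )


@dataclass(frozen=True)
class PerturbationSpec:
    """Pathology knobs applied, in this fixed order, to a perfect detection:

    1. drop whole clusters (``drop_cluster_rate`` — false negatives),
    2. per-protein drop-out (``drop_protein_rate``) and contamination
       (``add_noise_protein_rate``),
    3. append ``duplicate_clusters`` exact copies of surviving clusters,
    4. append ``spurious_pairs`` 2-protein clusters drawn from within
       single complexes,
    5. optionally append the giant union of all reference proteins.
    """

    drop_protein_rate: float = 0.0
    add_noise_protein_rate: float = 0.0
    duplicate_clusters: int = 0
    spurious_pairs: int = 0
    giant_component: bool = False
    drop_cluster_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.drop_protein_rate,
            self.add_noise_protein_rate,
            self.drop_cluster_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.duplicate_clusters < 0 or self.spurious_pairs < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class PlantedPPINSpec:
    """Planted-complex interaction network parameters.

    Complexes must be denser than their surroundings: ``p_in > p_out``.
    Weight bounds give the uniform reliability ranges for intra- and
    inter-complex edges.
    """

    p_in: float = 0.9
    p_out: float = 0.05
    weight_in: tuple[float, float] = (0.5, 1.0)
    weight_out: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1 (complexes are dense)")
        for lo, hi in (self.weight_in, self.weight_out):
            if not 0 < lo <= hi:
                raise ValueError("weight bounds must be positive and ordered")


def _pid(k: int) -> str:
    return f"P{k:06d}"


def make_gold(spec: GoldSpec) -> GoldStandard:
    """Generate a synthetic gold standard; same seed, same output."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)
    n_pairs = spec.n_complexes - 1
    n_overlapping = int(round(spec.overlap_fraction * n_pairs))
    overlapping = set(
        rng.choice(n_pairs, size=n_overlapping, replace=False).tolist()
    ) if n_overlapping else set()

    complexes: list[frozenset] = []
    next_id = 0
    for i, size in enumerate(sizes):
        members: set[str] = set()
        if i > 0 and (i - 1) in overlapping:
            shared = rng.choice(sorted(complexes[i - 1]), size=spec.shared_count,
                                replace=False)
            members.update(shared.tolist())
        while len(members) < size:
            members.add(_pid(next_id))
            next_id += 1
        complexes.append(frozenset(members))
    return GoldStandard(name=f"synthetic-gold(seed={spec.seed})", complexes=complexes)


def perturb(gold: GoldStandard, spec: PerturbationSpec) -> ClusterSet:
    """Derive a synthetic detected-cluster set from a gold standard.

    With an all-zero spec the clusters are identical to the complexes.
    """
    rng = np.random.default_rng(spec.seed)
    clusters = [set(P) for P in gold.complexes]

    # 1. false negatives: drop whole clusters
    if spec.drop_cluster_rate > 0:
        keep = rng.random(len(clusters)) >= spec.drop_cluster_rate
        clusters = [c for c, k in zip(clusters, keep) if k]

    # 2. per-protein drop-out and contamination
    noise_counter = 0
    if spec.drop_protein_rate > 0 or spec.add_noise_protein_rate > 0:
        perturbed = []
        for c in clusters:
            members = {p for p in sorted(c) if rng.random() >= spec.drop_protein_rate}
            n_noise = rng.binomial(len(c), spec.add_noise_protein_rate)
            for _ in range(n_noise):
                members.add(f"N{noise_counter:06d}")
                noise_counter += 1
            if members:
                perturbed.append(members)
        clusters = perturbed

    # 3. exact duplicate clusters
    if spec.duplicate_clusters > 0 and clusters:
        picks = rng.integers(0, len(clusters), size=spec.duplicate_clusters)
        clusters.extend(set(clusters[int(i)]) for i in picks)

    # 4. spurious within-complex 2-protein clusters
    if spec.spurious_pairs > 0:
        eligible = [sorted(P) for P in gold.complexes if len(P) >= 2]
        if not eligible:
            raise ValueError("spurious pairs need a complex with >= 2 proteins")
        for _ in range(spec.spurious_pairs):
            source = eligible[int(rng.integers(0, len(eligible)))]
            pair = rng.choice(source, size=2, replace=False)
            clusters.append(set(pair.tolist()))

    # 5. the giant cluster spanning all reference proteins
    if spec.giant_component:
        clusters.append(set(gold.proteins))

    return ClusterSet(
        name=f"perturbed(seed={spec.seed})",
        clusters=[frozenset(c) for c in clusters],
    )


def make_ppin(gold: GoldStandard, spec: PlantedPPINSpec) -> PPINetwork:
    """Plant the gold-standard complexes in a weighted interaction network.

    Each protein pair within a complex gets an edge with probability
    ``p_in`` (weight uniform in ``weight_in``); pairs never sharing a
    complex with probability ``p_out`` (weight uniform in ``weight_out``).
    No self-edges; isolated proteins are pruned (the returned network's
    protein set is exactly the edge endpoints).
    """
    rng = np.random.default_rng(spec.seed)
    proteins = sorted(gold.proteins)
    comembers: set[frozenset] = set()
    for P in gold.complexes:
        members = sorted(P)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                comembers.add(frozenset((members[ai], members[bi])))

    edges: list[tuple[str, str, float]] = []
    for ai in range(len(proteins)):
        for bi in range(ai + 1, len(proteins)):
            a, b = proteins[ai], proteins[bi]
            internal = frozenset((a, b)) in comembers
            p = spec.p_in if internal else spec.p_out
            if rng.random() < p:
                lo, hi = spec.weight_in if internal else spec.weight_out
                edges.append((a, b, float(rng.uniform(lo, hi))))
    return PPINetwork(edges=edges)
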