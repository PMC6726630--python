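# Methods

## The overlap model

All criteria are functions of the bipartite overlap structure between a
gold standard of reference complexes *P₁…Pₙ* and a method's detected
clusters *C₁…Cₘ*: the intersection counts *tᵢⱼ = |Pᵢ ∩ Cⱼ|*, the
neighborhood affinity *NA = |P∩C|²/(|P||C|)* and the Jaccard index
*JCC = |P∩C|/|P∪C|*. `build_overlap` computes all three matrices in one
pass so every criterion sees identical inputs. Both scores are symmetric,
live in [0, 1], and equal 1 exactly on identical sets; they are undefined
(an error) on empty sets, and empty collections raise an "empty
evaluation" error rather than returning a score.

## Criteria and their conventions

* **SN / PPV / ACC** are threshold-free marginal aggregates. When a method
  shares no protein with the gold standard, PPV (whose denominator Σtᵢⱼ
  would vanish) is defined as 0, not an error: no overlap is the worst
  score, not an invalid input.
* **Prec_N / Rec_N / F_N** gate the per-entity best overlap on a *strict*
  Jaccard comparison (JCC > θ); the empty max is 0 (an unmatched entity
  contributes nothing). Rec_N is implemented as the exact mirror image of
  Prec_N (per cluster, best complex above the threshold).
* **MMR** and the matching criteria use NA with a *non-strict* comparison
  (NA ≥ θ). The strict/non-strict asymmetry between the JCC- and NA-based
  families is the field's printed convention and is preserved deliberately.
  Pairs with tᵢⱼ = 0 are never edges, even at θ = 0; otherwise every
  complex–cluster pair would become an edge at the bottom of a threshold
  sweep and matchings would degenerate. This guard applies uniformly to
  MMR, Precision/Recall and the ⁺ family.
* **Harmonic means** (F, F_N, F⁺) return 0 when both components are 0.
* Threshold-dependent values default to θ = 0.25, the conventional NA
  cutoff in this literature.

## Matching backend and tie-breaking

Maximum-weight and maximum-cardinality bipartite matchings are computed
with SciPy's exact rectangular linear-assignment solver. Non-edges are
padded with weight 0, which is value-preserving because all genuine edge
weights are non-negative. For the maximum-cardinality matching, each edge
receives a bonus larger than any achievable NA total (min(n, m) + 1), so
cardinality dominates and NA weight breaks ties among equal-cardinality
matchings. The reported numbers — MMR, the matching cardinality, hence
Precision⁺/Recall⁺/F⁺ — are invariant to which optimal matching the solver
returns; the pair list itself is deterministic (sorted, fixed solver) but
not guaranteed to be the lexicographically smallest among exact weight
ties. Correctness is pinned by brute-force bitmask-DP oracles on instances
with n, m ≤ 6, not by the choice of algorithm.

## Threshold curves and areas

The default grid is θ ∈ {0.01, 0.02, …, 1.00}. θ = 0 is excluded: under
the ≥ comparison it adds no information beyond θ = 0.01 for realistic set
sizes and it is the degenerate end of the sweep. Integration is
trapezoidal, and areas are *not* normalized by grid width — AUMF of a
constant-2 curve on the default grid is 2 × 0.99 = 1.98, not 2 — so areas
are comparable only across identical grids; curve objects and CLI sidecars
record the grid used. The precision-recall curves (AUPR, AUPR⁺) collapse
duplicate recall values to their maximum precision and integrate over the
observed recall range only, with no extrapolation to recall 0 or 1; a
degenerate single-point curve therefore has area 0.

## Consensus integration and filters

Integration builds a k-partite graph (one part per method, one node per
cluster) and links clusters of different methods when JCC > φ, with one
exception: identical clusters (JCC = 1) are always linked. Without that
exception a strict comparison at φ = 1 would link nothing, while φ = 1 is
precisely the "exact consensus" setting (keep clusters reported
identically by several methods). Maximal cliques are enumerated with
networkx (Bron–Kerbosch); a clique survives if its size strictly exceeds
ψ (default k/2), and contributes the union or intersection of its member
clusters. Exact-duplicate integrated clusters are collapsed and empty
intersections dropped, since duplicates and empty sets would distort every
downstream metric. The Jaccard index is used as the "φ% overlap" measure
because it is the only pairwise cluster–cluster score the criteria family
defines, and it makes the φ = 1 ⇔ identity reading exact.

The reliability filter keeps a target cluster when at least β methods
(counting the target's own method) contain a cluster with JCC > φ
(default φ = 0.5, plain strict comparison); β = 1 is therefore the
identity, and β exceeding the number of supplied methods yields an empty
result with a warning. The size filter is an inclusive window; the protein
filter is an exact string match on opaque, case-sensitive protein IDs.

## Synthetic data

The generators emulate the benchmark's study conditions, not real PPI
biology:

* `make_gold` draws complexes with sizes uniform on a range (default 5
  complexes, sizes 3–8, disjoint) over a sequential `P######` namespace;
  an overlap fraction makes consecutive complexes share a fixed number of
  proteins, mimicking the overlapping complexes of curated catalogues.
* `perturb` starts from the perfect detection (clusters = complexes) and
  applies, in a fixed order so seeds reproduce across versions: cluster
  drop-out (false negatives) → per-protein drop-out and contamination
  (noise proteins come from a disjoint `N######` namespace, so
  contamination is traceable) → exact duplicate clusters → spurious
  2-protein within-complex clusters → optionally a giant cluster spanning
  every reference protein. Each knob reproduces one classic pathology of
  detector output, and each pathology's metric signature (SN saturation,
  PPV inflation, ACC blindness, MMR duplication blindness) is asserted in
  the tests.
* `make_ppin` plants the complexes in a weighted network with
  intra-complex edge probability p_in = 0.9 (weights uniform on
  [0.5, 1.0]) and inter-complex probability p_out = 0.05 (weights on
  [0.05, 0.5]); complexes must be denser than their surroundings
  (p_in > p_out is enforced).

What the generators do **not** model: scale-free degree structure,
socio-affinity weight calibration, protein identity semantics, or any
correlation between complex size and detectability. Passing tests
therefore demonstrate the correctness of the criteria and operations, not
the field performance of any detector on real interaction data.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give identical outputs.

## Problem sizes

Oracle-equivalence suites run 200 random instances with n, m ≤ 6 (bitmask
DP over 2⁶ cluster subsets is exact and instant) and 30–40 random
k-partite graphs with ≤ 12 nodes (exhaustive subset enumeration);
monotonicity suites run 50 random fixtures over the full 100-point default
grid. These sizes exercise every code path — rectangular tables, empty
matchings, ties, saturated thresholds — while the whole suite stays in the
seconds range.

## Known limitations

* Areas are grid-relative (see above); comparing areas computed on
  different grids is a user error the API does not prevent, though reports
  record the grid.
* The matching pair list, while deterministic, is not canonical under
  exact NA ties (the scores are).
* Reproduction of published benchmark tables that depend on running the
  original nine detectors on real datasets is out of scope; the package
  evaluates pre-computed cluster files.
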