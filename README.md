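# cdbench

Benchmarking of protein-complex detection results against gold-standard
complex catalogues.

Algorithms that mine protein–protein interaction networks (PPINs) for
complexes — MCL, ClusterONE, RNSC, CFinder and their successors — emit sets
of protein clusters that must be scored against curated references such as
MIPS, SGD or CYC2008. `cdbench` is a library plus command-line tool for
exactly that comparison. It is aimed at method developers who need to rank
a new detector against published ones, and at benchmark maintainers who
need reproducible, scriptable scoring.

## Criteria

Write the gold standard as complexes *P₁…Pₙ* and a method's output as
clusters *C₁…Cₘ*, with overlap counts *tᵢⱼ = |Pᵢ ∩ Cⱼ|*. Two pairwise
scores drive everything: the neighborhood affinity
*NA(P,C) = |P∩C|² / (|P||C|)* and the Jaccard index
*JCC(P,C) = |P∩C| / |P∪C|*.

| family | definition |
|---|---|
| SN, PPV, ACC | SN = Σᵢ maxⱼ tᵢⱼ / Σᵢ nᵢ;  PPV = Σⱼ maxᵢ tᵢⱼ / Σᵢⱼ tᵢⱼ;  ACC = √(SN·PPV) |
| Prec_N, Rec_N, F_N | per-entity best overlap among counterparts with JCC > θ, normalized by entity sizes |
| MMR | total weight of a maximum-weight matching on the NA ≥ θ bipartite graph, / n |
| Precision, Recall, F | fraction of complexes (resp. clusters) with any counterpart at NA ≥ θ |
| Precision⁺, Recall⁺, F⁺ | fractions covered by a maximum-**cardinality** one-to-one matching |
| MMR + F⁺ | the composite score; equals 2 exactly for a perfect one-to-one detection |
| AUMF, AUPR, AUPR⁺, AUC(·) | threshold-free areas under the (value, θ) or precision-recall curves |

("Precision" is over complexes and "Recall" over clusters, following the
complex-detection literature rather than the information-retrieval
convention.) The older families have known blind spots — a giant cluster
saturates SN, duplicated clusters inflate PPV, spurious within-complex
pairs leave ACC at 1, and MMR ignores duplicates entirely — which is what
the matching-based ⁺ family and the composite MMR + F⁺ were designed to
fix. The test suite asserts each of these behaviors.

Beyond scoring, `cdbench` integrates the outputs of k ≥ 2 methods into a
consensus cluster set (k-partite graph with JCC > φ edges; maximal cliques
larger than ψ; per-clique union or intersection) and filters results by
size, by query protein, or by cross-method reliability (detected by ≥ β
methods). Seeded generators produce gold standards, pathological detections
and planted-complex PPINs, so everything is testable offline.

## Worked example

```python
from cdbench import (GoldStandard, ClusterSet, build_overlap,
                     sn_ppv_acc, mmr, plus_metrics, composite_mmr_fplus)

gold = GoldStandard("gold", [frozenset("abcd"), frozenset("def")])
found = ClusterSet("method", [frozenset("abc"), frozenset("efg"), frozenset("xy")])
table = build_overlap(gold, found)

print(sn_ppv_acc(table).as_dict())
print("MMR", mmr(table, theta=0.25))
print(plus_metrics(table, theta=0.25).as_dict())
print("MMR+F+", composite_mmr_fplus(table, theta=0.25))
```

prints

```
{'SN': 0.7142857142857143, 'PPV': 1.0, 'ACC': 0.8451542547285166}
MMR 0.5972222222222222
{'Precision+': 1.0, 'Recall+': 0.6666666666666666, 'F+': 0.8}
MMR+F+ 1.3972222222222221
```

SN = 5/7: of the 7 reference-protein slots, 5 are recovered by the
best-matching clusters. PPV = 1 because every cluster's overlap is
concentrated on one complex. At θ = 0.25 both complexes are matched
one-to-one (Precision⁺ = 1) but only 2 of 3 clusters participate
(Recall⁺ = 2/3), and MMR sums the matched NA weights (0.75 + 4/9)/2.

The same evaluation from the shell:

```
cdbench simulate --n-complexes 5 --seed 3 --out sim/
cdbench evaluate sim/gold.txt sim/clusters.txt --theta 0.25 --out results/
cdbench evaluate sim/gold.txt sim/clusters.txt --out results-auc/   # areas instead of point values
cdbench integrate methodA.txt methodB.txt --phi 1 --psi 1 --out consensus/
```

`evaluate` writes `report.tsv` (one row per method) and `report.json`
(values plus provenance). Omitting `--theta` reports every
threshold-dependent criterion as the area under its curve over the default
θ grid {0.01, …, 1.00}.

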