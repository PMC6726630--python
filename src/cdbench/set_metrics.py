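"""Marginal/aggregation criteria: SN, PPV, ACC and the N-subscript family.

Sensitivity (SN), positive predictive value (PPV) and their geometric mean
ACC measure, per protein, how well reference complexes are covered by the
best-overlapping cluster and vice versa:

    SN  = sum_i max_j t_ij / sum_i n_i
    PPV = sum_j max_i t_ij / sum_ij t_ij
    ACC = sqrt(SN * PPV)

Prec_N / Rec_N / F_N are the analogous threshold-gated quantities: the best
overlap K_i is taken only over counterparts whose Jaccard index exceeds a
threshold theta (strict ``>``), and is 0 when none qualifies.

These criteria have well-documented blind spots — a single giant cluster
spanning all reference proteins saturates SN, duplicated clusters inflate
PPV, and spurious small within-complex clusters leave ACC at 1 — which the
matching-based criteria in :mod:`cdbench.match_metrics` address.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .overlap import OverlapTable

__all__ = ["MetricTriple", "harmonic_mean", "sn_ppv_acc", "n_metrics"]


@dataclass(frozen=True)
class MetricTriple:
    """Two component criteria plus their stated combination.

    ``combined`` is the geometric mean for (SN, PPV, ACC) and the 0-guarded
    harmonic mean for the F-type triples.
    """

    first: float
    second: float
    combined: float
    labels: tuple[str, str, str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, (self.first, self.second, self.combined)))

    # tuple-like access to (first, second, combined)
    def __iter__(self):
        return iter((self.first, self.second, self.combined))

    def __len__(self) -> int:
        return 3

    def __getitem__(self, index):
        return (self.first, self.second, self.combined)[index]


def harmonic_mean(a: float, b: float) -> float:
    """Harmonic mean with the 0-guard convention: 0 when ``a + b == 0``."""
    if a + b == 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def sn_ppv_acc(table: OverlapTable) -> MetricTriple:
    """Sensitivity, positive predictive value and accuracy.

    A method with no overlap at all scores PPV = ACC = 0 (worst score, not
    an error).
    """
    t = table.t
    sn = t.max(axis=1).sum() / table.n_sizes.sum()
    total = t.sum()
    ppv = t.max(axis=0).sum() / total if total > 0 else 0.0
    acc = math.sqrt(sn * ppv)
    return MetricTriple(float(sn), float(ppv), acc, ("SN", "PPV", "ACC"))


def n_metrics(table: OverlapTable, theta: float) -> MetricTriple:
    """Prec_N, Rec_N and F_N at Jaccard threshold ``theta``.

    Per reference complex, K_i is the intersection count with the best
    cluster among those with ``JCC > theta`` (0 if none); Prec_N normalizes
    the summed K_i by total complex size. Rec_N is the mirror image over
    clusters. The threshold comparison is strict.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    gated = np.where(table.jcc > theta, table.t, 0)
    k_complex = gated.max(axis=1)
    k_cluster = gated.max(axis=0)
    prec_n = k_complex.sum() / table.n_sizes.sum()
    rec_n = k_cluster.sum() / table.m_sizes.sum()
    return MetricTriple(
        float(prec_n),
        float(rec_n),
        harmonic_mean(float(prec_n), float(rec_n)),
        ("Prec_N", "Rec_N", "F_N"),
    )
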