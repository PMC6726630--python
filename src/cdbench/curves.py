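"""Threshold sweeps and threshold-free (area-under-curve) criteria.

Every threshold-dependent criterion can be freed of its threshold by
integrating it over a grid of theta values: the report then carries the area
under the (value, theta) curve. AUMF — the area under the
(MMR + F⁺, theta) curve — is the package's headline threshold-free score.
AUPR and AUPR⁺ are the areas under the precision-vs-recall curves traced as
theta varies.

Numerical choices: trapezoidal integration; the default grid is
theta in {0.01, 0.02, ..., 1.00} (theta = 0 is excluded as degenerate under
the ``>=`` edge rule); areas are NOT normalized by grid width, so they are
comparable only across identical grids — curves record their grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .overlap import OverlapTable
from . import match_metrics, set_metrics

__all__ = [
    "ThresholdCurve",
    "PRCurve",
    "CRITERIA",
    "default_grid",
    "sweep",
    "auc",
    "aumf",
    "aupr",
]


def default_grid() -> np.ndarray:
    """The default theta grid {0.01, 0.02, ..., 1.00}."""
    return np.arange(1, 101) / 100.0


def _triple_component(fn: Callable, index: int) -> Callable[[OverlapTable, float], float]:
    def metric(table: OverlapTable, theta: float) -> float:
        triple = fn(table, theta)
        return (triple.first, triple.second, triple.combined)[index]

    return metric


#: Threshold-dependent criteria available to :func:`sweep`, by name.
CRITERIA: dict[str, Callable[[OverlapTable, float], float]] = {
    "mmr": match_metrics.mmr,
    "precision": _triple_component(match_metrics.pr_metrics, 0),
    "recall": _triple_component(match_metrics.pr_metrics, 1),
    "f": _triple_component(match_metrics.pr_metrics, 2),
    "precision_plus": _triple_component(match_metrics.plus_metrics, 0),
    "recall_plus": _triple_component(match_metrics.plus_metrics, 1),
    "f_plus": _triple_component(match_metrics.plus_metrics, 2),
    "prec_n": _triple_component(set_metrics.n_metrics, 0),
    "rec_n": _triple_component(set_metrics.n_metrics, 1),
    "f_n": _triple_component(set_metrics.n_metrics, 2),
    "composite": match_metrics.composite_mmr_fplus,
}


@dataclass
class ThresholdCurve:
    """Sampled (theta, value) pairs for one criterion plus the area under them."""

    grid: np.ndarray
    values: np.ndarray
    metric_name: str
    area: float = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) != len(self.values):
            raise ValueError("grid and values must be 1-D and of equal length")
        self.area = float(np.trapezoid(self.values, self.grid))


@dataclass
class PRCurve:
    """Precision-vs-recall points traced over theta, plain or ⁺ variant."""

    points: list  # (recall, precision), sorted by recall
    area: float
    plus_variant: bool


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("grid must contain at least 2 theta values")
    if not (np.all(np.diff(g) > 0) and g[0] >= 0.0 and g[-1] <= 1.0):
        raise ValueError("grid must be strictly increasing within [0, 1]")
    return g


def sweep(
    table: OverlapTable, metric: str, grid: Sequence[float] | None = None
) -> ThresholdCurve:
    """Evaluate one criterion at every theta on the grid.

    ``metric`` is a key of :data:`CRITERIA`.
    """
    if metric not in CRITERIA:
        raise KeyError(
            f"unknown criterion {metric!r}; available: {sorted(CRITERIA)}"
        )
    g = default_grid() if grid is None else _check_grid(grid)
    fn = CRITERIA[metric]
    values = np.array([fn(table, float(theta)) for theta in g])
    return ThresholdCurve(grid=g, values=values, metric_name=metric)


def auc(curve: ThresholdCurve) -> float:
    """Trapezoidal area under a threshold curve (not width-normalized)."""
    return curve.area


def aumf(table: OverlapTable, grid: Sequence[float] | None = None) -> float:
    """Area under the (MMR + F⁺, theta) curve over the grid (default grid if none)."""
    return sweep(table, "composite", grid).area


def aupr(
    table: OverlapTable,
    grid: Sequence[float] | None = None,
    plus_variant: bool = False,
) -> PRCurve:
    """Area under the precision-vs-recall curve traced as theta varies.

    Duplicate recall values collapse to their maximum precision; the
    trapezoid runs over the observed recall range only (no extrapolation to
    recall 0 or 1, so a single observed point has area 0).
    """
    g = default_grid() if grid is None else _check_grid(grid)
    fn = match_metrics.plus_metrics if plus_variant else match_metrics.pr_metrics
    best: dict[float, float] = {}
    for theta in g:
        triple = fn(table, float(theta))
        recall, precision = triple.second, triple.first
        if recall not in best or precision > best[recall]:
            best[recall] = precision
    points = sorted(best.items())
    if len(points) < 2:
        area = 0.0
    else:
        rec = np.array([r for r, _ in points])
        prec = np.array([p for _, p in points])
        area = float(np.trapezoid(prec, rec))
    return PRCurve(points=points, area=area, plus_variant=plus_variant)
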