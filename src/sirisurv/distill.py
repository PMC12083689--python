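"""Distillation of a survival forest's split rules into a few cutoffs.

The idea: each internal node of a survival tree places its split where the
log-rank statistic is maximized *conditional on the partition built so
far*; greedy as that is, across a large ensemble the chosen thresholds for
a genuinely prognostic continuous variable concentrate around the optimal
cutpoints.  So:

1. extract every split threshold the forest used for the variable;
2. estimate the kernel density of those thresholds, and the kernel density
   of the variable's training values, on one shared grid;
3. subtract the two (equal-mass comparison) — regions where splits are
   over-represented relative to the data stand out;
4. take the local maxima of the difference as candidate cutoffs;
5. drop candidates whose induced partition of the training values leaves
   any cell with less than ``min_group_proportion`` (default 10%) of the
   subjects, removing the weakest candidate first and re-checking.

The result is a small ordered cutoff set that converts the continuous
variable into a categorical one for the clinic-facing decision tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import DomainError
from .forest import SurvivalForest, extract_split_thresholds

__all__ = [
    "DensityCurve",
    "CutoffSet",
    "estimate_density",
    "find_local_maxima",
    "distill_cutoffs",
    "shared_grid",
]

N_GRID = 512


@dataclass(frozen=True)
class DensityCurve:
    """A kernel density estimate evaluated on an ordered grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise DomainError("density grid must be strictly increasing")
        if len(self.density) != len(grid):
            raise DomainError("grid and density lengths differ")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class CutoffSet:
    """Distilled cutoffs for one continuous variable, with provenance."""

    variable: str
    cutoffs: np.ndarray
    split_density: DensityCurve | None = None
    data_density: DensityCurve | None = None
    difference: np.ndarray | None = None
    min_group_proportion: float = 0.10
    status: str = "ok"          # "ok" or "empty" (forest never split on the variable)

    @property
    def is_empty(self) -> bool:
        return len(self.cutoffs) == 0

    def to_json(self) -> str:
        payload = {
            "variable": self.variable,
            "cutoffs": [float(c) for c in self.cutoffs],
            "min_group_proportion": self.min_group_proportion,
            "status": self.status,
        }
        if self.split_density is not None and self.data_density is not None:
            payload["grid"] = self.split_density.grid.tolist()
            payload["split_density"] = self.split_density.density.tolist()
            payload["data_density"] = self.data_density.density.tolist()
            payload["difference"] = [float(d) for d in self.difference]
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CutoffSet":
        d = json.loads(text)
        split_density = data_density = difference = None
        if "grid" in d:
            grid = np.asarray(d["grid"])
            split_density = DensityCurve(grid, np.asarray(d["split_density"]), float("nan"))
            data_density = DensityCurve(grid, np.asarray(d["data_density"]), float("nan"))
            difference = np.asarray(d["difference"])
        return cls(variable=d["variable"], cutoffs=np.asarray(d["cutoffs"], dtype=float),
                   split_density=split_density, data_density=data_density,
                   difference=difference,
                   min_group_proportion=d["min_group_proportion"], status=d["status"])


def _silverman_bw(values: np.ndarray, weights: np.ndarray | None) -> float:
    """Silverman's rule-of-thumb bandwidth (via the weighted sample sd and
    effective sample size, as scipy's KDE computes them)."""
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    return float(kde.factor * np.sqrt(kde.covariance[0, 0] / kde.factor**2))


def shared_grid(*value_sets: np.ndarray, pad: float = 0.0, n_grid: int = N_GRID) -> np.ndarray:
    """A fixed-resolution grid spanning the pooled range of all inputs,
    optionally padded (in data units) on both sides."""
    lo = min(float(np.min(v)) for v in value_sets if len(v))
    hi = max(float(np.max(v)) for v in value_sets if len(v))
    return np.linspace(lo - pad, hi + pad, n_grid)


def estimate_density(values, weights=None, grid: np.ndarray | None = None,
                     n_grid: int = N_GRID) -> DensityCurve:
    """Gaussian-kernel density with Silverman bandwidth, evaluated on
    ``grid`` (default: the value range padded by three bandwidths so the
    curve integrates to ~1)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise DomainError("estimate_density needs at least 2 values")
    if not np.all(np.isfinite(values)):
        raise DomainError("estimate_density: values must be finite")
    if np.ptp(values) == 0:
        raise DomainError("estimate_density: values are all identical")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise DomainError("weights must be nonnegative with positive sum")
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    if grid is None:
        grid = shared_grid(values, pad=3.0 * bw, n_grid=n_grid)
    return DensityCurve(grid=np.asarray(grid, dtype=float),
                        density=kde(np.asarray(grid, dtype=float)), bandwidth=bw)


def find_local_maxima(grid, values) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima of a curve on a grid.

    A maximum must be strictly greater than both neighbours; plateaus
    report their midpoint; endpoints are excluded; only maxima with a
    strictly positive curve value are kept.  Returns ``(positions,
    heights)``, both possibly empty.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    idx, _ = find_peaks(values)       # handles plateaus, returns midpoints
    keep = values[idx] > 0
    idx = idx[keep]
    return grid[idx], values[idx]


def _partition_proportions(values: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Proportion of values in each interval induced by the cutoffs
    (left-closed: a value equal to a cutoff goes to the upper interval)."""
    counts = np.bincount(np.searchsorted(cutoffs, values, side="right"),
                         minlength=len(cutoffs) + 1)
    return counts / len(values)


def distill_cutoffs(forest: SurvivalForest, variable: str, training_values,
                    min_group_proportion: float = 0.10,
                    weight_by_node_size: bool = False) -> CutoffSet:
    """Run the full distillation pipeline for one continuous variable.

    ``training_values`` must be the variable's values in the forest's
    training set; candidates creating minor groups are excluded, weakest
    (smallest density difference) first.
    """
    training_values = np.asarray(training_values, dtype=float)
    if len(training_values) < 20:
        raise DomainError("need at least 20 training values to distill cutoffs")
    thresholds, node_sizes = extract_split_thresholds(forest, variable)
    if len(thresholds) == 0:
        return CutoffSet(variable=variable, cutoffs=np.empty(0), status="empty",
                         min_group_proportion=min_group_proportion)
    weights = node_sizes if weight_by_node_size else None
    # Shared grid over the pooled range; padding from the larger bandwidth
    # keeps each curve's mass on-grid.
    bw_split = _silverman_bw(thresholds, weights) if np.ptp(thresholds) > 0 else 0.0
    bw_data = _silverman_bw(training_values, None)
    pad = 3.0 * max(bw_split, bw_data)
    grid = shared_grid(thresholds, training_values, pad=pad)
    if np.ptp(thresholds) == 0:
        # All trees agree on a single threshold: no density comparison needed.
        cutoffs = np.asarray([float(thresholds[0])])
        return CutoffSet(variable=variable, cutoffs=cutoffs,
                         min_group_proportion=min_group_proportion)
    split_density = estimate_density(thresholds, weights=weights, grid=grid)
    data_density = estimate_density(training_values, grid=grid)
    difference = split_density.density - data_density.density
    positions, heights = find_local_maxima(grid, difference)
    order = np.argsort(positions)
    positions, heights = positions[order], heights[order]
    # Minor-group filter: drop the weakest candidate until every interval
    # holds at least min_group_proportion of the training subjects.
    while len(positions) > 0:
        props = _partition_proportions(training_values, positions)
        if np.all(props >= min_group_proportion):
            break
        weakest = int(np.argmin(heights))
        positions = np.delete(positions, weakest)
        heights = np.delete(heights, weakest)
    return CutoffSet(variable=variable, cutoffs=positions,
                     split_density=split_density, data_density=data_density,
                     difference=difference, min_group_proportion=min_group_proportion)
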