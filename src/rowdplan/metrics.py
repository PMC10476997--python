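"""Dose/LET statistics: cumulative volume histograms, D_q metrics, diff maps.

The cumulative histogram V(d) is the fraction of structure voxels with value
>= d. D_q (e.g. D50% at q = 0.5) is the largest histogram dose level with
V(d) >= q — the standard DVH threshold convention, evaluated on the bin grid
without interpolation so results are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .grids import VoxelGrid

__all__ = [
    "CumulativeHistogram",
    "dvh",
    "d_metric",
    "d_metric_from_values",
    "mean_dose",
    "max_dose",
    "difference_map",
]


@dataclass
class CumulativeHistogram:
    """Cumulative volume histogram: edges (Gy or keV/um) and V(edge)."""

    edges: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.edges.shape != self.volume_fraction.shape:
            raise ConfigurationError("edges and volume_fraction must share shape")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ConfigurationError("cumulative histogram must be nonincreasing")


def _mask_values(grid: VoxelGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid.values.shape:
        mask = mask.reshape(grid.values.shape)
    if not mask.any():
        raise ConfigurationError("mask is empty")
    return grid.values[mask].astype(float)


def dvh(grid: VoxelGrid, mask: np.ndarray, bin_width: float = 0.01) -> CumulativeHistogram:
    """Cumulative histogram of ``grid`` over ``mask``: V(d) = frac(values >= d)."""
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be > 0")
    values = np.sort(_mask_values(grid, mask))
    vmax = values[-1]
    edges = np.arange(0.0, vmax + 2 * bin_width, bin_width)
    # count of values >= edge via searchsorted on the sorted array
    counts = values.size - np.searchsorted(values, edges, side="left")
    return CumulativeHistogram(edges, counts / values.size)


def d_metric(hist: CumulativeHistogram, q: float) -> float:
    """D_q: the largest dose level with V(d) >= q (D50% at q = 0.5)."""
    if not 0.0 < q < 1.0:
        raise DomainError("q must lie in (0, 1)")
    covered = hist.volume_fraction >= q
    if not covered.any():
        return 0.0
    return float(hist.edges[covered][-1])


def d_metric_from_values(values: np.ndarray, q: float) -> float:
    """D_q straight from voxel values (no binning): largest v with frac(>= v) >= q."""
    if not 0.0 < q < 1.0:
        raise DomainError("q must lie in (0, 1)")
    v = np.sort(np.asarray(values, dtype=float).reshape(-1))
    n = v.size
    # frac(values >= v[k]) = (n - k) / n >= q  <=>  k <= n - q*n
    k = int(np.floor(n - q * n + 1e-9))
    k = min(max(k, 0), n - 1)
    return float(v[k])


def mean_dose(grid: VoxelGrid, mask: np.ndarray) -> float:
    return float(np.mean(_mask_values(grid, mask)))


def max_dose(grid: VoxelGrid, mask: np.ndarray) -> float:
    return float(np.max(_mask_values(grid, mask)))


def difference_map(a: VoxelGrid, b: VoxelGrid) -> VoxelGrid:
    """Voxelwise a - b on aligned grids."""
    a.assert_aligned(b)
    return a.like(a.values - b.values)
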