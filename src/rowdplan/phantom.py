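"""Synthetic study fixtures: the slabbed water phantom and patient-like pO2.

The water phantom is a water-equivalent box with a cubic target (default
4x4x4 cm^3 at 8 cm depth, 2 mm voxels) whose interior is divided into seven
slabs along the beam axis, each with a different pO2 between 2.5 and 30 mmHg
(most hypoxic slab in the middle). Everything outside the target is normoxic.

Patient-like cases are smoothed Gaussian random pO2 fields rescaled so that a
requested fraction of PTV voxels falls below the 60 mmHg hypoxia threshold,
emulating the two clinical oxygenation profiles (95% hypoxic vs 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, DomainError
from .grids import VoxelGrid

__all__ = [
    "PhantomSpec",
    "WaterPhantom",
    "SyntheticCaseSpec",
    "SyntheticCase",
    "make_water_phantom",
    "make_synthetic_case",
    "uptake_to_po2",
    "DEFAULT_SLAB_PO2",
]

# Seven distinct pO2 levels (mmHg) spanning 2.5-30, most hypoxic slab central.
DEFAULT_SLAB_PO2 = (30.0, 15.0, 7.5, 2.5, 5.0, 11.0, 22.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and oxygenation of the slabbed water phantom."""

    shape: tuple[int, int, int] = (40, 40, 80)
    spacing_mm: float = 2.0
    target_size_mm: float = 40.0
    target_depth_mm: float = 80.0  # depth of the proximal target face
    beam_axis: int = 2
    slab_po2_mmhg: tuple[float, ...] = DEFAULT_SLAB_PO2
    background_po2_mmhg: float = 160.0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing must be > 0")
        if self.beam_axis not in (0, 1, 2):
            raise ConfigurationError("beam_axis must be 0, 1 or 2")
        if not self.slab_po2_mmhg:
            raise ConfigurationError("at least one slab pO2 value is required")
        if any(not 0 <= v <= 160 for v in self.slab_po2_mmhg):
            raise ConfigurationError("slab pO2 values must lie in [0, 160] mmHg")
        extent = self.shape[self.beam_axis] * self.spacing_mm
        if self.target_depth_mm + self.target_size_mm > extent:
            raise ConfigurationError("target extends beyond the phantom along the beam axis")
        for a in range(3):
            if a != self.beam_axis and self.target_size_mm > self.shape[a] * self.spacing_mm:
                raise ConfigurationError("target extends beyond the phantom laterally")


@dataclass
class WaterPhantom:
    """Grids produced by :func:`make_water_phantom`."""

    spec: PhantomSpec
    density: VoxelGrid  # relative water density, 1 everywhere
    target_mask: VoxelGrid  # {0,1}
    po2: VoxelGrid  # mmHg
    slab_labels: VoxelGrid  # 0 outside target, 1..n_slabs inside

    def slab_mask(self, slab_index: int) -> np.ndarray:
        """Boolean mask of one slab (1-based index)."""
        return self.slab_labels.values == slab_index

    def most_hypoxic_slab_mask(self) -> np.ndarray:
        idx = int(np.argmin(self.spec.slab_po2_mmhg)) + 1
        return self.slab_mask(idx)


def make_water_phantom(spec: PhantomSpec = PhantomSpec()) -> WaterPhantom:
    """Build the slabbed water phantom (pure function of the spec)."""
    spacing = (spec.spacing_mm,) * 3
    origin = (spec.spacing_mm / 2.0,) * 3  # first voxel's proximal edge at 0 mm
    shape = spec.shape
    density = VoxelGrid(np.ones(shape, dtype=float), spacing, origin)

    mask = np.zeros(shape, dtype=np.uint8)
    slab_labels = np.zeros(shape, dtype=np.int16)
    sl: list[slice] = []
    for a in range(3):
        coords = density.axis_coords(a)
        if a == spec.beam_axis:
            lo = spec.target_depth_mm
            hi = spec.target_depth_mm + spec.target_size_mm
        else:
            center = (coords[0] + coords[-1]) / 2.0
            lo = center - spec.target_size_mm / 2.0
            hi = center + spec.target_size_mm / 2.0
        inside = np.where((coords > lo) & (coords < hi))[0]
        if inside.size == 0:
            raise ConfigurationError("target contains no voxels along axis %d" % a)
        sl.append(slice(inside[0], inside[-1] + 1))
    mask[sl[0], sl[1], sl[2]] = 1

    po2 = np.full(shape, spec.background_po2_mmhg, dtype=float)
    axis_slice = sl[spec.beam_axis]
    target_axis_indices = np.arange(axis_slice.start, axis_slice.stop)
    parts = np.array_split(target_axis_indices, len(spec.slab_po2_mmhg))
    for k, (indices, value) in enumerate(zip(parts, spec.slab_po2_mmhg), start=1):
        idx = [sl[0], sl[1], sl[2]]
        idx[spec.beam_axis] = indices
        if spec.beam_axis == 0:
            po2[np.ix_(indices, np.arange(sl[1].start, sl[1].stop), np.arange(sl[2].start, sl[2].stop))] = value
            slab_labels[np.ix_(indices, np.arange(sl[1].start, sl[1].stop), np.arange(sl[2].start, sl[2].stop))] = k
        elif spec.beam_axis == 1:
            po2[np.ix_(np.arange(sl[0].start, sl[0].stop), indices, np.arange(sl[2].start, sl[2].stop))] = value
            slab_labels[np.ix_(np.arange(sl[0].start, sl[0].stop), indices, np.arange(sl[2].start, sl[2].stop))] = k
        else:
            po2[np.ix_(np.arange(sl[0].start, sl[0].stop), np.arange(sl[1].start, sl[1].stop), indices)] = value
            slab_labels[np.ix_(np.arange(sl[0].start, sl[0].stop), np.arange(sl[1].start, sl[1].stop), indices)] = k

    return WaterPhantom(
        spec=spec,
        density=density,
        target_mask=VoxelGrid(mask, spacing, origin),
        po2=VoxelGrid(po2, spacing, origin),
        slab_labels=VoxelGrid(slab_labels, spacing, origin),
    )


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Patient-like pO2 field with a prescribed hypoxic-volume fraction."""

    seed: int
    hypoxic_fraction_below_60: float
    shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: float = 2.0
    correlation_length_mm: float = 8.0
    po2_range_mmhg: tuple[float, float] = (2.0, 160.0)
    ptv_size_mm: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hypoxic_fraction_below_60 <= 1.0:
            raise ConfigurationError("hypoxic fraction must lie in [0, 1]")
        lo, hi = self.po2_range_mmhg
        if lo >= hi or lo < 0:
            raise ConfigurationError("pO2 range must satisfy 0 <= lo < hi")
        f = self.hypoxic_fraction_below_60
        if f > 0 and lo >= 60.0:
            raise ConfigurationError("requested hypoxic fraction unattainable: range floor >= 60 mmHg")
        if f < 1 and hi <= 60.0:
            raise ConfigurationError("requested normoxic fraction unattainable: range ceiling <= 60 mmHg")


@dataclass
class SyntheticCase:
    spec: SyntheticCaseSpec
    po2: VoxelGrid
    ptv_mask: VoxelGrid
    oar_mask: VoxelGrid

    @property
    def realized_hypoxic_fraction(self) -> float:
        ptv = self.ptv_mask.values.astype(bool)
        return float(np.mean(self.po2.values[ptv] < 60.0))


def make_synthetic_case(spec: SyntheticCaseSpec) -> SyntheticCase:
    """Smoothed Gaussian random pO2 field matched to the requested fraction.

    A white-noise field is smoothed to the requested correlation length and
    mapped through a monotone piecewise-linear transform that sends the
    requested PTV quantile to 60 mmHg, so the realized sub-60 fraction equals
    the request up to the 1/N quantile resolution. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape)
    sigma_vox = spec.correlation_length_mm / spec.spacing_mm
    v = gaussian_filter(noise, sigma=sigma_vox, mode="nearest")

    spacing = (spec.spacing_mm,) * 3
    origin = (spec.spacing_mm / 2.0,) * 3
    geometry = VoxelGrid(np.zeros(spec.shape), spacing, origin)
    ptv = np.zeros(spec.shape, dtype=bool)
    sl = []
    for a in range(3):
        coords = geometry.axis_coords(a)
        center = (coords[0] + coords[-1]) / 2.0
        inside = np.where(np.abs(coords - center) < spec.ptv_size_mm / 2.0)[0]
        sl.append(slice(inside[0], inside[-1] + 1))
    ptv[sl[0], sl[1], sl[2]] = True
    # OAR: a lateral slab abutting the PTV along the first axis
    oar = np.zeros(spec.shape, dtype=bool)
    oar_lo = max(sl[0].start - max(1, (sl[0].stop - sl[0].start) // 4), 0)
    oar[oar_lo : sl[0].start, sl[1], sl[2]] = True

    lo, hi = spec.po2_range_mmhg
    f = spec.hypoxic_fraction_below_60
    vin = v[ptv]
    vmin, vmax = float(v.min()), float(v.max())
    if f <= 0.0:
        knot = vmin - 1e-9  # everything maps at or above 60
    elif f >= 1.0:
        knot = vmax + 1e-9
    else:
        knot = float(np.quantile(vin, f))
        knot = min(max(knot, vmin + 1e-12), vmax - 1e-12)
    xp = [vmin, knot, vmax]
    fp = [lo, 60.0, hi]
    if f <= 0.0:
        xp, fp = [vmin, vmax], [60.0, hi]
    elif f >= 1.0:
        xp, fp = [vmin, vmax], [lo, 60.0 - 1e-9]
    po2 = np.interp(v, xp, fp)

    case = SyntheticCase(
        spec=spec,
        po2=VoxelGrid(po2, spacing, origin),
        ptv_mask=VoxelGrid(ptv.astype(np.uint8), spacing, origin),
        oar_mask=VoxelGrid(oar.astype(np.uint8), spacing, origin),
    )
    realized = case.realized_hypoxic_fraction
    if abs(realized - f) > 0.02:
        raise ConfigurationError(
            f"requested hypoxic fraction {f:.3f} unattainable; realized {realized:.3f}"
        )
    return case


def uptake_to_po2(uptake: VoxelGrid, calibration: pd.DataFrame) -> VoxelGrid:
    """Convert PET uptake to pO2 through a pluggable calibration table.

    The table has columns ``uptake`` (strictly increasing) and ``pO2_mmHg``
    (monotone either way). Piecewise-linear interpolation, clamped at the
    table ends.
    """
    required = {"uptake", "pO2_mmHg"}
    if not required.issubset(calibration.columns):
        raise ConfigurationError(f"calibration table needs columns {sorted(required)}")
    x = calibration["uptake"].to_numpy(dtype=float)
    y = calibration["pO2_mmHg"].to_numpy(dtype=float)
    if x.size < 1:
        raise ConfigurationError("calibration table is empty")
    if np.any(np.diff(x) <= 0):
        raise ConfigurationError("calibration uptake values must be strictly increasing")
    dy = np.diff(y)
    if dy.size and not (np.all(dy >= 0) or np.all(dy <= 0)):
        raise ConfigurationError("calibration pO2 values must be monotone in uptake")
    values = np.interp(uptake.values, x, y)
    return uptake.like(values)
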