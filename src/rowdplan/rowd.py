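"""Mixed-field accumulation and the RBE-and-OER-weighted dose (ROWD).

The ROWD converts the proton effect in a voxel into the photon dose that
would produce the same LQ effect in aerobic tissue::

    ROWD_i = (D_i / Dp_i) * ( sqrt( (ax/(2 bx))^2 + (ah*Dp_i + bh*Dp_i^2)/bx )
                              - ax/(2 bx) )

where D is the total physical dose (protons + secondaries), Dp the proton
dose, (ax, bx) the aerobic photon LQ parameters, and (ah, bh) the hypoxic
proton parameters obtained by scaling the aerobic RBE-model parameters with
the voxel OER (itself a function of the voxel dose-averaged LET and pO2).
Voxels with zero proton dose have ROWD 0 by convention.

Per-voxel LET_d is accumulated from influence data as the dose-weighted mean
of per-spot LET contributions; (ah, bh) are then evaluated once per voxel at
that LET_d, matching the single-parameter-pair-per-voxel form of the ROWD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigurationError, DomainError
from .grids import VoxelGrid
from .influence import InfluenceData
from .radiobio import (
    OERModelParams,
    RBEModelSpec,
    TissueParams,
    hypoxic_params,
    oer,
    rbe_params_aerobic,
)

__all__ = [
    "DoseSet",
    "letd_from_influence",
    "compute_rowd",
    "rowd_from_dose",
    "evaluate_plan",
    "PlanEvaluation",
    "sensitivity",
]


@dataclass
class DoseSet:
    """Total and proton-only physical dose plus the LET_d grid.

    ``secondary_fraction`` is the constant fraction of total dose carried by
    non-proton secondaries: D_total = D_proton / (1 - secondary_fraction).
    The analytical engine transports primaries only, so the default is 0 and
    D_total == D_proton.
    """

    d_total: VoxelGrid
    d_proton: VoxelGrid
    letd: VoxelGrid
    secondary_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.d_total.assert_aligned(self.d_proton, self.letd)
        if not 0.0 <= self.secondary_fraction < 1.0:
            raise ConfigurationError("secondary_fraction must lie in [0, 1)")
        if np.any(self.d_proton.values > self.d_total.values * (1 + 1e-12)):
            raise ConfigurationError("proton dose cannot exceed total dose")

    @classmethod
    def from_proton_dose(
        cls, d_proton: VoxelGrid, letd: VoxelGrid, secondary_fraction: float = 0.0
    ) -> "DoseSet":
        if not 0.0 <= secondary_fraction < 1.0:
            raise ConfigurationError("secondary_fraction must lie in [0, 1)")
        d_total = d_proton.like(d_proton.values / (1.0 - secondary_fraction))
        return cls(d_total, d_proton, letd, secondary_fraction)


def letd_from_influence(weights: np.ndarray, influence: InfluenceData) -> np.ndarray:
    """Dose-averaged LET per voxel: sum_j w_j n_ij / sum_j w_j d_ij.

    Voxels receiving zero dose get LET_d = 0 by convention. Returns a flat
    array over the influence grid's voxels.
    """
    weights = influence.check_weights(weights)
    num = influence.let_dose @ weights
    den = influence.dose @ weights
    out = np.zeros_like(den)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _lq_photon_equivalent(
    effect_linear: np.ndarray, effect_quadratic: np.ndarray, tissue: TissueParams
) -> np.ndarray:
    """Photon dose with the same LQ effect: positive root of ax*d + bx*d^2 = E."""
    half_ratio = tissue.alpha_x / (2.0 * tissue.beta_x)
    return np.sqrt(half_ratio**2 + (effect_linear + effect_quadratic) / tissue.beta_x) - half_ratio


def rowd_from_dose(
    dp: np.ndarray,
    d_total: np.ndarray,
    alpha_h: np.ndarray,
    beta_h: np.ndarray,
    tissue: TissueParams,
) -> np.ndarray:
    """ROWD from proton dose and per-voxel hypoxic LQ parameters (flat arrays)."""
    if tissue.beta_x == 0:
        raise ConfigurationError("beta_x must be nonzero")
    dp = np.asarray(dp, dtype=float)
    d_total = np.asarray(d_total, dtype=float)
    out = np.zeros_like(dp)
    pos = dp > 0
    if np.any(pos):
        a = np.broadcast_to(np.asarray(alpha_h, dtype=float), dp.shape)[pos]
        b = np.broadcast_to(np.asarray(beta_h, dtype=float), dp.shape)[pos]
        eq = _lq_photon_equivalent(a * dp[pos], b * dp[pos] ** 2, tissue)
        out[pos] = d_total[pos] / dp[pos] * eq
    return out


def compute_rowd(
    doses: DoseSet,
    po2: VoxelGrid | None,
    tissue: TissueParams,
    model: RBEModelSpec,
    oer_params: OERModelParams = OERModelParams(),
) -> VoxelGrid:
    """ROWD grid in Gy(RBE) for one tissue over the whole grid.

    ``po2=None`` disables the OER (all voxels aerobic, OER = 1); otherwise the
    pO2 grid must be aligned with the dose grids.
    """
    if po2 is not None:
        doses.d_proton.assert_aligned(po2)
    letd = doses.letd.flat()
    alpha_rbe, beta_rbe = rbe_params_aerobic(model, letd, tissue)
    if po2 is None:
        alpha_h, beta_h = alpha_rbe, beta_rbe
    else:
        oer_v = oer(letd, po2.flat(), oer_params)
        alpha_h, beta_h = hypoxic_params(alpha_rbe, beta_rbe, oer_v)
    values = rowd_from_dose(
        doses.d_proton.flat(), doses.d_total.flat(), alpha_h, beta_h, tissue
    )
    return doses.d_proton.like(values)


@dataclass
class PlanEvaluation:
    """All per-voxel fields resulting from evaluating spot weights."""

    d_proton: VoxelGrid
    d_total: VoxelGrid
    letd: VoxelGrid
    rowd: VoxelGrid

    @property
    def doses(self) -> DoseSet:
        return DoseSet(self.d_total, self.d_proton, self.letd)


def evaluate_plan(
    weights: np.ndarray,
    influence: InfluenceData,
    geometry: VoxelGrid,
    po2: VoxelGrid | None,
    tissue: TissueParams,
    model: RBEModelSpec | None,
    oer_params: OERModelParams = OERModelParams(),
    secondary_fraction: float = 0.0,
) -> PlanEvaluation:
    """Recalculate dose, LET_d and ROWD grids for a weight vector.

    ``model=None`` yields raw physical dose in the ``rowd`` slot (useful for
    purely physical objectives and reference plans).
    """
    if geometry.n_voxels != influence.n_voxels:
        raise AlignmentError("geometry grid does not match influence voxel count")
    dp_flat = influence.physical_dose(weights)
    letd_flat = letd_from_influence(weights, influence)
    d_proton = geometry.like(dp_flat)
    letd = geometry.like(letd_flat)
    doses = DoseSet.from_proton_dose(d_proton, letd, secondary_fraction)
    if model is None:
        rowd_grid = doses.d_total.like(doses.d_total.values.copy())
    else:
        rowd_grid = compute_rowd(doses, po2, tissue, model, oer_params)
    return PlanEvaluation(doses.d_proton, doses.d_total, doses.letd, rowd_grid)


def sensitivity(
    doses: DoseSet,
    po2: VoxelGrid,
    tissue: TissueParams,
    model: RBEModelSpec,
    oer_params: OERModelParams = OERModelParams(),
    delta_p: float = 1.0,
    delta_l: float = 0.1,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Central finite-difference sensitivity of ROWD to pO2 and LET_d.

    Returns (dROWD/dpO2, dROWD/dLETd) grids in Gy(RBE)/mmHg and
    Gy(RBE)/(keV/um). pO2 is floored at 0 on the downward step.
    """
    if delta_p <= 0 or delta_l <= 0:
        raise DomainError("sensitivity deltas must be > 0")

    def _rowd(po2_vals: np.ndarray, letd_vals: np.ndarray) -> np.ndarray:
        letd_grid = doses.letd.like(letd_vals)
        shifted = DoseSet(doses.d_total, doses.d_proton, letd_grid, doses.secondary_fraction)
        return compute_rowd(shifted, po2.like(po2_vals), tissue, model, oer_params).values

    p = po2.values
    l = doses.letd.values
    p_hi, p_lo = p + delta_p, np.maximum(p - delta_p, 0.0)
    dp_step = (p_hi - p_lo) / 2.0
    d_dp = (_rowd(p_hi, l) - _rowd(p_lo, l)) / (2.0 * dp_step)
    l_hi, l_lo = l + delta_l, np.maximum(l - delta_l, 0.0)
    dl_step = (l_hi - l_lo) / 2.0
    d_dl = (_rowd(p, l_hi) - _rowd(p, l_lo)) / (2.0 * dl_step)
    return po2.like(d_dp), po2.like(d_dl)
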