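"""Iterative dose-difference spot-weight optimization of the ROWD.

The optimizer seeks a homogeneous ROWD equal to the prescription over the
target while keeping constraint structures below their levels. The cost is

    C = mean_{target} (R_i - P)^2
      + sum_{constraints} w_c * mean_c max(0, R_i - level)^2

The update is a damped multiplicative dose-difference step: each spot weight
is scaled by the influence-weighted ratio of effective prescription to
current ROWD over the voxels it sees,

    w_j <- max(w_min, w_j * [sum_i d_ij P_i^eff / sum_i d_ij R_i]^damping)

with P_i^eff = P on target voxels and the constraint level on violated
constraint voxels. The ROWD is nonlinear in the weights, so R is held fixed
within a step and refreshed (together with LET_d and the hypoxic LQ
parameters) between steps. A projected-gradient variant is available behind
``method='gradient'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
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
from .rowd import letd_from_influence, rowd_from_dose

__all__ = ["Objective", "OptimizerConfig", "cost", "step", "optimize", "optimize_weights"]

logger = logging.getLogger(__name__)


@dataclass
class Objective:
    """One planning objective on a voxel mask."""

    mask: np.ndarray
    level: float  # Gy(RBE)
    kind: str = "uniform_target"
    penalty_weight: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool).reshape(-1)
        if self.kind not in ("uniform_target", "max_constraint"):
            raise ConfigurationError(f"unknown objective kind {self.kind!r}")
        if self.kind == "uniform_target" and self.level <= 0:
            raise ConfigurationError("uniform_target level must be > 0")
        if self.penalty_weight < 0:
            raise ConfigurationError("penalty_weight must be >= 0")


@dataclass
class OptimizerConfig:
    """Loop controls. Fully deterministic; ``seed`` reserved for stochastic
    tie-breaking variants (none used by the default method)."""

    max_iters: int = 600
    rel_tol: float = 1e-7
    damping: float = 0.7
    min_weight: float = 0.0
    let_refresh_every: int = 1
    method: str = "dose_difference"
    gradient_step: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise ConfigurationError("rel_tol must be > 0")
        if not 0 < self.damping <= 1:
            raise ConfigurationError("damping must lie in (0, 1]")
        if self.min_weight < 0:
            raise ConfigurationError("min_weight must be >= 0")
        if self.let_refresh_every < 1:
            raise ConfigurationError("let_refresh_every must be >= 1")
        if self.method not in ("dose_difference", "gradient"):
            raise ConfigurationError(f"unknown method {self.method!r}")


def _split_objectives(objectives: list[Objective]) -> tuple[Objective, list[Objective]]:
    targets = [o for o in objectives if o.kind == "uniform_target"]
    if len(targets) != 1:
        raise ConfigurationError("exactly one uniform_target objective is required")
    if not targets[0].mask.any():
        raise ConfigurationError("target mask is empty")
    return targets[0], [o for o in objectives if o.kind == "max_constraint"]


def cost(rowd_values: np.ndarray, objectives: list[Objective]) -> float:
    """Quadratic target term plus one-sided quadratic constraint penalties."""
    r = np.asarray(rowd_values, dtype=float).reshape(-1)
    target, constraints = _split_objectives(objectives)
    if target.mask.size != r.size:
        raise ConfigurationError("objective mask length does not match the grid")
    c = float(np.mean((r[target.mask] - target.level) ** 2))
    for obj in constraints:
        excess = np.maximum(0.0, r[obj.mask] - obj.level)
        c += obj.penalty_weight * float(np.mean(excess**2))
    return c


def step(
    weights: np.ndarray,
    influence: InfluenceData,
    objectives: list[Objective],
    rowd_values: np.ndarray,
    config: OptimizerConfig = OptimizerConfig(),
) -> np.ndarray:
    """One multiplicative dose-difference update given the current ROWD."""
    weights = influence.check_weights(weights)
    r = np.asarray(rowd_values, dtype=float).reshape(-1)
    target, constraints = _split_objectives(objectives)
    p_eff = np.zeros_like(r)
    include = target.mask.copy()
    p_eff[target.mask] = target.level
    for obj in constraints:
        violated = obj.mask & ~target.mask & (r > obj.level)
        p_eff[violated] = obj.level
        include |= violated
    sel = include.astype(float)
    num = influence.dose.T @ (sel * p_eff)
    den = influence.dose.T @ (sel * r)
    ratio = np.ones_like(weights)
    ok = den > 0
    if not np.all(ok | (num == 0)):
        logger.warning("%d spots have zero accumulated ROWD; weights frozen", int((~ok).sum()))
    ratio[ok] = num[ok] / den[ok]
    new = weights * np.where(ok, ratio, 1.0) ** config.damping
    return np.maximum(new, config.min_weight)


def _gradient_step(
    weights: np.ndarray,
    influence: InfluenceData,
    objectives: list[Objective],
    rowd_values: np.ndarray,
    config: OptimizerConfig,
) -> np.ndarray:
    """Projected gradient step treating ROWD as locally linear in dose."""
    r = np.asarray(rowd_values, dtype=float).reshape(-1)
    target, constraints = _split_objectives(objectives)
    residual = np.zeros_like(r)
    residual[target.mask] = 2.0 * (r[target.mask] - target.level) / target.mask.sum()
    for obj in constraints:
        excess = np.maximum(0.0, r[obj.mask] - obj.level)
        residual[obj.mask] += 2.0 * obj.penalty_weight * excess / obj.mask.sum()
    grad = influence.dose.T @ residual
    if config.gradient_step is not None:
        eta = config.gradient_step
    else:
        gnorm = float(np.linalg.norm(grad))
        wnorm = float(np.linalg.norm(weights)) or 1.0
        eta = 0.1 * wnorm / gnorm if gnorm > 0 else 0.0
    return np.maximum(weights - eta * grad, config.min_weight)


def optimize_weights(
    weights: np.ndarray,
    influence: InfluenceData,
    geometry: VoxelGrid,
    po2: VoxelGrid | None,
    tissue: TissueParams,
    model: RBEModelSpec | None,
    objectives: list[Objective],
    config: OptimizerConfig = OptimizerConfig(),
    oer_params: OERModelParams = OERModelParams(),
    secondary_fraction: float = 0.0,
) -> tuple[np.ndarray, list[dict]]:
    """Iterate dose-difference (or gradient) steps until the cost stalls.

    Returns the optimized weights and a per-iteration convergence log with
    cost, target median ROWD and the maximum constraint violation.
    ``model=None`` optimizes raw physical dose; ``po2=None`` disables OER.
    """
    weights = influence.check_weights(weights).copy()
    target, constraints = _split_objectives(objectives)
    if po2 is not None:
        geometry.assert_aligned(po2)
        po2_flat = po2.flat()
    else:
        po2_flat = None

    alpha_h = beta_h = None

    def refresh_biology(w: np.ndarray) -> None:
        nonlocal alpha_h, beta_h
        if model is None:
            return
        letd = letd_from_influence(w, influence)
        a_rbe, b_rbe = rbe_params_aerobic(model, letd, tissue)
        if po2_flat is None:
            alpha_h, beta_h = a_rbe, b_rbe
        else:
            oer_v = oer(letd, po2_flat, oer_params)
            alpha_h, beta_h = hypoxic_params(a_rbe, b_rbe, oer_v)

    def current_rowd(w: np.ndarray) -> np.ndarray:
        dp = influence.physical_dose(w)
        if model is None:
            return dp / (1.0 - secondary_fraction)
        d_total = dp / (1.0 - secondary_fraction)
        return rowd_from_dose(dp, d_total, alpha_h, beta_h, tissue)

    log: list[dict] = []
    prev_cost = None
    refresh_biology(weights)
    for it in range(config.max_iters):
        if model is not None and it > 0 and it % config.let_refresh_every == 0:
            refresh_biology(weights)
        r = current_rowd(weights)
        c = cost(r, objectives)
        if not np.isfinite(c):
            raise RuntimeError(
                f"non-finite cost at iteration {it}: "
                f"weights [{weights.min():g}, {weights.max():g}], "
                f"rowd [{np.nanmin(r):g}, {np.nanmax(r):g}]"
            )
        tgt = r[target.mask]
        viol = 0.0
        for obj in constraints:
            viol = max(viol, float(np.maximum(0.0, r[obj.mask] - obj.level).max(initial=0.0)))
        log.append(
            {
                "iteration": it,
                "cost": c,
                "d50_target": float(np.median(tgt)),
                "max_violation": viol,
            }
        )
        if prev_cost is not None and abs(prev_cost - c) <= config.rel_tol * max(prev_cost, 1e-300):
            break
        prev_cost = c
        if config.method == "gradient":
            weights = _gradient_step(weights, influence, objectives, r, config)
        else:
            weights = step(weights, influence, objectives, r, config)
    return weights, log


def optimize(
    plan,
    influence: InfluenceData,
    geometry: VoxelGrid,
    po2: VoxelGrid | None,
    tissue: TissueParams,
    model: RBEModelSpec | None,
    objectives: list[Objective],
    config: OptimizerConfig = OptimizerConfig(),
    oer_params: OERModelParams = OERModelParams(),
    secondary_fraction: float = 0.0,
):
    """Plan-level wrapper around :func:`optimize_weights`."""
    weights, log = optimize_weights(
        plan.weights,
        influence,
        geometry,
        po2,
        tissue,
        model,
        objectives,
        config,
        oer_params,
        secondary_fraction,
    )
    return plan.with_weights(weights), log
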