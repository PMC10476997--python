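"""High-level study workflows shared by the CLI, tests and analysis scripts.

``run_phantom_study`` reproduces the slabbed-water-phantom experiment for one
plan type: build the phantom, construct the RBE1.1 initial SOBP plan, ROWD-
optimize the spot weights, and report hypoxic-slab dose/LET statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamConfig, Field, InitPlanResult, init_sobp_plan
from .errors import ConfigurationError
from .metrics import d_metric_from_values
from .optimizer import Objective, OptimizerConfig, optimize
from .phantom import PhantomSpec, WaterPhantom, make_water_phantom
from .radiobio import OERModelParams, RBEModelSpec, TARGET_TISSUE, TissueParams
from .rowd import PlanEvaluation, evaluate_plan

__all__ = ["PhantomStudyResult", "phantom_fields", "run_phantom_study", "MODEL_KINDS"]

MODEL_KINDS = {
    "rbe11": ("constant_1p1", False),
    "rbe11_oer": ("constant_1p1", True),
    "mcn_oer": ("MCN", True),
    "ror_oer": ("ROR_approx", True),
}


def phantom_fields(kind: str) -> list[Field]:
    if kind == "single":
        return [Field("F1", "+z")]
    if kind == "opposing":
        return [Field("F1", "+z"), Field("F2", "-z")]
    raise ConfigurationError("field arrangement must be 'single' or 'opposing'")


@dataclass
class PhantomStudyResult:
    phantom: WaterPhantom
    init: InitPlanResult
    plan: object
    log: list[dict]
    evaluation: PlanEvaluation
    reference: PlanEvaluation  # the RBE1.1 initial plan, evaluated physically

    def _central_axis_mask(self) -> tuple[int, int, np.ndarray]:
        mask = self.phantom.target_mask.values.astype(bool)
        ci, cj = mask.shape[0] // 2, mask.shape[1] // 2
        return ci, cj, mask[ci, cj, :]

    @property
    def max_physical_dose_hypoxic_slab(self) -> float:
        hyp = self.phantom.most_hypoxic_slab_mask()
        return float(self.evaluation.d_proton.values[hyp].max())

    @property
    def max_letd_central_axis(self) -> float:
        ci, cj, zmask = self._central_axis_mask()
        return float(self.evaluation.letd.values[ci, cj, zmask].max())

    @property
    def median_target_rowd(self) -> float:
        mask = self.phantom.target_mask.values.astype(bool)
        return d_metric_from_values(self.evaluation.rowd.values[mask], 0.5)


def run_phantom_study(
    fields_kind: str = "single",
    model_name: str = "rbe11_oer",
    prescription: float = 2.0,
    phantom_spec: PhantomSpec = PhantomSpec(),
    beam_config: BeamConfig = BeamConfig(),
    optimizer_config: OptimizerConfig | None = None,
    oer_params: OERModelParams = OERModelParams(),
    tissue: TissueParams = TARGET_TISSUE,
    init_result: InitPlanResult | None = None,
    phantom: WaterPhantom | None = None,
) -> PhantomStudyResult:
    """End-to-end phantom experiment for one of the four plan types.

    Pass ``phantom``/``init_result`` to reuse the fixture and the initial
    plan (and its influence matrices) across plan types.
    """
    if model_name not in MODEL_KINDS:
        raise ConfigurationError(
            f"model must be one of {sorted(MODEL_KINDS)}, got {model_name!r}"
        )
    kind, oer_enabled = MODEL_KINDS[model_name]
    model = RBEModelSpec.from_kind(kind)
    opt_config = optimizer_config or OptimizerConfig()
    phantom = phantom or make_water_phantom(phantom_spec)
    if init_result is None:
        init_result = init_sobp_plan(
            phantom.target_mask,
            phantom_fields(fields_kind),
            prescription,
            beam_config,
            opt_config,
        )
    influence = init_result.influence
    target_mask = phantom.target_mask.values.astype(bool)
    objectives = [Objective(mask=target_mask, level=prescription)]
    po2 = phantom.po2 if oer_enabled else None
    plan, log = optimize(
        init_result.plan,
        influence,
        phantom.target_mask,
        po2,
        tissue,
        model,
        objectives,
        opt_config,
        oer_params,
    )
    evaluation = evaluate_plan(
        plan.weights, influence, phantom.target_mask, po2, tissue, model, oer_params
    )
    reference = evaluate_plan(
        init_result.plan.weights,
        influence,
        phantom.target_mask,
        None,
        tissue,
        RBEModelSpec("constant_1p1"),
    )
    return PhantomStudyResult(phantom, init_result, plan, log, evaluation, reference)
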