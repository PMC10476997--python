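"""Dose-difference optimizer: cost, single steps, convergence properties."""

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import brentq

from rowdplan.errors import ConfigurationError
from rowdplan.grids import VoxelGrid
from rowdplan.influence import InfluenceData
from rowdplan.optimizer import Objective, OptimizerConfig, cost, optimize_weights, step
from rowdplan.phantom import PhantomSpec, make_water_phantom
from rowdplan.radiobio import OERModelParams, RBEModelSpec, TARGET_TISSUE
from rowdplan.rowd import rowd_from_dose
from rowdplan.workflows import phantom_fields, run_phantom_study
from rowdplan.beam import init_sobp_plan


def one_voxel_influence(d=0.5, let=6.0):
    dm = sparse.csr_matrix(np.array([[d]]))
    nm = sparse.csr_matrix(np.array([[let * d]]))
    return InfluenceData(dm, nm, (1, 1, 1))


class TestCost:
    def test_zero_when_target_met_and_constraints_satisfied(self):
        r = np.full(10, 2.0)
        objs = [
            Objective(mask=np.ones(10, bool), level=2.0),
            Objective(mask=np.zeros(10, bool) | (np.arange(10) < 3), level=2.5, kind="max_constraint"),
        ]
        assert cost(r, objs) == 0.0

    def test_unit_offset_gives_unit_quadratic(self):
        r = np.full(7, 3.0)
        assert cost(r, [Objective(mask=np.ones(7, bool), level=2.0)]) == pytest.approx(1.0)

    def test_matches_brute_force_loop(self, rng):
        r = rng.uniform(0.0, 4.0, size=10)
        tmask = rng.uniform(size=10) < 0.6
        tmask[0] = True
        cmask = rng.uniform(size=10) < 0.4
        objs = [
            Objective(mask=tmask, level=2.0),
            Objective(mask=cmask, level=1.5, kind="max_constraint", penalty_weight=0.7),
        ]
        expected = sum((r[i] - 2.0) ** 2 for i in range(10) if tmask[i]) / tmask.sum()
        if cmask.any():
            expected += 0.7 * sum(
                max(0.0, r[i] - 1.5) ** 2 for i in range(10) if cmask[i]
            ) / cmask.sum()
        assert cost(r, objs) == pytest.approx(expected, rel=1e-12)

    def test_requires_exactly_one_target(self):
        with pytest.raises(ConfigurationError):
            cost(np.ones(3), [Objective(mask=np.ones(3, bool), level=1.0, kind="max_constraint")])


class TestStep:
    def test_fixed_point_when_rowd_equals_prescription(self):
        infl = one_voxel_influence()
        objs = [Objective(mask=np.ones(1, bool), level=2.0)]
        w = np.array([1.3])
        new = step(w, infl, objs, np.array([2.0]))
        np.testing.assert_allclose(new, w, rtol=1e-14)

    def test_physical_objective_lands_exactly_in_one_undamped_step(self):
        d = 0.5
        infl = one_voxel_influence(d=d)
        objs = [Objective(mask=np.ones(1, bool), level=2.0)]
        w = np.array([1.0])
        r = infl.physical_dose(w)  # physical-dose-only objective
        new = step(w, infl, objs, r, OptimizerConfig(damping=1.0))
        assert new[0] == pytest.approx(2.0 / d, rel=1e-12)

    def test_weights_respect_min_weight_floor(self):
        infl = one_voxel_influence()
        objs = [Objective(mask=np.ones(1, bool), level=0.01)]
        cfg = OptimizerConfig(damping=1.0, min_weight=0.5)
        new = step(np.array([1.0]), infl, objs, np.array([5.0]), cfg)
        assert new[0] == 0.5


class TestOptimize:
    def geometry(self):
        return VoxelGrid(np.zeros((1, 1, 1)))

    def test_single_voxel_rowd_matches_bisection_oracle(self):
        d, let, p_voxel = 0.5, 6.0, 2.5
        infl = one_voxel_influence(d=d, let=let)
        po2 = self.geometry().like(np.array([[[p_voxel]]]))
        model = RBEModelSpec("constant_1p1")
        params = OERModelParams()
        objs = [Objective(mask=np.ones(1, bool), level=2.0)]
        w, _ = optimize_weights(
            np.array([1.0]), infl, self.geometry(), po2, TARGET_TISSUE, model, objs,
            OptimizerConfig(max_iters=500, rel_tol=1e-14, damping=1.0),
        )

        from rowdplan.radiobio import hypoxic_params, oer, rbe_params_aerobic

        def rowd_of_weight(wv):
            a, b = rbe_params_aerobic(model, let, TARGET_TISSUE)
            ah, bh = hypoxic_params(a, b, oer(let, p_voxel, params))
            return rowd_from_dose(np.array([wv * d]), np.array([wv * d]), ah, bh, TARGET_TISSUE)[0]

        w_star = brentq(lambda x: rowd_of_weight(x) - 2.0, 1e-6, 1e3, xtol=1e-12)
        assert abs(w[0] - w_star) / w_star < 1e-6

    def test_uniform_reference_po2_is_equivalent_to_oer_off(self, mini_phantom_spec):
        spec = PhantomSpec(
            shape=mini_phantom_spec.shape,
            target_size_mm=mini_phantom_spec.target_size_mm,
            target_depth_mm=mini_phantom_spec.target_depth_mm,
            slab_po2_mmhg=(30.0,) * 7,
            background_po2_mmhg=30.0,
        )
        ph = make_water_phantom(spec)
        cfg = OptimizerConfig(max_iters=60)
        res = init_sobp_plan(ph.target_mask, phantom_fields("single"), 2.0, optimizer_config=cfg)
        objs = [Objective(mask=ph.target_mask.values.astype(bool), level=2.0)]
        model = RBEModelSpec("constant_1p1")
        w_on, _ = optimize_weights(
            res.plan.weights, res.influence, ph.target_mask, ph.po2, TARGET_TISSUE, model, objs, cfg
        )
        w_off, _ = optimize_weights(
            res.plan.weights, res.influence, ph.target_mask, None, TARGET_TISSUE, model, objs, cfg
        )
        dose_on = res.influence.physical_dose(w_on)
        dose_off = res.influence.physical_dose(w_off)
        assert np.max(np.abs(dose_on - dose_off)) <= 1e-6

    def test_constraint_voxels_pull_dose_down(self):
        # two voxels, one spot: the OAR voxel above its level lowers the weight
        d = sparse.csr_matrix(np.array([[1.0], [0.8]]))
        n = sparse.csr_matrix(np.array([[2.0], [1.6]]))
        infl = InfluenceData(d, n, (2, 1, 1))
        objs_free = [Objective(mask=np.array([True, False]), level=2.0)]
        objs_con = objs_free + [
            Objective(mask=np.array([False, True]), level=1.0, kind="max_constraint", penalty_weight=1.0)
        ]
        geometry = VoxelGrid(np.zeros((2, 1, 1)))
        cfg = OptimizerConfig(max_iters=200, damping=1.0)
        w_free, _ = optimize_weights(np.array([1.0]), infl, geometry, None, TARGET_TISSUE, None, objs_free, cfg)
        w_con, _ = optimize_weights(np.array([1.0]), infl, geometry, None, TARGET_TISSUE, None, objs_con, cfg)
        assert w_con[0] < w_free[0]

    def test_prescription_scaling_scales_physical_dose(self, mini_phantom_spec):
        ph = make_water_phantom(mini_phantom_spec)
        cfg = OptimizerConfig(max_iters=150)
        res = init_sobp_plan(ph.target_mask, phantom_fields("single"), 2.0, optimizer_config=cfg)
        mask = ph.target_mask.values.astype(bool)
        model = RBEModelSpec("constant_1p1")
        means = {}
        for pres in (2.0, 1.0):
            objs = [Objective(mask=mask, level=pres)]
            w, _ = optimize_weights(
                res.plan.weights * pres / 2.0, res.influence, ph.target_mask, ph.po2,
                TARGET_TISSUE, model, objs, cfg,
            )
            means[pres] = res.influence.physical_dose(w)[mask.reshape(-1)].mean()
        ratio = means[1.0] / means[2.0]
        assert abs(ratio - 0.5) < 0.05 * 0.5 + 0.03  # LQ nonlinearity bound

    def test_gradient_variant_reduces_cost(self, mini_phantom_spec):
        ph = make_water_phantom(mini_phantom_spec)
        cfg0 = OptimizerConfig(max_iters=40)
        res = init_sobp_plan(ph.target_mask, phantom_fields("single"), 2.0, optimizer_config=cfg0)
        mask = ph.target_mask.values.astype(bool)
        objs = [Objective(mask=mask, level=2.0)]
        w0 = res.plan.weights * 0.8
        cfg = OptimizerConfig(max_iters=30, method="gradient")
        _, log = optimize_weights(
            w0, res.influence, ph.target_mask, None, TARGET_TISSUE, RBEModelSpec("constant_1p1"), objs, cfg
        )
        assert log[-1]["cost"] < log[0]["cost"]
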