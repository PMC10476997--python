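"""ROWD accumulation: LET_d mixing, the photon-equivalent dose, sensitivity."""

import math

import numpy as np
import pytest
from scipy import sparse

from rowdplan.errors import AlignmentError, DomainError
from rowdplan.grids import VoxelGrid
from rowdplan.influence import InfluenceData
from rowdplan.radiobio import OERModelParams, RBEModelSpec, TissueParams, oer
from rowdplan.rowd import (
    DoseSet,
    compute_rowd,
    letd_from_influence,
    rowd_from_dose,
    sensitivity,
)

from conftest import random_influence


def grid(values, spacing=(2.0, 2.0, 2.0)):
    return VoxelGrid(np.asarray(values, dtype=float), spacing)


def rowd_oracle(dp, d, alpha_h, beta_h, ax, bx):
    """Independent scalar evaluation of the photon-equivalent dose."""
    if dp == 0:
        return 0.0
    c = ax / (2.0 * bx)
    return d / dp * (math.sqrt(c * c + (alpha_h * dp + beta_h * dp * dp) / bx) - c)


class TestLetdAccumulation:
    def test_single_spot_weight_cancels(self):
        d = sparse.csr_matrix(np.array([[0.5], [1.0], [0.0]]))
        n = sparse.csr_matrix(np.array([[0.5 * 3.0], [1.0 * 7.0], [0.0]]))
        infl = InfluenceData(d, n, (3, 1, 1))
        letd = letd_from_influence([2.7], infl)
        assert letd[0] == pytest.approx(3.0, rel=1e-14)
        assert letd[1] == pytest.approx(7.0, rel=1e-14)
        assert letd[2] == 0.0  # zero-dose convention

    def test_equal_dose_spots_average_their_let(self):
        d = sparse.csr_matrix(np.array([[1.0, 1.0]]))
        n = sparse.csr_matrix(np.array([[2.0, 6.0]]))
        infl = InfluenceData(d, n, (1, 1, 1))
        assert letd_from_influence([1.0, 1.0], infl)[0] == pytest.approx(4.0, rel=1e-14)

    def test_matches_dense_double_loop(self, rng):
        infl, d, let = random_influence(rng)
        w = rng.uniform(0.0, 2.0, size=d.shape[1])
        letd = letd_from_influence(w, infl)
        for i in range(d.shape[0]):
            num = sum(w[j] * let[i, j] * d[i, j] for j in range(d.shape[1]))
            den = sum(w[j] * d[i, j] for j in range(d.shape[1]))
            expected = num / den if den > 0 else 0.0
            assert letd[i] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_spot_permutation_invariance(self, rng):
        infl, d, let = random_influence(rng, n_vox=20, n_spots=8)
        w = rng.uniform(0.1, 2.0, size=8)
        perm = rng.permutation(8)
        infl_p = InfluenceData(infl.dose[:, perm], infl.let_dose[:, perm], infl.grid_shape)
        a = letd_from_influence(w, infl)
        b = letd_from_influence(w[perm], infl_p)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_negative_weights_rejected(self, small_influence):
        infl, _, _ = small_influence
        with pytest.raises(DomainError):
            letd_from_influence([-1.0] * infl.n_spots, infl)


class TestComputeRowd:
    tissue = TissueParams(0.10, 0.010)

    def _doses(self, dp, letd=2.0, secondary_fraction=0.0):
        dpg = grid(np.full((2, 2, 2), dp))
        return DoseSet.from_proton_dose(dpg, dpg.like(np.full((2, 2, 2), letd)), secondary_fraction)

    def test_aerobic_photon_parameters_give_identity(self):
        # alpha_h = alpha_x, beta_h = beta_x collapses the expression to Dp
        out = rowd_from_dose(
            np.array([0.0, 0.5, 2.0, 7.3]),
            np.array([0.0, 0.5, 2.0, 7.3]),
            self.tissue.alpha_x,
            self.tissue.beta_x,
            self.tissue,
        )
        np.testing.assert_allclose(out, [0.0, 0.5, 2.0, 7.3], rtol=1e-12)

    def test_constant_rbe_with_unit_oer_is_perfect_square(self, rng):
        dp = rng.uniform(0.1, 4.0, size=50)
        a = 1.1 * self.tissue.alpha_x
        b = 1.1**2 * self.tissue.beta_x
        out = rowd_from_dose(dp, dp, a, b, self.tissue)
        np.testing.assert_allclose(out, 1.1 * dp, rtol=1e-10)

    def test_normoxic_grid_2gy_gives_2p2(self):
        doses = self._doses(2.0)
        po2 = doses.d_proton.like(np.full((2, 2, 2), 160.0))
        out = compute_rowd(doses, po2, self.tissue, RBEModelSpec("constant_1p1"))
        np.testing.assert_allclose(out.values, 2.2, rtol=1e-10)

    def test_hypoxic_voxel_matches_scalar_oracle(self):
        params = OERModelParams()
        doses = self._doses(2.0, letd=5.0)
        po2 = doses.d_proton.like(np.full((2, 2, 2), 2.5))
        out = compute_rowd(doses, po2, self.tissue, RBEModelSpec("constant_1p1"), params)
        o = oer(5.0, 2.5, params)
        expected = rowd_oracle(
            2.0, 2.0, 1.1 * self.tissue.alpha_x / o, 1.1**2 * self.tissue.beta_x / o**2,
            self.tissue.alpha_x, self.tissue.beta_x,
        )
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_strictly_increasing_in_proton_dose(self):
        dp = np.linspace(0.01, 10.0, 200)
        out = rowd_from_dose(dp, dp, 0.08, 0.006, self.tissue)
        assert np.all(np.diff(out) > 0)

    def test_vanishes_as_oer_grows(self):
        out = rowd_from_dose(np.array([2.0]), np.array([2.0]), 1e-9, 1e-18, self.tissue)
        assert out[0] < 1e-6

    def test_secondary_fraction_scales_leading_ratio(self):
        with_sec = self._doses(2.0, secondary_fraction=0.1)
        assert np.allclose(with_sec.d_total.values, 2.0 / 0.9)
        po2 = with_sec.d_proton.like(np.full((2, 2, 2), 160.0))
        out = compute_rowd(with_sec, po2, self.tissue, RBEModelSpec("constant_1p1"))
        np.testing.assert_allclose(out.values, (1.0 / 0.9) * 2.2, rtol=1e-10)

    def test_misaligned_po2_rejected(self):
        doses = self._doses(2.0)
        po2 = VoxelGrid(np.full((2, 2, 2), 30.0), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(AlignmentError):
            compute_rowd(doses, po2, self.tissue, RBEModelSpec("constant_1p1"))


class TestSensitivity:
    tissue = TissueParams(0.10, 0.010)

    def _setup(self, po2_value, letd=5.0):
        dp = grid(np.full((1, 1, 2), 2.0))
        doses = DoseSet.from_proton_dose(dp, dp.like(np.full((1, 1, 2), letd)))
        po2 = dp.like(np.full((1, 1, 2), po2_value))
        return doses, po2

    def test_normoxic_voxels_have_zero_oxygen_sensitivity(self):
        doses, po2 = self._setup(120.0)
        d_dp, _ = sensitivity(doses, po2, self.tissue, RBEModelSpec("constant_1p1"))
        np.testing.assert_allclose(d_dp.values, 0.0, atol=1e-14)

    def test_hypoxic_voxels_gain_effect_with_oxygen(self):
        doses, po2 = self._setup(2.5)
        d_dp, _ = sensitivity(doses, po2, self.tissue, RBEModelSpec("constant_1p1"))
        assert np.all(d_dp.values > 0)

    def test_matches_symbolic_derivative_on_one_voxel(self):
        sympy = pytest.importorskip("sympy")
        params = OERModelParams()
        L_val, p_val, dp_val = 5.0, 2.5, 2.0
        L, p = sympy.symbols("L p", positive=True)
        a = ((params.a1 + params.a2 * L) * p + (params.a3 + params.a4 * L) * params.K) / (p + params.K)
        b_expr = (params.b1 * p + params.b2 * params.K) / (p + params.K)
        b = b_expr**2
        ln_s = sympy.log(sympy.Rational(1, 10))
        d10 = (sympy.sqrt(a**2 - 4 * b * ln_s) - a) / (2 * b)
        oer_expr = d10 / d10.subs(p, params.p_a)
        ax, bx = self.tissue.alpha_x, self.tissue.beta_x
        ah = 1.1 * ax / oer_expr
        bh = 1.1**2 * bx / oer_expr**2
        c = ax / (2 * bx)
        rowd_expr = sympy.sqrt(c**2 + (ah * dp_val + bh * dp_val**2) / bx) - c
        expected = float(sympy.diff(rowd_expr, p).subs({L: L_val, p: p_val}))
        doses, po2 = self._setup(p_val, letd=L_val)
        d_dp, _ = sensitivity(doses, po2, self.tissue, RBEModelSpec("constant_1p1"), delta_p=1e-3)
        np.testing.assert_allclose(d_dp.values, expected, rtol=1e-5)
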