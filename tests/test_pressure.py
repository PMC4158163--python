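import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmps.constants import PA_PER_CMH2O, DEFAULT_CONSTANTS, ModelConstants
from abmps.geometry import AirwayGeneration, build_default_tree, per_branch_flow, scale_tree
from abmps.pressure import (
    drop_waveform,
    generation_resistance,
    lumped_coefficients,
    minor_loss_drop,
    poiseuille_drop,
    reynolds_profile,
    total_drop,
)


def poiseuille_oracle(d_mm, l_mm, q_lps, mu=DEFAULT_CONSTANTS.mu):
    """Scalar hand evaluation in SI, converted to cmH2O."""
    d, length, q = d_mm / 1e3, l_mm / 1e3, q_lps / 1e3
    return 128.0 * mu * length * q / (math.pi * d**4) / PA_PER_CMH2O


def minor_oracle(d_mm, q_lps, k_l=2.0, rho=1.25):
    d, q = d_mm / 1e3, q_lps / 1e3
    return (8.0 * k_l * rho / math.pi**2) * q * abs(q) / d**4 / PA_PER_CMH2O


class TestSingleBranchDrops:
    @pytest.mark.parametrize(
        "d, l, q",
        [(18.0, 120.0, 0.5), (9.0, 330.0, 0.5), (0.6, 1.7, 0.01), (12.2, 48.0, -0.3)],
    )
    def test_poiseuille_matches_hand_evaluation(self, d, l, q):
        gen = AirwayGeneration(0, d, l)
        assert poiseuille_drop(gen, q) == pytest.approx(poiseuille_oracle(d, l, q))

    def test_poiseuille_reference_magnitudes(self, tree):
        # trachea and ETT at a mid-inspiratory 0.5 L/s (frozen from the oracle)
        assert poiseuille_drop(tree[0], 0.5) == pytest.approx(0.0045118458, rel=1e-6)
        assert poiseuille_drop(tree[-1], 0.5) == pytest.approx(0.1985212169, rel=1e-6)

    def test_minor_loss_reference_magnitude(self, tree):
        assert minor_loss_drop(tree[-1], 0.5) == pytest.approx(0.7873712367, rel=1e-6)
        assert minor_loss_drop(tree[-1], -0.5) == pytest.approx(-0.7873712367, rel=1e-6)

    def test_zero_flow(self, tree):
        assert poiseuille_drop(tree[3], 0.0) == 0.0
        assert minor_loss_drop(tree[3], 0.0) == 0.0

    @given(
        d=st.floats(0.4, 20.0),
        l=st.floats(0.5, 330.0),
        q=st.floats(-1.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_major_loss_derivation_equals_poiseuille(self, d, l, q):
        # Darcy-Weisbach major loss with laminar f = 64/Re collapses onto the
        # Poiseuille form; check to machine precision against the derivation chain
        gen = AirwayGeneration(0, d, l)
        d_m, l_m, q_m3 = d / 1e3, l / 1e3, q / 1e3
        v = 4.0 * q_m3 / (math.pi * d_m**2)
        if v == 0:
            assert poiseuille_drop(gen, q) == 0.0
            return
        re = DEFAULT_CONSTANTS.rho * abs(v) * d_m / DEFAULT_CONSTANTS.mu
        f = 64.0 / re
        dp_major = f * (l_m / d_m) * DEFAULT_CONSTANTS.rho * v * abs(v) / 2.0
        assert poiseuille_drop(gen, q) == pytest.approx(
            dp_major / PA_PER_CMH2O, rel=1e-12
        )


class TestTotalDrop:
    def test_zero_flow(self, tree):
        prof = total_drop(tree, 0.0)
        assert prof.total == 0.0
        assert np.all(prof.per_generation == 0.0)

    def test_matches_brute_force_sum(self, tree):
        # independent scalar loop over generations, pure-python math
        q_in = 0.5
        expected = 0.0
        for g in tree.generations:
            qb = per_branch_flow(q_in, g.n)
            expected += poiseuille_oracle(g.diameter, g.length, qb)
            expected += minor_oracle(g.diameter, qb)
        prof = total_drop(tree, q_in)
        assert prof.total == pytest.approx(expected, rel=1e-12)

    def test_total_is_sum_of_parts(self, tree):
        prof = total_drop(tree, 0.73)
        assert prof.total == pytest.approx(
            float(np.sum(prof.poiseuille) + np.sum(prof.minor)), rel=1e-14
        )

    @given(
        alpha=st.floats(0.45, 1.5),
        q=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_alpha_scaling(self, alpha, q):
        tree = build_default_tree()
        scaled = scale_tree(tree, alpha)
        assert total_drop(scaled, q).total == pytest.approx(
            total_drop(tree, q).total / alpha**4, rel=1e-10, abs=1e-15
        )

    def test_half_diameter_sixteenfold(self, tree):
        assert total_drop(scale_tree(tree, 0.5), 0.4).total == pytest.approx(
            16.0 * total_drop(tree, 0.4).total, rel=1e-12
        )

    @given(q=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, q):
        tree = build_default_tree()
        assert total_drop(tree, -q).total == pytest.approx(
            -total_drop(tree, q).total, rel=1e-12
        )


class TestDropWaveform:
    def test_zero_and_constant_series(self, tree):
        np.testing.assert_array_equal(drop_waveform(tree, np.zeros(5)), np.zeros(5))
        const = drop_waveform(tree, np.full(7, 0.5))
        np.testing.assert_allclose(const, total_drop(tree, 0.5).total, rtol=1e-12)

    def test_scaling_identity_elementwise(self, tree):
        q = np.linspace(-1.0, 1.0, 21)
        scaled = scale_tree(tree, 0.7)
        np.testing.assert_allclose(
            drop_waveform(scaled, q), drop_waveform(tree, q) / 0.7**4, rtol=1e-10
        )

    def test_empty_series_rejected(self, tree):
        with pytest.raises(ValueError, match="empty"):
            drop_waveform(tree, np.array([]))


class TestGenerationResistance:
    def test_linear_regime_flow_independent(self, tree, constants_linear):
        r1 = generation_resistance(tree, 0.2, constants_linear)
        r2 = generation_resistance(tree, 0.9, constants_linear)
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_ett_exceeds_trachea(self, tree):
        r = generation_resistance(tree, 0.5)
        assert r[0] > r[1]  # ETT (L/D^4 = 330/9^4) dominates trachea (120/18^4)

    def test_alpha_scaling(self, tree):
        r1 = generation_resistance(tree, 0.5)
        r2 = generation_resistance(scale_tree(tree, 0.45), 0.5)
        np.testing.assert_allclose(r2, r1 / 0.45**4, rtol=1e-10)

    def test_zero_flow_raises(self, tree):
        with pytest.raises(ZeroDivisionError, match="Poiseuille"):
            generation_resistance(tree, 0.0)


class TestReynolds:
    def test_zero_flow_all_laminar(self, tree):
        states = reynolds_profile(tree, 0.0)
        assert all(s.reynolds == 0.0 and s.laminar for s in states)

    def test_tracheal_reynolds_back_solved(self, tree):
        # Re = 4 rho Q / (pi D mu); 0.167 L/s reproduces the tabulated ~775
        states = reynolds_profile(tree, 0.167)
        assert states[1].n == 0
        assert states[1].reynolds == pytest.approx(775.0, rel=0.01)

    def test_high_flow_ett_not_laminar(self, tree):
        states = reynolds_profile(tree, 1.0)
        assert states[0].n == -1
        assert states[0].reynolds > 2000 and not states[0].laminar

    def test_friction_factor_identity(self, tree):
        for s in reynolds_profile(tree, 0.3):
            if s.reynolds > 0:
                assert s.friction_factor * s.reynolds == pytest.approx(64.0)


def test_lumped_coefficients_reproduce_total(tree):
    a, b = lumped_coefficients(tree)
    for q in (0.1, 0.5, -0.8):
        assert a * q + b * q * abs(q) == pytest.approx(
            total_drop(tree, q).total, rel=1e-12
        )


def test_minor_loss_off_is_linear(tree):
    constants = ModelConstants(k_l=0.0)
    a, b = lumped_coefficients(tree, constants)
    assert b == 0.0
    assert total_drop(tree, 0.6, constants).total == pytest.approx(a * 0.6, rel=1e-12)
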