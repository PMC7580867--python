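"""Acid-base engine: dissociation fractions, pH solving, titration curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phlux as px
from phlux.chemistry import model_titration, solve_ph_many
from phlux.errors import DataError, OperatingRangeError, SolverError

from conftest import random_buffer_system


class TestDeprotonatedFraction:
    @pytest.mark.parametrize(
        "ph,pka,expected,tol",
        [
            (5.75, 3.8, 0.9889, 5e-5),    # lactate: ~99% deprotonated
            (5.75, 4.75, 10.0 / 11.0, 1e-12),  # acetate: >90%
            (5.75, 3.75, 0.9901, 5e-5),   # formate: >99%
            (6.2, 6.2, 0.5, 0.0),         # half-dissociation at the pKa
        ],
    )
    def test_worked_values(self, ph, pka, expected, tol):
        assert px.deprotonated_fraction(ph, pka) == pytest.approx(expected, abs=tol)

    @settings(derandomize=True, max_examples=100)
    @given(
        ph=st.floats(0.0, 14.0),
        pka=st.floats(0.0, 14.0),
        delta=st.floats(0.01, 2.0),
    )
    def test_monotone_in_ph_and_neg_pka(self, ph, pka, delta):
        f = px.deprotonated_fraction
        assert 0.0 <= f(ph, pka) <= 1.0
        assert f(ph + delta, pka) >= f(ph, pka)
        assert f(ph, pka + delta) <= f(ph, pka)
        if abs(ph - pka) < 8.0:  # strict away from float saturation
            assert f(ph + delta, pka) > f(ph, pka)
            assert f(ph, pka + delta) < f(ph, pka)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            px.deprotonated_fraction(np.nan, 4.0)


class TestProtonEquivalent:
    @pytest.mark.parametrize("ph,expected", [(7.0, 1e-7), (6.5, 10**-6.5), (4.0, 1e-4)])
    def test_definition(self, ph, expected):
        assert px.proton_equivalent(ph) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ph", [0.0, 14.0, -1.0, 15.0])
    def test_domain(self, ph):
        with pytest.raises(OperatingRangeError):
            px.proton_equivalent(ph)


class TestSolvePh:
    def test_pure_water(self):
        assert px.solve_ph(px.BufferSystem()) == pytest.approx(7.0, abs=1e-6)

    def test_half_neutralized_buffer_sits_at_pka(self):
        sp = px.ProtolyteSpecies("buf", (7.2,), 0.020)
        system = px.BufferSystem(species=(sp,), strong_acid_added=-0.010)
        assert px.solve_ph(system) == pytest.approx(7.2, abs=0.01)

    def test_agrees_with_grid_scan_oracle(self):
        # 20 mM monoprotic pKa 7.2 poised at 6.5, then +1 mM strong acid
        sp = px.ProtolyteSpecies("buf", (7.2,), 0.020)
        system = px.BufferSystem(species=(sp,)).poised_at(6.5).with_added_acid(0.001)
        grid = np.arange(0.0 + 1e-5, 14.0, 1e-5)
        resid = system.charge_imbalance(grid)
        oracle = grid[np.argmin(np.abs(resid))]
        assert px.solve_ph(system) == pytest.approx(oracle, abs=1e-4)

    def test_randomized_systems_match_grid_scan(self):
        rng = np.random.default_rng(42)
        grid = np.arange(1e-5, 14.0, 1e-5)
        for _ in range(10):
            system = random_buffer_system(rng)
            resid = system.charge_imbalance(grid)
            oracle = grid[np.argmin(np.abs(resid))]
            assert px.solve_ph(system) == pytest.approx(oracle, abs=1e-4)

    def test_adding_strong_acid_never_raises_ph(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            system = random_buffer_system(rng)
            ph0 = px.solve_ph(system)
            ph1 = px.solve_ph(system.with_added_acid(float(rng.uniform(0, 0.05))))
            assert ph1 <= ph0 + 1e-9

    def test_poised_at_hits_target(self):
        system = px.default_assay_medium().poised_at(6.5)
        assert px.solve_ph(system) == pytest.approx(6.5, abs=1e-6)

    def test_malformed_system_raises(self):
        # more strong acid than any root in (0, 14) can balance
        with pytest.raises(SolverError):
            px.solve_ph(px.BufferSystem(strong_acid_added=2.0))

    def test_vectorized_solver_matches_scalar(self):
        system = px.default_assay_medium(6.5)
        additions = np.array([0.0, 0.002, 0.01, 0.02])
        vec = solve_ph_many(system, additions)
        scalar = [px.solve_ph(system.with_added_acid(x)) for x in additions]
        np.testing.assert_allclose(vec, scalar, atol=1e-8)


class TestProtolyteSpecies:
    def test_invariants(self):
        with pytest.raises(ValueError):
            px.ProtolyteSpecies("x", (), 0.01)
        with pytest.raises(ValueError):
            px.ProtolyteSpecies("x", (7.0, 5.0), 0.01)
        with pytest.raises(ValueError):
            px.ProtolyteSpecies("x", (7.0,), -0.01)

    def test_state_fractions_sum_to_one(self):
        sp = px.ProtolyteSpecies("phos", (2.15, 7.20, 12.35), 0.02)
        ph = np.linspace(0.5, 13.5, 50)
        np.testing.assert_allclose(sp.state_fractions(ph).sum(axis=-1), 1.0)


class TestModelTitration:
    def test_single_point_grid_is_resting_ph(self):
        system = px.default_assay_medium(6.5)
        curve = model_titration(system, "acid", [0.0], required_ph_window=None)
        assert curve.ph[0] == pytest.approx(6.5, abs=1e-6)
        assert curve.added_equivalents[0] == 0.0

    def test_default_acid_curve_spans_assay_window(self, acid_titration):
        assert np.all(np.diff(acid_titration.ph) < 0)
        lo, hi = acid_titration.ph_range
        assert lo <= 4.0 and hi >= 6.5

    def test_default_base_curve_spans_assay_window(self, base_titration):
        assert np.all(np.diff(base_titration.ph) > 0)
        lo, hi = base_titration.ph_range
        assert lo <= 5.5 and hi >= 7.0

    def test_short_grid_fails_window_check(self):
        system = px.default_assay_medium(6.5)
        with pytest.raises(OperatingRangeError, match="grid"):
            model_titration(system, "acid", np.linspace(0.0, 0.002, 10))

    def test_grid_validation(self):
        system = px.default_assay_medium(6.5)
        with pytest.raises(ValueError):
            model_titration(system, "acid", [0.001, 0.002])
        with pytest.raises(ValueError):
            model_titration(system, "acid", [0.0, 0.002, 0.001])


class TestProductionFromPh:
    def test_anchor_point_is_zero(self, acid_titration):
        assert acid_titration.production_from_ph(acid_titration.start_ph) == 0.0

    def test_tabulated_point_identity(self, acid_titration):
        i = 100
        out = acid_titration.production_from_ph(float(acid_titration.ph[i]))
        assert out == pytest.approx(float(acid_titration.added_equivalents[i]), abs=1e-12)

    def test_halfway_point_matches_direct_reinterpolation(self, acid_titration):
        # halfway in log10 proton-equivalent space between two nodes
        u = -acid_titration.ph
        eq = acid_titration.added_equivalents
        i = 150
        u_mid = 0.5 * (u[i] + u[i + 1])
        expected = eq[i] + (u_mid - u[i]) * (eq[i + 1] - eq[i]) / (u[i + 1] - u[i])
        out = acid_titration.production_from_ph(-u_mid)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_far_end_excursion_errors_naming_window(self, acid_titration):
        lo, _ = acid_titration.ph_range
        with pytest.raises(OperatingRangeError, match="operational window"):
            acid_titration.production_from_ph(lo - 0.2)

    def test_small_far_end_excursion_clamps_with_warning(self, acid_titration):
        lo, _ = acid_titration.ph_range
        with pytest.warns(UserWarning, match="clamped"):
            out = acid_titration.production_from_ph(lo - 0.03)
        assert out == pytest.approx(float(acid_titration.added_equivalents[-1]))

    def test_resting_end_excursion_clamps_to_zero_production(self, acid_titration):
        assert acid_titration.production_from_ph(6.6) == 0.0

    def test_acid_mode_is_decreasing_in_ph(self, acid_titration):
        ph = np.linspace(4.2, 6.4, 40)
        out = acid_titration.production_from_ph(ph)
        assert np.all(np.diff(out) < 0)

    def test_loglinear_mode_is_sane(self, acid_titration):
        out = acid_titration.production_from_ph(
            np.array([6.0, 5.5, 5.0]), method="loglinear"
        )
        assert np.all(np.diff(out) > 0)


class TestRoundTrip:
    def test_on_grid_round_trip(self, acid_titration):
        system = px.default_assay_medium(6.5)
        for x in [0.001, 0.005, 0.0150]:  # titration grid nodes
            ph = px.solve_ph(system.with_added_acid(x))
            assert acid_titration.production_from_ph(ph) == pytest.approx(x, abs=1e-6)

    def test_off_grid_round_trip(self, acid_titration):
        system = px.default_assay_medium(6.5)
        rng = np.random.default_rng(3)
        for x in rng.uniform(0.0, 0.020, size=10):
            ph = px.solve_ph(system.with_added_acid(float(x)))
            assert acid_titration.production_from_ph(ph) == pytest.approx(x, abs=1e-4)

    def test_base_mode_round_trip(self, base_titration):
        system = px.default_assay_medium(5.5)
        for x in [0.002, 0.011]:
            ph = px.solve_ph(system.with_added_acid(-x))
            assert base_titration.production_from_ph(ph) == pytest.approx(x, abs=1e-4)


class TestTitrationCurveInvariants:
    def test_rejects_nonzero_start(self):
        with pytest.raises(DataError):
            px.TitrationCurve(np.array([0.001, 0.002]), np.array([6.5, 6.0]), "acid")

    def test_rejects_wrong_monotonicity(self):
        with pytest.raises(DataError):
            px.TitrationCurve(np.array([0.0, 0.001]), np.array([6.0, 6.5]), "acid")

    def test_inversion_is_order_preserving(self, base_titration):
        ph = np.linspace(5.6, 6.9, 25)
        out = base_titration.production_from_ph(ph)
        assert np.all(np.diff(out) > 0)
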