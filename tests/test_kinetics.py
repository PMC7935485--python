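"""Receptor-scheme structure, equilibrium, propagation and dose-response."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambientglu.kinetics import (
    N_STATES, STATE_NAMES, OccupancyState, RateScheme, SchemeValidationError,
    VoltageParams, current, dose_response, equilibrium_occupancy,
    generator_matrix, load_rate_scheme, propagate, save_rate_scheme,
    scale_rates_q10,
)
from ambientglu.trace import Trace


def _const_trace(c, dt, n):
    return Trace(0.0, dt, np.full(n, float(c)), unit="uM")


class TestSchemeValidation:
    def test_default_table_structure(self, scheme):
        assert len(set(s for row in scheme.transitions for s in row[:2])) == N_STATES
        # binding chain carries ligand_order 1 forward only
        for src, dst, rate, order in scheme.transitions:
            if order == 1:
                assert src.startswith("C") and dst.startswith("C")
                assert int(dst[1]) == int(src[1]) + 1
            assert rate >= 0

    def test_negative_rate_rejected(self, scheme):
        rows = list(scheme.transitions)
        rows[0] = (rows[0][0], rows[0][1], -1.0, rows[0][3])
        with pytest.raises(SchemeValidationError, match="negative rate"):
            RateScheme(transitions=rows)

    def test_unknown_state_rejected(self, scheme):
        rows = list(scheme.transitions) + [("C4", "O5", 1.0, 0)]
        with pytest.raises(SchemeValidationError, match="unknown state"):
            RateScheme(transitions=rows)

    def test_missing_edge_rejected(self, scheme):
        rows = [r for r in scheme.transitions if (r[0], r[1]) != ("D4", "C4")]
        with pytest.raises(SchemeValidationError, match="missing"):
            RateScheme(transitions=rows)

    def test_off_topology_edge_rejected(self, scheme):
        rows = list(scheme.transitions) + [("O1", "D1", 1.0, 0)]
        with pytest.raises(SchemeValidationError, match="topology"):
            RateScheme(transitions=rows)

    def test_table_round_trip(self, scheme, tmp_path):
        p = tmp_path / "rates.yaml"
        save_rate_scheme(scheme, p)
        back = load_rate_scheme(p)
        assert back.transitions == scheme.transitions
        assert back.g_max == scheme.g_max and back.Q10 == scheme.Q10


class TestQ10:
    def test_one_decade_multiplies_by_q10(self, scheme):
        scaled = scale_rates_q10(scheme, scheme.T_ref + 10.0)
        for r0, r1 in zip(scheme.transitions, scaled.transitions):
            assert r1[2] == pytest.approx(r0[2] * 2.4, rel=1e-12)

    def test_identity_at_reference(self, scheme):
        scaled = scale_rates_q10(scheme, scheme.T_ref)
        assert scaled.transitions == scheme.transitions

    def test_fractional_decade(self):
        # 23 -> 34 C with Q10 2.4: factor 2.4**1.1 = 2.62110...
        rows = ([(f"C{i}", f"C{i+1}", 100.0, 1) for i in range(4)]
                + [(f"C{i+1}", f"C{i}", 100.0, 0) for i in range(4)]
                + [(f"C{k}", f"O{k}", 100.0, 0) for k in range(1, 5)]
                + [(f"O{k}", f"C{k}", 100.0, 0) for k in range(1, 5)]
                + [(f"C{k}", f"D{k}", 100.0, 0) for k in range(1, 5)]
                + [(f"D{k}", f"C{k}", 100.0, 0) for k in range(1, 5)])
        s = RateScheme(transitions=rows, T_ref=23.0, Q10=2.4)
        scaled = scale_rates_q10(s, 34.0)
        assert scaled.transitions[0][2] == pytest.approx(100 * 2.4**1.1, rel=1e-12)
        assert scaled.transitions[0][2] == pytest.approx(261.958, abs=5e-3)
        assert scaled.T_ref == 34.0

    def test_equilibria_unchanged_relaxation_scaled(self, scheme):
        scaled = scale_rates_q10(scheme, scheme.T_ref + 10.0)
        for glu in (0.5, 5.0, 50.0, 500.0):
            p0 = equilibrium_occupancy(scheme, glu).probabilities
            p1 = equilibrium_occupancy(scaled, glu).probabilities
            np.testing.assert_allclose(p0, p1, atol=1e-10)
            ev0 = np.sort(np.linalg.eigvals(generator_matrix(scheme, glu)).real)
            ev1 = np.sort(np.linalg.eigvals(generator_matrix(scaled, glu)).real)
            np.testing.assert_allclose(ev1, 2.4 * ev0, rtol=1e-8, atol=1e-10)


class TestGeneratorMatrix:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(glu=st.floats(min_value=0.0, max_value=1e4))
    def test_columns_sum_to_zero(self, glu):
        a = generator_matrix(default_scheme_cached(), glu)
        np.testing.assert_allclose(a.sum(axis=0), 0.0, atol=1e-10)

    def test_zero_glu_kills_binding(self, scheme):
        a = generator_matrix(scheme, 0.0)
        for i in range(4):
            assert a[STATE_NAMES.index(f"C{i+1}"), STATE_NAMES.index(f"C{i}")] == 0.0

    def test_negative_glu_rejected(self, scheme):
        with pytest.raises(ValueError):
            generator_matrix(scheme, -1.0)


_DEFAULT = None


def default_scheme_cached():
    global _DEFAULT
    if _DEFAULT is None:
        from ambientglu.kinetics import default_scheme
        _DEFAULT = default_scheme()
    return _DEFAULT


class TestEquilibrium:
    def test_zero_glu_all_unbound(self, scheme):
        occ = equilibrium_occupancy(scheme, 0.0)
        assert occ["C0"] == pytest.approx(1.0, abs=1e-10)

    def test_unbound_fraction_at_5uM(self, scheme):
        # the calibration target: 54.2% of receptors agonist-free at 5 uM
        assert 100 * equilibrium_occupancy(scheme, 5.0)["C0"] == pytest.approx(54.2, abs=0.1)

    @pytest.mark.parametrize("glu", [0.5, 5.0, 32.0, 300.0])
    def test_agrees_with_forward_integration(self, scheme, glu):
        eq = equilibrium_occupancy(scheme, glu).probabilities
        # 16 multiples of the slowest relaxation time at this concentration
        # (exp(-16) ~ 1e-7 leaves margin under the 1e-6 tolerance)
        ev = np.sort(-np.linalg.eigvals(generator_matrix(scheme, glu)).real)
        tau_slow = 1.0 / ev[1]  # smallest nonzero relaxation rate
        glu_tr = _const_trace(glu, 2.0, int(16 * tau_slow / 2.0) + 2)
        init = OccupancyState(np.eye(N_STATES)[0])
        occ = propagate(scheme, glu_tr, init, method="expm")
        np.testing.assert_allclose(occ[-1], eq, atol=1e-6)


class TestPropagate:
    def test_no_glu_from_c0_is_constant(self, scheme):
        occ = propagate(scheme, _const_trace(0.0, 0.5, 200),
                        OccupancyState(np.eye(N_STATES)[0]))
        np.testing.assert_allclose(occ, np.tile(np.eye(N_STATES)[0], (200, 1)), atol=1e-12)

    def test_probability_conservation(self, scheme34, train50):
        from ambientglu.glutamate import TransientParams, train_concentration
        tp = TransientParams(M=5e6, r=1.23, ambient=4.7)
        tgrid = np.arange(0.0, 800.0, 0.2)
        conc = train_concentration(tp, train50, tgrid)
        for method in ("expm", "grid", "ode"):
            occ = propagate(scheme34, conc, method=method)
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-6)
            assert occ.min() >= -1e-6

    def test_expm_vs_ode_on_step_protocol(self, scheme):
        # step 0 -> 1 mM -> 0: the stiff cross-oracle
        c = np.zeros(3000)
        c[500:1500] = 1000.0
        glu = Trace(0.0, 0.1, c, unit="uM")
        occ_e = propagate(scheme, glu, method="expm")
        occ_o = propagate(scheme, glu, method="ode", rtol=1e-10, atol=1e-12)
        assert np.abs(occ_e - occ_o).max() < 1e-5

    def test_grid_path_matches_expm(self, scheme34, train50):
        from ambientglu.glutamate import TransientParams, train_concentration
        tp = TransientParams(M=5e6, r=1.23, ambient=4.7)
        conc = train_concentration(tp, train50, np.arange(0.0, 600.0, 0.2))
        occ_e = propagate(scheme34, conc, method="expm")
        occ_g = propagate(scheme34, conc, method="grid")
        assert np.abs(occ_e - occ_g).max() < 1e-4


class TestCurrentAndDoseResponse:
    def test_ohmic_form(self, scheme):
        # all occupancy in one open state, unit weight: g = g_max
        p = np.zeros(N_STATES)
        p[STATE_NAMES.index("O1")] = 1.0
        s = dataclasses.replace(scheme, g_max=1.0)
        assert current(OccupancyState(p), s, VoltageParams(-70, 0)) == pytest.approx(-70.0)

    def test_closed_states_carry_no_current(self, scheme):
        p = np.zeros(N_STATES)
        p[STATE_NAMES.index("C2")] = 0.5
        p[STATE_NAMES.index("D3")] = 0.5
        assert current(OccupancyState(p), scheme) == 0.0

    def test_linear_in_gmax(self, scheme):
        occ = equilibrium_occupancy(scheme, 32.0)
        half = dataclasses.replace(scheme, g_max=scheme.g_max / 2)
        assert current(occ, half) == pytest.approx(current(occ, scheme) / 2)

    def test_bell_shape_with_interior_peak_near_32(self, scheme):
        grid = np.logspace(0, 3, 301)
        dr = dose_response(scheme, grid)
        mag = np.abs(dr.currents)
        k = int(np.argmax(mag))
        assert 0 < k < grid.size - 1
        assert dr.peak_concentration == pytest.approx(32.0, rel=0.03)
        assert mag[-1] < mag[k]  # 1 mM below the peak
        # unique interior maximum: magnitude rises then falls
        assert np.all(np.diff(mag[:k + 1]) > 0) and np.all(np.diff(mag[k:]) < 0)

    def test_dose_response_invariant_under_q10(self, scheme):
        dr0 = dose_response(scheme, np.logspace(0, 3, 61))
        dr1 = dose_response(scale_rates_q10(scheme, 34.0), np.logspace(0, 3, 61))
        np.testing.assert_allclose(dr0.currents, dr1.currents, rtol=1e-8)
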