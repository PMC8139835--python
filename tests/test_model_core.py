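"""Gating kinetics, the membrane equation, fixed points and stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v1r import (
    ModelParameters,
    find_fixed_points,
    iv_fixed_point_curve,
    membrane_current,
    rhs,
    steady_state,
    steady_state_vector,
    table1_basic,
)
from v1r.model import jacobian
from v1r.params import GateSpec


class TestGates:
    def test_steady_state_half_at_midpoint(self, basic):
        n = basic.gates["n"]
        assert steady_state(n, n.v_half) == pytest.approx(0.5)

    def test_inap_midactivation_at_minus_36(self, basic):
        assert steady_state(basic.gates["mp"], -36.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("name", ["m", "mp", "n", "mA"])
    def test_activation_limits_and_monotonicity(self, basic, name):
        g = basic.gates[name]
        assert steady_state(g, -500.0) < 1e-10
        assert steady_state(g, 500.0) > 1 - 1e-10
        v = np.linspace(-100, 40, 200)
        assert np.all(np.diff(steady_state(g, v)) > 0)

    @pytest.mark.parametrize("name", ["h", "s", "hA"])
    def test_inactivation_decreasing(self, basic, name):
        v = np.linspace(-100, 40, 200)
        assert np.all(np.diff(steady_state(basic.gates[name], v)) < 0)

    def test_zero_steepness_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(-20.0, 0.0, 10.0)

    def test_tau_h_midpoint_and_limits(self, basic):
        assert basic.tau_h(-20.0) == pytest.approx(16.5)
        assert basic.tau_h(-1e6) == pytest.approx(30.0)
        assert basic.tau_h(1e6) == pytest.approx(3.0)
        v = np.linspace(-100, 40, 300)
        tau = basic.tau_h(v)
        assert np.all(np.diff(tau) < 0)
        assert np.all((tau > 3.0) & (tau < 30.0))


class TestParameters:
    def test_reversal_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(ek=-50.0, vr=-60.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            table1_basic().with_(gkdr=-1.0)

    def test_membrane_time_constant_is_13_ms(self, basic):
        assert basic.membrane_time_constant == pytest.approx(13.0)

    def test_serialization_roundtrip(self, basic, tmp_path):
        path = tmp_path / "params.yaml"
        p = basic.with_(gnap=1.7, include_slow_inactivation=True)
        p.save(path)
        from v1r import load_parameters

        q = load_parameters(path)
        assert q == p


class TestRhs:
    def test_leak_only_rest_is_fixed_point(self, basic):
        p = basic.with_(gnat=0.0, gnap=0.0, gkdr=0.0, i=0.0)
        y = steady_state_vector(p.vr, p)
        assert rhs(y, p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_leak_only_shifted_fixed_point(self, basic):
        # V* = Vr + I/Gin = -60 + 13 = -47 mV
        p = basic.with_(gnat=0.0, gnap=0.0, gkdr=0.0, i=13.0)
        y = steady_state_vector(-47.0, p)
        assert rhs(y, p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_depolarizing_drive_at_rest(self, basic):
        # oracle: direct substitution into the current balance
        p = basic.with_(gnap=1.2, gkdr=10.0, i=20.0)
        y = steady_state_vector(-60.0, p)
        expected = membrane_current(-60.0, p) / p.cin
        assert rhs(y, p)[0] == pytest.approx(expected)
        assert expected > 0

    def test_consistency_with_steady_state_current(self, basic):
        # rhs with gates at steady state equals the scalar I-V relation
        p = basic.with_(gnap=1.7, gkdr=6.0, i=11.0)
        for v in (-80.0, -55.0, -30.0, -5.0):
            y = steady_state_vector(v, p)
            assert rhs(y, p)[0] * p.cin == pytest.approx(
                float(membrane_current(v, p)), rel=1e-10
            )

    def test_nonfinite_state_rejected(self, basic):
        y = steady_state_vector(-60.0, basic)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(y, basic)

    @settings(max_examples=30, deadline=None)
    @given(v=st.floats(-90, 20))
    def test_gate_flow_keeps_fractions_in_unit_interval(self, v):
        # at x = 0 every dx/dt >= 0; at x = 1 every dx/dt <= 0
        p = table1_basic()
        y = steady_state_vector(v, p)
        lo = y.copy()
        lo[1:] = 0.0
        hi = y.copy()
        hi[1:] = 1.0
        assert np.all(rhs(lo, p)[1:] >= 0)
        assert np.all(rhs(hi, p)[1:] <= 0)


class TestFixedPoints:
    def test_leak_only_unique_stable_rest(self, basic):
        p = basic.with_(gnat=0.0, gnap=0.0, gkdr=0.0, i=0.0)
        fps = find_fixed_points(p)
        assert len(fps) == 1
        assert fps[0].v == pytest.approx(p.vr, abs=1e-4)
        assert fps[0].stable

    @pytest.mark.parametrize("gnap", [0.0, 0.8, 1.6, 2.5])
    def test_low_gkdr_always_single_stable_point(self, basic, gnap):
        # with GKdr = 2.5 nS the transition quiescence->plateau is gradual
        fps = find_fixed_points(basic.with_(gkdr=2.5, gnap=gnap, i=20.0))
        assert len(fps) == 1
        assert fps[0].stable

    def test_bistable_branch_has_three_roots(self, basic):
        fps = find_fixed_points(basic.with_(gkdr=5.0, gnap=1.65, i=5.0))
        assert len(fps) == 3
        stable = [fp.stable for fp in sorted(fps, key=lambda f: f.v)]
        assert stable == [True, False, True]

    def test_residual_small_at_every_root(self, basic):
        p = basic.with_(gkdr=5.0, gnap=2.0, i=0.0)
        for fp in find_fixed_points(p):
            assert np.max(np.abs(rhs(fp.state, p))) < 1e-6

    def test_stability_flag_matches_simulation(self, basic, rng):
        """Local stability must agree with the fate of a 0.5 mV perturbation
        integrated for 2 s, on a spread of random parameter sets."""
        from v1r.bifurcation import _simulate

        checked = 0
        trials = 0
        while checked < 50 and trials < 200:
            trials += 1
            p = basic.with_(
                gnap=float(rng.uniform(0.0, 2.5)),
                gkdr=float(rng.uniform(1.0, 20.0)),
                i=float(rng.uniform(0.0, 30.0)),
            )
            for fp in find_fixed_points(p):
                if abs(fp.leading_complex_real) < 1e-4 and fp.stable:
                    continue  # too close to marginal for a finite-time check
                y = fp.state.copy()
                y[0] += 0.5
                rec = _simulate(p, y, 2000.0, dt=0.02, stride=100)
                returned = abs(rec[-1, 0] - fp.v) < 0.25
                assert returned == fp.stable, (
                    f"stability mismatch at gnap={p.gnap:.3f} gkdr={p.gkdr:.3f} "
                    f"i={p.i:.2f} V*={fp.v:.2f}"
                )
                checked += 1
        assert checked >= 50


class TestIVCurve:
    def test_s_shape_in_bistable_regime(self, basic):
        p = basic.with_(gkdr=5.0, gnap=2.0)
        curve = iv_fixed_point_curve(p, "i", np.linspace(-20, 20, 81))
        per_i = {}
        for row in curve:
            per_i.setdefault(row["param"], []).append(row)
        n_roots = [len(v) for v in per_i.values()]
        assert max(n_roots) == 3  # coexistence window exists
        assert min(n_roots) == 1

    def test_monotone_single_branch_without_inward_current(self, basic):
        p = basic.with_(gnap=0.0, gnat=0.0, gkdr=10.0)
        curve = iv_fixed_point_curve(p, "i", np.linspace(-20, 20, 41))
        assert len(curve) == 41  # one root per current
        assert np.all(np.diff(curve["v"]) > 0)
        assert np.all(curve["stable"])

    def test_fold_window_matches_dense_root_count(self, basic):
        """Fold edges from the curve agree with brute-force root counting on
        a dense current grid (independent oracle)."""
        p = basic.with_(gkdr=5.0, gnap=2.0)
        vv = np.linspace(-100, 40, 10000)
        grid_counts = []
        for i_val in np.linspace(-15, 15, 61):
            # count sign changes of the steady-state I-V relation over V
            s = membrane_current(vv, p.with_(i=float(i_val)))
            grid_counts.append(int(np.sum(np.sign(s[:-1]) != np.sign(s[1:]))))
        grid_counts = np.array(grid_counts)
        curve = iv_fixed_point_curve(p, "i", np.linspace(-15, 15, 61))
        per_i = {}
        for row in curve:
            per_i.setdefault(round(float(row["param"]), 6), 0)
            per_i[round(float(row["param"]), 6)] += 1
        curve_counts = np.array([per_i[round(float(i), 6)] for i in np.linspace(-15, 15, 61)])
        assert np.array_equal(curve_counts, grid_counts)

    def test_empty_range_rejected(self, basic):
        with pytest.raises(ValueError):
            iv_fixed_point_curve(basic, "i", [])


def test_jacobian_matches_analytic_leak_rate(basic):
    # with channels blocked, dV/dt = -(Gin/Cin) (V - Vr): leading rate 1/13 ms
    p = basic.with_(gnat=0.0, gnap=0.0, gkdr=0.0, i=0.0)
    y = steady_state_vector(p.vr, p)
    eig = np.linalg.eigvals(jacobian(y, p))
    assert np.min(np.abs(eig + 1.0 / 13.0)) < 1e-6
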