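"""Simulation engine accuracy and the in-silico recording protocols."""

import numpy as np
import pytest

from v1r import (
    Protocol,
    apply_pharmacology,
    current_step_family,
    integrate,
    ramp_inap_protocol,
    table1_basic,
    vclamp_step_protocol,
)
from v1r.phenotype import detect_events
from v1r.population import DoseResponseModel


class TestRK4Accuracy:
    def test_matches_closed_form_rc_response(self, basic):
        """With all channels blocked the step response is the analytic RC
        charging curve V(t) = Vr + I/Gin (1 - exp(-t/tau)), tau = 13 ms."""
        p = basic.with_(gnat=0.0, gnap=0.0, gkdr=0.0)
        proto = Protocol("current_clamp", ((50.0, 0.0), (200.0, 10.0)), dt=0.01)
        tr = integrate(p, proto)
        m = tr.t >= 50.0
        t_rel = tr.t[m] - 50.0
        exact = -60.0 + 10.0 * (1.0 - np.exp(-t_rel / 13.0))
        assert np.max(np.abs(tr.v[m] - exact)) < 1e-6

    def test_step_halving_convergence_on_spiking_trace(self, basic):
        p = basic.with_(gnap=1.2, gkdr=10.0)
        v = {}
        for dt in (0.01, 0.005):
            proto = Protocol(
                "current_clamp", ((100.0, 0.0), (2000.0, 20.0)),
                dt=dt, record_stride=int(round(1.0 / dt)),
            )
            v[dt] = integrate(p, proto).v
        assert np.max(np.abs(v[0.01] - v[0.005])) < 1e-3

    def test_divergence_reported_with_diagnostic(self, basic):
        # a step size far beyond the stability limit of the stiffest time
        # constant must fail loudly, not return garbage
        from v1r import steady_state_vector

        bad = basic.with_(gkdr=1e6)
        proto = Protocol("current_clamp", ((100.0, 20.0),), dt=0.05)
        with pytest.raises(ArithmeticError):
            integrate(bad, proto, y0=steady_state_vector(-50.0, bad))

    def test_capacitance_scaling_of_dvdt(self, basic):
        from v1r import rhs, steady_state_vector

        y = steady_state_vector(-50.0, basic)
        half = basic.with_(cin=basic.cin / 2)
        assert rhs(y, half)[0] == pytest.approx(2 * rhs(y, basic)[0])


class TestCurrentSteps:
    def test_zero_amplitude_stays_at_rest(self, basic):
        # rest sits within a few hundredths of a mV of Vr (tiny sodium
        # window current) and the trace is flat
        tr = current_step_family(basic, [0.0], duration=500.0)[0]
        assert np.ptp(tr.v) < 1e-6
        assert np.max(np.abs(tr.v - basic.vr)) < 0.05

    def test_ss_point_fires_exactly_one_spike(self, canonical_traces):
        events = detect_events(canonical_traces[(0.2, 10.0)])
        assert len(events) == 1
        assert events[0].kind == "AP"

    def test_rs_point_fires_repetitively(self, canonical_traces):
        events = detect_events(canonical_traces[(1.2, 10.0)])
        assert len(events) >= 10
        assert all(e.kind == "AP" for e in events)

    def test_plateau_never_outlasts_the_pulse(self, canonical_traces):
        tr = canonical_traces[(1.2, 2.5)]
        post = tr.v[tr.t > tr.pulse_window[1] + 300.0]
        assert np.max(post) < -50.0  # back near rest after pulse offset

    def test_rheobase_of_rs_point_between_10_and_20_pa(self, basic):
        """Bisection on the step amplitude brackets the smallest current
        evoking a spike; oracle is the event count."""
        p = basic.with_(gnap=1.2, gkdr=10.0)

        def n_spikes(amp):
            tr = current_step_family(p, [amp], duration=500.0)[0]
            return len(detect_events(tr))

        assert n_spikes(10.0) == 0
        assert n_spikes(20.0) >= 1
        lo, hi = 10.0, 20.0
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            if n_spikes(mid) >= 1:
                hi = mid
            else:
                lo = mid
        assert 10.0 < hi <= 20.0

    def test_negative_amplitude_rejected(self, basic):
        with pytest.raises(ValueError):
            current_step_family(basic, [-5.0])


class TestVoltageClamp:
    def test_prepulse_minus_30_inactivates_ia(self, basic):
        # oracle: the sigmoid formula itself
        ha = basic.gates["hA"]
        assert float(ha.steady_state(-30.0)) < 0.005

    def test_ia_subtraction_is_exact_superposition(self, basic):
        """IKv (with IA) minus IKdr (IA inactivated in-silico by zeroing GA)
        equals the IA current term exactly: under an imposed voltage the
        current terms are additive."""
        p = apply_pharmacology(
            basic.with_(include_ia=True, ga=10.0), ttx=True
        )
        steps = [0.0, 20.0]
        total = vclamp_step_protocol(p, prepulse=(-100.0, 300.0), steps=steps)
        no_ia = vclamp_step_protocol(
            p.with_(ga=0.0), prepulse=(-100.0, 300.0), steps=steps
        )
        for tr_tot, tr_kdr in zip(total, no_ia):
            ia = tr_tot.i - tr_kdr.i
            assert np.allclose(ia, tr_tot.currents[:, 4], atol=1e-9)

    def test_peak_ikdr_recovers_conductance(self, basic):
        """Peak IKdr at +20 mV / driving force = GKdr n_inf(20)^3 within 2%
        (200 ms step saturates the n-gate, tau_n = 10 ms)."""
        p = apply_pharmacology(basic, ttx=True)
        tr = vclamp_step_protocol(
            p, prepulse=(-30.0, 300.0), steps=[20.0], step_dur=200.0
        )[0]
        peak = float(np.max(tr.currents[:, 3]))
        n_inf = float(p.gates["n"].steady_state(20.0))
        expected = p.gkdr * n_inf**3 * (20.0 - p.ek)
        assert peak == pytest.approx(expected, rel=0.02)


class TestRamp:
    def test_zero_sodium_gives_null_estimate(self, basic):
        p = basic.with_(gnap=0.0, gnat=0.0)
        _, _, est = ramp_inap_protocol(p)
        assert np.max(np.abs(est["i_nap_pa"])) < 1e-9

    def test_zero_gnap_leaves_only_small_nat_window_current(self, basic):
        # the TTX subtraction isolates INat + INap; with GNap = 0 only the
        # small transient-sodium window component remains
        p = basic.with_(gnap=0.0)
        _, _, est = ramp_inap_protocol(p)
        assert est["peak_pa"] < 0
        assert np.max(np.abs(est["i_nap_pa"])) < 15.0

    def test_estimate_is_inward_below_ena(self, basic):
        p = basic.with_(gnap=1.0)
        _, _, est = ramp_inap_protocol(p)
        assert est["peak_pa"] < 0
        assert est["v_at_peak_mv"] < p.ena

    def test_peak_conductance_underestimates_gnap(self, basic):
        """G = I/(V - ENa) at the ramp peak equals GNap times mp^3 s there,
        hence underestimates GNap by that activation factor."""
        p = basic.with_(gnap=1.0, gnat=0.0)  # isolate the persistent current
        _, _, est = ramp_inap_protocol(p)
        g_apparent = est["peak_pa"] / (est["v_at_peak_mv"] - p.ena)
        mp = float(p.gates["mp"].steady_state(est["v_at_peak_mv"]))
        assert 0 < g_apparent < p.gnap
        assert g_apparent == pytest.approx(p.gnap * mp**3, rel=0.02)


class TestPharmacology:
    def test_zero_concentration_is_identity(self, basic):
        assert apply_pharmacology(basic, fourap_um=0.0) == basic

    def test_ic50_halves_gkdr_when_imin_zero(self, basic):
        model = DoseResponseModel(imin=0.0, ic50=2.9, nh=1.0)
        p = apply_pharmacology(basic, fourap_um=2.9, dose_response=model)
        assert p.gkdr == pytest.approx(basic.gkdr / 2)

    def test_ttx_zeroes_sodium_conductances(self, basic):
        p = apply_pharmacology(basic, ttx=True)
        assert p.gnat == 0.0 and p.gnap == 0.0

    def test_300um_with_rheobase_matching_scales_gin_and_current(self, basic):
        p = apply_pharmacology(basic, fourap_um=300.0, rheobase_matched=True)
        assert p.gin == pytest.approx(0.77 * basic.gin)
        assert p.i == pytest.approx(0.77 * basic.i)

    def test_negative_concentration_rejected(self, basic):
        with pytest.raises(ValueError):
            apply_pharmacology(basic, fourap_um=-1.0)

    def test_high_dose_converts_ss_toward_excitable_patterns(self, basic):
        """Reducing GKdr (and Gin, rheobase-matched) moves an SS cell across
        the repetitive-firing boundary: the activity map labels shift."""
        from v1r import classify_cell

        ss = basic.with_(gnap=0.5, gkdr=10.0, i=20.0)
        assert classify_cell(ss) == "SS"
        blocked = apply_pharmacology(ss, fourap_um=300.0, rheobase_matched=True)
        assert classify_cell(blocked) != "SS"
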