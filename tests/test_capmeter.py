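"""Sine+DC lock-in, circuit inversion and exocytosis read-outs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synaptoflux import capmeter, synthgen
from synaptoflux.capmeter import (AdmittancePoint, circuit_admittance,
                                  lockin_extract, solve_circuit)
from synaptoflux.datatypes import BoutonParams, SineDCProtocol, SweepRecording

OMEGA = 2 * np.pi * 1000.0


def _passive_bouton(cm=1.0, rs=20.0, rm=2000.0):
    return BoutonParams(baseline_cm_pF=cm, rs_mohm=rs, rm_mohm=rm,
                        rrp_density_fF_per_pF=0.0, ca_density_pA_per_pF=0.0)


def _point_from_circuit(cm, rs, rm):
    y = circuit_admittance(cm, rs, rm, 1000.0)
    g_dc = 1.0 / ((rs + rm) * 1e6)
    return AdmittancePoint(0.0, y.real, y.imag, g_dc)


class TestLockin:
    def test_pure_resistor_gives_real_admittance(self):
        fs, g_ns = 50_000.0, 5.0  # 5 nS resistor
        proto = SineDCProtocol()
        t, v = proto.command(50.0, fs)
        i = g_ns * v  # pA = nS * mV
        sweep = SweepRecording(t, v, i, fs)
        pts = [p for p in lockin_extract(sweep, proto, 50.0) if p.valid]
        assert pts, "no valid lock-in windows"
        for p in pts:
            assert p.re_y == pytest.approx(g_ns * 1e-9, rel=1e-9)
            assert abs(p.im_y) < 1e-15

    def test_zero_current_gives_zero_admittance(self):
        fs = 50_000.0
        proto = SineDCProtocol()
        t, v = proto.command(50.0, fs)
        sweep = SweepRecording(t, v, np.zeros_like(t), fs)
        p = [q for q in lockin_extract(sweep, proto, 50.0) if q.valid][0]
        assert p.re_y == 0.0 and p.im_y == 0.0

    def test_matches_closed_form_admittance(self, protocol):
        sweep = synthgen.simulate_cm_sweep(_passive_bouton(), protocol,
                                           pulse_ms=50, noise_sd=0)
        y_true = circuit_admittance(1.0, 20.0, 2000.0, 1000.0)
        pts = [p for p in lockin_extract(sweep, protocol, 50.0)
               if p.valid and p.t_s < protocol.pulse_start_ms * 1e-3]
        for p in pts[1:]:
            rel = abs(complex(p.re_y, p.im_y) - y_true) / abs(y_true)
            assert rel < 1e-3  # 0.1% bound; in practice ~1e-14

    def test_no_sine_in_command_rejected(self):
        fs = 50_000.0
        n = 1000
        t = np.arange(n) / fs
        v = np.full(n, -80.0)
        sweep = SweepRecording(t, v, np.zeros(n), fs)
        with pytest.raises(ValueError, match="sine"):
            lockin_extract(sweep, SineDCProtocol(), 50.0)


class TestSolveCircuit:
    def test_forward_inverse_round_trip(self):
        cm, rs, rm = solve_circuit(_point_from_circuit(1.0, 10.0, 500.0), OMEGA)
        assert cm == pytest.approx(1.0, rel=1e-6)
        assert rs == pytest.approx(10.0, rel=1e-6)
        assert rm == pytest.approx(500.0, rel=1e-6)

    def test_random_circuit_grid_max_error(self, rng):
        worst = 0.0
        for _ in range(100):
            cm = rng.uniform(0.2, 5.0)
            rs = rng.uniform(5.0, 50.0)
            rm = rng.uniform(100.0, 5000.0)
            est = solve_circuit(_point_from_circuit(cm, rs, rm), OMEGA)
            worst = max(worst, *(abs(e / t - 1.0)
                                 for e, t in zip(est, (cm, rs, rm))))
        assert worst < 1e-6

    def test_negligible_series_resistance_limit(self):
        # with rs -> 0, im_y = omega * Cm directly
        pt = _point_from_circuit(2.0, 1e-4, 1000.0)
        assert pt.im_y == pytest.approx(OMEGA * 2.0e-12, rel=1e-6)
        cm, _, _ = solve_circuit(pt, OMEGA)
        assert cm == pytest.approx(2.0, rel=1e-6)

    def test_inconsistent_point_flagged_not_clamped(self):
        with pytest.raises(ValueError):
            solve_circuit(AdmittancePoint(0.0, 1e-9, 1e-9, 1.0), OMEGA)
        with pytest.raises(ValueError):
            solve_circuit(AdmittancePoint(0.0, 1e-9, -1e-9, 1e-10), OMEGA)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cm=st.floats(0.3, 4.0), rs=st.floats(5.0, 45.0),
           rm=st.floats(200.0, 4000.0))
    def test_inversion_property(self, cm, rs, rm):
        est = solve_circuit(_point_from_circuit(cm, rs, rm), OMEGA)
        assert np.allclose(est, (cm, rs, rm), rtol=1e-6)


class TestDeltaCm:
    def test_noiseless_recovery_is_exact(self, protocol):
        sweep = synthgen.simulate_cm_sweep(BoutonParams(), protocol, 50.0,
                                           noise_sd=0)
        est = capmeter.analyze_cm_sweep(sweep, protocol, 50.0, with_ica=False)
        assert est.delta_cm_fF == pytest.approx(sweep.meta["true_dcm_fF"],
                                                abs=0.01)

    def test_zero_pool_means_zero_jump(self, protocol):
        sweep = synthgen.simulate_cm_sweep(_passive_bouton(), protocol, 50.0,
                                           noise_sd=2.0, seed=7)
        est = capmeter.analyze_cm_sweep(sweep, protocol, 50.0, with_ica=False)
        assert abs(est.delta_cm_fF) < 1.0  # noise floor

    def test_planted_jump_recovered_at_default_noise(self, protocol):
        b = BoutonParams(rrp_density_fF_per_pF=20.0, release_tau_ms=1e-3)
        sweep = synthgen.simulate_cm_sweep(b, protocol, 50.0, noise_sd=2.0,
                                           seed=3)
        est = capmeter.analyze_cm_sweep(sweep, protocol, 50.0, with_ica=False)
        assert est.delta_cm_fF == pytest.approx(20.0, abs=1.0)

    def test_norm_invariant_to_bouton_size(self, protocol):
        vals = []
        for c0 in (0.5, 1.0, 2.0):
            b = BoutonParams(baseline_cm_pF=c0)
            sweep = synthgen.simulate_cm_sweep(b, protocol, 50.0, noise_sd=0)
            est = capmeter.analyze_cm_sweep(sweep, protocol, 50.0,
                                            with_ica=False)
            vals.append(est.cm_norm_fF_per_pF)
        assert np.ptp(vals) / np.mean(vals) < 0.02

    def test_delta_cm_monotone_in_pulse_duration(self, protocol):
        prev = -np.inf
        for T in (1.0, 2.0, 5.0, 10.0, 20.0, 50.0):
            sweep = synthgen.simulate_cm_sweep(BoutonParams(), protocol, T,
                                               noise_sd=0)
            est = capmeter.analyze_cm_sweep(sweep, protocol, T, with_ica=False)
            assert est.delta_cm_fF >= prev - 1e-6
            prev = est.delta_cm_fF


class TestClampedCm:
    def test_recovers_capacitance_within_two_percent(self, protocol):
        sweep = synthgen.simulate_cm_sweep(_passive_bouton(), protocol, 50.0,
                                           noise_sd=0)
        cm = capmeter.estimate_clamped_cm(sweep, protocol)
        assert cm == pytest.approx(1.0, rel=0.02)

    def test_step_size_invariance(self):
        vals = []
        for step in (5.0, 10.0):
            proto = SineDCProtocol(step_mV=step)
            sweep = synthgen.simulate_cm_sweep(_passive_bouton(), proto, 50.0,
                                               noise_sd=0)
            vals.append(capmeter.estimate_clamped_cm(sweep, proto))
        assert vals[0] == pytest.approx(vals[1], rel=0.02)


class TestICa:
    def test_noiseless_tau_and_density(self, protocol):
        sweep = synthgen.simulate_cm_sweep(BoutonParams(), protocol, 5.0,
                                           noise_sd=0)
        est = capmeter.analyze_cm_sweep(sweep, protocol, 5.0)
        assert est.tau_act_ms == pytest.approx(1.0, abs=0.01)
        assert est.ica_pA_per_pF == pytest.approx(53.0, rel=0.05)

    def test_density_scales_linearly(self, protocol):
        outs = []
        for dens in (53.0, 106.0):
            b = BoutonParams(ca_density_pA_per_pF=dens)
            sweep = synthgen.simulate_cm_sweep(b, protocol, 5.0, noise_sd=0)
            est = capmeter.analyze_cm_sweep(sweep, protocol, 5.0)
            outs.append(est.ica_pA_per_pF)
        assert outs[1] == pytest.approx(2 * outs[0], rel=0.01)
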