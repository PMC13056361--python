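"""Forward simulator: ledgers, conservation laws, determinism."""

import numpy as np
import pytest

from synaptoflux import synthgen
from synaptoflux.datatypes import (BoutonParams, PhModelParams, QuantalTemplate,
                                   SessionConfig)
from synaptoflux.phmodel import (protocol_repeated_trains, protocol_single_train,
                                 simulate_states)


class TestBoutonParams:
    def test_pool_ordering_enforced(self):
        with pytest.raises(ValueError):
            BoutonParams(f_ap=0.7, f_iono=0.5)

    def test_positive_circuit_enforced(self):
        with pytest.raises(ValueError):
            BoutonParams(baseline_cm_pF=-1.0)

    def test_suppression_shrinks_only_ap_partition(self):
        b = BoutonParams(suppression_ratio=0.5)
        assert b.f_ap_effective == pytest.approx(b.f_ap * 0.5)
        assert b.f_iono == BoutonParams().f_iono


class TestPairedRecording:
    def test_charge_conservation(self, template):
        b = BoutonParams()
        _, post, truth = synthgen.simulate_paired_recording(
            b, template, noise_sd=0, seed=0)
        dt_ms = 1e3 / post.rate_hz
        ipsc_charge = post.current_pA.sum() * dt_ms
        # released vesicles times unit charge (template truncation < 0.1%)
        expected = truth["cumulative"] * template.charge_pA_ms
        assert ipsc_charge == pytest.approx(expected, rel=2e-3)

    def test_waveform_has_hard_onset_and_planted_peak(self):
        t = np.linspace(0.0, 30.0, 3001)
        v = synthgen._release_waveform(t, onset_ms=11.63, peak_rate=45.7)
        assert np.all(v[t < 11.63] == 0.0)
        assert v.max() == pytest.approx(45.7, rel=1e-3)

    def test_short_template_rejected(self):
        b = BoutonParams()
        bad = QuantalTemplate(duration_ms=10.0)
        with pytest.raises(ValueError, match="support"):
            synthgen.simulate_paired_recording(b, bad)


class TestMinis:
    def test_zero_rate_gives_empty_ledger(self, template):
        sweep, truth = synthgen.simulate_minis(0.0, template, duration_s=30,
                                               seed=1)
        assert len(truth["times_s"]) == 0

    def test_poisson_count_within_three_se(self, template):
        rate, dur = 2.0, 300.0
        _, truth = synthgen.simulate_minis(rate, template, duration_s=dur,
                                           seed=5)
        expected = rate * dur
        assert abs(len(truth["times_s"]) - expected) < 3 * np.sqrt(expected)

    def test_amplitudes_centered_on_mean(self, template):
        _, truth = synthgen.simulate_minis(5.0, template, duration_s=300,
                                           seed=6, mean_amp_pA=30.0)
        assert truth["amps_pA"].mean() == pytest.approx(30.0, rel=0.05)


class TestSuppressionRelation:
    def test_printed_formula_values(self):
        assert synthgen.apply_suppression(0.0) == pytest.approx(1.375)
        assert synthgen.apply_suppression(1e6) == pytest.approx(0.355)

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            synthgen.apply_suppression(-1.0)

    def test_ensemble_mean_reduction_matches_calibration(self):
        from synaptoflux.calibration import BETA_AU_PER_PCT, solve_beta
        assert solve_beta() == pytest.approx(BETA_AU_PER_PCT, rel=1e-3)
        boutons, _ = synthgen.draw_boutons(4000, "gpr55_active", seed=3)
        r = np.array([b.suppression_ratio for b in boutons])
        assert (1.0 - r.mean()) * 100.0 == pytest.approx(53.8, abs=1.5)


class TestPhluorinSession:
    def test_missing_nh4cl_warns(self):
        proto = [e for e in protocol_single_train() if e.kind != "nh4cl"]
        cfg = SessionConfig(seed=0, n_boutons=2, protocol=proto)
        with pytest.warns(UserWarning, match="NH4Cl"):
            synthgen.simulate_phluorin_session(cfg)

    def test_determinism_bit_identical(self):
        cfg = SessionConfig(seed=42, n_boutons=5,
                            protocol=protocol_single_train())
        tr1, led1 = synthgen.simulate_phluorin_session(cfg)
        tr2, led2 = synthgen.simulate_phluorin_session(cfg)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.F, b.F)
        assert led1.to_json() == led2.to_json()

    def test_total_pool_conserved_under_suppression(self):
        # NH4Cl reveals the same total in control and GPR55-active sessions
        levels = {}
        for cond in ("control", "gpr55_active"):
            cfg = SessionConfig(seed=8, n_boutons=20, condition=cond,
                                protocol=protocol_single_train())
            traces, led = synthgen.simulate_phluorin_session(cfg)
            nh4 = [e for e in traces[0].epochs if e.kind == "nh4cl"][-1]
            levels[cond] = np.array([
                tr.window(nh4.end_s - 20, nh4.end_s).mean() for tr in traces])
            assert all(b.f_iono == 0.54 for b in led.boutons)
        assert np.allclose(levels["control"], levels["gpr55_active"], rtol=0.02)

    def test_surface_scaling_regression(self):
        # ledger AP-releasable amount grows as n_total^(2/3)
        boutons, _ = synthgen.draw_boutons(200, "control", seed=4)
        n = np.array([b.n_total for b in boutons])
        amount = np.array([b.f_ap_effective * b.n_total for b in boutons])
        r = np.corrcoef(n ** (2.0 / 3.0), amount)[0, 1]
        assert r ** 2 > 0.999

    def test_cumulative_release_monotone(self):
        ph = PhModelParams()
        states = simulate_states(np.array([0.276]), np.array([0.54]), ph,
                                 protocol_repeated_trains(), dt=0.2)
        bright_plus_recycled = states.bright[0]
        # bright trace after bafilomycin (no re-quench) is non-decreasing
        baf = 60.0 + 2 * 120.0
        post = bright_plus_recycled[states.t >= baf]
        assert np.all(np.diff(post) >= -1e-12)


class TestGcamp:
    def test_epoch_amplitudes(self):
        from synaptoflux import pool_dissection as pdis
        from synaptoflux.datatypes import Epoch
        proto = [Epoch("rest", 0, 60), Epoch("ap_train_400", 60, 20),
                 Epoch("rest", 80, 100), Epoch("ionomycin", 180, 90)]
        for comp, (a_tr, a_io) in (("varicosity", (5.3, 16.2)),
                                   ("axon", (1.6, 15.1))):
            tr = synthgen.simulate_gcamp(5, proto, comp, seed=2)[0]
            assert pdis.gcamp_dff(tr, proto[1]) == pytest.approx(a_tr, rel=0.1)
            assert pdis.gcamp_dff(tr, proto[3]) == pytest.approx(a_io, rel=0.1)

    def test_no_stimulation_gives_zero(self):
        from synaptoflux import pool_dissection as pdis
        from synaptoflux.datatypes import Epoch
        proto = [Epoch("rest", 0, 120), Epoch("rest", 120, 60)]
        tr = synthgen.simulate_gcamp(1, proto, "varicosity", seed=2,
                                     noise_rel=0.0)[0]
        assert pdis.gcamp_dff(tr, proto[1]) == pytest.approx(0.0, abs=1e-9)

    def test_train_responses_constant_across_repeats(self):
        from synaptoflux import pool_dissection as pdis
        from synaptoflux.datatypes import Epoch
        proto = [Epoch("rest", 0, 60)]
        t = 60.0
        for _ in range(4):
            proto.append(Epoch("ap_train_400", t, 20))
            proto.append(Epoch("rest", t + 20, 100))
            t += 120
        tr = synthgen.simulate_gcamp(1, proto, "varicosity", seed=3)[0]
        vals = [pdis.gcamp_dff(tr, e) for e in proto if e.kind == "ap_train_400"]
        assert np.ptp(vals) / np.mean(vals) < 0.1
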