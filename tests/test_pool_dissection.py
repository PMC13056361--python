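"""Pool fractions, depletion fits and the suppression relation."""

import numpy as np
import pytest

from synaptoflux import pool_dissection as pdis, synthgen
from synaptoflux.datatypes import Epoch, FluorTrace, SessionConfig
from synaptoflux.phmodel import (protocol_ionomycin, protocol_repeated_trains,
                                 protocol_single_train)


class TestFitRRP:
    def test_noiseless_recovery(self):
        T = np.array([1, 2, 5, 10, 20, 50], dtype=float)
        y = 31.0 * (1 - np.exp(-T / 8.0))
        cur = pdis.fit_rrp(T, y)
        assert cur.converged
        assert cur.plateau_fF_per_pF == pytest.approx(31.0, abs=1e-6)
        assert cur.tau_fit_ms == pytest.approx(8.0, abs=1e-6)

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            pdis.fit_rrp([1, 2, 5], [1, 2, 3])

    def test_plateau_not_far_below_observed_max(self, rng):
        T = np.array([1, 2, 5, 10, 20, 50], dtype=float)
        y = 31.0 * (1 - np.exp(-T / 8.0)) + rng.normal(0, 2.0, len(T))
        cur = pdis.fit_rrp(T, y)
        assert cur.plateau_fF_per_pF >= 0.8 * y.max()


class TestTrainResponse:
    def test_flat_trace_gives_zero(self):
        proto = protocol_single_train()
        t = np.arange(0, 380, 2.0)
        tr = FluorTrace(t, np.full(len(t), 100.0), "b0", epochs=proto)
        train = [e for e in proto if e.kind == "ap_train_400"][0]
        d, _ = pdis.quantify_train_response(tr, train, fit_decay=False)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_decay_tau_recovery(self):
        from synaptoflux.datatypes import BoutonParams
        cfg = SessionConfig(seed=0, n_boutons=1, fluor_noise_rel=0.0,
                            protocol=protocol_single_train())
        # reference-sized bouton: per-bouton dF400 scales with size
        tr = synthgen.simulate_phluorin_session(
            cfg, boutons=[BoutonParams()])[0][0]
        train = [e for e in tr.epochs if e.kind == "ap_train_400"][0]
        d, tau = pdis.quantify_train_response(tr, train)
        assert tau == pytest.approx(42.1, abs=1.0)
        assert d == pytest.approx(23.3, rel=0.05)


class TestNormalizeToTotal:
    def test_noiseless_surface_scaling_r2(self):
        cfg = SessionConfig(seed=9, n_boutons=40, fluor_noise_rel=0.0,
                            protocol=protocol_single_train())
        traces, _ = synthgen.simulate_phluorin_session(cfg)
        table, fit = pdis.normalize_to_total(traces)
        assert len(table) == 40
        assert fit["r_squared"] > 0.99

    def test_identical_sizes_degenerate(self):
        proto = protocol_single_train()
        t = np.arange(0, 380, 2.0)
        traces = []
        for k in range(5):
            f = np.full(len(t), 100.0)
            f[(t >= 60) & (t < 80)] = 120.0
            f[t >= 320] = 400.0
            traces.append(FluorTrace(t, f, f"b{k}", epochs=proto))
        _, fit = pdis.normalize_to_total(traces)
        assert fit["degenerate"]


class TestSuppressionFit:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(1.0, 150.0, 80)
        r = 1.02 * np.exp(-0.0334 * x) + 0.355
        fit = pdis.fit_suppression_relation(x, r)
        assert fit.a == pytest.approx(1.02, abs=1e-4)
        assert fit.b == pytest.approx(0.0334, abs=1e-6)
        assert fit.c == pytest.approx(0.355, abs=1e-4)

    def test_asymptote_recovered_under_matched_noise(self):
        x, r = synthgen.sample_suppression_dataset(seed=5)
        fit = pdis.fit_suppression_relation(x, r)
        assert fit.c == pytest.approx(0.355, abs=0.1)

    def test_constant_ratio_degenerate_limit(self, rng):
        x = np.linspace(1.0, 150.0, 40)
        r = np.full(40, 0.8)
        fit = pdis.fit_suppression_relation(x, r)
        assert np.allclose(fit(x), 0.8, atol=0.01)

    def test_narrow_range_flagged(self):
        x = np.linspace(10.0, 20.0, 25)
        r = 1.02 * np.exp(-0.0334 * x) + 0.355
        fit = pdis.fit_suppression_relation(x, r)
        assert any("narrow" in f for f in fit.flags)


class TestPrediction:
    @staticmethod
    def _tables(seed=9):
        out = {}
        for cond in ("control", "gpr55_active"):
            cfg = SessionConfig(seed=seed, n_boutons=60, condition=cond,
                                protocol=protocol_single_train())
            traces, _ = synthgen.simulate_phluorin_session(cfg)
            out[cond], _ = pdis.normalize_to_total(traces)
        return out

    def test_identity_fit_returns_control(self):
        tables = self._tables()
        ident = pdis.SuppressionFit(a=0.0, b=0.0, c=1.0, r_squared=1.0)
        pred, _ = pdis.predict_suppressed_distribution(tables["control"], ident)
        assert np.allclose(pred["dF400_au"], tables["control"]["dF400_au"])

    def test_generator_self_consistency_ks(self):
        from synaptoflux.calibration import BETA_AU_PER_PCT
        tables = self._tables()
        x, r = synthgen.sample_suppression_dataset(seed=9)
        fit = pdis.fit_suppression_relation(x, r)
        pred, comp = pdis.predict_suppressed_distribution(
            tables["control"], fit, observed=tables["gpr55_active"],
            x_column="dF400_pct", x_scale=BETA_AU_PER_PCT)
        assert comp["p_value"] > 0.05  # prediction overlaps the drug cohort


class TestCumulativePools:
    @staticmethod
    def _session(cond="control", seed=12, n=20):
        cfg = SessionConfig(seed=seed, n_boutons=n, condition=cond,
                            protocol=protocol_repeated_trains())
        return synthgen.simulate_phluorin_session(cfg)[0]

    def test_control_plateau_and_kcl_residual(self):
        fr = [pdis.cumulative_pool_analysis(tr) for tr in self._session()]
        plateau = np.mean([f.f_recycling_pct for f in fr])
        assert plateau == pytest.approx(27.6, rel=0.12)
        assert abs(np.mean([f.kcl_increment_pct for f in fr])) < 2.0

    def test_flat_increments_refuse_extrapolation(self):
        proto = protocol_repeated_trains()
        t = np.arange(0, proto[-1].end_s + 60, 2.0)
        f = 100.0 + 0.05 * t          # linear climb: increments never fall
        f[t >= proto[-2].start_s] = 400.0
        tr = FluorTrace(t, f, "b0", epochs=proto)
        out = pdis.cumulative_pool_analysis(tr)
        assert any("not decreasing" in fl for fl in out.flags)

    def test_missing_bafilomycin_rejected(self):
        proto = protocol_single_train()
        t = np.arange(0, 380, 2.0)
        tr = FluorTrace(t, np.full(len(t), 100.0), "b0", epochs=proto)
        with pytest.raises(ValueError, match="bafilomycin"):
            pdis.cumulative_pool_analysis(tr)


class TestIonomycin:
    def test_control_fraction_and_ratio(self):
        cfg = SessionConfig(seed=13, n_boutons=20, condition="control",
                            protocol=protocol_ionomycin())
        traces, _ = synthgen.simulate_phluorin_session(cfg)
        fr = [pdis.iono_fraction(tr, f_recycling_pct=27.6) for tr in traces]
        f_iono = np.mean([f.f_iono_pct for f in fr])
        assert f_iono == pytest.approx(54.0, rel=0.05)
        ratio = np.mean([f.ratio_iono_over_ap for f in fr])
        assert ratio == pytest.approx(54.0 / 27.6, rel=0.06)

    def test_equal_pools_give_zero_reluctant(self):
        cfg = SessionConfig(seed=13, n_boutons=3, condition="control",
                            protocol=protocol_ionomycin())
        traces, _ = synthgen.simulate_phluorin_session(cfg)
        out = pdis.iono_fraction(traces[0],
                                 f_recycling_pct=None)
        assert out.f_reluctant_pct is None
        out2 = pdis.iono_fraction(traces[0], f_recycling_pct=out.f_iono_pct)
        assert out2.f_reluctant_pct == pytest.approx(0.0, abs=1e-9)

    def test_order_violation_rejected(self):
        proto = [Epoch("rest", 0, 60), Epoch("nh4cl", 60, 60),
                 Epoch("ionomycin", 120, 60)]
        t = np.arange(0, 180, 2.0)
        tr = FluorTrace(t, np.full(len(t), 1.0), "b0", epochs=proto)
        with pytest.raises(ValueError, match="precede"):
            pdis.iono_fraction(tr)
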