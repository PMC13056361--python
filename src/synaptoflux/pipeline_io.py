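"""Configuration, file formats, statistics and end-to-end orchestration.

Tabular artifacts are UTF-8 CSV with mandatory headers (time in seconds,
currents in pA, potentials in mV); structured artifacts (configs, ledgers,
reports) are JSON.  ``run_pipeline`` chains simulate -> capacitance ->
deconvolve -> pools -> stats into one schema-versioned JSON report that is
byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as sp_stats

from . import capmeter, pool_dissection, release_kinetics, synthgen
from .datatypes import (Epoch, FluorTrace, GroundTruthLedger, QuantalTemplate,
                        SessionConfig, SineDCProtocol, SweepRecording,
                        _config_dict)
from .phmodel import protocol_single_train

__all__ = [
    "RunConfig",
    "StatResult",
    "stats_compare",
    "run_pipeline",
    "write_sweeps",
    "read_sweeps",
    "write_fluor_traces",
    "read_fluor_traces",
    "write_session",
    "read_session",
]

REPORT_SCHEMA = "synaptoflux-report/1"


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

class GeneratorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boutons_cap: int = Field(8, ge=1)
    n_boutons_imaging: int = Field(60, ge=1)
    n_paired: int = Field(8, ge=1)
    pulse_ms: float = Field(50.0, gt=0)
    egta_mM: float = 0.5
    current_noise_pA: float = Field(2.0, ge=0)
    fluor_noise_rel: float = Field(0.02, ge=0)


class CapmeterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lockin_window_ms: float = Field(10.0, gt=0)
    post_pulse_blank_ms: float = Field(50.0, ge=0)


class DeconvolutionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reg: float = Field(1e-5, gt=0)
    quantal_amp_pA: float = Field(30.0, gt=0)
    rise_tau_ms: float = Field(0.3, gt=0)
    decay_tau_ms: float = Field(5.0, gt=0)


class PoolsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_suppression_points: int = Field(60, ge=20)


class RunConfig(BaseModel):
    """Schema-validated top-level run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: Optional[str] = None
    generator: GeneratorBlock = GeneratorBlock()
    capmeter: CapmeterBlock = CapmeterBlock()
    deconvolution: DeconvolutionBlock = DeconvolutionBlock()
    pools: PoolsBlock = PoolsBlock()
    verbosity: int = 1


# --------------------------------------------------------------------------- #
# statistics
# --------------------------------------------------------------------------- #

@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    groups: list
    n_per_group: list
    note: str = ""
    table: Optional[list] = None


def stats_compare(groups: Sequence[np.ndarray], test: str,
                  labels: Optional[Sequence[str]] = None) -> StatResult:
    """Group comparison dispatch (paired/unpaired t, ANOVA, Dunnett, Tukey)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels else [f"g{k}" for k in range(len(groups))]
    ns = [len(g) for g in groups]
    if any(n < 2 for n in ns):
        raise ValueError("each group needs n >= 2")

    if test == "paired_t":
        if len(groups) != 2 or ns[0] != ns[1]:
            raise ValueError("paired t-test needs two equal-length samples")
        diff = groups[0] - groups[1]
        if np.allclose(diff, 0.0):
            return StatResult(test, 0.0, 1.0, labels, ns,
                              note="degenerate: all paired differences are zero")
        s, p = sp_stats.ttest_rel(groups[0], groups[1])
    elif test == "student_t":
        if len(groups) != 2:
            raise ValueError("Student t-test needs two groups")
        s, p = sp_stats.ttest_ind(groups[0], groups[1])
    elif test == "anova_oneway":
        s, p = sp_stats.f_oneway(*groups)
    elif test == "dunnett":
        res = sp_stats.dunnett(*groups[1:], control=groups[0])
        return StatResult(test, float(np.max(np.abs(res.statistic))),
                          float(np.min(res.pvalue)), labels, ns,
                          table=[{"vs_control": labels[k + 1],
                                  "statistic": float(res.statistic[k]),
                                  "p": float(res.pvalue[k])}
                                 for k in range(len(groups) - 1)])
    elif test == "tukey_kramer":
        res = sp_stats.tukey_hsd(*groups)
        pairs = [{"a": labels[i], "b": labels[j],
                  "statistic": float(res.statistic[i, j]),
                  "p": float(res.pvalue[i, j])}
                 for i in range(len(groups)) for j in range(i + 1, len(groups))]
        worst = min(pairs, key=lambda d: d["p"])
        return StatResult(test, worst["statistic"], worst["p"], labels, ns,
                          table=pairs)
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatResult(test, float(s), float(p), labels, ns)


# --------------------------------------------------------------------------- #
# readers / writers (round-trip safe)
# --------------------------------------------------------------------------- #

def write_sweeps(sweeps: Sequence[SweepRecording], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sw in sweeps:
        sw.to_frame().to_csv(out_dir / f"{sw.sweep_id}.csv", index=False,
                             float_format="%.9g")


def read_sweeps(in_dir: Path) -> list[SweepRecording]:
    out = []
    for p in sorted(Path(in_dir).glob("*.csv")):
        out.append(SweepRecording.from_frame(pd.read_csv(p), sweep_id=p.stem))
    return out


def write_fluor_traces(traces: Sequence[FluorTrace], path: Path) -> None:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({"time_s": tr.time_s,
                                  "bouton_id": tr.bouton_id, "F": tr.F}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.9g")


def read_fluor_traces(path: Path, epochs: Sequence[Epoch] = ()) -> list[FluorTrace]:
    df = pd.read_csv(path)
    out = []
    for bid, grp in df.groupby("bouton_id", sort=True):
        out.append(FluorTrace(time_s=grp["time_s"].to_numpy(),
                              F=grp["F"].to_numpy(), bouton_id=str(bid),
                              epochs=list(epochs)))
    return out


def write_session(out_dir: Path, traces: Sequence[FluorTrace],
                  ledger: GroundTruthLedger) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fluor_traces(traces, out_dir / "fluorescence.csv")
    (out_dir / "ledger.json").write_text(ledger.to_json())
    if ledger.config is not None:
        (out_dir / "config.json").write_text(
            json.dumps(_config_dict(ledger.config), indent=2, sort_keys=True))


def read_session(in_dir: Path) -> tuple[list[FluorTrace], GroundTruthLedger]:
    in_dir = Path(in_dir)
    ledger = GroundTruthLedger.from_json((in_dir / "ledger.json").read_text())
    epochs = ledger.config.protocol if ledger.config else ()
    traces = read_fluor_traces(in_dir / "fluorescence.csv", epochs)
    return traces, ledger


# --------------------------------------------------------------------------- #
# orchestration
# --------------------------------------------------------------------------- #

def _json_clean(obj):
    if isinstance(obj, dict):
        return {k: _json_clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float):
        return round(obj, 9)
    return obj


def _capacitance_stage(cfg: RunConfig, condition: str) -> dict:
    sweeps, ledger = synthgen.simulate_cm_cohort(
        n_boutons=cfg.generator.n_boutons_cap, condition=condition,
        pulse_ms=cfg.generator.pulse_ms, egta_mM=cfg.generator.egta_mM,
        noise_sd=cfg.generator.current_noise_pA, seed=cfg.seed)
    protocol = SineDCProtocol(lockin_window_ms=cfg.capmeter.lockin_window_ms,
                              post_pulse_blank_ms=cfg.capmeter.post_pulse_blank_ms)
    rows, recov = [], []
    for sw in sweeps:
        est = capmeter.analyze_cm_sweep(sw, protocol, cfg.generator.pulse_ms)
        rows.append({"sweep_id": sw.sweep_id,
                     "cm_norm_fF_per_pF": est.cm_norm_fF_per_pF,
                     "delta_cm_fF": est.delta_cm_fF,
                     "ica_pA_per_pF": est.ica_pA_per_pF,
                     "tau_act_ms": est.tau_act_ms})
        recov.append(est.delta_cm_fF - ledger.delta_cm_fF[sw.sweep_id])
    vals = np.array([r["cm_norm_fF_per_pF"] for r in rows])
    return {"per_sweep": rows, "mean_cm_norm_fF_per_pF": float(vals.mean()),
            "recovery_rmse_fF": float(np.sqrt(np.mean(np.square(recov)))),
            "values": vals}


def _deconvolution_stage(cfg: RunConfig, condition: str) -> dict:
    template = QuantalTemplate(amp_pA=cfg.deconvolution.quantal_amp_pA,
                               rise_tau_ms=cfg.deconvolution.rise_tau_ms,
                               decay_tau_ms=cfg.deconvolution.decay_tau_ms)
    pairs, ledger = synthgen.simulate_paired_cohort(
        n_boutons=cfg.generator.n_paired, condition=condition,
        template=template, noise_sd=cfg.generator.current_noise_pA,
        seed=cfg.seed)
    peaks, delays, truth_err = [], [], []
    for k, (pre, post) in enumerate(pairs):
        rate = release_kinetics.deconvolve_release(post, template,
                                                   reg=cfg.deconvolution.reg)
        p0 = post.meta["pulse_onset_ms"]
        release_kinetics.detect_onset(rate, (0.0, p0), p0)
        truth = ledger.release_waveforms[f"b{k:03d}"]
        peaks.append(rate.peak_v)
        if rate.delay_ms is not None:
            delays.append(rate.delay_ms)
        truth_err.append(rate.peak_v / truth["peak_rate"] - 1.0)
    return {"mean_peak_vesicles_per_ms": float(np.mean(peaks)),
            "mean_delay_ms": float(np.mean(delays)) if delays else None,
            "peak_recovery_rel_err": float(np.mean(np.abs(truth_err))),
            "n_onsets": len(delays)}


def _pools_stage(cfg: RunConfig) -> tuple[dict, tuple]:
    out: dict = {}
    n_img = cfg.generator.n_boutons_imaging
    for condition in ("control", "gpr55_active"):
        sc = SessionConfig(seed=cfg.seed, n_boutons=n_img, condition=condition,
                           protocol=protocol_single_train(),
                           fluor_noise_rel=cfg.generator.fluor_noise_rel)
        traces, _ = synthgen.simulate_phluorin_session(sc)
        dfs, taus = [], []
        for tr in traces:
            train = [e for e in tr.epochs if e.kind == "ap_train_400"][0]
            d, tau = pool_dissection.quantify_train_response(tr, train)
            dfs.append(d)
            if tau is not None:
                taus.append(tau)
        out[condition] = {"mean_dF400_pct": float(np.mean(dfs)),
                          "mean_tau_decay_s": float(np.mean(taus)),
                          "dF400": dfs}
    pre = np.array(out["control"]["dF400"])
    post = np.array(out["gpr55_active"]["dF400"])
    out["mean_suppression_pct"] = float(np.mean(1.0 - post / pre) * 100.0)

    x, r = synthgen.sample_suppression_dataset(
        n=cfg.pools.n_suppression_points, seed=cfg.seed)
    fit = pool_dissection.fit_suppression_relation(x, r, seed=cfg.seed)
    out["suppression_fit"] = {"a": fit.a, "b": fit.b, "c": fit.c,
                              "r_squared": fit.r_squared}
    for k in ("control", "gpr55_active"):
        out[k].pop("dF400")
    return out, (pre, post)


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> capacitance -> deconvolve -> pools -> stats, one report."""
    cfg_payload = json.loads(config.model_dump_json(exclude={"out_dir"}))
    report: dict = {"schema": REPORT_SCHEMA, "seed": config.seed,
                    "config": cfg_payload}
    cap_c = _capacitance_stage(config, "control")
    cap_g = _capacitance_stage(config, "gpr55_active")
    report["capacitance"] = {
        "control": {k: v for k, v in cap_c.items() if k != "values"},
        "gpr55_active": {k: v for k, v in cap_g.items() if k != "values"},
        "suppression_ratio": float(cap_g["mean_cm_norm_fF_per_pF"]
                                   / cap_c["mean_cm_norm_fF_per_pF"]),
    }
    report["deconvolution"] = {
        "control": _deconvolution_stage(config, "control"),
        "gpr55_active": _deconvolution_stage(config, "gpr55_active"),
    }
    pools, (pre, post) = _pools_stage(config)
    report["pools"] = pools
    st = stats_compare([cap_c["values"], cap_g["values"]], "student_t",
                       ["control", "gpr55_active"])
    report["stats"] = [{"test": st.test, "statistic": st.statistic, "p": st.p,
                        "groups": st.groups, "n": st.n_per_group}]
    stp = stats_compare([pre, post], "paired_t", ["pre", "post"])
    report["stats"].append({"test": stp.test, "statistic": stp.statistic,
                            "p": stp.p, "groups": stp.groups,
                            "n": stp.n_per_group})
    report = _json_clean(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        (out / "resolved_config.json").write_text(config.model_dump_json(indent=2))
    return report
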