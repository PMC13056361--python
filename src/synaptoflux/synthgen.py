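"""Forward simulation of every recording modality in the study.

Everything is generated from an explicit bouton model whose hidden parameters
are emitted in a :class:`~synaptoflux.datatypes.GroundTruthLedger`, so the
whole analysis chain (capacitance, deconvolution, pHluorin pools) can be
scored against planted truth without any external data.

Electrical sweeps are exact linear-circuit responses computed segment-wise in
closed form (steady sinusoid + DC + boundary transient), so the lock-in
analysis can be validated against the analytic admittance to numerical
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from . import calibration as cal
from .datatypes import (BoutonParams, Epoch, FluorTrace, GroundTruthLedger,
                        PhModelParams, QuantalTemplate, SessionConfig,
                        SineDCProtocol, SweepRecording, AmplitudeSeries)
from .phmodel import relative_fluorescence, simulate_states

__all__ = [
    "simulate_cm_sweep",
    "simulate_cm_cohort",
    "simulate_paired_recording",
    "simulate_paired_cohort",
    "simulate_minis",
    "simulate_phluorin_session",
    "apply_suppression",
    "sample_suppression_dataset",
    "simulate_gcamp",
    "simulate_eipsc_series",
    "draw_boutons",
    "expected_df400_pct",
]

PF, MOHM = 1e-12, 1e6


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# --------------------------------------------------------------------------- #
# exact passive-circuit response
# --------------------------------------------------------------------------- #

def _passive_segments(t: np.ndarray, segments, rs_mohm: float, rm_mohm: float,
                      holding_mV: float, omega: float) -> np.ndarray:
    """Pipette current (pA) of Rs-(Rm||Cm) for a piecewise command.

    ``segments`` is a list of (t0, t1, v_dc_mV, v_ac_phasor_mV, cm_pF); the
    command within a segment is Vdc + Im(Vac * exp(j*w*t)).  The membrane
    voltage is propagated exactly across boundaries (voltage-continuous, also
    across Cm jumps: newly added membrane arrives charged to Vm).
    """
    rs, rm = rs_mohm * MOHM, rm_mohm * MOHM
    alpha = rm / (rm + rs)
    i = np.zeros_like(t)
    vm_carry = holding_mV * 1e-3 * alpha          # start at DC steady state
    for (t0, t1, vdc_mV, vac_mV, cm_pF) in segments:
        sel = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
        tt = t[sel]
        cm = cm_pF * PF
        tau = cm * rs * rm / (rs + rm)
        vdc = vdc_mV * 1e-3
        vac = vac_mV * 1e-3
        vm_dc = vdc * alpha
        vmc = vac * (1.0 / (rs * cm)) / (1j * omega + 1.0 / tau)
        k0 = vm_carry - vm_dc - np.imag(vmc * np.exp(1j * omega * t0))
        vm = vm_dc + np.imag(vmc * np.exp(1j * omega * tt)) + k0 * np.exp(-(tt - t0) / tau)
        v = vdc + np.imag(vac * np.exp(1j * omega * tt))
        i[sel] = (v - vm) / rs * 1e12
        vm_carry = (vm_dc + np.imag(vmc * np.exp(1j * omega * t1))
                    + k0 * np.exp(-(t1 - t0) / tau))
    return i


def _egta_suppression_factor(pulse_ms: float, egta_mM: float,
                             gpr55_active: bool, short_factor: float = 1.3) -> float:
    """Extra suppression of short-pulse release under 5 mM EGTA + GPR55.

    Interpolates (in log duration) from ``short_factor`` at <=2 ms to 1.0 at
    >=50 ms; control release is EGTA-insensitive.
    """
    if not gpr55_active or egta_mM < 5.0:
        return 1.0
    w = np.clip((np.log(50.0) - np.log(max(pulse_ms, 1e-6)))
                / (np.log(50.0) - np.log(2.0)), 0.0, 1.0)
    return 1.0 + (short_factor - 1.0) * float(w)


def simulate_cm_sweep(params: BoutonParams, protocol: SineDCProtocol,
                      pulse_ms: float, noise_sd: float = 2.0, seed: int = 0,
                      pulse_mV: float = 0.0, egta_mM: float = 0.5,
                      ) -> SweepRecording:
    """Sine+DC sweep around one depolarizing pulse.

    Cm steps by C0 * rrp_density * (1 - exp(-T/tau_rel)) at pulse end (scaled
    by the bouton's suppression ratio and the EGTA coupling factor); the Ca
    current rides on the pulse segment; white current noise is added.
    """
    if pulse_ms <= 0:
        raise ValueError("pulse duration must be positive")
    rate = 50_000.0
    t, v = protocol.command(pulse_ms, rate, pulse_mV=pulse_mV)
    omega = 2 * np.pi * protocol.sine_freq_hz
    c0 = params.baseline_cm_pF
    rho_eff = (params.rrp_density_fF_per_pF * params.suppression_ratio
               / _egta_suppression_factor(pulse_ms, egta_mM,
                                          params.suppression_ratio < 1.0))
    dcm_fF = c0 * rho_eff * (1.0 - np.exp(-pulse_ms / params.release_tau_ms))
    c1 = c0 + dcm_fF * 1e-3

    ms = 1e-3
    hold = protocol.holding_mV
    amp = protocol.sine_peak_mV
    s0, s1 = protocol.step_start_ms * ms, (protocol.step_start_ms + protocol.step_dur_ms) * ms
    sine0 = protocol.sine_start_ms * ms
    p0 = protocol.pulse_start_ms * ms
    p1 = p0 + pulse_ms * ms
    t_end = t[-1] + 1.0 / rate
    vac = amp * np.exp(-1j * omega * sine0)       # sine phase: sin(w (t - sine0))
    segments = [
        (0.0, s0, hold, 0.0, c0),
        (s0, s1, hold - abs(protocol.step_mV), 0.0, c0),
        (s1, sine0, hold, 0.0, c0),
        (sine0, p0, hold, vac, c0),
        (p0, p1, pulse_mV, 0.0, c0),
        (p1, t_end, hold, vac, c1),
    ]
    i = _passive_segments(t, segments, params.rs_mohm, params.rm_mohm, hold, omega)

    in_pulse = (t >= p0) & (t < p1)
    i[in_pulse] += -c0 * params.ca_density_pA_per_pF * (
        1.0 - np.exp(-(t[in_pulse] - p0) / (params.ca_act_tau_ms * ms)))

    if noise_sd > 0:
        i = i + _rng(seed, 1).normal(0.0, noise_sd, len(i))
    return SweepRecording(time_s=t, command_mV=v, current_pA=i, rate_hz=rate,
                          meta={"pulse_ms": pulse_ms, "true_dcm_fF": float(dcm_fF),
                                "egta_mM": egta_mM})


# --------------------------------------------------------------------------- #
# bouton cohorts
# --------------------------------------------------------------------------- #

def expected_df400_pct(n_total: float | np.ndarray) -> float | np.ndarray:
    """Analytic single-train dF/F0 (%) implied by a bouton's size.

    Surface-to-volume scaling makes the AP-releasable amount grow as
    n_total^(2/3), so the relative response falls as n_total^(-1/3); the
    distribution mean is anchored at the reference value.
    """
    rel = (np.asarray(n_total, dtype=float) / cal.N_TOTAL_MEDIAN) ** (-1.0 / 3.0)
    return cal.DF400_REF_PCT * rel / np.exp(cal.SIZE_SIGMA_LOG ** 2 / 18.0)


def _f_ap_for_size(n_total: np.ndarray) -> np.ndarray:
    rel = (n_total / cal.N_TOTAL_MEDIAN) ** (-1.0 / 3.0)
    f = cal.F_AP_REF * rel / np.exp(cal.SIZE_SIGMA_LOG ** 2 / 18.0)
    return np.minimum(f, cal.F_IONO_REF)


def draw_boutons(n: int, condition: str = "control", seed: int = 0,
                 suppression_noise_sd: float = 0.12,
                 ) -> tuple[list[BoutonParams], dict]:
    """Seeded cohort with size heterogeneity and per-bouton GPR55 suppression.

    Sizes: n_total lognormal (median 600, sigma_log 0.5); C0 follows size as
    (n/600)^0.6 pF with small independent scatter.  Under ``gpr55_active``
    each bouton's AP-sensitive partition is scaled by the exponential
    suppression relation evaluated at its own pre-drug response.
    """
    rng_size = _rng(seed, 10)
    rng_sup = _rng(seed, 11)
    n_total = cal.N_TOTAL_MEDIAN * np.exp(
        rng_size.normal(0.0, cal.SIZE_SIGMA_LOG, n))
    n_total = np.clip(n_total, 90.0, None)
    c0 = (n_total / cal.N_TOTAL_MEDIAN) ** 0.6 * np.exp(rng_size.normal(0, 0.1, n))
    f_ap = _f_ap_for_size(n_total)

    ratios = np.ones(n)
    if condition == "gpr55_active":
        x_au = cal.BETA_AU_PER_PCT * expected_df400_pct(n_total)
        ratios = apply_suppression(x_au, noise_sd=suppression_noise_sd,
                                   rng=rng_sup)
    boutons = []
    for k in range(n):
        boutons.append(BoutonParams(
            baseline_cm_pF=float(c0[k]),
            n_total=float(n_total[k]),
            f_ap=float(f_ap[k]),
            f_iono=cal.F_IONO_REF,
            suppression_ratio=float(ratios[k]),
        ))
    return boutons, {"suppression_ratios": {f"b{k:03d}": float(ratios[k])
                                            for k in range(n)}}


def simulate_cm_cohort(n_boutons: int = 8, condition: str = "control",
                       pulse_ms: float = 50.0, egta_mM: float = 0.5,
                       noise_sd: float = 2.0, seed: int = 0,
                       protocol: Optional[SineDCProtocol] = None,
                       ) -> tuple[list[SweepRecording], GroundTruthLedger]:
    """Cohort of sine+DC sweeps (one bouton each) for a given pulse length."""
    protocol = protocol or SineDCProtocol()
    boutons, extra = draw_boutons(n_boutons, condition, seed)
    sweeps, ledger = [], GroundTruthLedger(boutons=boutons, extras=extra)
    ledger.suppression_ratios = extra["suppression_ratios"]
    for k, b in enumerate(boutons):
        sw = simulate_cm_sweep(b, protocol, pulse_ms, noise_sd=noise_sd,
                               seed=seed + 1000 + k, egta_mM=egta_mM)
        sw.sweep_id = f"b{k:03d}"
        sweeps.append(sw)
        ledger.delta_cm_fF[sw.sweep_id] = sw.meta["true_dcm_fF"]
    return sweeps, ledger


# --------------------------------------------------------------------------- #
# paired pre/post recordings and deconvolution truth
# --------------------------------------------------------------------------- #

def _release_waveform(t_ms: np.ndarray, onset_ms: float, peak_rate: float,
                      rise_ms: float = 0.6) -> np.ndarray:
    """Smooth unimodal fusion-rate pulse with a hard onset.

    v(u) = peak * u^2 * exp(2(1-u)), u = (t-onset)/rise; peaks at u = 1.
    """
    u = np.maximum(t_ms - onset_ms, 0.0) / rise_ms
    return peak_rate * u ** 2 * np.exp(2.0 * (1.0 - u))


def simulate_paired_recording(params: BoutonParams, template: QuantalTemplate,
                              pulse_ms: float = 2.0, noise_sd: float = 2.0,
                              seed: int = 0, pre_ms: float = 10.0,
                              total_ms: float = 80.0, rate: float = 50_000.0,
                              ) -> tuple[SweepRecording, SweepRecording, dict]:
    """Presynaptic Ca-current sweep plus the postsynaptic IPSC it evokes.

    The IPSC is the ground-truth fusion-rate waveform convolved with the
    quantal template (positive-deflection convention) plus white noise; the
    exact waveform is returned for the ledger.
    """
    if template.duration_ms < 4 * template.decay_tau_ms:
        raise ValueError("template support too short for the release waveform")
    n = int(round(total_ms * 1e-3 * rate))
    t = np.arange(n) / rate
    t_ms = t * 1e3
    p0 = pre_ms

    v_pre = np.full(n, -70.0)
    v_pre[(t_ms >= p0) & (t_ms < p0 + pulse_ms)] = 0.0
    ica = np.zeros(n)
    in_pulse = (t_ms >= p0) & (t_ms < p0 + pulse_ms)
    ica[in_pulse] = -params.baseline_cm_pF * params.ca_density_pA_per_pF * (
        1.0 - np.exp(-(t_ms[in_pulse] - p0) / params.ca_act_tau_ms))
    rng = _rng(seed, 2)
    pre = SweepRecording(t, v_pre, ica + rng.normal(0, noise_sd, n), rate,
                         meta={"pulse_ms": pulse_ms})

    onset = p0 + params.delay_true_ms
    peak = params.peak_rate_true * params.suppression_ratio
    v_true = _release_waveform(t_ms, onset, peak)
    dt_ms = 1e3 / rate
    h = template.sample(dt_ms)
    ipsc = np.convolve(v_true, h)[:n] * dt_ms
    post = SweepRecording(t, np.full(n, -70.0),
                          ipsc + rng.normal(0, noise_sd, n), rate,
                          meta={"pulse_onset_ms": p0})
    truth = {"t_ms": t_ms, "v_true": v_true, "onset_ms": onset,
             "peak_rate": float(peak),
             "cumulative": float(v_true.sum() * dt_ms)}
    return pre, post, truth


def simulate_paired_cohort(n_boutons: int = 8, condition: str = "control",
                           template: Optional[QuantalTemplate] = None,
                           rate_cv: float = 0.10, delay_cv: float = 0.05,
                           noise_sd: float = 2.0, seed: int = 0,
                           ) -> tuple[list, GroundTruthLedger]:
    """Cohort of paired recordings with mild bouton-to-bouton kinetic scatter."""
    template = template or QuantalTemplate()
    boutons, extra = draw_boutons(n_boutons, condition, seed)
    rng = _rng(seed, 3)
    out, ledger = [], GroundTruthLedger(boutons=boutons, extras=extra)
    ledger.suppression_ratios = extra["suppression_ratios"]
    for k, b in enumerate(boutons):
        b = replace(b,
                    peak_rate_true=b.peak_rate_true * float(
                        np.exp(rng.normal(0, rate_cv))),
                    delay_true_ms=b.delay_true_ms * float(
                        np.exp(rng.normal(0, delay_cv))))
        boutons[k] = b
        pre, post, truth = simulate_paired_recording(
            b, template, noise_sd=noise_sd, seed=seed + 2000 + k)
        out.append((pre, post))
        ledger.release_waveforms[f"b{k:03d}"] = {
            "onset_ms": truth["onset_ms"], "peak_rate": truth["peak_rate"],
            "cumulative": truth["cumulative"]}
    ledger.extras["template"] = template
    return out, ledger


def simulate_minis(rate_hz: float, template: Optional[QuantalTemplate] = None,
                   amp_cv: float = 0.3, duration_s: float = 120.0,
                   noise_sd: float = 2.0, seed: int = 0,
                   mean_amp_pA: float = 30.0, sample_rate: float = 20_000.0,
                   ) -> tuple[SweepRecording, dict]:
    """Poisson mIPSC train: lognormal amplitudes convolved with the template."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    template = template or QuantalTemplate()
    rng = _rng(seed, 4)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    n_ev = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, n_ev))
    sigma = np.sqrt(np.log(1.0 + amp_cv ** 2))
    amps = mean_amp_pA * np.exp(rng.normal(0, sigma, n_ev) - sigma ** 2 / 2)
    dt_ms = 1e3 / sample_rate
    h = template.sample(dt_ms) / template.amp_pA
    impulses = np.zeros(n)
    idx = np.minimum((times * sample_rate).astype(int), n - 1)
    np.add.at(impulses, idx, amps)
    trace = np.convolve(impulses, h)[:n] + rng.normal(0, noise_sd, n)
    sweep = SweepRecording(t, np.full(n, -70.0), trace, sample_rate,
                           meta={"rate_hz": rate_hz})
    return sweep, {"times_s": times, "amps_pA": amps}


# --------------------------------------------------------------------------- #
# suppression relation
# --------------------------------------------------------------------------- #

def apply_suppression(x_au, a: float = cal.SUPPRESSION_A,
                      b: float = cal.SUPPRESSION_B, c: float = cal.SUPPRESSION_C,
                      noise_sd: float = 0.0, seed: int = 0,
                      rng: Optional[np.random.Generator] = None):
    """Per-bouton post/pre response ratio r = a*exp(-b*x) + c (+ noise, > 0)."""
    x = np.asarray(x_au, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    r = a * np.exp(-b * x) + c
    if noise_sd > 0:
        rng = rng if rng is not None else _rng(seed, 5)
        r = r + rng.normal(0.0, noise_sd, np.shape(x))
    r = np.maximum(r, 0.02)
    return float(r) if np.isscalar(x_au) else r


def sample_suppression_dataset(n: int = 120, x_pct_range: tuple = (2.0, 60.0),
                               r_squared: float = 0.506, seed: int = 0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (x, ratio) pairs spanning a wide pre-drug response range.

    Residual noise is scaled so the population R^2 of the true relation
    matches the target; ratios are truncated positive.
    """
    rng = _rng(seed, 6)
    x_au = cal.BETA_AU_PER_PCT * rng.uniform(*x_pct_range, n)
    clean = apply_suppression(x_au)
    var_sig = float(np.var(clean))
    noise_sd = np.sqrt(var_sig * (1.0 / r_squared - 1.0))
    ratios = np.maximum(clean + rng.normal(0, noise_sd, n), 0.02)
    return x_au, ratios


# --------------------------------------------------------------------------- #
# pHluorin sessions
# --------------------------------------------------------------------------- #

def simulate_phluorin_session(config: SessionConfig,
                              ph: Optional[PhModelParams] = None,
                              boutons: Optional[Sequence[BoutonParams]] = None,
                              dt_fine: float = 0.1,
                              ) -> tuple[list[FluorTrace], GroundTruthLedger]:
    """Per-bouton fluorescence traces for one imaging session.

    Boutons are drawn from the default size distribution (shared across
    control/gpr55_active sessions with the same seed, so drug effects are
    paired per bouton); the state model supplies the deterministic signal and
    multiplicative frame noise is added on top.
    """
    ph = ph or PhModelParams()
    if not config.epochs("nh4cl"):
        warnings.warn("protocol has no terminal NH4Cl epoch: downstream "
                      "total-pool normalization will be impossible",
                      stacklevel=2)
    if boutons is None:
        boutons, _ = draw_boutons(config.n_boutons, config.condition,
                                  config.seed)
    f_ap_eff = np.array([b.f_ap_effective for b in boutons])
    f_iono = np.array([b.f_iono for b in boutons])
    states = simulate_states(f_ap_eff, f_iono, ph, config.protocol, dt=dt_fine)
    f_rel = relative_fluorescence(states, ph)

    stride = int(round(1.0 / (config.imaging_rate_hz * dt_fine)))
    idx = np.arange(0, len(states.t), stride)
    t_frames = states.t[idx]
    rng = _rng(config.seed, 7)
    traces = []
    ledger = GroundTruthLedger(boutons=list(boutons), ph=ph, config=config)
    for k, b in enumerate(boutons):
        bid = f"b{k:03d}"
        scale = b.n_total / (1.0 - ph.f_surf)     # camera units per reporter
        f = scale * f_rel[k, idx]
        if config.fluor_noise_rel > 0:
            f = f * (1.0 + rng.normal(0, config.fluor_noise_rel, len(idx)))
        traces.append(FluorTrace(time_s=t_frames, F=f, bouton_id=bid,
                                 epochs=config.protocol,
                                 meta={"n_total": b.n_total,
                                       "f_ap_eff": float(f_ap_eff[k])}))
        ledger.suppression_ratios[bid] = b.suppression_ratio
        ledger.released_per_epoch[bid] = {
            str(ep): float(v[k] * b.n_total)
            for ep, v in states.released_per_epoch.items()}
    ledger.extras["dark_pool_final"] = states.dark_pool_final
    return traces, ledger


# --------------------------------------------------------------------------- #
# GCaMP
# --------------------------------------------------------------------------- #

GCAMP_AMPS = {"varicosity": {"train": 5.3, "ionomycin": 16.2},
              "axon": {"train": 1.6, "ionomycin": 15.1}}


def simulate_gcamp(n_rois: int, protocol: Sequence[Epoch],
                   compartment: str = "varicosity", noise_rel: float = 0.02,
                   seed: int = 0, imaging_rate_hz: float = 0.5,
                   ) -> list[FluorTrace]:
    """Ca-indicator dF/F traces: constant train responses, larger ionomycin."""
    if compartment not in GCAMP_AMPS:
        raise ValueError("compartment must be 'varicosity' or 'axon'")
    amps = GCAMP_AMPS[compartment]
    t_end = max(e.end_s for e in protocol)
    dt = 1.0 / imaging_rate_hz
    t = np.arange(0.0, t_end, dt)
    sig = np.zeros_like(t)
    for e in protocol:
        if e.kind == "ap_train_400":
            rise = (1.0 - np.exp(-(t - e.start_s) / 2.0))
            on = (t >= e.start_s) & (t < e.end_s)
            sig[on] = np.maximum(sig[on], amps["train"] * rise[on])
            after = t >= e.end_s
            peak = amps["train"] * (1.0 - np.exp(-e.duration_s / 2.0))
            sig[after] = np.maximum(sig[after],
                                    peak * np.exp(-(t[after] - e.end_s) / 4.0))
        elif e.kind == "ionomycin":
            on = t >= e.start_s
            sig[on] = np.maximum(
                sig[on], amps["ionomycin"] * (1.0 - np.exp(-(t[on] - e.start_s) / 5.0)))
    rng = _rng(seed, 8)
    traces = []
    for k in range(n_rois):
        f = (1.0 + sig) * (1.0 + rng.normal(0, noise_rel, len(t)))
        traces.append(FluorTrace(time_s=t, F=f, bouton_id=f"roi{k:03d}",
                                 epochs=list(protocol), compartment=compartment))
    return traces


# --------------------------------------------------------------------------- #
# evoked-IPSC amplitude series (quantal CV analysis)
# --------------------------------------------------------------------------- #

def simulate_eipsc_series(n_sites: int = 100, p_release: float = 0.3,
                          quantal_nA: float = 0.0667, quantal_cv: float = 0.0,
                          stim_rate_hz: float = 0.1, duration_min: float = 15.0,
                          drug_time_min: float = 5.0, drug_n_factor: float = 1.0,
                          drug_p_factor: float = 1.0, seed: int = 0,
                          ) -> AmplitudeSeries:
    """Binomial quantal amplitude time course with a drug step.

    Each stimulus releases Binomial(N, p) quanta; the drug multiplies the
    release-site count and/or probability from ``drug_time_min`` onward.
    """
    rng = _rng(seed, 9)
    times = np.arange(0.0, duration_min * 60.0, 1.0 / stim_rate_hz) / 60.0
    amps = np.empty_like(times)
    for k, tm in enumerate(times):
        n_eff = n_sites if tm < drug_time_min else max(
            int(round(n_sites * drug_n_factor)), 1)
        p_eff = p_release if tm < drug_time_min else min(p_release * drug_p_factor, 1.0)
        q = rng.binomial(n_eff, p_eff)
        scale = 1.0 if quantal_cv <= 0 else np.prod(
            np.exp(rng.normal(0, np.sqrt(np.log(1 + quantal_cv ** 2)), 1)))
        amps[k] = q * quantal_nA * scale
    return AmplitudeSeries(time_min=times, amp_nA=amps)
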