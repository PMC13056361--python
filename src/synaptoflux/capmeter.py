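"""Sine+DC membrane-capacitance measurement.

A voltage-clamped bouton is modelled as an access resistance Rs in series
with the membrane (Rm parallel Cm).  A 1 kHz sinusoid riding on the holding
potential probes the complex admittance; together with the DC conductance the
three circuit elements are identified in closed form, time-resolved over
integer-cycle lock-in windows.  Exocytosis is read out as the capacitance
step dCm across a depolarizing pulse, normalized to the clamped-area Cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .datatypes import SineDCProtocol, SweepRecording

__all__ = [
    "circuit_admittance",
    "AdmittancePoint",
    "CircuitEstimate",
    "lockin_extract",
    "solve_circuit",
    "estimate_circuit_series",
    "measure_delta_cm",
    "estimate_clamped_cm",
    "measure_ica",
    "analyze_cm_sweep",
]

# unit conventions used throughout this module (SI internally):
PF = 1e-12
MOHM = 1e6


def circuit_admittance(cm_pF: float, rs_mohm: float, rm_mohm: float,
                       freq_hz: float) -> complex:
    """Closed-form admittance (S) of Rs in series with (Rm || Cm)."""
    cm, rs, rm = cm_pF * PF, rs_mohm * MOHM, rm_mohm * MOHM
    ym = 1.0 / rm + 1j * 2 * np.pi * freq_hz * cm
    return ym / (1.0 + rs * ym)


@dataclass
class AdmittancePoint:
    """One lock-in window: complex admittance plus DC conductance (S)."""

    t_s: float
    re_y: float
    im_y: float
    g_dc: float
    valid: bool = True
    note: str = ""


@dataclass
class CircuitEstimate:
    """Time-resolved (Cm, Rs, Rm) with exocytosis read-outs."""

    t_s: np.ndarray
    cm_pF: np.ndarray
    rs_mohm: np.ndarray
    rm_mohm: np.ndarray
    valid: np.ndarray
    delta_cm_fF: Optional[float] = None
    cm_norm_fF_per_pF: Optional[float] = None
    cm_clamped_pF: Optional[float] = None
    ica_pA_per_pF: Optional[float] = None
    tau_act_ms: Optional[float] = None
    flags: list = field(default_factory=list)


# --------------------------------------------------------------------------- #
# lock-in extraction
# --------------------------------------------------------------------------- #

def lockin_extract(sweep: SweepRecording, protocol: SineDCProtocol,
                   pulse_ms: float) -> list[AdmittancePoint]:
    """Two-phase correlation of current against the command sinusoid.

    Windows overlapping the depolarizing pulse or the post-pulse blank
    interval are omitted.  The DC conductance follows the declared
    convention g_dc = <I> / (holding - leak reversal).
    """
    t, v, i = sweep.time_s, sweep.command_mV, sweep.current_pA
    f = protocol.sine_freq_hz
    win_s = protocol.lockin_window_ms * 1e-3
    n_win = int(round(win_s * sweep.rate_hz))
    if n_win < 2:
        raise ValueError("lock-in window shorter than two samples")

    p0 = protocol.pulse_start_ms * 1e-3
    p1 = p0 + pulse_ms * 1e-3
    blank_end = p1 + protocol.post_pulse_blank_ms * 1e-3
    sine0 = protocol.sine_start_ms * 1e-3
    sine_end = p1 + protocol.post_sine_ms * 1e-3

    # command must actually carry the sinusoid somewhere
    vac = v - np.median(v)
    if np.max(np.abs(vac)) < 0.5 * protocol.sine_peak_mV:
        raise ValueError("command contains no sine component")

    drive_mV = protocol.holding_mV - protocol.leak_reversal_mV
    points: list[AdmittancePoint] = []
    # skip one settle window after sine onset (decaying boundary transient)
    start = sine0 + win_s
    while start + win_s <= t[-1] + 0.5 / sweep.rate_hz:
        end = start + win_s
        if end <= p0 or start >= blank_end:
            # window must lie fully inside a sine segment
            if start >= sine0 - 1e-12 and end <= sine_end + 1e-9:
                k0 = int(round(start * sweep.rate_hz))
                seg_i = i[k0:k0 + n_win]
                seg_t = t[k0:k0 + n_win]
                seg_v = v[k0:k0 + n_win]
                if len(seg_i) == n_win:
                    ref = np.exp(-2j * np.pi * f * seg_t)
                    i_ph = 2.0 * np.mean(seg_i * ref)
                    v_ph = 2.0 * np.mean((seg_v - protocol.holding_mV) * ref)
                    if abs(v_ph) < 1e-3:
                        points.append(AdmittancePoint(start + win_s / 2, 0.0, 0.0,
                                                      0.0, False, "no sine in window"))
                    else:
                        # pA/mV = nS -> S
                        y = (i_ph / v_ph) * 1e-9
                        g_dc = (np.mean(seg_i) / drive_mV) * 1e-9
                        points.append(AdmittancePoint(start + win_s / 2,
                                                      float(y.real), float(y.imag),
                                                      float(g_dc)))
        start += win_s
    return points


# --------------------------------------------------------------------------- #
# circuit inversion
# --------------------------------------------------------------------------- #

def solve_circuit(pt: AdmittancePoint, omega: float) -> tuple[float, float, float]:
    """Invert (Re Y, Im Y, G_dc) to (Cm pF, Rs MOhm, Rm MOhm).

    With z = 1/Y = zr + j zi and u = zr - Rs, the DC constraint
    Rs + Rm = 1/G_dc collapses to u = zi^2 / (1/G_dc - zr), after which
    Gm = u / (u^2 + zi^2) and  w Cm = -zi / (u^2 + zi^2).

    Raises ValueError when the point is inconsistent with a passive circuit.
    """
    y = complex(pt.re_y, pt.im_y)
    if pt.g_dc <= 0 or y.real <= 0 or y.imag <= 0:
        raise ValueError("admittance point inconsistent with a passive circuit")
    z = 1.0 / y
    zr, zi = z.real, z.imag            # zi < 0 for capacitive load
    r_tot = 1.0 / pt.g_dc
    if r_tot <= zr:
        raise ValueError("DC resistance below AC input resistance: no passive solution")
    u = zi * zi / (r_tot - zr)
    rs = zr - u
    if rs <= 0 or u <= 0:
        raise ValueError("no strictly positive series resistance solution")
    gm = u / (u * u + zi * zi)
    cm = -zi / (omega * (u * u + zi * zi))
    rm = r_tot - rs
    if cm <= 0 or rm <= 0:
        raise ValueError("no positive (Cm, Rm) solution")
    # verify against the forward map (guards numerically marginal points)
    y_chk = circuit_admittance(cm / PF, rs / MOHM, rm / MOHM, omega / (2 * np.pi))
    resid = abs(y_chk - y) / abs(y)
    if resid > 1e-9:
        raise ValueError(f"forward-map residual {resid:.2e} exceeds tolerance")
    return cm / PF, rs / MOHM, rm / MOHM


def estimate_circuit_series(points: list[AdmittancePoint],
                            freq_hz: float) -> CircuitEstimate:
    """Run the closed-form inversion over a window series; invalid points flagged."""
    omega = 2 * np.pi * freq_hz
    t, cm, rs, rm, ok = [], [], [], [], []
    flags = []
    for pt in points:
        t.append(pt.t_s)
        if not pt.valid:
            cm.append(np.nan); rs.append(np.nan); rm.append(np.nan); ok.append(False)
            flags.append(f"{pt.t_s:.3f}s: {pt.note}")
            continue
        try:
            c, s, m = solve_circuit(pt, omega)
            cm.append(c); rs.append(s); rm.append(m); ok.append(True)
        except ValueError as err:
            cm.append(np.nan); rs.append(np.nan); rm.append(np.nan); ok.append(False)
            flags.append(f"{pt.t_s:.3f}s: {err}")
    return CircuitEstimate(
        t_s=np.asarray(t), cm_pF=np.asarray(cm), rs_mohm=np.asarray(rs),
        rm_mohm=np.asarray(rm), valid=np.asarray(ok, dtype=bool), flags=flags,
    )


# --------------------------------------------------------------------------- #
# exocytosis read-outs
# --------------------------------------------------------------------------- #

def measure_delta_cm(est: CircuitEstimate, pulse_window: tuple[float, float],
                     cm_clamped_pF: Optional[float] = None,
                     blank_s: float = 0.05, min_points: int = 10,
                     drift_tol_fF_per_s: float = 50.0) -> CircuitEstimate:
    """Capacitance step across the pulse, normalized to clamped-area Cm.

    dCm = mean(Cm after the blank) - mean(Cm before the pulse); requires at
    least ``min_points`` valid windows on each side.
    """
    p0, p1 = pulse_window
    pre = est.valid & (est.t_s < p0)
    post = est.valid & (est.t_s >= p1 + blank_s)
    if pre.sum() < min_points or post.sum() < min_points:
        raise ValueError("need >= %d valid windows on each side of the pulse"
                         % min_points)
    cm_pre = est.cm_pF[pre]
    t_pre = est.t_s[pre]
    slope = np.polyfit(t_pre, cm_pre, 1)[0] * 1e3  # fF/s
    if abs(slope) > drift_tol_fF_per_s:
        est.flags.append(f"baseline drift {slope:.1f} fF/s exceeds tolerance")
    delta_fF = (est.cm_pF[post].mean() - cm_pre.mean()) * 1e3
    cm_ref = cm_clamped_pF if cm_clamped_pF is not None else float(cm_pre.mean())
    est.delta_cm_fF = float(delta_fF)
    est.cm_norm_fF_per_pF = float(delta_fF / cm_ref)
    est.cm_clamped_pF = float(cm_ref)
    return est


def estimate_clamped_cm(sweep: SweepRecording, protocol: SineDCProtocol,
                        settle_ms: float = 5.0) -> float:
    """Clamped-area Cm (pF) from the capacitive transient of the test step.

    Integrates the baseline-subtracted onset transient charge and divides by
    the step size, after removing the steady-state resistive current.
    """
    dv = abs(protocol.step_mV)
    if dv not in (5.0, 10.0):
        raise ValueError("step must be 5 or 10 mV")
    fs = sweep.rate_hz
    s0 = protocol.step_start_ms * 1e-3
    s1 = s0 + protocol.step_dur_ms * 1e-3
    if protocol.step_dur_ms < settle_ms + 1.0:
        raise ValueError("step too short for a settled tail")
    i = sweep.current_pA
    t = sweep.time_s
    base = i[(t >= 0) & (t < s0)].mean()
    tail = i[(t >= s1 - settle_ms * 1e-3) & (t < s1)]
    if tail.std() > 10 * i[(t >= 0) & (t < s0)].std() + 1e-12:
        raise ValueError("transient not settled within the step")
    i_ss = tail.mean()
    on = (t >= s0) & (t < min(s1, s0 + 3e-3))
    tt = t[on] - s0
    y = i[on] - i_ss
    sign = -1.0 if y[0] < 0 else 1.0
    y = y * sign
    # charge from an exponential fit of the onset transient: Q = A*tau is
    # robust even when the access time constant is near the sample interval
    a0 = max(float(y[0]), 1e-6)
    tau0 = max(2.0 / fs, 2e-5)

    def model(ts, a, tau):
        return a * np.exp(-ts / tau)

    popt, _ = optimize.curve_fit(model, tt, y, p0=[a0, tau0],
                                 bounds=([0, 1e-7], [np.inf, 5e-3]),
                                 maxfev=20_000)
    q_pA_s = popt[0] * popt[1]
    cm_pF = q_pA_s / dv * 1e3                    # pA*s/mV = nF -> *1e3 pF
    return float(cm_pF)


def measure_ica(sweep: SweepRecording, protocol: SineDCProtocol, pulse_ms: float,
                cm_clamped_pF: float, circuit: tuple[float, float, float],
                pulse_mV: float = 0.0, blank_ms: float = 0.3,
                ) -> tuple[float, float]:
    """Peak Ca-current density (pA/pF) and activation tau (ms).

    The passive response to the voltage step (leak plus capacitive transient,
    predicted from the fitted circuit) is subtracted before the fit — the
    scaled step-response template is computed analytically from (Cm, Rs, Rm).
    """
    cm_pF, rs_mohm, rm_mohm = circuit
    cm, rs, rm = cm_pF * PF, rs_mohm * MOHM, rm_mohm * MOHM
    fs = sweep.rate_hz
    t = sweep.time_s
    p0 = protocol.pulse_start_ms * 1e-3
    p1 = p0 + pulse_ms * 1e-3
    sel = (t >= p0) & (t < p1)
    if sel.sum() < 5:
        raise ValueError("pulse window too short")
    tt = t[sel] - p0

    # analytic passive response to a step holding -> pulse_mV
    tau = cm * rs * rm / (rs + rm)
    v0, v1 = protocol.holding_mV * 1e-3, pulse_mV * 1e-3
    vm0 = v0 * rm / (rs + rm)
    vm_inf = v1 * rm / (rs + rm)
    vm = vm_inf + (vm0 - vm_inf) * np.exp(-tt / tau)
    i_passive = (v1 - vm) / rs * 1e12  # pA

    ica = sweep.current_pA[sel] - i_passive
    keep = tt > blank_ms * 1e-3
    tt_ms = tt[keep] * 1e3
    y = ica[keep]

    def model(tms, amp, tau_ms):
        return -amp * (1.0 - np.exp(-tms / tau_ms))

    amp0 = max(-y.min(), 1.0)
    try:
        popt, _ = optimize.curve_fit(model, tt_ms, y, p0=[amp0, 1.0],
                                     bounds=([0, 0.01], [np.inf, 50.0]),
                                     maxfev=10_000)
    except RuntimeError as err:
        raise ValueError(f"Ca-current fit did not converge: {err}") from err
    amp, tau_ms = popt
    return float(amp / cm_clamped_pF), float(tau_ms)


# --------------------------------------------------------------------------- #
# one-call sweep analysis
# --------------------------------------------------------------------------- #

def analyze_cm_sweep(sweep: SweepRecording, protocol: SineDCProtocol,
                     pulse_ms: float, with_ica: bool = True) -> CircuitEstimate:
    """Full chain on one sweep: lock-in, inversion, clamped Cm, dCm, ICa."""
    pts = lockin_extract(sweep, protocol, pulse_ms)
    est = estimate_circuit_series(pts, protocol.sine_freq_hz)
    cm_clamped = estimate_clamped_cm(sweep, protocol)
    p0 = protocol.pulse_start_ms * 1e-3
    p1 = p0 + pulse_ms * 1e-3
    measure_delta_cm(est, (p0, p1), cm_clamped_pF=cm_clamped,
                     blank_s=protocol.post_pulse_blank_ms * 1e-3)
    if with_ica:
        pre = est.valid & (est.t_s < p0)
        circuit = (float(np.nanmean(est.cm_pF[pre])),
                   float(np.nanmean(est.rs_mohm[pre])),
                   float(np.nanmean(est.rm_mohm[pre])))
        try:
            ica_norm, tau_act = measure_ica(sweep, protocol, pulse_ms,
                                            cm_clamped, circuit)
            est.ica_pA_per_pF = ica_norm
            est.tau_act_ms = tau_act
        except ValueError as err:
            est.flags.append(f"ICa fit: {err}")
    return est
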