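"""Shared domain containers for the presynaptic analysis pipeline.

All time-series are plain numpy arrays inside small dataclasses; units follow
electrophysiology conventions: time in seconds on disk (milliseconds where a
field name says so), potentials in mV, currents in pA, capacitances in pF
(increments in fF), fluorescence in arbitrary camera units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SweepRecording",
    "Epoch",
    "SessionConfig",
    "BoutonParams",
    "PhModelParams",
    "GroundTruthLedger",
    "FluorTrace",
    "SineDCProtocol",
    "QuantalTemplate",
    "AmplitudeSeries",
]


# --------------------------------------------------------------------------- #
# electrophysiology containers
# --------------------------------------------------------------------------- #

@dataclass
class SweepRecording:
    """A voltage-clamp sweep: command voltage, recorded current, metadata."""

    time_s: np.ndarray
    command_mV: np.ndarray
    current_pA: np.ndarray
    rate_hz: float
    sweep_id: str = "sweep"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.command_mV = np.asarray(self.command_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if not (len(self.time_s) == len(self.command_mV) == len(self.current_pA)):
            raise ValueError("time, command and current must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def n(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "command_mV": self.command_mV,
                "current_pA": self.current_pA,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sweep_id: str = "sweep",
                   meta: Optional[dict] = None) -> "SweepRecording":
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("sweep needs at least two samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            time_s=t,
            command_mV=df["command_mV"].to_numpy(dtype=float),
            current_pA=df["current_pA"].to_numpy(dtype=float),
            rate_hz=rate,
            sweep_id=sweep_id,
            meta=dict(meta or {}),
        )


@dataclass
class QuantalTemplate:
    """Unitary miniature-IPSC waveform used for convolution/deconvolution.

    Biexponential difference ``(exp(-t/decay) - exp(-t/rise))`` normalized so
    its peak equals ``amp_pA`` (one vesicle's peak current).
    """

    amp_pA: float = 30.0
    rise_tau_ms: float = 0.3
    decay_tau_ms: float = 5.0
    duration_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= self.rise_tau_ms:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.amp_pA <= 0:
            raise ValueError("quantal amplitude must be positive")

    def _peak_time_ms(self) -> float:
        tr, td = self.rise_tau_ms, self.decay_tau_ms
        return tr * td / (td - tr) * np.log(td / tr)

    def sample(self, dt_ms: float) -> np.ndarray:
        """Waveform sampled at ``dt_ms``; h[0] = 0, peak = amp_pA."""
        t = np.arange(0.0, self.duration_ms, dt_ms)
        raw = np.exp(-t / self.decay_tau_ms) - np.exp(-t / self.rise_tau_ms)
        tp = self._peak_time_ms()
        peak = np.exp(-tp / self.decay_tau_ms) - np.exp(-tp / self.rise_tau_ms)
        return self.amp_pA * raw / peak

    @property
    def charge_pA_ms(self) -> float:
        """Analytic unit charge (pA*ms) of the full (untruncated) waveform."""
        tr, td = self.rise_tau_ms, self.decay_tau_ms
        tp = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-tp / td) - np.exp(-tp / tr)
        return self.amp_pA * (td - tr) / peak

    @property
    def risetime_20_80_ms(self) -> float:
        dt = min(self.rise_tau_ms, 0.05) / 50.0
        h = self.sample(dt)
        peak = h.max()
        i20 = np.argmax(h >= 0.2 * peak)
        i80 = np.argmax(h >= 0.8 * peak)
        return (i80 - i20) * dt

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QuantalTemplate":
        return cls(**json.loads(text))


@dataclass
class AmplitudeSeries:
    """Evoked-IPSC amplitude time course for CV analysis."""

    time_min: np.ndarray
    amp_nA: np.ndarray
    bin_min: float = 1.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.amp_nA = np.asarray(self.amp_nA, dtype=float)
        if len(self.time_min) != len(self.amp_nA):
            raise ValueError("time and amplitude length mismatch")


# --------------------------------------------------------------------------- #
# sine+DC protocol
# --------------------------------------------------------------------------- #

@dataclass
class SineDCProtocol:
    """Sine+DC capacitance protocol: sinusoid on a steady holding potential.

    The lock-in window must contain an integer number of sine cycles; the
    interval right after the depolarizing pulse is blanked because membrane
    conductance is unstable there.
    """

    holding_mV: float = -80.0
    sine_freq_hz: float = 1000.0
    sine_peak_mV: float = 30.0
    lockin_window_ms: float = 10.0
    post_pulse_blank_ms: float = 50.0
    step_mV: float = 10.0          # hyperpolarizing step for clamped-area Cm
    step_start_ms: float = 10.0
    step_dur_ms: float = 20.0
    sine_start_ms: float = 50.0
    pre_sine_ms: float = 200.0     # sine length before the pulse
    post_sine_ms: float = 200.0    # sine length after the pulse
    leak_reversal_mV: float = 0.0  # declared convention for the DC conductance

    def __post_init__(self) -> None:
        n_cycles = self.lockin_window_ms * 1e-3 * self.sine_freq_hz
        if abs(n_cycles - round(n_cycles)) > 1e-9 or round(n_cycles) < 1:
            raise ValueError("lock-in window must hold an integer number of sine cycles")

    @property
    def pulse_start_ms(self) -> float:
        return self.sine_start_ms + self.pre_sine_ms

    def total_ms(self, pulse_ms: float) -> float:
        return self.pulse_start_ms + pulse_ms + self.post_sine_ms

    def command(self, pulse_ms: float, rate_hz: float,
                pulse_mV: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Command waveform (t in s, V in mV) for one sweep."""
        n = int(round(self.total_ms(pulse_ms) * 1e-3 * rate_hz))
        t = np.arange(n) / rate_hz
        v = np.full(n, self.holding_mV)
        tms = t * 1e3
        in_step = (tms >= self.step_start_ms) & (tms < self.step_start_ms + self.step_dur_ms)
        v[in_step] -= abs(self.step_mV)
        p0 = self.pulse_start_ms
        sine_on = ((tms >= self.sine_start_ms) & (tms < p0)) | (
            (tms >= p0 + pulse_ms) & (tms < p0 + pulse_ms + self.post_sine_ms)
        )
        v[sine_on] += self.sine_peak_mV * np.sin(
            2 * np.pi * self.sine_freq_hz * (t[sine_on] - self.sine_start_ms * 1e-3)
        )
        in_pulse = (tms >= p0) & (tms < p0 + pulse_ms)
        v[in_pulse] = pulse_mV
        return t, v


# --------------------------------------------------------------------------- #
# generator parameterization
# --------------------------------------------------------------------------- #

@dataclass
class BoutonParams:
    """Ground-truth biophysical parameters of one simulated bouton."""

    baseline_cm_pF: float = 1.0          # clamped membrane capacitance C0
    rs_mohm: float = 20.0                # access (series) resistance
    rm_mohm: float = 2000.0              # membrane resistance
    rrp_density_fF_per_pF: float = 31.0  # releasable capacitance per membrane
    release_tau_ms: float = 8.0          # depletion tau of dCm vs pulse length
    ca_density_pA_per_pF: float = 53.0   # peak Ca-current density
    ca_act_tau_ms: float = 1.0           # Ca-current activation tau
    n_total: float = 600.0               # vesicles at the bouton
    f_iono: float = 0.54                 # Ca-sensitive (ionomycin) fraction
    f_ap: float = 0.276                  # AP-sensitive recycling fraction
    suppression_ratio: float = 1.0       # GPR55 scaling of the AP pool
    delay_true_ms: float = 1.63          # depolarization-to-release latency
    peak_rate_true: float = 45.7         # peak fusion velocity, vesicles/ms

    def __post_init__(self) -> None:
        if min(self.baseline_cm_pF, self.rs_mohm, self.rm_mohm) <= 0:
            raise ValueError("circuit parameters must be strictly positive")
        if self.rrp_density_fF_per_pF < 0 or self.ca_density_pA_per_pF < 0:
            raise ValueError("densities must be non-negative")
        if not (0.0 < self.f_ap <= self.f_iono <= 1.0):
            raise ValueError("need 0 < f_ap <= f_iono <= 1")
        if self.suppression_ratio <= 0:
            raise ValueError("suppression_ratio must be positive")

    @property
    def f_ap_effective(self) -> float:
        """AP-sensitive fraction after GPR55 partition shrinkage (capped at f_iono)."""
        return min(self.f_ap * self.suppression_ratio, self.f_iono)


@dataclass
class PhModelParams:
    """Optical state-model parameters for synapto-pHluorin.

    ``tau_quench_s`` is the resting re-quench clock (endocytosis plus
    re-acidification collapsed); ``tau_fast_s`` is an extra activity-coupled
    retrieval pathway active only during AP trains; ``f_stranded`` is the
    fraction of fused reporters stranded bright on the surface beyond the
    session timescale (gives the partial, not complete, post-train decay).
    """

    q_quench: float = 0.05
    f_surf: float = 0.177804
    tau_quench_s: float = 42.1
    tau_fast_s: float = 20.3158
    f_stranded: float = 0.213904
    per_train_release: float = 0.414383
    replenish_rate: float = 0.0          # extra reserve->pool refill (frac/s)
    train_release_tau_s: float = 10.0    # within-train front-loading
    tau_kcl_s: float = 3.0
    tau_iono_s: float = 10.0
    tau_nh4cl_s: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_quench < 1.0 and 0.0 < self.f_surf < 1.0):
            raise ValueError("q_quench and f_surf must lie in (0, 1)")
        if self.tau_quench_s <= 0 or self.tau_fast_s <= 0:
            raise ValueError("quench time constants must be positive")
        if not (0.0 <= self.f_stranded < 1.0):
            raise ValueError("f_stranded in [0, 1)")
        if not (0.0 < self.per_train_release <= 1.0):
            raise ValueError("per_train_release in (0, 1]")

    @property
    def f0_unit(self) -> float:
        """Resting fluorescence per reporter unit."""
        return self.f_surf + (1.0 - self.f_surf) * self.q_quench


# --------------------------------------------------------------------------- #
# session protocol / ledger
# --------------------------------------------------------------------------- #

EPOCH_KINDS = {
    "rest",
    "ap_train_400",
    "depol_pulse",
    "bafilomycin",
    "kcl",
    "ionomycin",
    "nh4cl",
}


@dataclass
class Epoch:
    kind: str
    start_s: float
    duration_s: float
    param: float = 0.0  # pulse length (ms) for depol_pulse epochs

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if self.duration_s < 0 or self.start_s < 0:
            raise ValueError("epoch times must be non-negative")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SessionConfig:
    """One imaging/recording session: who, when, what protocol."""

    seed: int = 0
    n_boutons: int = 60
    condition: str = "control"           # control | gpr55_active
    egta_mM: float = 0.5
    protocol: Sequence[Epoch] = field(default_factory=list)
    ephys_rate_hz: float = 50_000.0
    imaging_rate_hz: float = 0.5
    current_noise_pA: float = 2.0
    fluor_noise_rel: float = 0.02

    def __post_init__(self) -> None:
        if self.condition not in ("control", "gpr55_active"):
            raise ValueError("condition must be 'control' or 'gpr55_active'")
        if self.n_boutons < 1:
            raise ValueError("need at least one bouton")
        if self.egta_mM not in (0.5, 5.0):
            raise ValueError("egta_mM must be 0.5 or 5.0")
        eps = sorted(self.protocol, key=lambda e: e.start_s)
        # agent epochs (bafilomycin etc.) mark bath state and may span trains;
        # only stimulus epochs must not overlap one another.
        stim = [e for e in eps if e.kind in ("ap_train_400", "depol_pulse", "rest")]
        for a, b in zip(stim, stim[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"overlapping stimulus epochs at {b.start_s} s")
        self.protocol = list(eps)

    @property
    def duration_s(self) -> float:
        return max((e.end_s for e in self.protocol), default=0.0)

    def epochs(self, kind: str) -> list[Epoch]:
        return [e for e in self.protocol if e.kind == kind]


@dataclass
class GroundTruthLedger:
    """Hidden truth emitted with every synthetic dataset."""

    boutons: list[BoutonParams] = field(default_factory=list)
    ph: Optional[PhModelParams] = None
    config: Optional[SessionConfig] = None
    released_per_epoch: dict = field(default_factory=dict)   # bouton_id -> [vesicles]
    delta_cm_fF: dict = field(default_factory=dict)          # bouton_id -> dCm
    suppression_ratios: dict = field(default_factory=dict)   # bouton_id -> r
    release_waveforms: dict = field(default_factory=dict)    # bouton_id -> (t_ms, v)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = {
            "boutons": [asdict(b) for b in self.boutons],
            "ph": asdict(self.ph) if self.ph else None,
            "config": _config_dict(self.config) if self.config else None,
            "released_per_epoch": _clean(self.released_per_epoch),
            "delta_cm_fF": _clean(self.delta_cm_fF),
            "suppression_ratios": _clean(self.suppression_ratios),
            "release_waveforms": _clean(self.release_waveforms),
            "extras": _clean(self.extras),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        cfg = None
        if d.get("config"):
            c = dict(d["config"])
            c["protocol"] = [Epoch(**e) for e in c.get("protocol", [])]
            cfg = SessionConfig(**c)
        return cls(
            boutons=[BoutonParams(**b) for b in d.get("boutons", [])],
            ph=PhModelParams(**d["ph"]) if d.get("ph") else None,
            config=cfg,
            released_per_epoch=d.get("released_per_epoch", {}),
            delta_cm_fF=d.get("delta_cm_fF", {}),
            suppression_ratios=d.get("suppression_ratios", {}),
            release_waveforms=d.get("release_waveforms", {}),
            extras=d.get("extras", {}),
        )


def _config_dict(cfg: SessionConfig) -> dict:
    d = asdict(cfg)
    d["protocol"] = [asdict(e) for e in cfg.protocol]
    return d


# --------------------------------------------------------------------------- #
# fluorescence container
# --------------------------------------------------------------------------- #

@dataclass
class FluorTrace:
    """Per-bouton fluorescence time course with its protocol epochs."""

    time_s: np.ndarray
    F: np.ndarray
    bouton_id: str
    epochs: Sequence[Epoch] = field(default_factory=list)
    compartment: str = "varicosity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.time_s) != len(self.F):
            raise ValueError("time and F length mismatch")

    def window(self, t0: float, t1: float) -> np.ndarray:
        return self.F[(self.time_s >= t0) & (self.time_s < t1)]

    def baseline_F0(self, before_s: Optional[float] = None,
                    min_frames: int = 3) -> float:
        """Mean fluorescence before ``before_s`` (default: first non-rest epoch)."""
        if before_s is None:
            stim = [e for e in self.epochs if e.kind != "rest"]
            before_s = min(e.start_s for e in stim) if stim else self.time_s[-1]
        sel = self.time_s < before_s
        if sel.sum() < min_frames:
            raise ValueError("not enough baseline frames")
        return float(self.F[sel].mean())
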