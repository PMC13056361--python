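"""Vesicle/reporter state model behind the synthetic pHluorin traces.

Each bouton's vesicles are partitioned into an AP-sensitive recycling pool
(fraction ``f_ap`` of ``n_total``), a reluctant Ca-sensitive remainder
(``f_iono - f_ap``, released only by ionomycin), and a never-released rest.
A fused reporter is bright; it re-quenches (endocytosis + re-acidification,
one collapsed clock ``tau_quench_s``) and returns to the dark recycling pool,
except for a fraction ``f_stranded`` that remains bright on the surface
beyond the session timescale.  During AP trains an additional activity-coupled
fast retrieval pathway (``tau_fast_s``) operates.  Bafilomycin switches all
re-quenching off from its application onward; NH4Cl neutralizes every lumen.

All state variables are deterministic fractions of ``n_total``; measurement
noise is applied downstream, per frame, by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Epoch, PhModelParams

__all__ = [
    "StateTrace",
    "simulate_states",
    "relative_fluorescence",
    "protocol_single_train",
    "protocol_repeated_trains",
    "protocol_ionomycin",
]

TRAIN_S = 20.0  # 400 APs at 20 Hz


@dataclass
class StateTrace:
    """Fine-grid state history for a cohort of boutons."""

    t: np.ndarray                      # fine time grid, s
    bright: np.ndarray                 # (n_boutons, n_t) bright vesicle fraction
    neutralized: np.ndarray            # (n_t,) NH4Cl lumen neutralization 0..1
    released_per_epoch: dict = field(default_factory=dict)  # epoch idx -> (n_b,)
    dark_pool_final: np.ndarray = None


def _train_density(u: float, tau: float, T: float) -> float:
    """Front-loaded within-train release density, integral 1 over [0, T]."""
    return np.exp(-u / tau) / (tau * (1.0 - np.exp(-T / tau)))


def simulate_states(f_ap: np.ndarray, f_iono: np.ndarray, ph: PhModelParams,
                    protocol: list[Epoch], dt: float = 0.1) -> StateTrace:
    """Integrate the state model on a fine grid (exponential-Euler steps)."""
    f_ap = np.atleast_1d(np.asarray(f_ap, dtype=float))
    f_iono = np.atleast_1d(np.asarray(f_iono, dtype=float))
    if np.any(f_ap > f_iono + 1e-12) or np.any(f_iono > 1.0 + 1e-12):
        raise ValueError("need f_ap <= f_iono <= 1 per bouton")
    nb = len(f_ap)
    t_end = max(e.end_s for e in protocol)
    nt = int(np.ceil(t_end / dt)) + 1
    t = np.arange(nt) * dt

    D = f_ap.copy()                    # dark AP-sensitive pool
    REL = f_iono - f_ap                # dark reluctant Ca-sensitive pool
    BQ = np.zeros(nb)                  # bright, re-quenchable
    BS = np.zeros(nb)                  # bright, stranded
    nu = 0.0                           # NH4Cl neutralization level

    trains = [(k, e) for k, e in enumerate(protocol) if e.kind == "ap_train_400"]
    baf_start = min((e.start_s for e in protocol if e.kind == "bafilomycin"),
                    default=np.inf)
    kcl = [e for e in protocol if e.kind == "kcl"]
    iono = [e for e in protocol if e.kind == "ionomycin"]
    nh4 = [e for e in protocol if e.kind == "nh4cl"]

    bright = np.empty((nb, nt))
    neutral = np.empty(nt)
    released = {k: np.zeros(nb) for k, _ in trains}
    for e_list, label in ((kcl, "kcl"), (iono, "ionomycin")):
        for k, e in enumerate(protocol):
            if e.kind == label:
                released[k] = np.zeros(nb)

    D0_by_train = {}
    for step in range(nt):
        ts = t[step]
        bright[:, step] = BQ + BS
        neutral[step] = nu

        in_train = False
        for k, e in trains:
            if e.start_s <= ts < e.end_s:
                if k not in D0_by_train:
                    D0_by_train[k] = D.copy()
                u = ts - e.start_s
                g = _train_density(u, ph.train_release_tau_s, e.duration_s)
                dR = np.minimum(ph.per_train_release * D0_by_train[k] * g * dt, D)
                D -= dR
                BS += ph.f_stranded * dR
                BQ += (1.0 - ph.f_stranded) * dR
                released[k] += dR
                in_train = True

        for k, e in enumerate(protocol):
            if e.kind == "kcl" and e.start_s <= ts < e.end_s:
                dR = D * (1.0 - np.exp(-dt / ph.tau_kcl_s))
                D -= dR
                BS += ph.f_stranded * dR
                BQ += (1.0 - ph.f_stranded) * dR
                released[k] += dR
            elif e.kind == "ionomycin" and e.start_s <= ts < e.end_s:
                rate = 1.0 - np.exp(-dt / ph.tau_iono_s)
                dR = (D + REL) * rate
                D *= np.exp(-dt / ph.tau_iono_s)
                REL *= np.exp(-dt / ph.tau_iono_s)
                BS += ph.f_stranded * dR
                BQ += (1.0 - ph.f_stranded) * dR
                released[k] += dR

        if ts < baf_start:
            k_req = 1.0 / ph.tau_quench_s + (1.0 / ph.tau_fast_s if in_train else 0.0)
            dQ = BQ * (1.0 - np.exp(-k_req * dt))
            BQ -= dQ
            D += dQ

        if ph.replenish_rate > 0:
            deficit = np.maximum(f_ap - (D + BQ + BS), 0.0)
            D += np.minimum(ph.replenish_rate * dt, 1.0) * deficit

        if any(e.start_s <= ts < e.end_s for e in nh4):
            nu += (1.0 - nu) * (1.0 - np.exp(-dt / ph.tau_nh4cl_s))

    return StateTrace(t=t, bright=bright, neutralized=neutral,
                      released_per_epoch=released, dark_pool_final=D.copy())


def relative_fluorescence(states: StateTrace, ph: PhModelParams) -> np.ndarray:
    """Fluorescence per reporter unit: surface + bright + quenched vesicular."""
    b = states.bright
    nu = states.neutralized[None, :]
    dark_brightness = ph.q_quench + (1.0 - ph.q_quench) * nu
    vesicular = b + (1.0 - b) * dark_brightness
    return ph.f_surf + (1.0 - ph.f_surf) * vesicular


# --------------------------------------------------------------------------- #
# canonical session protocols
# --------------------------------------------------------------------------- #

def protocol_single_train(baseline_s: float = 60.0, decay_s: float = 240.0,
                          nh4cl_s: float = 60.0) -> list[Epoch]:
    """One 400-AP train, a long decay window, then terminal NH4Cl."""
    t = baseline_s
    eps = [Epoch("rest", 0.0, baseline_s),
           Epoch("ap_train_400", t, TRAIN_S)]
    t += TRAIN_S
    eps.append(Epoch("rest", t, decay_s))
    t += decay_s
    eps.append(Epoch("nh4cl", t, nh4cl_s))
    return eps


def protocol_repeated_trains(n_pre: int = 2, n_post: int = 8,
                             baseline_s: float = 60.0, inter_s: float = 100.0,
                             kcl_s: float = 60.0, nh4cl_s: float = 60.0,
                             with_kcl: bool = True) -> list[Epoch]:
    """Repetitive 400-AP trains around a bafilomycin switch, then KCl, NH4Cl."""
    eps = [Epoch("rest", 0.0, baseline_s)]
    t = baseline_s
    for _ in range(n_pre):
        eps.append(Epoch("ap_train_400", t, TRAIN_S))
        t += TRAIN_S
        eps.append(Epoch("rest", t, inter_s))
        t += inter_s
    baf_start = t
    for _ in range(n_post):
        eps.append(Epoch("ap_train_400", t, TRAIN_S))
        t += TRAIN_S
        eps.append(Epoch("rest", t, inter_s))
        t += inter_s
    if with_kcl:
        eps.append(Epoch("kcl", t, kcl_s))
        t += kcl_s
    eps.append(Epoch("nh4cl", t, nh4cl_s))
    end = t + nh4cl_s
    eps.append(Epoch("bafilomycin", baf_start, end - baf_start))
    return eps


def protocol_ionomycin(n_pre: int = 2, baseline_s: float = 60.0,
                       inter_s: float = 100.0, iono_s: float = 90.0,
                       nh4cl_s: float = 60.0) -> list[Epoch]:
    """Trains, bafilomycin, ionomycin, then terminal NH4Cl."""
    eps = [Epoch("rest", 0.0, baseline_s)]
    t = baseline_s
    for _ in range(n_pre):
        eps.append(Epoch("ap_train_400", t, TRAIN_S))
        t += TRAIN_S
        eps.append(Epoch("rest", t, inter_s))
        t += inter_s
    baf_start = t
    eps.append(Epoch("rest", t, 30.0))
    t += 30.0
    eps.append(Epoch("ionomycin", t, iono_s))
    t += iono_s
    eps.append(Epoch("nh4cl", t, nh4cl_s))
    end = t + nh4cl_s
    eps.append(Epoch("bafilomycin", baf_start, end - baf_start))
    return eps
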