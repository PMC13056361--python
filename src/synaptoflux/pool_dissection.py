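"""Vesicle-pool structure from capacitance and pHluorin measurements.

Readily-releasable pool size from dCm-vs-pulse-duration curves; AP-sensitive,
Ca-sensitive and reluctant pool fractions from repeated-train / bafilomycin /
KCl / ionomycin / NH4Cl pHluorin protocols; the per-bouton suppression
relation r(x) = a*exp(-b*x) + c and the distribution prediction built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import Epoch, FluorTrace

__all__ = [
    "PulseReleaseCurve",
    "PoolFractions",
    "SuppressionFit",
    "smoothed_peak",
    "fit_peak",
    "fit_rrp",
    "quantify_train_response",
    "normalize_to_total",
    "fit_suppression_relation",
    "predict_suppressed_distribution",
    "cumulative_pool_analysis",
    "iono_fraction",
    "gcamp_dff",
]


@dataclass
class PulseReleaseCurve:
    durations_ms: np.ndarray
    cm_norm_fF_per_pF: np.ndarray
    plateau_fF_per_pF: float = np.nan
    tau_fit_ms: float = np.nan
    cov: Optional[np.ndarray] = None
    residuals: Optional[np.ndarray] = None
    converged: bool = False
    egta_mM: float = 0.5
    drug: str = "control"


@dataclass
class PoolFractions:
    f_recycling_pct: Optional[float] = None   # bafilomycin cumulative plateau / total
    f_iono_pct: Optional[float] = None        # ionomycin plateau / total
    f_reluctant_pct: Optional[float] = None
    ratio_iono_over_ap: Optional[float] = None
    per_train_increments_pct: Optional[list] = None
    baf_enhancement_pct: Optional[float] = None
    remaining_40s_pct: Optional[float] = None
    kcl_increment_pct: Optional[float] = None
    dF_nh4cl_pct: Optional[float] = None
    flags: list = field(default_factory=list)


@dataclass
class SuppressionFit:
    a: float
    b: float
    c: float
    r_squared: float
    n: int = 0
    flags: list = field(default_factory=list)

    def __call__(self, x):
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #

def smoothed_peak(f: np.ndarray, k: int = 3) -> float:
    """Peak as the max of a k-frame moving average (suppresses 1-frame noise)."""
    f = np.asarray(f, dtype=float)
    if len(f) == 0:
        raise ValueError("empty window")
    if len(f) < k:
        return float(f.mean())
    kernel = np.ones(k) / k
    return float(np.convolve(f, kernel, mode="valid").max())


def fit_peak(f: np.ndarray, deg: int = 3) -> float:
    """Peak as the maximum of a low-order polynomial fit over the window.

    Taking the max of raw (or lightly smoothed) noisy frames is biased
    upward by frame noise, and the bias is absolute — it distorts ratios of
    small to large responses.  The max of a fitted smooth curve averages the
    noise over the whole window and is unbiased to first order.
    """
    f = np.asarray(f, dtype=float)
    if len(f) < deg + 3:
        return smoothed_peak(f)
    x = np.linspace(-1.0, 1.0, len(f))
    coef = np.polynomial.polynomial.polyfit(x, f, deg)
    xs = np.linspace(-1.0, 1.0, 201)
    return float(np.polynomial.polynomial.polyval(xs, coef).max())


def _frames(trace: FluorTrace, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    sel = (trace.time_s >= t0) & (trace.time_s < t1)
    return trace.time_s[sel], trace.F[sel]


def _next_epoch_start(epochs: Sequence[Epoch], after_s: float,
                      kinds: tuple = ("ap_train_400", "kcl", "ionomycin", "nh4cl"),
                      ) -> float:
    starts = [e.start_s for e in epochs if e.kind in kinds and e.start_s > after_s + 1e-9]
    return min(starts) if starts else np.inf


# --------------------------------------------------------------------------- #
# RRP from dCm vs pulse duration
# --------------------------------------------------------------------------- #

def fit_rrp(durations_ms: Sequence[float], cm_norm: Sequence[float],
            seed: int = 0, **labels) -> PulseReleaseCurve:
    """Single-exponential depletion fit cm_norm(T) = P * (1 - exp(-T/tau)).

    Multi-start (3 seeded initializations) least squares; on non-convergence
    the raw points are still returned with ``converged=False``.
    """
    T = np.asarray(durations_ms, dtype=float)
    y = np.asarray(cm_norm, dtype=float)
    if len(np.unique(T)) < 4:
        raise ValueError("need >= 4 distinct pulse durations")
    curve = PulseReleaseCurve(durations_ms=T, cm_norm_fF_per_pF=y, **labels)

    def model(t, P, tau):
        return P * (1.0 - np.exp(-t / tau))

    rng = np.random.default_rng(seed)
    p_guess = max(y.max(), 1e-6)
    starts = [(p_guess, 8.0), (p_guess * 1.5, 3.0), (p_guess, 25.0)]
    starts += [(p_guess * rng.uniform(0.8, 1.5), rng.uniform(2, 30))]
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, T, y, p0=p0, bounds=([0, 0.1], [np.inf, 500.0]),
                maxfev=20_000)
        except RuntimeError:
            continue
        res = y - model(T, *popt)
        sse = float(res @ res)
        key = (sse, float(np.linalg.norm(popt)))
        if best is None or key < best[0]:
            best = (key, popt, pcov, res)
    if best is None:
        return curve
    _, popt, pcov, res = best
    curve.plateau_fF_per_pF = float(popt[0])
    curve.tau_fit_ms = float(popt[1])
    curve.cov = pcov
    curve.residuals = res
    curve.converged = True
    return curve


# --------------------------------------------------------------------------- #
# train responses
# --------------------------------------------------------------------------- #

def quantify_train_response(trace: FluorTrace, train_epoch: Epoch,
                            f0_session: Optional[float] = None,
                            baseline_frames: int = 10,
                            fit_decay: bool = True,
                            peak_pad_s: float = 4.0,
                            ) -> tuple[float, Optional[float]]:
    """(dF_400 in % of F0, post-train decay tau in s or None).

    dF_400 = (peak F in the train window - pre-train baseline) / F0 * 100,
    with the running pre-train baseline so that repeated-train protocols
    measure each train's own increment.  The decay tau is a single-exponential
    fit towards a free local plateau over the post-train segment.
    """
    t0, t1 = train_epoch.start_s, train_epoch.end_s
    pre_t, pre_f = _frames(trace, max(0.0, t0 - 60.0), t0)
    if len(pre_f) < max(baseline_frames, 3):
        raise ValueError("not enough pre-train baseline frames")
    base = float(pre_f[-baseline_frames:].mean())
    f0 = f0_session if f0_session is not None else trace.baseline_F0()
    _, win_f = _frames(trace, t0, t1 + peak_pad_s)
    if len(win_f) == 0:
        raise ValueError("train window holds no frames")
    peak = fit_peak(win_f)
    df400 = (peak - base) / f0 * 100.0

    tau: Optional[float] = None
    if fit_decay:
        seg_end = min(_next_epoch_start(trace.epochs, t1), trace.time_s[-1])
        dec_t, dec_f = _frames(trace, t1 + peak_pad_s, seg_end)
        if len(dec_f) >= 8 and peak > base:
            tt = dec_t - dec_t[0]
            # pin the local plateau from the late segment (several time
            # constants out) and fit only amplitude and tau: much better
            # conditioned than a free 3-parameter fit on noisy frames
            n_tail = max(int(0.12 * len(dec_f)), 3)
            if tt[-1] - tt[0] > 150.0:
                c_fix = float(dec_f[-n_tail:].mean())

                def model(t, a, tau_s):
                    return c_fix + a * np.exp(-t / tau_s)

                p0 = [max(float(dec_f[0] - c_fix), 1e-9), 40.0]
                bounds = ([0.0, 1.0], [np.inf, 500.0])
            else:
                def model(t, c, a, tau_s):
                    return c + a * np.exp(-t / tau_s)

                c0 = float(dec_f[-n_tail:].mean())
                p0 = [c0, max(float(dec_f[0] - c0), 1e-9), 40.0]
                bounds = ([-np.inf, 0.0, 1.0], [np.inf, np.inf, 500.0])
            try:
                popt, _ = optimize.curve_fit(model, tt, dec_f, p0=p0,
                                             bounds=bounds, maxfev=20_000)
                tau = float(popt[-1])
                if tau > 495.0 or tau < 1.05:     # pinned at a bound: unidentified
                    tau = None
            except RuntimeError:
                tau = None
    return float(df400), tau


# --------------------------------------------------------------------------- #
# total-pool normalization (NH4Cl) and bouton-size scaling
# --------------------------------------------------------------------------- #

def normalize_to_total(traces: Sequence[FluorTrace],
                       train_index: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-bouton (dF_400, dF_NH4Cl, dF_NH4Cl^(2/3)) table with an OLS line.

    dF quantities are reported both in camera units (``*_au``, used for the
    surface-area scaling plot) and as % of F0.  Boutons with non-positive
    NH4Cl response are excluded and logged in the fit dict.
    """
    rows = []
    excluded = []
    for tr in traces:
        nh4 = [e for e in tr.epochs if e.kind == "nh4cl"]
        trains = [e for e in tr.epochs if e.kind == "ap_train_400"]
        if not nh4 or len(trains) <= train_index:
            raise ValueError("trace lacks a train or terminal NH4Cl epoch")
        f0 = tr.baseline_F0()
        df_pct, _ = quantify_train_response(tr, trains[train_index],
                                            f0_session=f0, fit_decay=False)
        e = nh4[-1]
        _, tail = _frames(tr, e.end_s - min(20.0, e.duration_s / 2), e.end_s)
        nh4_level = float(tail.mean())
        d_nh4_au = nh4_level - f0
        if d_nh4_au <= 0:
            excluded.append(tr.bouton_id)
            continue
        rows.append({
            "bouton_id": tr.bouton_id,
            "dF400_au": df_pct / 100.0 * f0,
            "dF400_pct": df_pct,
            "dF_nh4cl_au": d_nh4_au,
            "dF_nh4cl_pct": d_nh4_au / f0 * 100.0,
            "dF_nh4cl_23_au": d_nh4_au ** (2.0 / 3.0),
        })
    table = pd.DataFrame(rows)
    fit: dict = {"excluded": excluded, "degenerate": False}
    if len(table) >= 2 and table["dF_nh4cl_23_au"].std() > 1e-12:
        res = stats.linregress(table["dF_nh4cl_23_au"], table["dF400_au"])
        fit.update(slope=float(res.slope), intercept=float(res.intercept),
                   r_squared=float(res.rvalue ** 2))
    else:
        fit["degenerate"] = True
    return table, fit


# --------------------------------------------------------------------------- #
# suppression relation
# --------------------------------------------------------------------------- #

def fit_suppression_relation(x: Sequence[float], ratio: Sequence[float],
                             seed: int = 0) -> SuppressionFit:
    """Seeded multi-start least squares of r(x) = a*exp(-b*x) + c."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if len(x) < 20:
        raise ValueError("need >= 20 paired boutons")
    flags = []
    if x.min() <= 0 or x.max() / max(x.min(), 1e-12) < 3.0:
        flags.append("x-range narrower than 3-fold: asymptote c weakly identified")

    def model(xx, a, b, c):
        return a * np.exp(-b * xx) + c

    rng = np.random.default_rng(seed)
    starts = [(1.0, 0.03, 0.35), (0.5, 0.01, 0.6), (1.5, 0.1, 0.1)]
    starts += [(rng.uniform(0.2, 2.0), rng.uniform(0.005, 0.2), rng.uniform(0.0, 1.0))
               for _ in range(3)]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, x, r, p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, 10.0, 1.5]), maxfev=30_000)
        except RuntimeError:
            continue
        res = r - model(x, *popt)
        key = (float(res @ res), float(np.linalg.norm(popt)))
        if best is None or key < best[0]:
            best = (key, popt)
    if best is None:
        raise ValueError("suppression fit did not converge from any start")
    (sse, _), popt = best
    sst = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return SuppressionFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                          r_squared=float(r2), n=len(x), flags=flags)


def predict_suppressed_distribution(control: pd.DataFrame, fit: SuppressionFit,
                                    observed: Optional[pd.DataFrame] = None,
                                    x_column: str = "dF400_au",
                                    x_scale: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Convert each control bouton's dF_400 by r(x) and compare distributions.

    ``x_scale`` maps the table's dF_400 column onto the units the relation was
    fitted in.  Returns the converted table and a two-sided two-sample KS
    comparison against ``observed`` (if given).
    """
    pred = control.copy()
    r = fit(control[x_column].to_numpy() * x_scale)
    for col in ("dF400_au", "dF400_pct"):
        if col in pred:
            pred[col] = pred[col] * r
    comparison: dict = {}
    if observed is not None and len(observed) and len(pred):
        ks = stats.ks_2samp(pred["dF400_au"], observed["dF400_au"])
        comparison = {"ks_statistic": float(ks.statistic), "p_value": float(ks.pvalue)}
    return pred, comparison


# --------------------------------------------------------------------------- #
# cumulative (bafilomycin) pool analysis
# --------------------------------------------------------------------------- #

def _nh4cl_level_pct(trace: FluorTrace, f0: float) -> float:
    nh4 = [e for e in trace.epochs if e.kind == "nh4cl"]
    if not nh4:
        raise ValueError("no NH4Cl epoch: total-pool normalization impossible")
    e = nh4[-1]
    _, tail = _frames(trace, e.end_s - min(20.0, e.duration_s / 2), e.end_s)
    return (float(tail.mean()) - f0) / f0 * 100.0


def cumulative_pool_analysis(trace: FluorTrace, min_post_trains: int = 6,
                             ) -> PoolFractions:
    """Pool fractions from a trains + bafilomycin + KCl + NH4Cl session.

    The cumulative (non-decaying) signal after each bafilomycin-era train is
    fitted with a saturating exponential in train index; its asymptote over
    the NH4Cl-revealed total gives the AP-sensitive recycling fraction.
    """
    baf = [e for e in trace.epochs if e.kind == "bafilomycin"]
    if not baf:
        raise ValueError("no bafilomycin epoch in protocol")
    baf_start = min(e.start_s for e in baf)
    trains = [e for e in trace.epochs if e.kind == "ap_train_400"]
    pre = [e for e in trains if e.end_s <= baf_start + 1e-9]
    post = [e for e in trains if e.start_s >= baf_start - 1e-9]
    if len(post) < min_post_trains:
        raise ValueError(f"need >= {min_post_trains} trains after bafilomycin")
    f0 = trace.baseline_F0()
    out = PoolFractions()
    out.dF_nh4cl_pct = _nh4cl_level_pct(trace, f0)

    def _plateau_after(e: Epoch) -> float:
        stop = min(_next_epoch_start(trace.epochs, e.end_s), trace.time_s[-1])
        _, seg = _frames(trace, e.end_s + 4.0, min(e.end_s + 40.0, stop))
        if len(seg) == 0:
            _, seg = _frames(trace, e.end_s, stop)
        return (float(seg.mean()) - f0) / f0 * 100.0

    # cumulative level before the first post-baf train, then after each train
    lead_t0 = max(baf_start - 30.0, 0.0)
    _, lead = _frames(trace, lead_t0, post[0].start_s)
    cum0 = (float(lead.mean()) - f0) / f0 * 100.0
    cum = np.array([cum0] + [_plateau_after(e) for e in post])
    idx = np.arange(len(cum), dtype=float)
    increments = np.diff(cum)
    out.per_train_increments_pct = increments.tolist()

    # refuse extrapolation when increments do not fall off
    half = max(len(increments) // 2, 1)
    if increments[:half].mean() <= increments[half:].mean() + 1e-12:
        out.flags.append("per-train increments not decreasing: plateau not extrapolated")
        plateau = cum[-1]
    else:
        def model(n, P, c0, k):
            return P - (P - c0) * np.exp(-n / k)

        try:
            popt, _ = optimize.curve_fit(
                model, idx, cum, p0=[cum[-1], cum[0], 1.5],
                bounds=([0.0, -np.inf, 0.05], [np.inf, np.inf, 50.0]),
                maxfev=20_000)
            plateau = float(popt[0])
        except RuntimeError:
            out.flags.append("saturating fit failed; last cumulative level used")
            plateau = cum[-1]
    out.f_recycling_pct = plateau / out.dF_nh4cl_pct * 100.0

    # bafilomycin enhancement of the per-train response
    if pre:
        pre_df = [quantify_train_response(trace, e, f0_session=f0,
                                          fit_decay=False)[0] for e in pre]
        post_df, _ = quantify_train_response(trace, post[0], f0_session=f0,
                                             fit_decay=False)
        mean_pre = float(np.mean(pre_df))
        if mean_pre > 0:
            out.baf_enhancement_pct = (post_df / mean_pre - 1.0) * 100.0

        # fraction of the first pre-baf train response remaining 40 s later
        e0 = pre[0]
        t0, t1 = e0.start_s, e0.end_s
        _, base_f = _frames(trace, max(0.0, t0 - 20.0), t0)
        _, win_f = _frames(trace, t0, t1 + 4.0)
        _, at40 = _frames(trace, t1 + 38.0, t1 + 44.0)
        peak = fit_peak(win_f)
        if len(at40) and peak > base_f.mean():
            out.remaining_40s_pct = float(
                (at40.mean() - base_f.mean()) / (peak - base_f.mean()) * 100.0)

    kcl = [e for e in trace.epochs if e.kind == "kcl"]
    if kcl:
        e = kcl[-1]
        _, after = _frames(trace, max(e.end_s - 12.0, e.start_s), e.end_s)
        kcl_level = (float(after.mean()) - f0) / f0 * 100.0
        out.kcl_increment_pct = float((kcl_level - cum[-1]) / plateau * 100.0)
    return out


def iono_fraction(trace: FluorTrace,
                  f_recycling_pct: Optional[float] = None) -> PoolFractions:
    """Ca-sensitive pool from an ionomycin + NH4Cl session."""
    iono = [e for e in trace.epochs if e.kind == "ionomycin"]
    nh4 = [e for e in trace.epochs if e.kind == "nh4cl"]
    if not iono or not nh4 or iono[-1].start_s >= nh4[-1].start_s:
        raise ValueError("ionomycin epoch must precede a terminal NH4Cl epoch")
    f0 = trace.baseline_F0()
    out = PoolFractions(f_recycling_pct=f_recycling_pct)
    out.dF_nh4cl_pct = _nh4cl_level_pct(trace, f0)
    e = iono[-1]
    _, tail = _frames(trace, e.end_s - min(20.0, e.duration_s / 3), e.end_s)
    iono_level = (float(tail.mean()) - f0) / f0 * 100.0
    out.f_iono_pct = iono_level / out.dF_nh4cl_pct * 100.0
    if f_recycling_pct is not None:
        out.f_reluctant_pct = out.f_iono_pct - f_recycling_pct
        if f_recycling_pct > 0:
            out.ratio_iono_over_ap = out.f_iono_pct / f_recycling_pct
    else:
        out.flags.append("f_recycling not supplied: reluctant fraction absent")
    return out


# --------------------------------------------------------------------------- #
# GCaMP
# --------------------------------------------------------------------------- #

def gcamp_dff(trace: FluorTrace, epoch: Epoch, pad_s: float = 6.0) -> float:
    """(peak - F0)/F0 within one epoch, F0 from the frames preceding it."""
    _, pre = _frames(trace, max(0.0, epoch.start_s - 30.0), epoch.start_s)
    if len(pre) < 3:
        raise ValueError("not enough baseline frames before epoch")
    f0 = float(pre.mean())
    _, win = _frames(trace, epoch.start_s, epoch.end_s + pad_s)
    if len(win) == 0:
        raise ValueError("epoch holds no frames")
    return float((smoothed_peak(win) - f0) / f0)
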