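# Methods

`synaptoflux` analyzes presynaptic function at a voltage-clamped bouton
through three measurement chains — membrane-capacitance exocytosis, quantal
deconvolution of postsynaptic currents, and synapto-pHluorin pool imaging —
and ships a forward simulator whose hidden per-bouton parameters (the
*ground-truth ledger*) let every estimator be scored end to end. This note
documents the models, the calibrated defaults, and what the synthetic data do
and do not capture.

## Circuit model and the sine+DC capacitance chain

A clamped bouton is a three-element circuit: access resistance `Rs` in series
with the membrane (`Rm` parallel `Cm`). A 1 kHz sinusoid (30 mV peak) rides
on the −80 mV holding potential; per 10 ms window (10 integer cycles) a
two-phase correlation against the command yields the complex admittance
`Y = (Gm + jωCm) / (1 + Rs(Gm + jωCm))`, and the cycle-mean current divided
by the holding driving force gives the DC conductance `G_dc = 1/(Rs + Rm)`
(leak reversal is taken at 0 mV; both conventions are configurable). Writing
`z = 1/Y = zr + j·zi` and `u = zr − Rs`, the DC constraint collapses the
inversion to closed form:

    u  = zi² / (1/G_dc − zr),   Rs = zr − u,
    Gm = u / (u² + zi²),        ωCm = −zi / (u² + zi²).

Every inversion is verified against the forward map (relative residual
< 1e−9); inconsistent windows are flagged invalid rather than clamped.
Windows overlapping the depolarizing pulse or the 50 ms post-pulse blank
(membrane conductance is unstable there) are dropped, as is one settle
window after sine onset. ΔCm is the mean post-blank minus mean pre-pulse
`Cm` (≥10 valid windows each side), normalized to the clamped-area `Cm`
estimated from the exponential-fit charge of a hyperpolarizing test-step
transient (`Q = A·τ`, robust when the access time constant is near one
sample). The Ca-current density subtracts the analytic passive step response
of the fitted circuit before a single-exponential activation fit.

Simulated sweeps are computed segment-wise in closed form (steady-state
sinusoid + DC + boundary transient of the scalar membrane ODE), so the
simulator is exact to machine precision and the lock-in chain can be checked
against the analytic admittance rather than against itself.

Generator defaults: `Cm` jump `C0·ρ_RRP·(1 − e^(−T/τ_rel))` at pulse end with
`ρ_RRP = 31 fF/pF` (control) and `τ_rel = 8 ms` (chosen so 50 ms pulses sit
on the plateau while 1–5 ms pulses ride the rising phase); Ca-current density
53 pA/pF with activation τ = 1 ms; `Rs = 20 MΩ`, `Rm = 2 GΩ`; current noise
2 pA SD. With 5 mM EGTA and active GPR55, short-pulse release is additionally
suppressed by a factor interpolating (in log duration) from 1.3 at ≤2 ms to
1.0 at ≥50 ms; this coupling factor is a stand-in for a loosened
channel–sensor arrangement, not a quantity with a measured value, and control
release is EGTA-insensitive.

## Quantal deconvolution and release onset

The unitary event is a biexponential difference (rise τ 0.3 ms, decay τ
5 ms, peak 30 pA; the published recordings leave the authors' template
unprinted, so these are declared defaults with the 20–80% risetime kept near
the measured evoked risetimes). Fusion velocity `v(t)` (vesicles/ms) solves
`v ⊛ template = IPSC` by frequency-domain division with Tikhonov
regularization scaled to the template's spectral peak
(`|H|² + reg·max|H|²`, default `reg = 1e−5`). Negative ripple is reported,
not clipped (clipping is opt-in). The default `reg` was chosen on the
round-trip and ledger-recovery properties: re-convolving `v` must reproduce a
noiseless IPSC to < 2% relative RMS, and the planted peak velocity must come
back within a few percent at 2 pA noise.

Release onset is the first crossing of baseline mean + 2 SD of the
deconvolved baseline that is *sustained for 0.2 ms* (at least two samples).
A purely sample-count rule admits the short acausal ripple lobes of the
regularized filter (they last < 0.1 ms and scale with signal, not noise);
the time-based sustain suppresses them while genuine release stays above
threshold for milliseconds, recovering planted latencies to < 0.05 ms.

Miniature events are detected on a lightly smoothed trace by peak finding
with a prominence gate (0.7× threshold; prevents noise wiggles on a decay
from double-counting), local-baseline amplitude ≥ 7 pA, and a template
risetime screen (±3-fold). Coincident small events can merge and exceed
threshold — that is physics, not a detector fault.

Evoked-amplitude CV analysis bins sweeps (default 0.1 Hz stimulation, 1 min
bins), reports per-bin mean and CV normalized to pre-drug baselines, and is
validated against the binomial closed form `CV = √((1−p)/(Np))`.

## The pHluorin state model

Each bouton holds `n_total` vesicles: an AP-sensitive recycling pool
(`f_ap`), a reluctant Ca-sensitive remainder (`f_iono − f_ap`, released only
by ionomycin), and a never-released rest. A fraction `f_surf` of reporter
sits on the plasma membrane (always bright); vesicular reporter is quenched
to `q_quench = 0.05` of full brightness. Fluorescence per reporter unit is

    F = f_surf + (1 − f_surf)·[b + (1 − b)(q + (1 − q)·ν)],

with `b` the bright vesicle fraction and `ν` the NH4Cl lumen-neutralization
level (→1 with τ = 4 s during NH4Cl). Camera units scale with `n_total`, so
absolute ΔF grows with bouton size while ΔF/F0 shrinks as `n_total^(−1/3)`
(the AP-releasable amount scales with surface area, `n_total^(2/3)`).

Fused reporter re-quenches (endocytosis + re-acidification, one collapsed
clock `tau_quench = 42.1 s`) and returns to the dark pool, except a stranded
fraction `f_stranded` that stays bright beyond the session (the local
plateau of the post-train decay). During AP trains an additional
activity-coupled retrieval pathway (`tau_fast`) operates. Bafilomycin
switches all re-quenching off from its application onward — already-dark
vesicles stay dark, bright ones stay bright — so repeated trains build a
non-decaying cumulative signal that saturates at the AP-sensitive pool. KCl
releases the residual depolarization-sensitive pool (τ = 3 s); ionomycin
releases the whole Ca-sensitive pool (τ = 10 s) regardless of
channel–sensor coupling.

Within a train, release is front-loaded: density `∝ e^(−t/τ_train)` with
`τ_train = 10 s` over the 20 s train (63% of fusion in the first half).
A stronger front-loading (τ_train ≈ 4 s) was tried first; with the
enhancement and remaining-at-40-s constraints it forces so much in-train
retrieval that the post-train exponential almost vanishes (amplitude ~1–3×
frame noise) and the fluorescence peaks mid-train — neither matches the
published train responses, and the decay constant becomes unrecoverable per
bouton. τ_train = 10 s keeps the same constraints with an end-of-train peak
and a well-conditioned decay fit.

### Calibration (all solved, none hand-set)

With `q_quench = 0.05` fixed:

* `f_surf = 0.17780` — closed form from ΔF_NH4Cl/F0 = 3.568;
* `(f_stranded, tau_fast) = (0.2139, 20.32 s)` — 2-D root of the *measured*
  (bafilomycin enhancement = 55.9%, remaining-at-40-s = 59.8%) read-outs on
  a noiseless simulated repeated-train session, because in-train retrieval
  and the stranded fraction interact through the measured peak;
* `per_train_release = 0.4144` — so one 400-AP train gives ΔF/F0 = 23.3% at
  the reference bouton (this leaves ~1% of the AP pool after eight
  bafilomycin-era trains, hence the near-zero KCl increment);
* `beta = 2.989` camera-units per ΔF/F0-% — the scale on which the
  exponential suppression relation `r(x) = 1.02·e^(−0.0334x) + 0.355`
  operates, root-found so the ensemble-mean suppression over the default
  size distribution is 53.8%. Evaluating the printed relation directly on
  ΔF/F0 percent cannot reproduce the published mean suppression (it would
  give ~18%), so the relation's abscissa is treated as camera units.

`calibration.calibrate_ph_model()` re-derives all of these from scratch; a
test pins the frozen defaults to the solver output.

The published summary values are themselves not perfectly mutually
consistent: a mean suppression of 53.8% implies a mean ratio of 0.462,
while the cumulative plateaus imply 13.2/27.6 = 0.478. The generator follows
the 53.8% calibration, so its GPR55-active plateau sits near 12–13% rather
than exactly 13.2%. Both are reported; nothing forces them to agree.

### Estimators

Train responses use a running pre-train baseline and define the peak as the
maximum of a low-order polynomial fit over the train window: the max of raw
noisy frames is biased upward by an *absolute* amount, which distorts ratios
of small to large responses (the bafilomycin enhancement most of all); the
fitted peak is unbiased to first order. The decay constant is fitted with
the local plateau pinned from the late rest frames (several time constants
out) so only amplitude and τ remain free. The cumulative plateau is the
asymptote of a saturating exponential in train index (alternative: last-two
-train mean); extrapolation is refused when increments do not fall off.
Suppression-relation and RRP fits are seeded multi-start least squares, ties
broken by lowest residual then lowest parameter norm; a < 3-fold abscissa
range flags the asymptote as weakly identified.

## Bouton population and noise

`n_total` is lognormal (median 600, σ_log 0.5); `C0` follows size as
`(n/600)^0.6` pF with 10% independent scatter (σ_log ≈ 0.32 overall,
median 1 pF). Per-bouton `f_ap` scales as `n^(−1/3)` normalized so its
population mean is 0.276; `f_iono = 0.54` everywhere. GPR55 activation
multiplies only the AP-sensitive partition by `r = 1.02·e^(−β·x) + 0.355`
plus N(0, 0.12) biological scatter (truncated positive), leaving `n_total`
and `f_iono` untouched — total-pool conservation is a tested invariant.
Fluorescence noise is 2% multiplicative per frame at 0.5 frames/s; current
noise 2 pA SD at 50 kHz. All randomness flows through seeded generators;
identical (config, seed) reproduces datasets byte for byte.

## Problem sizes

The bundled acceptance computation uses 12-bouton capacitance cohorts (the
largest direct-recording cohorts reported), 8 paired recordings, 60-bouton
imaging sessions and 120-point suppression-relation datasets; the whole run
completes in a few seconds.

## What the simulator does not capture

No pixel-level imaging (traces only), no Hodgkin–Huxley action-potential
model, no stochastic single-channel Ca influx, no diffusion/buffering PDE
for EGTA, no receptor saturation/desensitization beyond the fixed quantal
template, and no amplifier artifacts (pipette capacitance, phase error —
a phase-offset hook exists but defaults to ideal). Passing tests therefore
demonstrate that the estimators recover planted truth through realistic
noise and heterogeneity, not that they are robust to every artifact of real
recordings.

## Known limitations

* Per-bouton decay-constant fits remain noisy at 2% frame noise; cohort
  means are accurate but single-bouton values carry ~30% spread.
* The clamped-area estimate inherits the `(Rm/(Rs+Rm))²` attenuation
  (~2% at default parameters); it is not corrected, matching the stated
  2% tolerance of the transient method.
* The EGTA–GPR55 interaction factor is qualitative; do not interpret its
  magnitude quantitatively.
* The paired ratio estimator (post/pre of noisy responses) is biased toward
  1 by a few percent; the mean-suppression read-out sits correspondingly
  below its calibration target.
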