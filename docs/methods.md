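# Methods

This note documents the forward model behind the simulator, the
correction algorithms, the tunable parameters and their defaults, the
numerical choices, and the known limitations.  Units throughout:
minutes, nM for enzyme species, µM for substrate/fluorophore, RFU for
fluorescence.

## Forward model

### Thrombin kinetics

Free thrombin `T(t)` is driven by a phenomenological, gamma-shaped
prothrombinase pulse and removed by its two plasma sinks:

```
dT/dt    = g(t) − (k_at · at_fraction · heparin_factor + k_a2m) · T
dα2MT/dt = k_a2m · T
g(t)     = A · u^s e^(−u) / (s^s e^(−s)),   u = (t − t0)/τ
```

The pulse is normalized so its maximum is `A`.  No attempt is made to
model the coagulation cascade factor by factor; three parameters
(amplitude, time constant `τ`, shape `s`) are enough to reproduce the
canonical lag / peak / decay shape of a thrombogram, which is all the
downstream signal-processing questions need.

The amidolytic (substrate-cleaving) activity seen by the fluorogenic
substrate is

```
E(t) = T(t) + f · α2MT(t)
```

because the α₂-macroglobulin–thrombin complex is inert toward clotting
factors but keeps part (`f = a2m_amidolytic_fraction`) of its activity
against small synthetic substrates.  This term is what produces the
persistent upward slope at the tail of real fluorescence curves, and it
is exactly the signal that calibrator reagents (which *are* Tα₂M
complex) exploit.

Condition modifiers:

* **FVIII level** (hemophilia model): the drive amplitude scales by
  `0.15 + 0.85·FVIII` and `τ` stretches by `(2 − FVIII)`, so FVIII = 0
  gives a late, low, broad curve with TPH ≈ 16% of the normalized
  plasma — in the range reported for severe hemophilia A plasma vs the
  same plasma restored with 1 IU/mL FVIII.
* **Tissue-factor dose**: amplitude scales log-linearly,
  `1 + 0.35·ln(TF/5 pM)` (floored at 0.02), and the onset delay is
  `3 pM·min / TF`.  Only the qualitative dose dependence (higher and
  earlier curves at more TF) matters for the edge scans.

Defaults: `A = 350 nM/min`, `τ = 1.5 min`, `s = 3`, `k_at = 0.75/min`,
`k_a2m = 0.035/min`, `f = 0.55`, `TF = 5 pM`.  These put the normalized
plasma curve at TPH ≈ 400 nM, time-to-peak ≈ 6.5 min, ETP ≈ 3000
nM·min, with an α₂MT tail of ≈ 57 nM-equivalent at 60 min (≈ 14% of the
peak) — a realistic, sharply peaked thrombogram.

### Substrate consumption

Cleavage follows Michaelis–Menten kinetics,

```
dS/dt = − kcat · (E/1000) · S/(Km + S)        [S in µM, E in nM]
```

integrated exactly through its implicit form
`Km·ln(S0/S) + (S0 − S) = (kcat/1000)·∫E dt`, solved per time point by
a clipped Newton iteration.  Product `P = S0 − S` is conserved to
machine precision by construction.  Defaults `kcat = 60/min`
(= 1 s⁻¹), `Km = 200 µM`, `S0 = 416 µM` (commercial reagent level; 800
µM for the in-house-style scenarios).  With these numbers a 100
nM-equivalent calibrator consumes roughly half the substrate over 60
minutes — enough that consumption, not only the IFE, bends the
calibrator curve, as on the bench.

### Optics

The fluorophore-equivalent load is `x(t) = P(t) + amc_spike`.  The
inner filter effect is modeled by the saturating transform

```
Φ(x) = K · (1 − e^(−x/K))
```

chosen because it is strictly increasing, concave, satisfies
`Φ(x) ≤ x` with `Φ'(0) = 1`, has a single parameter, and reduces to the
identity as `K → ∞`.  The recorded signal is

```
F(t) = dark_offset + gain·Φ(x(t)) + afc_bleed_coeff·afc_substrate + ε
```

with `ε ~ N(0, noise_sd²)` drawn from a seeded generator.  Uncleaved
ZGGR-AFC substrate contributes only the constant bleed-through baseline
in the AMC channel (its consumption and spectra are out of scope; the
constant term reproduces the analytically relevant effect — a baseline
offset that the sample and its paired calibrator share).  An optional
early-minutes exponential settling transient (`early_drop_rfu`,
`early_drop_tau`, off by default) reproduces the instrument artifact
seen in the first ~5 minutes of real records; it is unrelated to the
IFE and therefore excluded from the default conditions.

Defaults: `gain = 20 RFU/µM`, `ife_K = 350 µM`, `dark_offset = 50 RFU`,
`noise_sd = 1 RFU`, `afc_bleed_coeff = 2 RFU/µM`.

### Plates and scenarios

`generate_plate` lays out replicate sample wells and ≥1 calibrator
well per condition, with deterministic per-plate seeding.  Built-in
scenarios mirror the forced-artifact designs: `ife_spike`
(free AMC 0–200 µM × FVIII 0/1), `substrate_reduction` (S0 down
20-fold), `amc_afc_mixture` (AMC+AFC substrates summing to 800 µM),
`atiii_procoagulant` (5% residual antithrombin ± heparin × TF 0.12–20
pM), and `custom`.  Calibrator wells share the sample's substrate and
optics state but **not** the free-AMC spike (the spike models a
sample-borne artifact; see the confound note below).  Default cadence
30 s, record 60 min; 52 s and 24 s cadences are available via
`sampling_interval`.

## Analysis stack

### Derivatives and smoothing

All derivative outputs live on the native time grid.  `none` is plain
central differencing (exact for quadratics); `savgol` is the
Savitzky–Golay smoothed derivative (default window 5, order 2 — the
smallest legal stencil; ends handled by polynomial fit on the truncated
window); `supersmoother` smooths with Friedman's variable-span smoother
(local linear fits at spans 0.05/0.2/0.5 of the record, pointwise span
selection by smoothed leave-one-out residuals, interpolation between
bracketing spans, final tweeter pass, bass enhancement 0) and then
differentiates.  The implementation reproduces R's `supsmu` to ~5
significant digits on smooth test curves.

A consequence worth knowing: a variable-span *local linear* smoother
attenuates sharp peaks.  On the default simulated thrombogram the
supersmoother (ours and R's alike) lowers the apparent peak by ~9–10%
even with zero noise, because its smallest span covers ~3 minutes of a
~5-minute-wide peak.  ETP is essentially unaffected (local linear
smoothing preserves area).  The `cat4ss` preset therefore carries an
intrinsic TPH bias on sharp curves — the same behavior class the
supersmoother-based bench software shows — and the no-artifact
fidelity check documents it rather than hiding it.

### Calibration

`fit_calibrator` fits the baseline-subtracted calibrator fluorescence
with a 3rd- or 4th-order polynomial; `slope0` is the fitted derivative
at the window start.  The **internal linear** route multiplies the
sample rate curve by `activity/slope0` — one coefficient, no artifact
correction, never fails.

`cat_correct` implements the fluorescence-matched correction: invert
the fitted calibrator polynomial (root finding on its monotone branch)
to find `t*` with `F_cal(t*) = F_sample(t)`, divide the sample rate by
`v* = F_cal'(t*)`.  Both wells are referred to the *calibrator's*
initial reading, which acts as the shared instrument baseline; this
way a spiked sample is matched onto the later, more attenuated part of
the calibrator curve, which is precisely how the calibrator encodes
the IFE at that signal level.  The running correction factor
`slope0/v*` is capped at `max_gain` (default 20): beyond-range or
turned-over fits would otherwise send it to infinity — the runaway
second rise that extrapolating implementations show after substrate
depletion — so the cap keeps it finite but flags the
curve `nonphysical`.  With `range_policy="refuse"`, sample
fluorescence above the calibrator's *observed* maximum aborts the well
(`no_curve`), modeling software that declines to report distorted
curves; refusal keys on the observed range (not the fitted branch) so
the set point coincides exactly with the fluorescence-ceiling
crossing.

**The spiked-AMC confound.**  Matched fluorescence equalizes the
optical operating point but not the substrate state: at matched `F`,
the (unspiked) calibrator has cleaved `spike` µM more substrate than
the sample actually has, so `v*` carries a Michaelis factor
`(S_s − spike)/(Km + S_s − spike)` where the sample's true factor is
`S_s/(Km + S_s)`.  The corrected activity is overestimated by the
ratio of the two, which grows with the spike (≈ 4% at 47 µM, ≈ 7% at
70 µM, ≈ 11% at 102 µM under the defaults).  This reproduces the
concentration-dependent overestimation that extrapolating desktop
implementations show at high spiked AMC, and it bounds the accuracy
of any purely fluorescence-matched correction applied to a
baseline-shifted sample.

### α₂M subtraction

Calibrated activity is `E = T + k·∫T` (with the amidolytic fraction
folded into the effective `k`).  Free thrombin is recovered by the
discrete deconvolution `T_i = E_i − k·Δt·Σ_{j<i} T_j` (left-Riemann;
negative intermediates retained so noise statistics survive).
`auto_k` chooses `k` so the mean of `T` over the final 10% of the
record vanishes — by the end of a record free thrombin is fully
inhibited, so any residual mean signal there is complex activity.  The
root is located by the fixed-point iteration
`k ← mean_tail(E) / mean_tail(∫T_k)`, which converges from below to
the smallest root; a simple bisection on the tail mean is *not* used
because, when upstream smoothing leaves the estimated tail with a
slight upward slope, the tail mean never crosses zero and a bracket
search runs away to the cap.  `k` is capped at 1/min; an already
negative tail at `k = 0` falls back to no subtraction with a warning.
On forward-constructed curves the deconvolution is exact to 1e-16 and
`auto_k` recovers `k` to ~0.1%.

### Failure detection

`detect_failure` classifies each curve: upstream `no_curve`
propagates; `nonphysical` is assigned when (i) any value exceeds
`10 × E_cal` (runaway correction — the cap is deliberately generous so
genuinely procoagulant samples only trip it together with depletion
artifacts), (ii) the curve re-ascends above its first prominent peak
by >20% (the depletion "second peak"), or (iii) the tail noise exceeds
5× the pre-lag noise *and* 2% of the curve maximum.  Noise in each 10%
window is measured as the residual sd about a Savitzky–Golay fit, so
slow curve shape (late-onset thrombograms) does not masquerade as
noise; the three guards together make the failure set an upper set
along severity axes.  The noise-amplification ratio is reported on
every status.

### Parameters, normalization, statistics

TPH is the maximum of the (negative-clipped) curve, ETP its trapezoid
integral over the full record (no return-to-baseline detection — the
recorded window *is* the integration window), time-to-peak the first
maximum.  Lag time — not standardized anywhere — is the first time the
curve exceeds `max(2 nM, 10%·TPH)`; the hybrid rule stays meaningful
for both hemophilia-scale and normal-scale peaks, and both knobs are
exposed.  Normalization divides by a reference TPH; group comparisons
use a paired t-test by default with a two-sample option (both appear
in the field's usage; the paired form matches the paired-well designs
simulated here).

### Edge scans

`run_scan` sweeps one severity axis (`amc_spike`, `substrate_total`,
`tf_pM`, `at_fraction`), simulating one plate per (severity,
replicate) and analyzing it with every method, recording TG parameters,
statuses and — since inputs are synthetic — relative TPH/ETP errors
against ground truth.  The set point is the smallest severity at which
at least half the replicates fail (a majority rule is needed once noise
replicates exist); summary rows label each method `failed` (stops
reporting), `overestimated` (reports inflated peaks: nonphysical basis
or TPH > 1.1× truth), or `corrected`, and record the largest severity
with TPH error < 10%.

## Problem sizes

Default records are 121 points (30 s × 60 min); the acceptance script
simulates ~10 plates of 3–30 wells each and completes in a few
seconds.  The kinetics integrator runs on a 20× refined grid
(exponential integrator, exact for piecewise-linear drive; verified
against closed forms to <1e-12), and the substrate solver's implicit
form conserves `S + P = S0` to machine precision.

## What the simulator does not capture

* No factor-by-factor cascade model — the thrombin pulse is
  phenomenological, so scenario effects (TF dose, FVIII, antithrombin)
  enter as parameter maps, not mechanism.
* The AFC substrate is optically inert except for its constant
  bleed-through; its cleavage, spectra and any IFE of its own are not
  modeled.
* Plasma-to-plasma optical variability (sample-specific gain/IFE) is
  not modeled; sample and calibrator wells share optics exactly, which
  is the best case for CAT correction.
* Noise is additive Gaussian; shot noise and drift are not modeled.
  This is sufficient to reproduce noise *amplification* by the
  correction factor, which is the phenomenon of interest.
* Passing tests therefore validate the algorithms' behavior under a
  controlled artifact model, not instrument-specific numbers: failure
  *set points* depend on the (unpublished) fluorescence scale of real
  instruments and are reproduced as phenomena and orderings, not as
  particular µM values.
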