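# Methods

## The physiological model

A passively ventilated respiratory system is treated as a single
compartment obeying the equation of motion

    Paw(t) = E_rs · V(t) + R_rs · Q(t) + P_o ,

with airway pressure `Paw` (cmH2O), volume above the onset of inspiration
`V` (L), flow `Q` (L/s), respiratory elastance `E_rs` (cmH2O/L), resistance
`R_rs` (cmH2O·s/L) and offset pressure `P_o` — the sum of applied PEEP and
any intrinsic (auto-)PEEP. All pressures entering the estimators are
plateau airway pressures read at zero flow: at end-inspiration the
resistive term vanishes and `Paw = P_o + E_rs·V_t`; at end-expiration
`Paw = P_o`.

dFRC is the end-expiratory volume retained above FRC because of PEEP. It
is never derived from the waveform integral (the integral only tracks
within-breath volume); clinically measured dFRC is an external input, and
the simulator provides ground truth.

## Estimators

**SSMB** — stress–strain theory relates dFRC to the patient's volume
responsiveness across a PEEP step: `dFRC = (ΔdFRC/ΔPEEP)·β`. Specific lung
elastance, the lung/chest-wall elastance ratio and the PEEP-dependent
scaling are not separately identifiable at the bedside, so they are folded
into the single per-PEEP constant β, assumed shared across patients.

**SSSB** — the same form applied within one breath,
`dFRC = (V_t/ΔPaw)·β`, with β normalised by tidal volume (`β₁ = β/V_t`,
units cmH2O/L) because the raw constant scales with the applied V_t. The
estimate is therefore `β₁·V_t²/ΔPaw`.

**SCSB** — interpreting `P_o = PEEP = E_rs·V_Po` gives `V_Po = PEEP/E_rs`,
the additional volume the single-compartment model attributes to PEEP.
`V_Po` is proportional to dFRC but not rescaled by default (an optional
cohort-level rescaling exists for evaluation); it needs no population
constant.

**CM** — while only one PEEP level has been observed the combined method
returns the SSSB estimate; from the moment a measured ΔdFRC across the
step ending at the target PEEP exists it returns the SSMB estimate. The
switch is hard — estimates are never blended — and never reverts. The
returned estimate carries `method="CM"` with the firing branch in
`source_method`; all numeric fields equal the delegated estimator's
output exactly.

Every estimate at PEEP below 5 cmH2O carries a low-PEEP caution flag:
responsiveness denominators and constants are small there and relative
errors grow.

## Calibration

β is solved analytically per patient and PEEP from measured dFRC
(`β = dFRC·ΔPEEP/ΔdFRC`, and for the single-breath variant
`β = dFRC·ΔPaw/V_t`, `β₁ = β/V_t`), then the per-PEEP **median** across
patients becomes the population constant, stored with n, min, max and IQR.
Medians with even counts average the two central values; IQR is the
linear-interpolated 75th minus 25th percentile. Steps with `ΔdFRC = 0`
are excluded with a warning; a PEEP level with no contributing patients is
absent from the table.

ΔdFRC/ΔPEEP is taken between **consecutive** measured steps (previous →
current), matching a stepwise-PEEP protocol; a `pairing="baseline"` switch
(first → current) exists for sensitivity analysis. A patient's lowest
step has no preceding step and contributes no multiple-breath β; that PEEP
level is covered only by other patients.

Lookup at uncalibrated PEEPs linearly interpolates between bracketing
levels; outside the calibrated span the default policy refuses (a
clamp-with-warning policy is available, and clamped lookups flag the
estimate as extrapolated).

Cohorts calibrated under different dFRC measurement protocols should not
be merged: the single-breath constants in particular diverge with PEEP
between measurement routes, and a merged median degrades both. The API
allows merging but the practice is discouraged.

In-sample application (each patient scored against medians it contributed
to) is the default, being how such tables are used once published;
`loo_evaluate` provides leave-one-out scoring to quantify the in-sample
optimism.

### PEEP levels versus measured pressures

Quantities entering formulas (ΔPEEP, ΔPaw) are measured end-expiratory /
end-inspiratory zero-flow pressures. Grouping keys — calibration bins,
table lookup, per-PEEP error groups — use the step's nominal *level* (the
ventilator setting when known, else the measured pressure), so that
pressure noise or auto-PEEP cannot scatter one protocol level into many
bins. With auto-PEEP above a set level the measured ΔPEEP shrinks
accordingly (e.g. 7 → 10 rather than 5 → 10), which is exactly the
compliance-break behaviour the multiple-breath method should see.

## Identification numerics

The cited integral-based method is implemented as linear least squares on
cumulative trapezoidal integrals of the equation of motion over the
inspiratory portion only (onset through the end-inspiratory zero-flow
sample):

    ∫Paw dt = E_rs·∫V dt + R_rs·∫Q dt + P_o·t .

Integration acts as a low-pass filter, which is why sample-level pressure
noise of 0.5 cmH2O perturbs the fitted elastance by only ~1% at 50 Hz.
Two intercept modes exist: `free` estimates `P_o`; `fixed` pins it to the
set PEEP, which is the `V_Po` re-parameterisation of the same model. The
two elastances coincide exactly without intrinsic PEEP and diverge under
auto-PEEP — the basis of the paired-elastance diagnostic.

Numerical choices: regressor matrices with condition number above 1e8
(double-precision least-squares safety margin) raise an unidentifiability
error — constant inspiratory flow, which makes volume proportional to
time, is the canonical case. Non-positive fitted elastance or negative
resistance is *flagged*, never clamped or hidden; downstream estimators
refuse flagged fits with diagnostics. The RMS residual is reported in
pressure space. Fits need at least 8 inspiratory samples.

## Waveform handling

Core units are fixed — s, cmH2O, L, L/s — and the CSV reader converts
declared source units (ms; kPa/hPa/mbar; mL/s, L/min …) at the boundary.
Time grids may be non-uniform; every integral is trapezoidal. Breaths are
segmented at upward zero crossings of flow (a recording that begins with
non-negative flow is taken to begin at an onset, but a recording with no
crossing at all contains no complete breath); fragments shorter than a
minimum duration (default 0.5 s) are dropped, and each breath's volume is
re-zeroed at its onset.

"Zero airflow" on sampled data is `|Q| ≤ 0.005 L/s` (configurable); the
end-inspiratory index is the last inspiratory sample inside tolerance and
the end-expiratory index the analogous sample at the breath end. When no
sample is inside tolerance the minimum-|Q| sample of the phase is used and
a warning logged. Per-step summaries are medians across breaths.

## The virtual-patient simulator

Breaths use a half-sine inspiratory flow profile scaled to the set tidal
volume (profile pluggable), an end-inspiratory pause (0.3 s), and passive
expiration with time constant `τ = R_rs/E_rs`. Expiratory flow is
discretised by the trapezoid-consistent recurrence of `Q = −V/τ`, so the
sampled volume decays exactly geometrically and the simulated airway
pressure relaxes exactly to `P_o` on the grid — the generated breath is
single-compartment-consistent to machine precision, which is what makes
0.1%-level identification closure meaningful. The volume channel is by
construction the running trapezoidal integral of the flow channel.
Defaults: 50 Hz sampling, 3 breaths per PEEP level, 15 breaths/min.

Ground-truth recruitment follows a logistic sigmoid
`dFRC(PEEP) = v_max / (1 + exp(−(PEEP − p_mid)/s))`, held at its auto-PEEP
value below the auto-PEEP level (incomplete expiration keeps those units
open; `P_o` floors at the auto-PEEP). Measured dFRC is truth plus
zero-mean Gaussian noise (default SD 0.05 L), floored at 0.

Cohort defaults are adult-ICU-plausible fixtures, chosen once: elastance
25 cmH2O/L (CV 20%), resistance 10 cmH2O·s/L (CV 20%), tidal volume 0.5 L
(CV 30%), respiratory rate 15/min (CV 20%), recruitment asymptote 2.0 L
(deviation CV 25%), half-recruitment at 9 cmH2O with width 3.5 cmH2O,
pressure noise 0.2 cmH2O, protocol {5, 10, 15} cmH2O. Draws are Gaussian
truncated away from zero.

Two deliberate structural choices shape the default population:

* **Recruitment magnitude couples to body size.** Tidal volumes are set
  per predicted body weight and recruitable volume scales with lung size,
  so `v_max ∝ V_t` up to a patient deviation factor γ (CV 25%). This is
  the single-breath population hypothesis — volume responsiveness
  proportional to `V_t/ΔPaw` — holding *imperfectly*: γ is exactly the
  part the tidal-volume-normalised constant cannot explain. Setting γ's
  CV larger degrades the single-breath method toward the uncalibrated
  proxy; smaller makes it rival the multiple-breath method. The coupling
  can be disabled to draw recruitment independently.
* **The recruitment shape is shared.** Per-PEEP constants shared across
  patients presuppose a common normalised volume response; the default
  cohort realises that premise (shape CVs 0), with heterogeneity living in
  mechanics, tidal volume and magnitude. Raising the shape CVs breaks the
  premise and, as expected, collapses the stress–strain methods' accuracy.

`make_eq8_consistent_cohort` rebuilds the measured dFRC sequence so each
patient satisfies the multiple-breath identity exactly under a given β
profile, via the recurrence `dFRC_k = dFRC_{k−1}·β_k/(β_k − ΔPEEP_k)`
(profiles with `β_k ≤ ΔPEEP_k` are rejected as infeasible). Both noise
sources are forced to zero there; it exists for exact closure tests.

What the simulator does **not** emulate: overdistension and PV-loop
inflection morphology, spontaneous breathing effort, gas exchange,
viscoelastic or multi-compartment dynamics, and device-specific dFRC
measurement artefacts. Consequently, passing tests demonstrate internal
consistency and behaviour under the stated population model — not clinical
accuracy on real cohorts. In particular, on real data the single-breath
constant degrades further when measurement protocols differ, and the
single-compartment proxy suffers from model misspecification that a
single-compartment generator cannot reproduce; the expected
accuracy ordering (multiple-breath and combined above single-breath above
the proxy) emerges here because the population-constant premise is built
into the cohort, and it holds in roughly nine of ten replicate cohorts
rather than always — at 10 patients per cohort the pooled R² of the two
weaker methods overlap in unlucky draws, as they also did between the
published clinical cohorts.

## Evaluation

R² is the squared Pearson correlation of pooled measured-vs-estimated
pairs (not regression through the origin); the OLS trend line of estimated
on measured is reported alongside. Error statistics are non-parametric —
median, IQR, min, max of estimated − measured (overestimation positive) —
pooled and per PEEP level, with per-level groups keyed on exact nominal
levels. Zero variance on either axis makes R² undefined; it is reported
as absent with a reason while error statistics are still produced.
Box-plot truncation at ±1 L affects display only. Pooling across all
patients and levels per cohort is the default granularity; method ranking
sorts by pooled R² descending with ties broken by method name.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
the study's natural scale: 10-patient cohorts on the {5, 10, 15} cmH2O
protocol, 3 breaths per level at 50 Hz, 20 replicate cohorts for the
method comparison, 100 breaths for the noise-robustness check. A full
acceptance run completes in seconds on one CPU.

## Known limitations

* The SSSB output is algebraically a ΔdFRC-form quantity evaluated from a
  single level; it is reported as the dFRC estimate at that level (how it
  is compared against measured dFRC in practice), and the baseline it
  implicitly references at a patient's first observed PEEP is ambiguous.
* `V_Po` is a proxy: linear in PEEP at constant elastance, hence
  systematically concave against a saturating true recruitment curve.
* Calibration tables are only valid within their calibrated PEEP span and
  measurement protocol; extrapolation is refused by default.
* The estimators assume passive ventilation; spontaneous effort violates
  the equation of motion and invalidates all four.
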