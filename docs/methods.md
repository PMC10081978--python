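# Methods

## The model

Rhythmic bimanual coordination is described by the relative phase
φ = θ_right − θ_left between the two hands' oscillations.  The package uses
the extended Haken–Kelso–Bunz (HKB) potential

    V(φ) = −Δω·φ − a·cos(φ) − b·cos(2φ)

with overdamped gradient dynamics and additive phase noise:

    dφ = (Δω − a·sin φ − 2b·sin 2φ) dt + √Q dW.

`a` and `b` (1/s) set the depth of the in-phase (φ = 0) and anti-phase
(φ = π) wells; for a, b > 0 the in-phase well is always the stiffer
(V″(0) = a + 4b > V″(π) = −a + 4b), and anti-phase stability is lost
entirely when b/a < 1/4.  The detuning Δω (rad/s) is a symmetry-breaking
tilt produced by an eigenfrequency difference between the limbs; it shifts
the stable phase away from the intended 0/π and, when large enough,
destroys entrainment altogether (no fixed point — `fixed_points` returns an
empty list).  Q (rad²/s) is the phase-noise intensity.

The potential is the model; the equation of motion is a choice.  We adopt
the gradient (first-order, overdamped) flow because it is the minimal
dynamics consistent with the potential; full two-oscillator limit-cycle
equations (hybrid Rayleigh–van der Pol) with amplitude dynamics are out of
scope.

Defaults a = b = 1 s⁻¹ are configuration, not empirical claims: they give
the canonical bistable landscape with both wells present and the classic
√(5/3) variability ratio between them, and every consumer of `HKBParams`
accepts other values.

## Fixed points and the small-noise oracle

Stationary phases are located on (−π, π] by a sign-change scan of the
drift on a 4096-point grid followed by Brent bisection to 1e−12; roots
within float noise of the ±π seam are detected by magnitude rather than
sign change (the drift at the seam evaluates to ~1e−16 of either sign).
Stability is the sign of V″.

Linearizing around a stable fixed point gives an Ornstein–Uhlenbeck
process with stationary SD √(Q / 2V″(φ*)).  `predicted_sd` exposes this as
a *test oracle only* — it is valid for SD ≪ basin width and is used to
check the simulator, never claimed as a property of movement data.

## Synthetic trials

Generation is phase-first.  Per trial, φ(t) is integrated by
Euler–Maruyama at dt = 1/fs (default 1 ms, far below the ~1/V″ ≈ 0.2–0.3 s
system timescale; the deterministic path was verified against an adaptive
RK oracle at 1e−10 tolerance).  The trial is then rendered into Kinarm-like
kinematics: y_left = (A/2)·sin θ, y_right = (A/2)·sin(θ − φ) with
θ = 2πt/T, A = 10 cm peak-to-peak, T ∈ {750, 1200} ms, 45 s at 1000 Hz,
x holding a constant lateral offset per hand.  Velocities are analytic
derivatives of the rendered positions; optional white measurement noise
(default SD 0.5 mm, roughly robot spatial resolution) is added to positions
only.

Load conditions (none / viscous / elastic per arm, 9 ordered pairs) act
through a configurable mapping onto (Δω, Q): each load pulls the loaded
arm's eigenfrequency (defaults: none 0, viscous −0.35, elastic
−0.15 rad/s), so Δω = pull(left) − pull(right) — matched pairs are exactly
symmetric and swapping arms flips the sign — and phase noise is
Q = 0.02 + per-arm increments (viscous +0.01, elastic +0.02), doubled in
anti-phase mode.  These numbers are calibrated only to produce the
qualitative orderings (detuned pairs shift; anti-phase noisier); they are
not fits to human data.

The robot's orthogonal force fields, F = k·R·v (viscous, k = −15) and
F = k·R·(p − p₀) (elastic, k = +15) with R a 90° rotation, are computed as
per-sample annotations but are **not** fed back into the kinematics: no
limb-impedance model is assumed, so the behavioural effect of loading
enters solely through the (Δω, Q) mapping.  Both gains are quoted as
magnitude-15 "per meter" constants; note a velocity-dependent gain is
dimensionally N·s/m while a position-dependent one is N/m — we store the
magnitude and signs as quoted.

A full experiment is, per participant and mode, 9 load pairs × 2 cycle
times × 5 repetitions = 90 trials in seeded random order.  Participant
heterogeneity is a constant phase bias (SD 2°) plus a multiplicative noise
factor (1 ± 0.2), drawn once per participant; this is what gives the mixed
models a non-degenerate participant variance component.  All randomness
flows from one `numpy` Generator, so a (design, seed) pair reproduces an
experiment bit for bit.

What the generator does *not* emulate: amplitude dynamics and amplitude–
phase coupling, movement onsets/reaction times, joint-angle kinematics,
visual-cue timing, and any mechanical response of the limb to the force
fields.  Passing tests therefore validate the measurement and inference
pipeline under known phase dynamics — they say nothing about whether real
limbs follow the extended-HKB flow.

## The measurement pipeline

Per hand, the oscillation-axis position is amplitude-centered by midrange
removal, x − (max + min)/2 (so the extremes become symmetric about zero —
this is the sense in which the signal is "amplitude-centered around
zero"), and turned into an analytic signal ζ = x + iH[x] via the
frequency-domain Hilbert transform.  Relative phase is the four-quadrant
angle of ζ₁ζ̄₂:

    CRP(t) = atan2(H₁x₂ − H₂x₁, x₁x₂ + H₁H₂),

with x₁ the right hand, folded to [0°, 180°] by taking |wrap(·)|.  A plain
arctan of the ratio cannot reach 180° and was not used.  The sign
(lead/lag) is discarded by the fold, exactly as the reported summaries
discard it; circular statistics are not used — after folding, values
cluster near 0 or 180 on a half-range and arithmetic moments are
well-defined.

Trials are summarized over the 12–42 s steady-state window (half-open;
exactly 30 000 samples at 1000 Hz) by the mean and SD of folded CRP, and
the deviation |mean − intended|.  Trials whose 3 s moving average (0.5 s
step) of folded CRP strays more than 90° from the intended phase in any
window are flagged as phase transitions and excluded from pooling; the
rule's parameters are configuration, since exclusion is required but no
concrete criterion is standard.  Closed-form comparisons in the tests
exclude a 0.5 s edge margin (named constant) because the discrete Hilbert
transform is unreliable within a fraction of a cycle of the trace ends.

### Two analytic facts about folding

Folding to [0°, 180°] is not statistically innocent, and two consequences
matter for interpreting the summaries:

1. **SD shrinkage at the fold point.**  For fluctuations φ = π + ε centered
   exactly on a fold point, folded CRP is 180° − |ε|, so
   SD(folded) = SD(|ε|) = √(1 − 2/π)·SD(ε) ≈ 0.603·SD(ε).  The pipeline's
   SD_φ is therefore systematically ~0.6× the raw phase SD for well-centered
   trials (verified against the OU oracle in the tests).  Ratios between
   conditions are unaffected — the factor cancels.

2. **Variance leaks into mean deviation.**  E|N(0, σ)| = σ√(2/π) > 0, so a
   zero-detuning condition with high phase noise shows a positive mean
   deviation.  Under the default mapping this makes the matched
   elastic/elastic pair (Δω = 0 but the highest Q) deviate *more* on
   average than the weakly detuned elastic mismatches (|Δω| = 0.15 rad/s
   shifts the attractor by only ~1.7° in-phase) — so "every mismatched pair
   deviates more than every matched pair" does not hold for those specific
   comparisons, and the corresponding end-to-end test documents this as an
   expected failure of the strict ordering.  The anomaly is intrinsic to
   fold-then-average summaries, and the same elastic/elastic exception is
   exactly what the human experiment reported.

## Statistics

Retained trials are pooled into four strata (mode × cycle time).  Per
stratum and response (mean CRP or SD CRP):

    response ~ load_condition + (1 | participant) + (1 | trial),

fitted by REML through statsmodels' `MixedLM`, with the crossed random
intercepts implemented as variance components on a single all-data group
and reference level none/none (the intercept estimates the unperturbed
condition).  If that fit fails to converge the model downgrades to a
participant-only random intercept with a logged note — never silently.
Per-coefficient p-values are Wald χ² (z² against χ²₁).

Marginal means per condition are intercept + β (treatment coding, balanced
single-factor design); all 36 pairwise differences get studentized-range
("Tukey HSD") adjusted p-values and simultaneous confidence intervals at
the model's residual df.  Adjusted p ≥ raw p for every contrast by
construction; on balanced data with negligible random structure the
contrasts agree with classical Tukey HSD (cross-checked in the tests
against `statsmodels.stats.multicomp.pairwise_tukeyhsd`).  The
learning-effect variant adds trial index as a fixed slope and reports its
CI and significance.

Error-rate and recovery simulations run at summary level
(`simulate_summary_table`: additive condition offsets, participant and
trial random intercepts, i.i.d. residuals) rather than through full
kinematic rendering — the mixed model only sees trial summaries, so
rendering adds cost but no information.  Problem sizes used by the test
suite: offset recovery at 20 participants × 50 replicates (|bias| < 0.5°
for a 5° offset); null family-wise error over 200 replicates of
8-participant tables (≤ 0.07 against the nominal 0.05); the end-to-end
qualitative comparison at 6 participants under the full 180-trial design.

The Edinburgh-handedness classifier (LQ ≤ −61 left, ≥ 61 right, mixed
between) is a sample-description utility; handedness never enters the
default models.

## Numerical choices and degenerate inputs

- Radians internally everywhere; degrees only at reporting boundaries.
- Half-open windows everywhere (t ∈ [start, end)) so sample counts are
  exact at integer rates.
- Constant traces are rejected by centering (no defined amplitude);
  samples where both analytic components vanish propagate the previous
  phase angle and are flagged; CRP samples with vanishing numerator *and*
  denominator (amplitude dropout) are excluded from summaries.
- Euler–Maruyama warns when the worst-case deterministic step
  (|Δω| + a + 2b)/fs exceeds 0.1 rad.
- `fit_lme` requires ≥ 2 participants and the reference level present;
  degenerate contrast variances raise with the stratum named.

## Known limitations

- The 1° round-trip fidelity bound applies to deterministic phase
  trajectories; for stochastic paths the broadband Euler–Maruyama jitter
  exceeds the Hilbert estimator's bandwidth, adding ~1° RMS at Q = 0.02
  (and ~√Q beyond), which is attenuation of unobservable high-frequency
  content, not bias.
- Trial summaries use linear moments of folded CRP; a circular-statistics
  variant is deliberately not the default (see the folding discussion).
- The force annotations are open-loop; condition effects on kinematics are
  entirely phase-mediated.
- Mixed-model p-values are Wald-based; at the shipped sample sizes they
  are indistinguishable from likelihood-ratio tests, but very small
  designs should not over-interpret them.
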