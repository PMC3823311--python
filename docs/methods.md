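# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `impactsense`.

## Signal chain

Traces are uniformly sampled multi-axis accelerations (default
`t_s = 27.5` ms, i.e. 36.4 S/s — adequate because trunk-worn activity
lives in a 5–20 Hz band).  The DC component (gravity, posture) is
removed by the two-tap FIR `a_AC(t) = (a(t) − a(t − t_s))/2`.  The
filter state starts at zero, so the first output sample is `a[0]/2`;
this is a streaming-friendly convention (no lookahead) and a flag
(`first_output_zero`) forces the alternative. All later samples are
offset-invariant exactly.

Energy is the sliding sum of `|a_AC|` over `N_w = round(τ/t_s)` samples
(defaults: `τ = 660` ms, `N_w = 24`).  Absolute values replace squares so
an 8-bit integer accumulator suffices.  During warm-up the sum runs over
the samples available so far; downstream consumers can mask the first
`N_w` samples if they prefer.  All thresholds are expressed on the
*E_avg* scale, `E_avg = E_AC / N_w` — the per-sample mean absolute AC
acceleration in g — which makes them independent of the window width.

Count coding follows the study hardware: 128 counts = 2 g
(64 counts/g, 4 g full range = 256 counts).  An amplitude quantity codes
as `g × 64`; an E_avg-scale quantity as `g × N_w × 64` (so the optimal
region's 0.04 g energy extent is 61 counts across, ±31 counts about its
center).  Rounding is half-away-from-zero.

## Detectors

All three detectors share flag-and-hold logic: a crossing (strict `>`)
raises a per-axis binary flag that remains true for the hold time
`t_h` (default 1.76 s ≈ 2.5 τ).  The hold exists because the amplitude
and energy maxima of a real impact do not coincide in time.  Output
`h` is true when the required flag combination holds, and an event is
emitted at each rising edge of `h`.

* The full isotropic detector computes
  `h = (OR_i af_i) AND (OR_i ef_i)`: the amplitude and energy crossings
  may occur on *different* axes (the OR reductions are taken before the
  AND).  The per-axis pairing `OR_i (af_i AND ef_i)` is a stricter
  variant a caller can emulate by running per-axis configs; the
  cross-axis reading is the default because the flags are defined per
  axis but the impact condition is a whole-body statement.
* Amplitude is compared on the DC-suppressed signal by default
  (`amplitude_on="ac"`); this keeps `A` orientation-independent and on
  the same g scale as the energy thresholds.  `amplitude_on="raw"`
  compares the raw trace instead.
* Re-crossings refresh a flag's hold window (`refresh="latest"`);
  `refresh="first"` freezes the initial expiry instead.  An optional
  refractory period (default 0) thins event trains; per-activity
  classification only asks whether ≥ 1 event fired, so event
  multiplicity is immaterial there.
* The energy-only isotropic detector drops the amplitude term entirely
  — threshold-sensitivity analysis shows `E` governs both error rates
  while `A`'s influence is abrupt and cannot trade fpr for tpr — and the
  anisotropic detector replaces the scalar `E` with a per-axis vector,
  which is the family with the best enveloping ROC.

## Threshold learning

Activity bouts are segmented on the energy trace subsampled once per
window τ (across-axes maximum).  The local baseline is the median of the
last 5 out-of-segment window values; a segment opens when the level
exceeds `edge_factor` (default *e* ≈ 2.718) times the baseline and
closes when it falls back below the same gate.  The factor-*e* criterion
is read per window step; the factor is a parameter because the original
formulation ("energy varies e⁻¹ per unit") does not fix the time unit
beyond ambiguity.

A segment's mean energy is `E_m = (1/n) Σ_{k=1..n} E_avg(t_i + kτ)` —
an arithmetic mean of per-window samples, equivalently maintained by the
running-mean recurrence `E_m,k = E_m,k−1 + (E_k − E_m,k−1)/k`, the
unique incremental form of that mean (the two agree to 1e−12 by test).
The fixed-`n` variant averages at most the first 30 windows of a
segment (≈ 10× the largest duration SD of the protocol's activities);
both variants coincide on constant-energy segments.

The threshold is unsupervised: `per_axis_max` keeps, per axis, the
maximum `E_m` over confirmed non-impact segments; `vector_magnitude`
keeps the whole `E_m` vector of largest Euclidean norm.  Per-axis max is
the default — it reaches the operating point more efficiently and needs
no vector norm on the sensor node.  Confirmed impacts never move the
threshold.  A pure running max never forgets; an optional exponential
forgetting factor (off by default, and an extension beyond the original
design) lets the threshold track a subject whose energies drift down.

## ROC evaluation

An activity counts as detected if the detector fires anywhere in its
trace; `tpr = TP/P` over impact activities, `fpr = FP/N` over non-impact
ones.  `sweep` maps a threshold grid into ROC space.  Default grids are
linear from 0 to 1.05× the largest observed value, 64 points per
dimension for the scalar modes and 24 for the per-axis mode, capped at
10⁶ configurations.

Rather than pruning the grid, the sweep reduces each trace once to a
threshold-independent summary — per-axis peak `E_avg`, and for the full
isotropic mode the per-sample pairs (max-axis amplitude, hold-window
energy envelope) sorted into a Pareto structure — after which every grid
point is an exact vectorised comparison.  The result is identical,
activity by activity, to running the streaming detector at each grid
point (tested on both routes); it is just faster.

The enveloping curve is the Pareto-maximal staircase of the swept ROC
points, anchored at (0,0) and (1,1) (the all-negative and all-positive
classifiers), and AUC is the trapezoidal area under its vertices — the
standard empirical-ROC choice; a convex hull would only be larger and is
not what a single swept family realizes.

`R_opt(α)` is the set of grid points with `tpr = 1` exactly (a count
equality, not a tolerance) and `fpr < α` strictly.  Robustness is
reported as the per-dimension half-widths of the largest axis-aligned
box of grid cells inscribed in the region (cube radius by iterative
erosion, then round-robin stretching from the best center), converted to
ADC counts on each parameter's own scale.  The box must lie inside the
swept grid; regions touching the grid border are not extrapolated.

`compare_personalization` draws random groups of (subject, set) units,
computes each group's sweep AUC, and compares the group mean against
`AUC_avg`, the mean of single-unit AUCs — the per-unit ceiling.  The gap
`AUC_avg − AUC` measures the price of sharing thresholds across the
grouped units; personalization shows up as a smaller gap.

## Synthetic study conditions

The generator emulates the 11-activity laboratory protocol: 5 non-impact
activities (slow/normal/fast walking, stairs up/down) and 6 impact
activities (vertical jump, knee fall, horizontal fall, each on hard and
soft floor), in the personalized (1 × 8 sets, 88 activities) and
non-personalized (12 × 1, 132 activities) layouts.  Per-activity bout
durations (in τ units) and dominant-axis segment energies `E_m` are
drawn from the published per-activity mean ± SD (soft-floor impacts
carry the larger spreads of the source table), truncated at ±2.5 SD.

Choices the source statistics do not fix, made once as design
decisions:

* **Axis mixes.**  Walking concentrates energy on the vertical axis
  (mix ≈ 0.25/0.55/0.20 over x1/y1/y2); falls excite the horizontal
  sagittal axis strongly (knee fall 0.45/0.35/0.20, horizontal fall
  0.50/0.30/0.20).  This axis heterogeneity is what gives the
  anisotropic detector its advantage and mirrors the published learned
  vector, whose second component is half the others.
* **Morphology.**  Non-impact bouts are sums of 2–4 sinusoids drawn one
  per band from 5–18 Hz (band-stratified so near-degenerate pairs cannot
  beat at window timescales), under a slow amplitude modulation of depth
  0.25; with the sampling-phase fluctuation of the windowed mean this
  puts a bout's peak windowed energy near 1.5× its mean, and the
  maximum over a study's sets in the 1.6–2.0× band the protocol's
  walking tasks show.  Impacts are short bursts (≈ 3 windows) whose
  per-window energy profile has a leading peak `impact_peak_factor`
  times the segment mean, the factor seeded per activity from the
  published peak-to-mean ratios (≈ 2.0–3.0).  Gravity (1 g) sits on the
  vertical axis; quiet padding (E_avg ≈ 0.002 g noise) surrounds every
  bout; samples clip at ±2 g like the sensor.
* **Calibration.**  Each trace is synthesized, run through the actual
  DC-suppression + windowed-energy chain, and rescaled (4 iterations,
  clipping inside the loop) until the realized per-axis segment `E_m`
  matches its drawn target; the suite asserts agreement within 5%,
  typically it is ≤ 0.1%.
* **Between-subject variation.**  Each subject carries one lognormal
  energy factor and one duration factor per activity type (σ = 0.3 and
  0.1 by default).  The personalized preset switches these off: the
  personalized profile column already describes one subject, and its
  SDs are the set-to-set spread.
* **Separation guarantee.**  Within each subject, every impact's
  achievable peak energy must clear that subject's non-impact energy
  ceiling (largest non-impact `E_m` target inflated by the modulation
  crest) by a 1.15 margin on at least one axis; targets are scaled up
  if not.  This encodes the premise that impacts are separable *per
  subject*; across subjects the classes may still overlap, which is
  exactly what makes shared (non-personalized) thresholds worse.
* **Randomness.**  All draws flow from one root seed through
  per-(subject, set, activity) seed-sequence keys, so studies are
  bit-reproducible and any single activity can be regenerated in
  isolation.
* **Fourth axis.**  When requested, the sagittal bisectrix x2 is the
  normalized sum of x1 and y1 plus independent noise; it is a redundant
  measurement direction, not an independent energy source.

What the generator does **not** model: biomechanically realistic fall
waveforms, orientation changes and posture transitions, sensor
misplacement, non-periodic daily-living confounders (sitting down hard,
vehicle vibration), or free-living class imbalance.  Passing tests on
this data shows the algorithms behave as specified under the published
energy/duration statistics; it does not certify field performance.

One consequence of the synthetic conditions worth naming: the lowest
energy impact (knee fall) can draw peak energies below the walking
crests on a *shared* scalar scale, so the scalar isotropic family's
minimum fpr at tpr = 1 saturates near 0.4 here, while per-axis
thresholds separate the same traces easily — the anisotropy argument in
miniature.  The learned per-axis operating point lands at
fpr ≈ 0.33–0.40 across seeds (sensitivity always 100%), bracketing the
published learned operating points (fpr 0.37 scalar, 0.40 vectorial).
The personalization gap comparison is likewise noisy at the
single-replicate level (shared thresholds pay the larger gap in roughly
three quarters of the replicates), which is why the claim is made — and
tested — as a sign test over 10 replicates, not per replicate.

## Problem sizes and tolerances

The default suite runs the full pipeline on the 88-activity
personalized study plus 10-replicate experiments for the
personalization and anisotropy effects (each replicate a fresh 88- or
132-activity study); the whole suite completes in well under a minute
on one core.  Oracle equivalences (streaming detector vs materialized
flag intervals; sliding energy vs naive sums; incremental vs batch
means) are exact to 1e−12.  Statistical acceptance checks are seeded:
AUC ≈ 0.5 on label-shuffled data is asserted to ±0.05 at n = 2000, the
personalization effect by a one-sided sign test over 10 replicates at
the 5% level, and anisotropic ≥ isotropic AUC in ≥ 9 of 10 replicates.
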