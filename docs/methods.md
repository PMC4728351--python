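# Methods

## Scope and data model

The package consumes tracked 2-D point trajectories — per frame: centre
of mass (CoM) and snout tip in cm, at a uniform frame rate (240 Hz
default) — plus per-trial metadata (stimulus contact frame, stimulus
edge coordinates, fish ID, trial number, total length TL). Conventions
are fixed once: frames 0-based, y up, angles in degrees and
counterclockwise-positive, times in ms, lengths cm, speeds cm/s,
accelerations cm/s². It does not handle video, automated tracking,
midline/curvature analysis, 3-D correction, or single- vs double-bend
classification.

## Per-trial kinematics

**Smoothing.** All derivative estimates use the five-point quadratic
polynomial regression: an order-2 polynomial least-squares fitted to each
centred five-frame window, equivalent to convolution with closed-form
weights — value (−3,12,17,12,−3)/35, first derivative (−2,−1,0,1,2)/(10 Δt),
second derivative (2,−1,−2,−1,2)/(7 Δt²). These are exact for quadratic
(and, for the first derivative, cubic) motion. The first and last two
frames carry no estimate; window maxima are taken over fully covered
frames only, avoiding asymmetric-window artifacts.

**Onset and latency.** The manual criterion ("first head movement",
judged by eye) is operationalized deterministically: the pre-stimulus
snout positions give a noise floor σ (combined per-axis SD about the
median); detection requires displacement > max(5σ, 0.05 cm) on two
consecutive frames; the onset frame is then the last preceding frame
whose displacement is back at noise level (≤ max(2.5σ, 0.025 cm)) — the
frame at which the head starts to move. Latency is (onset −
stimulus)/frame rate. No crossing before the recording ends yields a
structured "non-responsive" result, not an exception. Latency > 200 ms
sets the non-Mauthner flag. The threshold rule is a documented surrogate
for a perceptual judgement; its parameters are config knobs
(`onset_k`, `onset_min_cm`).

**Stages.** The heading is the planar angle of the CoM→snout segment,
unwrapped; its smoothed first derivative is the angular velocity ω.
Stage 1 ends at the first sign change of ω after the turn is under way
(|ω| must first exceed 4× its pre-stimulus noise level, so tracking
jitter near onset cannot fake a reversal). Stage 2 ends at the next sign
change or when |ω| decays below 10% of its stage-1 peak — a two-point
proxy for "body straightening", which is not strictly measurable from
two markers. Only the optional data-driven window (`mean_stage_window`)
depends on the stage-2 end.

**Window measures.** The analysis window is round(window_ms · frame rate)
frame intervals from the onset frame inclusive (42 ms at 240 Hz → 10
intervals, 41.67 ms — an explicit rounding contract). D_esc is the path
length of the smoothed CoM polyline over the window (distance travelled;
a net-displacement variant is a config switch, and path ≥ net always).
U_max and A_max are the maxima of the smoothed first and second
derivatives of the cumulative distance–time curve of the CoM — the
distance-time route, in which A_max is the tangential acceleration and
matches the closed-form ground truth π·U_max/(2 t_U) of the simulator's
speed profile. A component-wise route (derivatives of x(t), y(t) and
Euclidean norms, which additionally picks up the centripetal term during
the turn) is available as `deriv_method="vector"`. The turning angle is
the inter-vector angle in [0°, 180°] between the CoM→snout segments at
onset and at stage-1 end (not cumulative rotation); turning rate is that
angle over the stage-1 duration, exactly.

## Synthetic trials

The generator is a parametric stand-in for the filmed behaviour, built
for exact recovery testing rather than hydrodynamic realism:

* heading: half-sine angular-velocity pulses, ω(t) = ω₁ sin(π t/T1) over
  stage 1 (integrating to the stage-1 angle Δθ1), then the
  opposite-signed stage-2 pulse over T2 — zero at both ends of each
  stage, single-signed, hence exactly one reversal at t = T1;
* speed: u_max sin²(π t/(2 t_U)) to the peak at t_U, held at u_max to
  the end of stage 2, then a cos² coast-down (post_stage2_ms);
* CoM = time integral of speed along the heading (trapezoid quadrature
  at 64 substeps per frame, ~10⁻⁸ cm accurate); snout = CoM + one
  snout-to-CoM body length along the heading;
* tracking error: isotropic Gaussian noise added to the *stored*
  coordinates only — the dynamics are noise-free, mimicking digitizing
  error, the dominant error of manual tracking.

Ground truth is closed-form: U_max = u_max, A_max = π u_max/(2 t_U)
(the tangential peak of the sin² rise), D_esc = the elementary integral
of the speed profile over the 42 ms window, stage-1 duration = T1, turn
angle = |Δθ1|.

Two alignment choices matter and are deliberate. First, motion onset is
snapped to the frame grid (ceil of stimulus time + latency) and the
ground truth records the realized latency: at 240 Hz the sub-frame phase
of the onset is unobservable, and leaving it random would make the
recovery tests measure that unobservable phase (a half-frame shift at
plateau speed is ~7% of D_esc) rather than the estimator. Second, the
default stage-2 return angle follows Δθ2 ≈ −Δθ1 (T2/T1)², which keeps
the heading's curvature continuous across the stage-1 peak; a strongly
asymmetric return flip shifts the smoothed-ω zero crossing by more than
a frame, which is a property of the smoother, not of the segmentation.

Defaults emulate a ~11.5 cm damselfish startled at ~90° and ~23 cm from
the stimulus: latency 35 ms, T1 = 24 ms, T2 = 18 ms (stage 1+2 = 42 ms,
matching the analysis window), Δθ1 = 75°, u_max = 150 cm/s, t_U = 28 ms,
pre-stimulus baseline 500 ms (so onset detectors have a noise floor),
TL 11.53 ± 0.53 cm, stimulus angle 81.3° ± 25.4°, distance 22.8 ± 3.7 cm
— the covariate distributions of the reference protocol. No within-trial
kinematic shape is dictated by the data this design emulates; the sin²/
half-sine profiles are conventions chosen for their closed forms.

What the generator does *not* emulate: body bending (the two markers are
rigidly linked), hydrodynamics, stage-3 behaviour, responsiveness or
directionality, occlusions or tracking dropouts. Passing recovery tests
therefore show that the estimators are unbiased for smooth single-C-start
motion under Gaussian digitizing noise — not that they are robust to
tracking failures or multi-bend responses.

## Population simulation

`simulate_population` writes a fish × trial × measure table directly:
per fish a lognormal individual mean (population CV = among_cv, default
0.30), per trial a lognormal multiplier (CV = within_cv, default 0.25),
an optional multiplicative trial trend (1 + trial_effect·(j−1)) for
habituation/fatigue, and optional covariate effects exp(β·z) on
standardized covariates. Lognormal effects keep all five measures
positive and give CV a clean parameterization. `simulate_experiment`
applies the same among/within structure to the *trajectory* generator's
parameters (peak speed, latency, turn magnitude), producing a full
synthetic study that is analysed end to end from raw tracks.

## Statistics

* CV uses the n−1 standard deviation; it requires n ≥ 2 and a positive
  mean. The within-individual summary is the mean of per-fish CVs with a
  t-interval across fish (df = n_fish − 1) — the simplest defensible CI
  for a mean of per-fish statistics; a seeded bias-corrected percentile
  bootstrap (10,000 draws) is available for sensitivity. The overlap
  flag reports whether the among-individual CV falls outside that CI.
* Repeatability: per fish the two best values (direction "max" by
  default, matching the "highest and second highest" convention; "min"
  available for the biological reading of latency), ties broken by trial
  order; Pearson r and two-sided p across fish. ICC is fixed to the
  one-way random-effects ICC(1,1) — trials are exchangeable
  stimulations, so no trial-specific (two-way) effect is modelled — with
  the harmonic-mean-adjusted k₀ for unbalanced data and the exact
  F-based CI. MSB ≤ MSW is truncated at the −1/(k₀−1) lower bound and
  flagged.
* Trial-order model: REML random-intercept LMM, trial categorical
  (numerator df k−1), covariates TL, stimulus distance and angle;
  latency is natural-log transformed (CV and R² are base-invariant).
  The joint trial-factor Wald F uses a containment denominator df,
  N − n_fish − p_within, which reduces to (n−1)(k−1) on balanced data
  with no within-fish covariates, where the F equals the two-way
  repeated-measures ANOVA F; `ddf_method="residual"` (N − rank X) is the
  alternative, since no single df convention is canonical for REML Wald
  tests. σ²f is the variance (n−1 denominator) of the fixed-effect
  linear predictor over the data. Zero-variance responses short-circuit
  to a flagged degenerate result; a random-intercept variance at the
  boundary is flagged, not an error. Constant covariate columns are
  dropped (flagged) to keep the design full rank. No multiple-testing
  correction is applied; measures are reported separately.
* Exclusion rule: a fish is excluded from the four kinematic analyses
  (never from latency) when its median latency exceeds 200 ms or ≥ 60%
  of its trials are non-responsive / without a stage-1 reversal — a
  configurable operationalization of "consistently weak responses and
  long latencies".

## Problem sizes

The test suite and acceptance script use: 100 simulated trials for
kinematic recovery (0.02 cm noise); 200 replicates of 100-fish designs
for variance-structure recovery; 500 null 14×5 experiments for the
trial-order type-I rate plus 150 replicates at each of three effect
sizes for power monotonicity; 1,000 random series for the smoother
oracle. These sizes put Monte-Carlo error comfortably below the
tolerances being checked while keeping the default suite fast.

## Known limitations

* A_max from any five-point quadratic smoother at 240 Hz underestimates
  a ~50–60 ms acceleration pulse by roughly 5–15% (attenuation at the
  pulse frequency); the recovery tests budget for this. Studies using
  the same smoother carry the same bias, so comparisons within the
  convention are consistent.
* The stage-2 end is a proxy; downstream results do not depend on it
  except the optional mean-window calculation.
* The onset rule assumes a stationary pre-stimulus baseline; a fish
  swimming at stimulus onset is flagged (`moving_at_stimulus`) and its
  latency should be treated with caution.
* The LMM denominator df is a convention (see above); p-values near a
  decision boundary can differ across conventions.
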