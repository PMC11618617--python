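# Methods

This note documents the models and procedures implemented in `vrheadmotion`,
the defaults of the synthetic-cohort generator, the numerical choices made
where the design was genuinely open, and the known limits of what the test
suite can demonstrate.

## Setting

The package analyses head-tracking telemetry from *passive* VR driving
studies: participants wear a head-mounted display and watch pre-recorded
60-second driving laps (no vehicle control, no motion platform), rate each
lap on three 1–20 scales — vection magnitude, motion sickness (an FMS-style
single item), and presence — and their head rotation (pitch, yaw, roll, in
degrees) is logged at a nominal 90 Hz.  The speed manipulation presents the
same recorded lap at full or half playback speed, so the two speed conditions
share timing (60 s) but not distance.  Vection onset and duration are
recorded only for laps rated 2 or higher, since 1 means no vection at all.

## Preprocessing

Each Euler channel is unwrapped with a 360° period and re-referenced so the
first sample — the participant's forward-facing orientation at lap start — is
zero.  Continuity wins over range: genuine cumulative rotation past ±180° is
preserved rather than re-wrapped.  Traces are then linearly interpolated onto
the uniform analysis grid of `round(rate × duration)` points (5400 at
90 Hz × 60 s).  Timestamp gaps up to 100 ms (9 frames) are bridged by the
interpolation; anything longer flags the trial as excluded from head-motion
analysis, and the pipeline logs every exclusion.  The 100 ms threshold is
far below the several-second duration of a turn-driven head excursion, so
interpolation cannot fabricate a turn.  A trace must cover at least 95% of
the requested duration; shorter records are rejected outright.

## Velocity summary

Head motion per lap and axis is summarized as the mean absolute velocity in
degrees/second: the mean of |successive differences| times the sampling
rate.  No smoothing is applied before differencing — any low-pass filter
would bias the summary downward, and the statistic is reported raw.
Yaw-vs-pitch and yaw-vs-roll contrasts use paired t-tests per speed
condition; a zero-variance set of paired differences is reported as a
flagged degenerate result instead of an infinite t.

## Conformity to the normative trajectory

The central statistic: a participant's conformity on one axis and lap is the
Pearson correlation between their deviation series and the pointwise
*median* series of every other participant (leave-one-out), over all 5400
grid points.  The median is used rather than the mean to limit the influence
of outliers; leave-one-out keeps each participant's reference independent of
their own data.  Even-count medians are the mean of the two central values.
Implementation: one sort per time point plus an order-statistics lookup per
excluded participant (O(nT log n) rather than O(n²T log n)); tests verify it
against a naive delete-and-sort oracle.

Pearson correlation is location- and positive-scale-invariant, so the
centering convention has no effect on scores.  Constant traces cannot be
scored; they are flagged degenerate and *excluded with a logged count*, not
scored 0, because 0 would assert "uncorrelated" without evidence.  If a
condition cell ever holds several laps, their scores are combined via Fisher
z averaging; in the standard designs each cell is a single lap.

Cohort cells (axis × speed) are summarized by mean, SD, and a two-tailed
one-sample t-test against zero.

## Anticipatory lag

The signed head-to-vehicle delay is estimated by brute force: Pearson
correlation of head yaw at time t with vehicle yaw at time t − d for every
lag d on a symmetric grid (default ±2000 ms at one-sample ≈ 11.1 ms steps),
computed on the overlapping region only.  Truncation is used instead of
padding because padding biases r toward zero asymmetrically.  Negative lags
mean the head *leads* the vehicle.  Ties at the peak break toward the
smallest |lag|, which is conservative against over-claiming anticipation.
Two modes exist: per-participant estimates (default, summarized by cohort
median/IQR) and a pooled mode that estimates the lag of the cohort's
pointwise median trace.

Precision is physics-limited: with turn lobes several seconds wide the
r(lag) curve is nearly flat within ±30 ms of its peak, so single-trace
estimates under realistic wander scatter by roughly ±100 ms (see
"Limitations").  The pooled mode at the combined-cohort scale (n = 88)
recovers a planted 750 ms lead to within ±33 ms essentially always.

## Factorial statistics

`rm_anova` implements the classical univariate mixed-model ANOVA for
balanced complete within-subject factorials, optionally with between-subjects
factors (the sex/order moderation screens).  Sums of squares are computed by
inclusion–exclusion differencing of marginal means, which is exact for
balanced data; each within effect E is tested against E × S(B) (its
interaction with subjects nested in groups), between effects against S(B).
Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).
Design choices:

* No sphericity correction by default — plain degrees of freedom are
  reported; Greenhouse–Geisser is available via `correction="gg"` (epsilon
  from the eigenvalues of the contrast covariance, clamped to [1/df, 1]).
* No multiple-testing correction anywhere; raw p-values are reported.
* Unequal between-group sizes (e.g. 52 participants over 16 order levels)
  use the unweighted-means solution with the harmonic mean group size as the
  replication factor; the within-subject part is unaffected.  The function
  warns when this path is taken.
* Stationary baseline trials are excluded from condition ANOVAs; their
  ratings are exported for descriptive use only.
* A constant dependent variable yields F = 0, η²ₚ = 0 (not 0/0).

Tests verify F, df, p, and η²ₚ against a longhand SS oracle, against
statsmodels' `AnovaRM` for pure within designs, and against pingouin's
`mixed_anova` for the mixed case.

The conformity–rating association table crosses {vection, sickness,
presence} × {pitch, yaw, roll} × {slow, fast} (18 rows), joining each
participant's conformity score with their rating from the matching
upright/aligned/forward lap at the same speed.  The vection–presence (and
other) intercorrelations are computed over participant means of lap trials,
so the reported df is n − 2.

## Study designs

Experiment 1: posture {upright, reclined} × alignment {aligned, misaligned}
× speed {slow, fast}; 12 trials in 2 posture main blocks × 2 alignment
sub-blocks × [stationary, lap, lap].  Counterbalancing components: posture
block order × sub-block order within each main block × speed order =
2·2·2·2 = 16 order levels.  The decomposition of the 16 levels is a design
decision: those four binary choices are the only order freedoms the block
structure admits.

Experiment 2: direction {forward, reverse, lateral} × speed; 9 trials in 3
direction blocks × [stationary, lap, lap]; 3! × 2 = 12 order levels.  Speed
order is fixed within participant in both experiments.  Cohorts are assigned
to orders round-robin; when the cohort size is not a multiple of the order
count (52 over 16 levels) the assignment is as even as possible and a
warning is issued.

## Synthetic cohort generator

The generator emulates the study's data with known planted parameters so
every analysis stage can be verified without participant data.

**Vehicle.** The track's yaw profile is a sequence of `n_turns = 6`
alternating left/right raised-cosine lobes over the 60-s fast lap, with
seeded jitter of lobe centers (±30% of spacing), widths (±20%), and
amplitudes (±25%) so the profile is smooth but aperiodic (an exactly
periodic track would make the lag argmax ambiguous).  Raised cosines keep
the discrete derivative bounded, so the velocity summary is well behaved.
The slow lap is the time-dilated first half: `slow(t) = fast(t/2)` on the
same grid.  Amplitude is expressed on the *head-excursion* scale
(`turn_amplitude = 4.5°`, population gain mean 1.0): conformity and lag are
correlation-based and scale-free, so only the shape matters, and this makes
"noise sd relative to turn amplitude" unambiguous.

**Head model.** Per participant and lap:
`yaw(t) = g · vehicle_yaw(t + λ) + AR(1) wander + random-walk drift`, with
pitch and roll as attenuated copies (fixed gains 0.55 / 0.35) plus their own
scaled-down wander (noise scales 0.75 / 0.70).  λ ≥ 0 is the anticipatory
lead in ms (the head moves before the vehicle); edge values are held when
the shift runs past the lap.  Population defaults: g ~ N(1.0, 0.45) floored
at 0.05; λ ~ N(750, 100) ms floored at 0; wander sd 0.5° × lognormal(σ=0.6)
per participant, AR coefficient 0.999 (correlation time ≈ 11 s at 90 Hz);
drift 0.1 °/√s.  These were set by a velocity/SNR analysis so that default
cohorts land in plausible descriptive ranges: yaw excursions of a few
degrees per side, mean |yaw velocity| ≈ 2.5/2.8 °/s (slow/fast), the axis
ordering yaw > pitch > roll in both velocity and conformity, and a
conformity-score spread across participants (SD ≈ 0.15) wide enough to carry
a rating coupling.  Mean synthetic conformity (~0.85 on yaw) is higher than
real cohorts show; matching that level and the velocity range simultaneously
is impossible with smooth Gaussian wander (large-amplitude wander implies
large velocity), and the orderings, not the absolute conformity level, are
what the tests rely on.

**Ratings.** Each measure has a Gaussian latent: intercept + condition
effects + participant traits + conformity coupling + N(0, 3) residual,
rounded and clamped to integers 1–20.  Planted condition effects (rating
points): vection — fast +2.0, stationary −7.5, visual-cue availability
(viewpoint parallel to the road, i.e. upright-aligned or
reclined-misaligned) +1.2, direction reverse −1.5 / lateral −3.0; sickness —
fast +1.0, reverse/lateral −1.2; presence — fast +1.8, reclined −0.7.  The
direction effects are sized so their ordering is reliably detectable at the
study's n = 36.  A shared "immersion" trait (loadings 3.0 on vection, 2.8 on
presence) reproduces the strong vection–presence correlation (~0.87 at the
participant-mean level) while sickness loads 1.5 on an independent
susceptibility trait, leaving sickness uncorrelated with both.  Onset is
drawn earlier for stronger vection; duration is a Beta-distributed fraction
of the remaining lap, so onset + duration ≤ 60 s by construction.

**Conformity coupling.** With coupling β (rating points per unit
correlation), the vection latent adds β·(score − 0.85), where the score is
the participant's *measured* yaw conformity for the matching lap and 0.85 is
a fixed reference so switching the coupling on does not shift the intercept.
The default β = 9.5 was calibrated against the measured score spread to give
a population conformity–vection correlation of ≈ 0.32 (60-rep measurement) —
the "moderate coupling" regime the recovery tests target.

**Purity and the firewall.** All generation is a pure function of
(config, seed); per-participant substreams are keyed by (seed, stream,
participant index), so enlarging a cohort never perturbs earlier
participants.  Both experiments share one `track_seed`, because the study
replays the same recorded lap in both.  Planted parameters are written to a
`ground_truth.json` sidecar that the analysis pipeline never reads (a test
deletes it and checks the analysis is unchanged).  By default head traces
are simulated only for the upright-aligned/forward laps the combined
head-motion analysis uses — the head model is only specified for
forward-facing viewing — with `head_trace_scope="all"` available.

## What the synthetic tests do and do not show

The generator produces linear-gain followers of a smooth stylized track with
Gaussian wander and latent-Gaussian ordinal ratings.  Real head motion has
saccade-coupled micro-adjustments, asymmetric turn anticipation, and
non-Gaussian rating behavior (end-point pile-ups, integer anchoring), none
of which are modeled.  Passing recovery tests therefore demonstrates that
the *analysis machinery* is correct and well calibrated — oracle-exact
statistics, planted effects recovered at the planted magnitudes, nominal
type-I rates — not that real cohorts will show these effect sizes.

Known quantitative limits, measured during development:

* Single-lap conformity scores carry sampling error of roughly ±0.05–0.1
  (one 60-s lap ≈ 40 effective independent samples once the wander's
  correlation time is accounted for).  Consequently a per-lap ranking of 20
  finely spaced planted gains tops out near Spearman 0.86 regardless of
  noise level; ranking Monte-Carlo *expected* scores recovers the planted
  order essentially perfectly, and that is what the invariant test asserts.
* Single-trace lag estimates under moderate wander scatter by ~±100 ms even
  though the noise-free estimate is grid-exact; cohort-pooled estimates
  (median trace, n = 88) are reliable to ±33 ms.  Anticipation claims from
  single laps should therefore quote the cohort median, not individual fits.

## Numerical conventions

* Roundtrip I/O is exact to 1e-9 (CSV written at %.12g precision).
* Radians are accepted only when a dialect declares them; converted on read.
* Degenerate statistics (zero-variance inputs) are flagged, never silently
  coerced to 0 or ±inf; degenerate scores are excluded from summaries with
  logged counts.
* The report bundle is a pure function of (input data, config, seed):
  analysis CSVs are written at fixed %.10g precision and identical runs are
  byte-identical.
* Config validation is fail-fast and complete before any computation; no
  silent defaulting of required keys.
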