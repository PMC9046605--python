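# Methods

This note documents the models, conventions and numerical choices behind
`stancelab`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Measurement model and conventions

A trial is one stance of treadmill running: vertical and anterior-posterior
ground reaction force (GRF) at 1000 Hz, and five foot-segment poses (shank,
calcaneus, midfoot, metatarsus, hallux) with a reduced marker set at 200 Hz.
The laboratory frame has x anterior, y vertical, z medio-lateral. Forces are
normalized to body weight, BW = mass × g with g = 9.80665 m/s².

Stance is delimited by 30 N crossings of the vertical GRF: heel strike is
the first sample at or above threshold after a below-threshold run, toe-off
the last such sample before the next one. The pipeline applies hysteresis
(minimum 10 ms contact, minimum 50 ms flight, both configurable) to reject
chatter on noisy treadmill data; the primitive `detect_stance` defaults to
the pure crossing rule. Detection runs on the filtered vertical GRF by
default; raw-signal detection is a configuration switch.

Signals are conditioned with a dual-pass (zero-lag) Butterworth low-pass
filter: a 2nd-order filter run forward and backward, the dominant gait
convention for a "4th-order zero-lag" filter, giving a gain of exactly 0.5
at the cutoff. Defaults: 10 Hz for kinematic channels, 80 Hz for GRF.
Edges are padded by odd reflection (pad length 3× the effective order);
the alternative reading (4th-order dual-pass, 8th-order effective) is
selectable. All channels are then linearly interpolated onto 101 nodes
spanning 0–100% of stance.

## Joint and planar angles

Joint rotations use the Joint Coordinate System: with the first body-fixed
axis the proximal z (sagittal; dorsiflexion positive), the third the distal
y (transverse), and the floating axis their mutual perpendicular (frontal;
for Sha-Cal eversion positive, inversion negative), the decomposition of the
relative rotation R = Rpᵀ Rd is exactly the intrinsic Z-X-Y Euler sequence.
Composition and decomposition therefore round-trip to machine precision
away from the gimbal singularity at ±90° frontal, where a warning flag is
set (|frontal| within 1°).

The per-segment anatomical-frame construction from the full 16-marker
protocol is deliberately out of scope: the module consumes segment poses
(the testable interface), with marker-level operations for the planar
angles. The medial longitudinal arch (MLA) angle is the apex angle at an
arch marker (a sustentaculum-tali/navicular proxy) between the heel and
first-metatarsal-head markers; larger = flatter, range (90°, 180°) for
plausible feet. Metatarsal inclinations (F2G/S2G/V2G) are the angle of the
base→head axis to the ground plane, head-down positive; transverse
divergences (S2F/S2V) are signed angles between ground-plane projections of
the metatarsal axes, measured from the second metatarsal.

## Discrete risk factors

Per trial: MLA range of motion (max − min over stance); Sha-Cal frontal
peaks (inversion = minimum, eversion = maximum); vertical impact peak (first
local maximum of the filtered vertical GRF within the first 30% of stance,
in BW — the search window is configurable); vertical average loading rate
(VALR): the secant slope of the line through the force values at 20% and
80% of the contact-to-impact-peak interval, in BW/s (a least-squares
"regression" reading is selectable); and peak braking force (most negative
anterior-posterior force, in BW). A trace with no early local maximum (a
forefoot-strike-like waveform) yields missing impact peak and VALR, which
propagate as NaN and are dropped listwise in the models.

## Mixed model

Each outcome is modelled with fixed group, time and group×time effects and
a Gaussian random intercept per participant, fitted by REML (statsmodels
MixedLM; OLS fallback when the mixed fit is singular or fails — recorded in
the result). The interaction is the primary comparison and equals the
difference-in-differences of the cell means. Wald statistics use a t
reference with n₁+n₂−2 df, the exact df for the interaction in the balanced
complete-case design. Estimated marginal means are the model cell means;
the four natural pairwise comparisons (within-group changes, between-group
contrasts at each time) are Bonferroni-adjusted (k = 4). Cohen's d between
groups at the post assessment uses the n-weighted pooled sd, with bins
negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large; the change-score
variant is available through `cohens_d` directly.

## 1D statistical parametric mapping

Node-wise t (two-sided), one-/two-way F, and Hotelling's T² fields over the
101 nodes are thresholded with random-field-theory critical values based on
the expected Euler characteristic of a smooth 1D field:
P(max > u) ≈ P₀(u) + R·ρ₁(u), with R = 100/FWHM resels and the standard
Worsley-family EC densities for t and F fields; T² fields are thresholded
through their monotone F transform F = (ν−p+1)/(νp)·T². Smoothness (FWHM)
is estimated from the gradient of variance-normalized residual fields.
Because inference is over sampled nodes, the threshold is capped at the
Bonferroni-over-nodes quantile (binding only for very rough fields).
Suprathreshold clusters are maximal runs of nodes exceeding the threshold;
cluster-extent p-values use the standard exponential approximation and are
secondary. Post-hoc protocol after a vector-field T²: component-wise t
fields at the Šidák-adjusted level α' = 1 − (1−α)^(1/k) with k = 3
components. A max-statistic permutation/sign-flip threshold is provided
both as a nonparametric alternative and as the validation oracle for the
parametric thresholds (they agree within ~2% on smooth Gaussian nulls).

The field ANOVA for scalar channels treats pre/post rows as independent
(type-III two-way OLS per node); the repeated-measures covariance is
handled only in the paired T² and paired t comparisons. This mirrors
common practice but slightly misstates the interaction F field's null for
strongly correlated pre/post trajectories — a known limitation.

## Synthetic cohorts

The generator defines the study conditions: two arms (default 41/46
subjects), two assessments, body mass ~ N(70.5, 13.1) kg truncated at ±3 sd,
stance duration 0.25 s, rates 200/1000 Hz. The effect table (cell means and
sds for all six discrete outcomes) defaults to the trial's published
pre/post values per arm. Each subject draws a random intercept per outcome
(by default half of the smallest cell variance) plus cell-specific residuals
so the marginal cell sds equal the configured values.

Waveforms are built so the planted values are *analytically* recoverable:

* the vertical GRF rises linearly from exactly 30 N at a grid-aligned
  contact sample at slope VALR×BW; the peak sample carries exactly
  impact×BW; a valley and an active peak (default 2.4 BW) follow; the
  trace descends through exactly 30 N at the grid-aligned toe-off sample;
* the braking minimum of the AP force lies on a grid sample;
* the MLA program places its extrema at 0% and 50% of stance and the
  Sha-Cal frontal program its eversion/inversion peaks at 30% and 80%, all
  of which lie on both the 200 Hz grid and the 101-node grid;
* segment rotations are composed in the exact inverse order of the JCS
  decomposition, so decomposition round-trips to the programs.

With all noise and cell sds at zero, the full pipeline (with filters
disabled — a dual-pass filter is not the identity on any sampled signal, so
the analytic-recovery oracle bypasses it) reproduces every planted value to
~1e-13 relative. Under the default conditions the filters and marker noise
(0.5 mm) perturb extraction at realistic magnitudes (median ~0.4–1° on
angle peaks, ~1 BW/s on VALR).

Physically unrealizable draws (negative MLA ROM, inversion above eversion,
impact-rise outside 7 GRF samples–24% of stance) are clamped to the
feasible boundary for waveform synthesis, and the clamped value is stored
as that trial's ground truth. Statistical-recovery simulations use
`simulate_outcome_table`, which draws the unconstrained Gaussian values, so
recovery of the planted group×time effect is tested without truncation
bias. Remaining non-planted trajectories are smooth templates loosely
shaped on normative barefoot running curves with low-order Fourier
variability (default sd 1.5°), which keeps residual fields smooth enough
for the random-field machinery (estimated FWHM ≫ 1 node).

What the synthetic data do **not** emulate: soft-tissue marker artifact,
step-to-step variability within a session (one stance per session),
non-Gaussian outcome distributions, forefoot strikers (no absent impact
transient under defaults), inter-channel biomechanical coupling beyond the
kinematic chain, and treadmill drift. Passing tests therefore demonstrate
correctness of the computational pipeline under its stated assumptions, not
robustness to every artifact of real motion-capture data.

## Problem sizes and numerics

Simulation-based checks use sizes chosen to keep the whole suite around a
minute while leaving Monte-Carlo error well inside the asserted bands:
2000 replicates for the family-wise-error calibration, 5000 permutations
for the threshold cross-check, 500 replicates (the full 41/46 cohort each)
for interaction recovery and CI coverage, 400 for the type-I error check,
and 20 seeded full-pipeline runs for null specificity. RFT thresholds are
solved by bracketed root finding to 1e-6. Singular node covariances in T²
are ridge-stabilized with a warning; zero-variance nodes are excluded from
smoothness estimation. Degenerate inputs (NaNs, too-short windows, gimbal
proximity, unsatisfiable waveform constraints) raise typed errors rather
than propagating silently.
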