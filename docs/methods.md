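# Methods

This note documents the models, parameter choices and numerical
decisions behind `emotrace`, and what the synthetic validation does and
does not establish about real data.

## Study design emulated

Two groups (clinical BPD, healthy controls; default 14 per group) view
48 socio-emotional pictures: 2 presentation blocks (*short* 5 s, *long*
15 s) × 3 valence categories (negative / neutral / positive, classified
from 9-point pilot valence ratings: <4 negative, 4–6 neutral, >6
positive) × 8 pictures. Trial order is a per-participant seeded
permutation; inter-trial intervals are uniform on 10–15 s; a 120-s
physiological baseline precedes the task. Affective sliders (valence,
arousal, dominance) are bounded on [0, 1]. Questionnaire summary scores
(emotion-dysregulation total on a 1–5 item-mean scale, maladaptive-trait
domain on 0–3, positive/negative affect sums) are drawn from
group-specific normal profiles and serve only the group-contrast stage.

## Synthetic data channels

The generator's defaults are the study conditions; every magnitude
below was chosen once, from the reference descriptive tables, and is
exposed in `CohortConfig` / `EffectSpec`.

**Gaze.** A two-state alternating renewal process: the eye dwells on an
attractor either inside an experimental AoI or elsewhere on screen, with
exponential holding times (mean in-AoI dwell 0.45 s plus an 80-ms
refractory floor) and isotropic Gaussian jitter (SD 18 px) around the
attractor. The stationary in-AoI occupancy is 0.55 for controls, with a
between-participant log-normal trait (SD 0.2 on the log scale); the
planted avoidance effect multiplies the clinical group's occupancy by
`aoi_dwell_ratio` (default 0.8, i.e. a 20% reduction). Trials start on
the central fixation cross. 2% of samples are flagged invalid. The
default sampling rate is 30 Hz (consumer-grade tracker class) and is
configurable because the hardware rate is not a modeling commitment.
This process produces I-DT-detectable fixations with realistic dwell
statistics; it does **not** model saccade kinematics, blinks as events,
smooth pursuit, or image-content salience.

**EDA.** Trace = tonic + phasic + sensor noise, in arbitrary instrument
units (the reference SCL scale, ≈810). Tonic: participant offset
(SD 100) plus a slow drift (SD 0.5, ≈100-s correlation length) — kept
deliberately much slower than phasic rises so that onset detection on
the filtered trace is meaningful. Phasic: each trial elicits, with
probability 0.9, a Bateman-shaped response (rise 0.75 s, decay 2 s)
with log-normal amplitude (median 7 units; with the 10% non-response
trials this puts mean log(1+amplitude) near 1.85, the scale of the
reference tables) at onset latency ~ N(μ_group, 0.25 s) truncated to
[0.5, 3.9] s, plus a participant latency trait (SD 0.12 s). Controls
have μ = 1.68 s; the planted hypersensitivity effect subtracts
`latency_shift` (default 0.13 s) for the clinical group. Spontaneous
fluctuations (rate 0.02 Hz, smaller amplitudes) are placed outside the
stimulus response windows so that planted-onset recovery can be scored
against ground truth.

**RR intervals.** Within each timeline segment (baseline, trial, ITI),
intervals are independent normals around a participant mean
(N(780, 100) ms, i.e. HR ≈ 77 bpm) with the successive-difference SD set
so that the segment's expected RMSSD equals its target: a participant
base trait N(38, 13) ms everywhere, shifted by ±crossover/2 during
trials (default crossover 5.5 ms, participant SD 4 ms), with the sign
flipping between blocks and groups — controls gain RMSSD in the long
block, the clinical group loses it. Independent intervals make RMSSD
directly controllable; no respiratory sinus arrhythmia, ectopy or
frequency-domain structure is modeled.

**Ratings.** Category-anchored means (valence .27/.41/.66 for
negative/neutral/positive; arousal and dominance analogous), participant
intercepts (SD 0.08), trial noise (SD 0.12), clipped to [0, 1]. The
planted modulation effect shifts valence by ±`valence_block_crossover`/2
(default 0.03) with opposite sign per group between blocks.

`null_mode=True` zeroes all four planted effects (traits and noise
remain), which makes the groups exchangeable — the basis of the
type-I-error calibration.

## Areas of Interest

AoIs are unions of axis-aligned, half-open pixel rectangles (point-in-
region tests are O(#rects); union areas via polygon union). Pilot AoIs
are derived per stimulus from pooled gaze: samples are binned on a 4-px
grid, smoothed with a Gaussian kernel (σ = 50 px ≈ 1.5° at typical
viewing geometry; configurable), and cells reaching 20% of the peak
density are kept; the bounding boxes of the connected components,
unioned with the experimental AoI, form the pilot region. The union
enforces the containment invariant (pilot ⊇ experimental) by
construction. The pipeline pools the cohort's own gaze rather than a
separate pilot sample; since one common pilot region is applied to every
participant, this choice cannot bias group contrasts, but it does make
the pilot region mildly outcome-dependent in a way a pre-registered
pilot sample would not be.

## Gaze indexes

Fixations: dispersion-based I-DT — maximal runs with
(max x − min x) + (max y − min y) ≤ 60 px lasting ≥ 100 ms; invalid
samples break runs. Per trial and AoI family:

* *prop gaze* — in-AoI gaze samples ÷ valid samples ("gazes" are read as
  samples; a fixation-count mode is available via `prop_gaze_mode`);
* *mean time* — mean over the family's AoIs of total fixation time in
  each AoI;
* *time 1st fixation* / *1st fixation duration* — onset-relative start
  time and duration of the first fixation in each AoI.

Multi-AoI aggregation sums per-AoI values except *mean time*, which is
averaged. Corrections: prop gaze, mean time and 1st-fixation duration
are divided by the family's screen-area fraction; the first-fixation
time is divided by the pixel distance from the trial's first gaze sample
to the nearest point of the AoI first fixated, floored at 1 px (the
floor avoids division by zero when the trial starts inside the AoI and
preserves ordering). The absolute scale of corrected indexes is
therefore a package convention; downstream rank-based tests are
invariant to any positive per-stimulus rescaling shared by all
participants. Missing indexes (no fixation ever reaches an AoI)
propagate as missing, never as zero; participant-level cell means use
the available trials. Delta scores are pilot-minus-experimental on the
corrected indexes; positive deltas indicate attention on pilot-only
picture elements.

## Physiological indexes

EDA is low-pass filtered at 2 Hz with a zero-phase second-order Bessel
design (magnitude-normalized, forward-backward). A Bessel rather than a
sharper filter is a deliberate choice: its monotone step response does
not ring ahead of the steep SCR rise, and ringing precursors are
precisely what a trough-to-peak onset detector mistakes for early
onsets.

Within the 5-s post-onset response window: SCL is the window mean; the
SCR onset is the local minimum from which the first rise of at least
0.01 units (peak prominence) starts; the amplitude is the maximal rise
from that trough within the window, reported as log(1+amplitude) so
zero-response trials are well defined; a rise truncated by the window
end counts as a response. Because zero-phase smoothing smears the rise
foot symmetrically backward (≈0.2 s at 2 Hz), the reported onset is
refined by intersecting the maximum-slope tangent of the rising limb
with the trough level — on generated data this brings the mean absolute
latency error to ≈0.04 s with no group asymmetry. This extractor is a
simplified stand-in for continuous decomposition approaches: it recovers
onset latency and amplitude (the quantities the hypotheses need) but
does not separate overlapping SCRs or estimate the tonic level
independently of the phasic component.

HR = 60000/mean(NN); RMSSD = sqrt(mean of squared successive NN
differences), after excluding physiologically impossible intervals
(outside 200–3000 ms). Per-trial RMSSD on a 5-s window rests on ~6
intervals; the square root makes this estimator downward-biased at such
sizes (extracted cohort means ≈34 ms against a planted 38 ms base), a
property of short-window RMSSD generally, not of the generator. Optional
smoothness-priors detrending solves
(I + λ²D₂ᵀD₂)·trend = NN (regularized second differences, default
λ = 500, mean restored) before RMSSD; it is off by default because the
generator plants no slow trends.

## Inference

Outcomes are aggregated to participant × cell means before testing
(group-level inference at n = 14 per cell). For each outcome two
split-plot ART ANOVAs are run: group × category (reporting the group
main effect and the interaction) and group × block (reporting the
interaction).

ART alignment: residual = value − full-model cell mean; the target
effect's marginal-mean estimate (margins unweighted over cells, as
estimated marginal means) is added back; the aligned column is
midranked. The split-plot F uses participants-within-groups as the error
term for the between effect and the participant × factor residual for
within and interaction effects; group sizes may be unbalanced (the EDA
subsample) but every participant must hold every within level —
participants with an entirely empty cell (e.g. no measurable SCR in any
trial of a cell) are dropped from that outcome's test and logged. The
implementation's degrees of freedom are (a−1, N−a) for the between
effect and ((a−1)(b−1), (N−a)(b−1)) for the interaction; with the full
cohort that is (1, 26) for the group effect and the group × block
interaction. Published two-way interaction dfs of the form (2, 25) or
(2, 20) are not derivable from this (or any standard) mixed layout; the
package documents and reports its own dfs rather than mimicking them.
η²ₚ = F·df₁/(F·df₁+df₂) is reported for every effect. Note that ART is
*not* invariant under nonlinear monotone transforms of the response
(alignment acts on the raw scale); positive affine transforms leave all
F statistics unchanged, and this is the invariance the tests assert.

Mann-Whitney contrasts: midrank U; the reported U is min(U₁, U₂) (the
convention of common statistical software); Z uses the tie-corrected
normal approximation without continuity correction, signed by the
direction of the first sample's ranks; r = Z/√N with N the total of the
compared samples. The exact two-sided p enumerates all label assignments
when C(n₁+n₂, n₁) ≤ 10⁶ (the pipeline's 14-vs-14 contrasts exceed this;
the 9-vs-14 EDA contrasts do not); otherwise the Monte-Carlo permutation
p (default 10,000 seeded resamples) with its two-tailed 99%
Clopper-Pearson interval stands in. Post-hoc families: three category
contrasts at α/3 = .0167, the block trend contrast (per-participant
long − short difference) at α/2 = .025 — run only within significant
ART effects. Delta scores, questionnaires and the four baseline indexes
(SCR, SCL, HR, RMSSD) get direct group contrasts. The Spearman coherence
screen correlates participant task means across modality pairs
(self-report × physiology × eye-tracking) within each group separately.
Group contrasts use the corrected gaze indexes by default
(`use_corrected`). Participants without an EDA recording are excluded
from electrodermal analyses only.

## Calibration and problem sizes

Replicate simulations (type-I error, parameter recovery) use a
scaled-down profile chosen once: 14 participants per group (the quantity
the inference is calibrated for), 2 pictures per category per block
(12 trials), gaze at 15 Hz, EDA at 16 Hz, 60-s baseline, 2–4-s ITIs.
The trimmed rates and dead time leave the tested statistics unchanged
while keeping a full generate → extract → test cycle under a second.
Under this profile, across 500 null replicate cohorts the group-effect
rejection rate pooled over five outcomes (valence, SCR latency, RMSSD,
prop gaze, 1st-fixation duration — one per data channel family) sits
near the nominal 5%, and the planted 0.13-s latency shift is recovered
to ≈0.12–0.13 s over 100 cohorts.

## What passing tests do and do not show

The synthetic cohorts validate the *pipeline*: index definitions,
extraction accuracy against planted ground truth, type-I calibration and
effect-direction recovery. They do not validate the noise models against
real physiology or gaze — real EDA has overlapping and spontaneous
responses inside stimulus windows, real RR series have autocorrelated
and respiratory structure, real gaze has saccade dynamics and salience
effects, and real group differences are not homogeneous shifts. Passing
here therefore means the analysis chain does what it claims under its
stated assumptions, not that those assumptions hold in any clinical
dataset.
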