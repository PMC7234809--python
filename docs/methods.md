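# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The latency model

All latency inference works on *promptness*, the reciprocal reaction time.
Under the LATER (Linear Approach to Threshold with Ergodic Rate) account a
decision signal rises linearly from a start level to a threshold at
distance θ, at a rate drawn per trial from a Gaussian with mean μ and SD
σ₁; the latency is θ/rate, so promptness is Gaussian with mean m = μ/θ and
SD s = σ₁/θ.  Latency data identify only (m, s): any common rescaling of
(μ, σ₁, θ) fits identically.  Reported (θ, μ, σ₁) therefore use the
convention σ₁ = 1, i.e. θ = 1/s, μ = m/s.

The likelihood is the Gaussian density of 1/RT on the promptness scale,
with no Jacobian back to seconds.  All four model variants are compared on
this same scale, so the choice cancels in every BIC difference; it also
matches the convention of plotting and fitting reciprobit lines in
promptness coordinates.

Two-condition contrasts (within- vs. across-context trials) are fit under
four constraints:

| variant  | free parameters | interpretation |
|----------|-----------------|----------------|
| null     | shared (m, s), k = 2 | manipulation has no effect |
| shift    | free m per condition, shared s, k = 3 | rate-of-rise change; parallel reciprobit lines |
| swivel   | shared m/s, free s per condition, k = 3 | threshold change; lines pivot on the infinite-time intercept |
| two_fits | free (m, s) per condition, k = 4 | conditions unrelated |

The swivel constraint is formalized as a shared m/s ratio — the reciprobit
line's intercept at promptness zero — which is the standard reading of
"swivelling around the infinite-time intercept".  Null and two-fits have
closed-form Gaussian MLEs; shift and swivel are solved by derivative-free
Nelder–Mead from the unconstrained solution, optimizing log s for
positivity, with relative function tolerance 1e−8 and at most 10⁴
iterations.  Only the main (single-Gaussian) component is fit; no
early-response second component is modelled.

BIC = −2 logL + k ln(n) with n the pooled observation count; ΔBIC > 2 is
labelled positive and > 6 strong evidence.

Empirical reciprobit coordinates use Hazen plotting positions
((i − 0.5)/n), with exact ties collapsed into single points carrying their
pooled mass.

## Reaction-time RSA and the replay-model family

Within-context trials are binned into n equal-width segments (8 by
default; 10 and 14 supported) by chosen-frame location normalized to
[0, 1].  Because each segment is summarized by a scalar mean RT, the
"Euclidean distance" between segments reduces to the absolute difference
of means.  Off-diagonal entries are rank-transformed (average ranks for
ties) over the upper triangle only and scaled linearly to [0, 1]; a matrix
of all-tied entries (constant profile) maps to 0.5 everywhere and carries a
degeneracy flag.

Hypothetical replay models are per-segment RT patterns
`slope·i + offset·slope·[i ≥ boundary_segment]` with the offset expressed
in slope units.  `offset = 0` is strict-forward replay; `offset =
−(boundary_segment − 1)` is the full reset in which clip 2's first segment
replays as fast as clip 1's first segment (global compression).  The
11-model grid spans ±(boundary_segment − 1) symmetrically (−4…+4 in steps
of 0.8 for 8 segments with the boundary at segment 5), placing the
strict-forward model exactly at the centre.  Grid models with large
same-sign offsets can have *identical* rank-transformed RDMs — once every
cross-clip distance exceeds every within-clip distance the rank structure
saturates — so the sweep's argmax is reported as the set of exactly tied
maximizers (`argmax_offsets`).

Model fit is the Spearman correlation between model and group-average data
RDMs over the upper triangle.  Uncertainty comes from bootstrap
iterations (100 by default): trials are resampled with replacement within
each subject, per-subject RDMs rebuilt and averaged; iterations leaving a
segment empty are redrawn.  The resampling unit is the trial within
subject; subject-level resampling is a caller option for larger cohorts.
Paired model contrasts use the two-sided Wilcoxon signed-rank test over
the paired iteration vectors with Benjamini–Hochberg FDR adjustment across
the supplied contrast set; each model's iteration distribution is also
tested against zero, since either convention may be wanted.

## Regression and trends

Promptness is regressed on standardized covariates (z-scored continuous,
±0.5-coded binary) with a Gaussian identity-link model fit by ordinary
least squares, so betas are comparable effect sizes.  The ten standard
regressors are video category, play order, exposure, touch side, elapsed
session time, chosen frame location, temporal similarity, temporal
distance, response correctness, and (for across-context sets) perceptual
similarity.  Chosen-frame location is normalized to [0, 1] by
frame/(n_frames − 1) so slopes are comparable across 8–12 s videos; the
raw-frame alternative is a linear rescaling and changes nothing but units.
Per-subject slope tables are produced for all trials and for
correct-only/incorrect-only splits (splits under 30 trials are flagged,
not fit); per-subject p-values are reported raw, uncorrected.

Trend testing uses an orthonormal polynomial basis (QR of the centred
Vandermonde matrix), so the t-test of each degree's coefficient is exactly
the incremental test of that degree given all lower-order terms, and
lower-degree estimates do not move as higher degrees are added.

## The synthetic generator

The generator emulates the factorial design of the macaque study this
pipeline targets: 50 sessions × 100 trials crossing Boundary (within vs.
across) × Play order × Temporal distance (25 levels: 25 frames + 3 per
step at 25 fps, i.e. 1000–3880 ms) × Exposure (5; the human variant runs
20 sessions × 2 exposures).  Videos are two clips drawn uniformly from
4–6 s; probe frames are placed uniformly subject to the trial's TD level
and boundary condition.  Factor cells are balanced within exposure blocks
and permuted into sessions with a seeded generator; the whole pipeline is
byte-reproducible for a fixed seed.

Reaction times come from a replay mechanism mirroring the LATER fit:

    mean_rt = t0 + scan_rate · t(chosen frame) + replay_offset · [chosen ∈ clip 2]
    promptness ~ Normal(1/mean_rt + context_rate_gain · [across], promptness_sd)

truncated below at 0.05 s⁻¹ by rejection (guaranteeing RT ≤ 20 s with
negligible distortion relative to the 0.7–10 s analysis window), and
RT = 1/promptness.  Defaults: t0 = 0.9 s; scan_rate = 0.0942 s per second
of video (the compression-defining slope, set to the value measured in the
study the pipeline targets); promptness_sd = 0.15 s⁻¹, a typical latency
variability for trained non-human primates; replay_offset = 0 (strict
forward).  `offset_seconds` converts model-family offsets (slope units per
segment) into seconds for generation.

context_rate_gain — the promptness-mean increase on across-context trials,
i.e. boundary-triggered facilitation of the rate of rise — defaults to
0.10 s⁻¹.  This value is derived from the magnitude of the shift-vs-swivel
evidence reported for this paradigm: BIC differences of roughly 15–300 at
~2500 trials per condition imply, through the noncentrality relation
λ ≈ 2n(g/2m)², per-subject gains between about 0.05 and 0.22 s⁻¹; the
default is the geometric midpoint of that range.

Choices are generated by a chance-floored logistic,
P(correct) = clip(σ(c₀ + c₁(1 − TS) + c₂·[across]), 0.5, 1) with defaults
c₀ = 0.2, c₁ = 1.5, c₂ = 0.4, giving ~68% overall accuracy, harder
discrimination as temporal similarity approaches one, and an
across-context advantage.  This rule is declared synthetic scaffolding:
the paradigm's literature reports accuracy patterns but no generative
choice model, and nothing downstream depends on its specific form.

What the generator does *not* emulate: real video content (category and
play order are inert factors), sequential/learning effects across
sessions, attention lapses or fast guesses outside the LATER distribution,
and the idiosyncratic boundary-position distribution of a real clip
library (uniform 4–6 s clips put the mean boundary mid-video).  Passing
recovery tests therefore demonstrates that the estimators identify the
generating mechanism at realistic effect sizes and trial counts — not that
any particular animal behaved this way.

A consequence worth knowing: on full-pipeline synthetic data the two-fits
LATER variant typically beats shift at large n, because chosen-frame
location varies within condition and inflates each condition's promptness
variance differently — a real model violation, honestly detected.  The
shift/swivel/null recovery studies therefore use condition-pure latency
samples drawn directly from the promptness process, which is also the
regime the variant definitions describe.

## Numerical and degenerate-case decisions

* RT exclusion bounds are inclusive: rt = 0.7 s and rt = 10.0 s are
  retained; "faster than 0.7 s" and "slower than 10 s" are excluded.
* Frame indices are 0-based internally with half-open intervals; I/O
  offers a `one_based` flag for ordinal-numbered exports.
* The default test clock for temporal similarity is video offset + 2 s
  (the retention delay), overridable per trial.
* Zero-variance promptness samples, identical probe frames, empty
  segments, rank-deficient designs and constant outcomes raise typed
  errors rather than propagating NaNs; all-tied RDMs and all-zero Wilcoxon
  differences take defined degenerate values (0.5 with a flag; p = 1).
* Paired contrasts with zero-variance differences define t = 0, p = 0.5
  (null case) or ±∞ (deterministic difference); one-way ANOVAs with zero
  within-group variance define F = 0 (equal means) or ∞.
* The nominal video duration for compression arithmetic is 10 s, the
  design mean; the table's empirical mean duration can be supplied
  instead.
* Sliding windows default to 25 frames (~1 s) with 1-frame steps; empty
  windows are gaps, never interpolated.
* HOG defaults to 8 orientations and 16-px cells; keypoint descriptors
  default to the ORB backend, and the across-context perceptual regressor
  falls back from keypoint distance to HOG correlation when no keypoints
  are found, with the method recorded.

## Problem sizes

The test suite and the acceptance script use the design's native sizes:
5000-trial subjects, 6-subject cohorts, 100 bootstrap iterations, 100
seeded repetitions per recovery study, and 33 offset-grid runs (11 offsets
× 3 seeds).  These sizes were chosen to match the emulated study's own
scale; the full suite runs in about a minute of CPU time.

## Known limitations

* The LATER machinery is written for two-condition contrasts; multi-way
  condition structures require repeated pairwise calls.
* Bootstrap SEMs describe resampling variability of the group RDM, not
  across-subject variability (six subjects is too few for subject-level
  resampling to be the default).
* The inverse-efficiency ANOVA and trial-type ANOVA treat subject ×
  condition cells as independent groups, matching the degrees of freedom
  convention of the emulated analyses rather than a repeated-measures
  decomposition (both layouts are simple to obtain from the returned
  per-cell tables).
* Perceptual similarity operates on provided raster frames; no video
  decoding is included.
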