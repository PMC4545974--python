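# Methods

## Signal model and conventions

Marker positions are expressed in millimetres with +z superior. Oral
*opening* therefore moves the lower lip downward and shows as a
**negative** lower-lip velocity; closing is positive. The time axis is
implicit and uniform (frame *i* at *i*/rate seconds); the reference
sampling rate is 250 Hz, but nothing in the pipeline assumes it.

A span of *n* frames lasts (*n* − 1)/rate seconds. This off-by-one
convention matters for every duration reported and is applied
consistently.

## Head-motion correction

Lip markers are re-expressed in a per-frame head frame estimated from
≥3 non-collinear head-mounted markers. Each frame's pose is the
least-squares rigid transform (SVD superposition / Kabsch, no scaling)
aligning that frame's head markers onto their configuration at the
**first frame** of the trial; the head-frame axes inherit the lab axes
there, so superior–inferior remains lab z. Per-frame RMS fit residuals
are reported as a rigidity diagnostic. For any motion applied rigidly to
all markers, projected lip trajectories are invariant to numerical
precision; the batched-SVD implementation is cross-checked in the tests
against an independent superposition solver.

## Filtering and differentiation

Displacement is low-pass filtered with a 4th-order Butterworth applied
forward–backward (zero phase, DC gain 1, odd reflection at the edges),
default cutoff 10 Hz — the conventional choice for orofacial kinematics,
whose energy in these tasks lies below ~8 Hz. Velocity is the central
difference of displacement (one-sided at the ends), exact for linear
signals and adequate at 250 Hz for ≤10 Hz content. Both operators are
linear and commute away from the edges.

## Utterance segmentation

Opening velocity peaks are local minima of lower-lip velocity that dip
below −0.10·max|v| within the trial (the threshold replaces the
operator-in-the-loop display of interactive protocols; it is a config
knob, `segmentation.prominence_frac`). Boundary samples count as peaks
so that segmentation is idempotent. The utterance is cut inclusively
between the 1st and 5th peaks; the lower-lip velocity defines the cut
and all articulators are cut at identical frames. If more than five
candidates qualify, the five deepest are taken in temporal order; fewer
than five is an error naming the trial. Movement onsets/offsets for
single-syllable cycles are the velocity zero-crossings flanking the
cycle's opening peak — the conventional kinematic landmarks. The
syllable→cycle map (*Bob*→2, *pup*→4 for the default sentence) is
configuration, since ordinal positions depend on the sentence.

Participants enter the analysis with ≥7 valid repetitions; at most the
first 10 valid are used, mirroring protocols that collect up to 12
productions to obtain 10 analysable ones.

## Phrase-level measures

"Operating range" is computed as the central 80% of the sample-value
distribution — the 10th-to-90th-percentile span with linear-interpolation
percentiles — of the displacement and of the *signed* velocity samples
(a speed-based variant is a flag; signed is the default so opening and
closing extremes both contribute). The measure is translation-invariant
and positively homogeneous. One value per trial, averaged per
participant.

A normative screen flags participants whose averaged dynamic range
exceeds a configured external normative mean by more than 3 SD
(`exclusion.normative`, `exclusion.k_sd`); such values indicate
measurement artifacts. The screen is off unless normative values are
supplied, since they come from a separate normative sample.

## LA variability index

Per trial: LA = upper − lower displacement (mm); cubic-spline
(not-a-knot) time normalization onto 1000 points spanning [0, 1]
inclusive; z-scoring with the **population** SD. Across trials: sample
SD (n − 1) at 50 grid points — every 20th sample of the 1000-point axis,
ending at the last (relative times ≈0.02…1.00) — summed. The
denominators and the grid are fixed so that an independent brute-force
implementation agrees bit for bit; both are configurable (`sti.*`),
including a 51-point variant that adds relative time 0. The grid
excludes time 0 by default because endpoint-anchored synthetic
ensembles can be degenerate there; the two variants differ negligibly
on realistic data.

Consequences used as sharp tests: identical trials give index 0; a
per-trial positive affine amplitude transform changes nothing (z-scoring
removes it); uniform time dilation changes nothing (time normalization
removes it — exactly so for shapes polynomial of degree ≤3 in relative
time, where the not-a-knot spline is exact; generic re-sampled shapes
agree to interpolation error, O((1/n)^4)); timing jitter between
gestures is precisely what the index detects.

## The simulator

A sentence is five opening/closing lower-lip cycles. Each movement is a
minimum-jerk profile x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵), chosen for analytic
tractability (peak speed exactly 15D/8T at midcycle), not physiological
realism; the shape is pluggable. The default template (opening extents
7.5/9.0/7.0/6.5/7.0 mm, opening 0.15 s, closing 0.12 s at 95% of the
opening extent, 0.05 s gaps) produces first-to-fifth-peak spans of
~1.2 s, extents 6–10 mm and peak speeds ~75–190 mm/s — the ranges
typical of preschool speakers in these tasks. The upper lip
counter-moves at gain 0.3, so the aperture is lower-lip dominated.

Variability knobs and what they isolate: `amplitude_cv` (one gain per
trial on all extents — effort scaling, removed by amplitude
normalization), `timing_jitter_sd` (per-gesture onset jitter, durations
intact — phase variability, the LA index's target), `tempo_cv` (one time
scaling per trial — rate variability, removed by time normalization),
`noise_sd` (white sensor noise per sample, as broadband optical-tracker
error; the analysis filter attenuates it). Jitter that would overlap
gestures is resampled up to 10 times, then errors; trial-set generation
attempts n+2 realisations, mirroring the over-collection of recording
protocols. All randomness derives from one root seed through spawned
`SeedSequence` streams per cell/participant/trial.

The default cohort design emulates the 2×2 study structure: cells of
43/14/27/13 participants (stutter×sex), per-cell mean gesture scales
calibrated against the template's measured dynamic range so programmed
cell means sit at 8.3/9.4/10.0/8.6 mm with between-participant SD
2.45 mm, and slightly larger timing jitter (25 vs 20 ms) for the
stuttering-male cell to emulate its elevated coordination variability.

What the simulator does **not** emulate: disfluencies and their
perceptual screening, articulatory undershoot/coarticulation structure,
non-rigid facial tissue, marker dropout patterns, or acoustic coupling.
Passing tests therefore validate the measurement and statistics chain on
data with the assumed structure, not the perceptual trial-selection step
of real protocols.

## Group statistics

Levene's test (centre = mean) screens variance homogeneity per ANOVA.
The mixed-design ANOVA treats between effects by Type III
(sum-to-zero coding, unweighted means) on per-subject means — the
standard choice for unbalanced factorial cells — and each within effect
by per-subject contrast scores regressed on the between design (the
univariate split-plot decomposition). All repeated factors here have two
levels, so each contrast is a single score and sphericity is moot.
Subjects with incomplete within cells are excluded listwise and
reported. Post hocs are Tukey–Kramer: studentized-range p-values with
SE = √(MSE/2·(1/nᵢ + 1/nⱼ)); for two equal-sized groups this reduces
exactly to the two-sample t-test. Pearson correlations use pairwise
deletion; a constant column yields an undefined (missing) r. α = 0.05
throughout, with no correction beyond Tukey.

Calibration (in the test suite): interaction type-I error within
[0.03, 0.07] over 2000 null replicates at the study's unbalanced cell
sizes; Levene likewise; Tukey two-group equivalence to 1e-6.

## Problem sizes and determinism

The validation suite uses 200 utterances for segmentation recovery, 50
seeds × 4 jitter levels for the LA dose–response, 2000 null replicates
for calibration, and 200 study-sized cohort replicates for effect
recovery — sizes chosen to give binomial standard errors of 1–3% on the
rates being checked. Fixed inputs, configuration and seed give
byte-identical output tables.

## Known limitations

- Power at the emulated effect size: with cell means 8.3/9.4/10.0/8.6,
  SD 2.45 and cells 43/14/27/13, the interaction contrast has
  noncentrality ≈2.2, i.e. two-sided power ≈0.6 at α = 0.05. Replicate
  detection rates of simulated cohorts at exactly these conditions hover
  near 60%, as the arithmetic requires; this is a property of the design,
  not of the implementation.
- The smoothing applied by any given laboratory is rarely reported;
  absolute velocity-derived values depend on the cutoff, so dependent
  variables are validated against simulation ground truth, not against
  published group tables.
- The unweighted-means within-effect F differs from weighted
  (classic RM-ANOVA) software under unequal group sizes; between and
  interaction effects agree exactly, and all effects agree on balanced
  designs (verified against an independent package in the tests).
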