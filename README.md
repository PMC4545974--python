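# speechkin

Articulatory speech-kinematics analysis for repeated sentence-production
tasks: utterance segmentation from lip velocity, single-movement and
phrase-level kinematic measures, the lip-aperture (LA) coordination
variability index, and the group statistics used to compare speaker
groups — plus a gestural simulator that generates whole cohorts with
known ground truth so every stage can be validated.

## Who this is for

Speech-motor-control researchers working with optically tracked lip
markers (e.g. infrared-diode systems sampled at 250 Hz) in paradigms
where a participant repeats a sentence such as *"Buy Bobby a puppy"*
7–10 times, and group contrasts (for example children who stutter vs.
fluent peers, crossed with sex) are evaluated on per-participant averaged
kinematics.

## The measures

For each fluent repetition, the lower-lip velocity trace defines the
utterance: the segment runs from the **first** to the **fifth negative
opening velocity peak** (superior is +z, so oral opening has negative
lower-lip velocity). From the segmented traces the pipeline computes:

- **Single movements** — for target syllables (default *Bob* = cycle 2,
  *pup* = cycle 4), opening and closing amplitude |Δx| (mm), peak
  velocity max|v| (mm/s), and duration (s), delimited by velocity
  zero-crossings.
- **Dynamic ranges** — the central 80% span of displacement and of
  velocity samples over the whole utterance (10th–90th percentile span):
  the articulator's operating range.
- **Sentence duration** — the time between the first and fifth opening
  peaks of the non-normalized trace.
- **LA variability index** — per trial, LA(t) = upper-lip(t) −
  lower-lip(t); each LA trajectory is time-normalized onto 1000 points
  with a cubic spline and z-scored; the standard deviation across trials
  is evaluated at 2% increments of relative time (50 points) and summed:

  LA index = Σ_{k=1}^{50} SD_trials[ LA_norm(0.02 k) ]

  Higher values mean less consistent interarticulator coordination.

Group comparisons use Levene's variance check, mixed-design ANOVA
(Type III / unweighted means for the unbalanced 2×2 between design, with
two-level repeated factors), and Tukey–Kramer post hocs for unequal
group sizes.

## Worked example

Simulate one participant (10 repetitions, realistic trial-to-trial
variability) and analyse them:

```python
from speechkin import synthetic as syn
from speechkin.pipeline import run_participant

var = syn.VariabilityModel(amplitude_cv=0.10, timing_jitter_sd=0.020,
                           tempo_cv=0.03, noise_sd=0.05)
trials = syn.generate_participant(syn.default_score(), var, n_trials=10,
                                  seed=7, participant_id="demo")
record, qc = run_participant([t.recording for t in trials])
for k, v in record.to_row().items():
    print(k, round(v, 3) if isinstance(v, float) else v)
```

prints

```
participant_id demo
sentence_id BBAP
n_trials 10
displacement_dynamic_range_mm 7.089
velocity_dynamic_range_mm_s 163.689
sentence_duration_s 1.304
la_index 12.84
excluded False
exclusion_reason None
Bob_opening_amplitude_mm 9.352
Bob_opening_peak_velocity_mm_s 107.425
Bob_opening_duration_s 0.162
...
```

The sentence lasts ~1.3 s, the lower lip operates over ~7 mm and
~164 mm/s, the larger-opening syllable *Bob* shows a ~9.4 mm opening at
~107 mm/s, and an LA index of 12.8 quantifies the coordination
variability injected by the 20 ms timing jitter (identical repetitions
would give exactly 0).

The same workflow is available from the shell:

```sh
speechkin simulate --out data/ --seed 7
speechkin analyze-cohort --data data/ --out results/
```

which writes per-participant records, a per-cell group summary, Levene /
ANOVA / post-hoc tables, QC, and the resolved configuration.

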