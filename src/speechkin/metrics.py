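"""Single-movement and phrase-level kinematic measures.

Single movements are characterised by displacement amplitude (mm), peak
velocity magnitude (mm/s) and duration (s). Whole utterances are
characterised by the displacement and velocity *dynamic ranges* — the span
containing the central 80% of sample values across the trajectory, i.e.
the articulator's operating range — and by the sentence duration. Per-trial
values are averaged arithmetically per participant.

Duration convention: a span of n frames lasts (n - 1) / sample_rate
seconds (time between the first and last frame). Percentiles use linear
interpolation. The velocity dynamic range is computed on signed velocity
samples so opening and closing extremes both contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .errors import ComputationError, InputError
from .preprocess import Trajectory, VelocityTrace
from .segmentation import MovementCycle, TrialSet, UtteranceSegment

__all__ = [
    "MovementParameters",
    "KinematicRecord",
    "movement_parameters",
    "dynamic_range",
    "sentence_duration",
    "summarize_participant",
]


@dataclass(frozen=True)
class MovementParameters:
    """Amplitude / peak velocity / duration for one movement."""

    amplitude: float  # mm, >= 0
    peak_velocity: float  # mm/s magnitude, >= 0
    duration: float  # s, > 0
    direction: str
    syllable_label: str | None = None


@dataclass
class KinematicRecord:
    """One participant's averaged dependent variables for one sentence."""

    participant_id: str
    sentence_id: str
    n_trials: int
    displacement_dynamic_range: float | None = None  # mm
    velocity_dynamic_range: float | None = None  # mm/s
    sentence_duration: float | None = None  # s
    movement_means: dict[tuple[str, str], MovementParameters] = field(default_factory=dict)
    la_index: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    def to_row(self) -> dict:
        """Flatten to one results-table row."""
        row: dict = {
            "participant_id": self.participant_id,
            "sentence_id": self.sentence_id,
            "n_trials": self.n_trials,
            "displacement_dynamic_range_mm": self.displacement_dynamic_range,
            "velocity_dynamic_range_mm_s": self.velocity_dynamic_range,
            "sentence_duration_s": self.sentence_duration,
            "la_index": self.la_index,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }
        for (syllable, direction), mp in sorted(self.movement_means.items()):
            stem = f"{syllable}_{direction}"
            row[f"{stem}_amplitude_mm"] = mp.amplitude
            row[f"{stem}_peak_velocity_mm_s"] = mp.peak_velocity
            row[f"{stem}_duration_s"] = mp.duration
        return row


def movement_parameters(
    cycle: MovementCycle, displ: Trajectory, vel: VelocityTrace
) -> MovementParameters:
    """Kinematic parameters of one opening or closing movement.

    amplitude = |displacement(offset) - displacement(onset)|;
    peak velocity = max |velocity| within the cycle;
    duration = (offset - onset) / sample_rate.
    """
    a, b = cycle.onset_index, cycle.offset_index
    if not 0 <= a < b < displ.n_frames:
        raise ComputationError("cycle indices invalid for the traces")
    x = displ.samples
    v = vel.samples
    return MovementParameters(
        amplitude=float(abs(x[b] - x[a])),
        peak_velocity=float(np.max(np.abs(v[a : b + 1]))),
        duration=(b - a) / displ.sample_rate,
        direction=cycle.direction,
        syllable_label=cycle.syllable_label,
    )


def dynamic_range(samples: np.ndarray, coverage: float = 0.8) -> float:
    """Central-coverage span of a sample distribution.

    With the default coverage of 0.8 this is the 10th-to-90th percentile
    span (linear-interpolation percentiles): the range containing the
    central 80% of sample values.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ComputationError("dynamic range needs >= 10 samples")
    if not 0 < coverage < 1:
        raise InputError("coverage must be in (0, 1)")
    lo = 50.0 - coverage * 50.0
    hi = 50.0 + coverage * 50.0
    p_lo, p_hi = np.percentile(samples, [lo, hi])
    return float(p_hi - p_lo)


def sentence_duration(seg: UtteranceSegment) -> float:
    """Seconds spanned by one segmented repetition (first to fifth peak)."""
    return (seg.end_index - seg.start_index) / seg.sample_rate


def summarize_participant(
    trials: TrialSet,
    cycles_per_trial: list[list[MovementCycle]] | None = None,
    *,
    la_index: float | None = None,
    coverage: float = 0.8,
    min_trials: int = 7,
    normative: dict[str, tuple[float, float]] | None = None,
    k_sd: float = 3.0,
) -> KinematicRecord:
    """Average per-trial measures into one :class:`KinematicRecord`.

    ``normative`` optionally maps a phrase measure name
    (``displacement_dynamic_range`` / ``velocity_dynamic_range``) to a
    (mean, sd) pair from an external normative sample; a participant whose
    averaged measure exceeds mean + ``k_sd``·sd is flagged excluded —
    such values indicate a measurement artifact rather than speech.
    """
    n = trials.n_trials
    if n < min_trials:
        raise ComputationError(
            f"participant {trials.participant_id}: {n} trials < minimum {min_trials}"
        )
    ddr, vdr, dur = [], [], []
    for seg in trials.segments:
        ddr.append(dynamic_range(seg.displacement["lower_lip"].samples, coverage))
        vdr.append(dynamic_range(seg.velocity.samples, coverage))
        dur.append(sentence_duration(seg))

    movement_means: dict[tuple[str, str], MovementParameters] = {}
    if cycles_per_trial is not None:
        if len(cycles_per_trial) != n:
            raise InputError("cycles_per_trial length must match trial count")
        acc: dict[tuple[str, str], list[MovementParameters]] = {}
        for seg, cycles in zip(trials.segments, cycles_per_trial):
            for cyc in cycles:
                mp = movement_parameters(cyc, seg.displacement["lower_lip"], seg.velocity)
                acc.setdefault((cyc.syllable_label or "", cyc.direction), []).append(mp)
        for key, mps in acc.items():
            movement_means[key] = MovementParameters(
                amplitude=fmean(m.amplitude for m in mps),
                peak_velocity=fmean(m.peak_velocity for m in mps),
                duration=fmean(m.duration for m in mps),
                direction=key[1],
                syllable_label=key[0],
            )

    rec = KinematicRecord(
        participant_id=trials.participant_id,
        sentence_id=trials.sentence_id,
        n_trials=n,
        displacement_dynamic_range=fmean(ddr),
        velocity_dynamic_range=fmean(vdr),
        sentence_duration=fmean(dur),
        movement_means=movement_means,
        la_index=la_index,
    )
    if normative:
        for measure, (mean, sd) in normative.items():
            value = getattr(rec, measure, None)
            if value is not None and value > mean + k_sd * sd:
                rec.excluded = True
                rec.exclusion_reason = (
                    f"{measure} {value:.3g} exceeds normative {mean:.3g} + "
                    f"{k_sd:g} SD ({sd:.3g})"
                )
    return rec
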