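"""Utterance segmentation from lower-lip velocity.

A five-syllable sentence like "Buy Bobby a puppy" produces five oral
opening/closing cycles. With superior as +z, oral opening moves the lower
lip downward, so each opening movement shows up as a *negative* peak in
lower-lip velocity. Each repetition is cut between the first and the fifth
negative opening velocity peak; the lower-lip velocity defines the cut and
the upper-lip trajectory is cut at the identical frames.

Single opening and closing movements for target syllables are delimited by
the velocity zero-crossings flanking the corresponding opening peak — the
conventional kinematic landmarks for movement onset and offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ExtractionError, InputError, SegmentationError
from .preprocess import Trajectory, VelocityTrace

__all__ = [
    "UtteranceSegment",
    "MovementCycle",
    "TrialSet",
    "find_opening_peaks",
    "segment_utterance",
    "extract_movement_cycles",
]


@dataclass(frozen=True)
class MovementCycle:
    """One opening or closing movement within a segmented utterance.

    Indices are frames into the segment's traces; ``onset < peak < offset``.
    """

    direction: str  # "opening" | "closing"
    onset_index: int
    offset_index: int
    peak_velocity_index: int
    syllable_label: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("opening", "closing"):
            raise InputError(f"bad direction {self.direction!r}")
        if not self.onset_index < self.peak_velocity_index < self.offset_index:
            raise InputError("cycle indices must satisfy onset < peak < offset")


@dataclass
class UtteranceSegment:
    """One fluent repetition cut between the first and fifth opening peak.

    ``displacement`` maps articulator name to its cut trajectory; the cut
    indices are identical for every articulator. ``opening_peak_indices``
    are within-segment frames of the five opening velocity peaks; the first
    is 0 and the last is the final frame.
    """

    displacement: dict[str, Trajectory]
    velocity: VelocityTrace
    start_index: int
    end_index: int
    opening_peak_indices: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.opening_peak_indices, dtype=int)
        self.opening_peak_indices = peaks
        if peaks.size < 2 or np.any(np.diff(peaks) <= 0):
            raise InputError("opening peaks must be >= 2 strictly increasing indices")
        if peaks[0] != 0 or peaks[-1] != self.velocity.n_frames - 1:
            raise InputError("segment must start and end at opening peaks")
        v = self.velocity.samples
        if np.any(v[peaks] >= 0):
            raise InputError("velocity at opening peaks must be negative")

    @property
    def sample_rate(self) -> float:
        return self.velocity.sample_rate

    @property
    def n_frames(self) -> int:
        return self.velocity.n_frames


@dataclass
class TrialSet:
    """All fluent repetitions of one sentence for one participant."""

    participant_id: str
    sentence_id: str
    segments: list[UtteranceSegment] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.segments)


def find_opening_peaks(vel: VelocityTrace, prominence_frac: float = 0.10) -> np.ndarray:
    """Locate negative opening velocity peaks in temporal order.

    A frame qualifies if it is a local minimum of velocity and its depth
    below zero exceeds ``prominence_frac * max(|velocity|)``. Flat or empty
    signals yield an empty array (the caller decides whether that is an
    error).
    """
    if not 0 < prominence_frac < 1:
        raise InputError("prominence_frac must be in (0, 1)")
    v = np.asarray(vel.samples, dtype=float)
    vmax = np.max(np.abs(v)) if v.size else 0.0
    if vmax == 0.0:
        return np.array([], dtype=int)
    thr = prominence_frac * vmax
    peaks, _ = find_peaks(-v, height=thr)
    # boundary samples count as peaks too (a cut segment starts and ends
    # exactly at opening peaks, so segmentation stays idempotent)
    out = list(peaks)
    if v.size >= 2 and v[0] < -thr and v[0] < v[1]:
        out.insert(0, 0)
    if v.size >= 2 and v[-1] < -thr and v[-1] < v[-2]:
        out.append(v.size - 1)
    return np.array(sorted(out), dtype=int)


def segment_utterance(
    displ: dict[str, Trajectory],
    vel: VelocityTrace,
    first: int = 1,
    last: int = 5,
    prominence_frac: float = 0.10,
) -> UtteranceSegment:
    """Cut one repetition between the ``first`` and ``last`` opening peaks.

    All articulator trajectories and the velocity trace are cut to the
    inclusive frame span ``[peak_first, peak_last]``; the lower-lip
    velocity defines the cut for every articulator.

    If more than ``last`` candidate peaks qualify, the ``last`` deepest
    ones are selected (they are then required to be in temporal order by
    construction); fewer than ``last`` is a segmentation error.
    """
    if not 1 <= first < last:
        raise InputError("need 1 <= first < last")
    for name, traj in displ.items():
        if traj.n_frames != vel.n_frames:
            raise InputError(f"trajectory {name!r} length differs from velocity")
    peaks = find_opening_peaks(vel, prominence_frac)
    if peaks.size < last:
        raise SegmentationError(
            f"found {peaks.size} opening peaks, need >= {last}"
        )
    if peaks.size > last:
        depth = -vel.samples[peaks]
        keep = np.sort(np.argsort(depth)[-last:])
        peaks = peaks[keep]
    sel = peaks[first - 1 : last]
    start, end = int(sel[0]), int(sel[-1])
    cut_displ = {
        name: Trajectory(
            samples=traj.samples[start : end + 1],
            sample_rate=traj.sample_rate,
            label=traj.label,
        )
        for name, traj in displ.items()
    }
    cut_vel = VelocityTrace(
        samples=vel.samples[start : end + 1],
        sample_rate=vel.sample_rate,
        label=vel.label,
    )
    return UtteranceSegment(
        displacement=cut_displ,
        velocity=cut_vel,
        start_index=start,
        end_index=end,
        opening_peak_indices=sel - start,
    )


def _scan_backward_nonneg(v: np.ndarray, start: int) -> int:
    """Last index at or before ``start`` where velocity is >= 0."""
    i = start
    while i >= 0 and v[i] < 0:
        i -= 1
    if i < 0:
        raise ExtractionError("no zero-crossing before the opening peak")
    return i


def _scan_forward(v: np.ndarray, start: int, condition) -> int:
    i = start
    n = v.size
    while i < n and not condition(v[i]):
        i += 1
    if i >= n:
        raise ExtractionError("no zero-crossing before the segment edge")
    return i


def extract_movement_cycles(
    seg: UtteranceSegment, cycle_map: dict[str, int]
) -> list[MovementCycle]:
    """Delimit opening and closing movements for the requested cycles.

    ``cycle_map`` maps a syllable label to a 1-based opening-cycle ordinal
    (within the five opening peaks of the segment). For each requested
    cycle the opening movement runs from the velocity zero-crossing
    preceding its opening peak to the crossing following it, and the
    closing movement from that crossing to the next; each yields one
    :class:`MovementCycle`.
    """
    n_peaks = seg.opening_peak_indices.size
    v = seg.velocity.samples
    out: list[MovementCycle] = []
    for syllable, ordinal in cycle_map.items():
        if not 1 <= ordinal <= n_peaks:
            raise ExtractionError(
                f"cycle {ordinal} for {syllable!r} outside 1..{n_peaks}"
            )
        peak = int(seg.opening_peak_indices[ordinal - 1])
        onset = _scan_backward_nonneg(v, peak)
        open_off = _scan_forward(v, peak, lambda x: x >= 0)
        out.append(
            MovementCycle(
                direction="opening",
                onset_index=onset,
                offset_index=open_off,
                peak_velocity_index=onset + int(np.argmin(v[onset : open_off + 1])),
                syllable_label=syllable,
            )
        )
        close_peak = _scan_forward(v, open_off, lambda x: x > 0)
        close_peak = close_peak + int(
            np.argmax(
                v[close_peak : _first_nonpos(v, close_peak)]
            )
        )
        close_off = _scan_forward(v, close_peak, lambda x: x <= 0)
        out.append(
            MovementCycle(
                direction="closing",
                onset_index=open_off,
                offset_index=close_off,
                peak_velocity_index=close_peak,
                syllable_label=syllable,
            )
        )
    return out


def _first_nonpos(v: np.ndarray, start: int) -> int:
    """Index of the first non-positive sample at/after ``start`` (exclusive bound)."""
    rel = np.flatnonzero(v[start:] <= 0)
    return start + int(rel[0]) if rel.size else v.size
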