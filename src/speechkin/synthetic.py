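"""Gestural simulator: articulatory trajectory ensembles with known ground truth.

A sentence like "Buy Bobby a puppy" is modelled as five opening/closing
lower-lip cycles. Each movement is a minimum-jerk displacement profile
x(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5), chosen for analytic
tractability: its endpoints have zero velocity and its peak speed is
exactly 15 D / (8 T) at the movement midpoint. The upper lip is modelled
as a scaled counter-movement (a fraction of the lower-lip deviation with
opposite sign), so the lip-aperture signal is dominated by the lower lip.

Trial-to-trial variability decomposes into four independent knobs:

* ``amplitude_cv`` — one multiplicative gain per trial applied to every
  gesture extent (a global effort scaling; removed by amplitude
  normalization, so it does not move the LA variability index);
* ``timing_jitter_sd`` — per-gesture onset jitter in seconds, durations
  intact (phase variability; the main driver of the LA index);
* ``tempo_cv`` — one multiplicative time scaling per trial applied to all
  durations and gaps (rate variability; removed by time normalization);
* ``noise_sd`` — additive broadband sensor noise in mm on the lip
  channels (tracker noise; the analysis low-pass removes most of it).

All randomness flows from a root seed through ``numpy.random.SeedSequence``
spawned per participant and per trial.

Default gesture parameters produce utterances of roughly 1.2 s between the
first and fifth opening peaks, lower-lip extents of 6-10 mm and peak
speeds of roughly 75-190 mm/s — the range typical of preschool speakers
producing these sentences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import GenerationError, InputError
from .io import MarkerRecording, ParticipantMeta

__all__ = [
    "GestureCycle",
    "GestureScore",
    "VariabilityModel",
    "HeadMotion",
    "TrialTruth",
    "SimulatedTrial",
    "CellParams",
    "CohortDesign",
    "CohortData",
    "min_jerk_segment",
    "default_score",
    "template_dynamic_range",
    "generate_trial",
    "generate_participant",
    "generate_cohort",
    "default_cohort_design",
]

_HEAD_MARKERS_MM = np.array(
    [
        [0.0, 80.0, 60.0],
        [30.0, 70.0, 90.0],
        [-30.0, 70.0, 90.0],
        [0.0, 60.0, 110.0],
    ]
)
_UPPER_LIP_REST = np.array([0.0, 0.0, 8.0])
_LOWER_LIP_REST = np.array([0.0, 0.0, -7.0])


def _min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_segment(extent: float, duration: float, sample_rate: float) -> np.ndarray:
    """Sampled minimum-jerk movement from 0 to ``extent`` over ``duration``.

    Returns ``round(duration * sample_rate) + 1`` samples including both
    endpoints; velocity is zero at both ends and peaks at
    ``15 * extent / (8 * duration)`` at the midpoint.
    """
    if extent <= 0 or duration <= 0 or sample_rate <= 0:
        raise InputError("extent, duration and sample_rate must be positive")
    n = int(round(duration * sample_rate))
    tau = np.linspace(0.0, 1.0, n + 1)
    return extent * _min_jerk_profile(tau)


@dataclass(frozen=True)
class GestureCycle:
    """One opening/closing cycle: extents in mm, durations in s."""

    opening_extent: float
    opening_duration: float
    closing_extent: float
    closing_duration: float
    inter_cycle_gap: float = 0.05

    def __post_init__(self) -> None:
        if min(self.opening_extent, self.closing_extent) <= 0:
            raise InputError("gesture extents must be positive")
        if min(self.opening_duration, self.closing_duration) <= 0:
            raise InputError("gesture durations must be positive")
        if self.inter_cycle_gap < 0:
            raise InputError("inter_cycle_gap must be >= 0")


@dataclass(frozen=True)
class GestureScore:
    """Deterministic trial template: five cycles plus lip-coupling gain."""

    cycles: tuple[GestureCycle, ...]
    upper_lip_gain: float = 0.3
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.cycles) < 1:
            raise InputError("score needs at least one cycle")

    def scaled(self, amplitude: float = 1.0, tempo: float = 1.0) -> "GestureScore":
        """Scale every extent by ``amplitude`` and every time by ``tempo``."""
        cycles = tuple(
            GestureCycle(
                opening_extent=c.opening_extent * amplitude,
                opening_duration=c.opening_duration * tempo,
                closing_extent=c.closing_extent * amplitude,
                closing_duration=c.closing_duration * tempo,
                inter_cycle_gap=c.inter_cycle_gap * tempo,
            )
            for c in self.cycles
        )
        return replace(self, cycles=cycles)


def default_score() -> GestureScore:
    """Five-cycle template for a "Buy Bobby a puppy"-like sentence.

    Cycle 2 ("Bob") carries the largest oral opening, cycle 4 ("pup") the
    smallest; closing extents are 5% smaller than openings, giving a
    slight progressive lowering over the utterance. First-to-fifth peak
    span is about 1.2 s.
    """
    opens = [7.5, 9.0, 7.0, 6.5, 7.0]
    return GestureScore(
        cycles=tuple(
            GestureCycle(
                opening_extent=d,
                opening_duration=0.15,
                closing_extent=0.95 * d,
                closing_duration=0.12,
                inter_cycle_gap=0.05,
            )
            for d in opens
        )
    )


@dataclass(frozen=True)
class VariabilityModel:
    """Trial-to-trial variability parameters (all non-negative)."""

    amplitude_cv: float = 0.0
    timing_jitter_sd: float = 0.0  # s
    tempo_cv: float = 0.0
    noise_sd: float = 0.0  # mm

    def __post_init__(self) -> None:
        if min(self.amplitude_cv, self.timing_jitter_sd, self.tempo_cv, self.noise_sd) < 0:
            raise InputError("variability parameters must be >= 0")


@dataclass(frozen=True)
class HeadMotion:
    """Programmed rigid head motion composited onto all markers.

    Sinusoidal rotation about the x axis (nod) plus sinusoidal translation.
    """

    rotation_amplitude_deg: float = 0.0
    rotation_freq_hz: float = 0.5
    translation_amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_freq_hz: float = 0.4


@dataclass
class TrialTruth:
    """Ground-truth annotations attached to a simulated trial."""

    opening_onsets: np.ndarray  # s, absolute trial time
    opening_offsets: np.ndarray  # = closing onsets
    closing_offsets: np.ndarray
    opening_peak_times: np.ndarray
    opening_peak_velocities: np.ndarray  # mm/s, negative
    opening_extents: np.ndarray  # mm, after per-trial gain
    closing_extents: np.ndarray
    amplitude_gain: float
    tempo_factor: float

    @property
    def peak_span(self) -> float:
        """Seconds between the first and fifth opening velocity peaks."""
        return float(self.opening_peak_times[-1] - self.opening_peak_times[0])


@dataclass
class SimulatedTrial:
    recording: MarkerRecording
    truth: TrialTruth


def _noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """White sensor noise with per-sample SD ``sd`` (mm).

    Optical-tracker error is broadband at 250 Hz; the analysis chain's own
    low-pass filter is what attenuates it, as it would real data.
    """
    if sd == 0:
        return np.zeros(shape)
    return sd * rng.standard_normal(shape)


def generate_trial(
    score: GestureScore,
    var: VariabilityModel,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 250.0,
    lead_in: float = 0.2,
    lead_out: float = 0.2,
    head_motion: HeadMotion | None = None,
    participant_id: str = "sim",
    trial_id: str = "trial",
    max_retries: int = 10,
) -> SimulatedTrial:
    """Realise one trial of a gesture score under a variability model.

    The lower-lip superior-inferior channel is the concatenation of
    jittered minimum-jerk opening (downward) and closing (upward)
    movements around ``score.baseline``; the upper lip counter-moves with
    gain ``score.upper_lip_gain``. Head markers are static unless a
    :class:`HeadMotion` is given, in which case the programmed rigid
    motion is composited onto *all* markers (so head-frame correction can
    be verified end to end). Ground-truth gesture boundaries, peak times
    and closed-form peak velocities are attached as a sidecar.

    Onset jitter that would make consecutive gestures overlap is resampled
    up to ``max_retries`` times, then raises :class:`GenerationError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gain = 1.0
    if var.amplitude_cv > 0:
        gain = max(0.1, 1.0 + var.amplitude_cv * rng.standard_normal())
    tempo = 1.0
    if var.tempo_cv > 0:
        tempo = max(0.5, 1.0 + var.tempo_cv * rng.standard_normal())
    realized = score.scaled(amplitude=gain, tempo=tempo)
    cycles = realized.cycles
    k = len(cycles)

    # nominal onsets, then jittered with overlap rejection
    nominal = np.empty(k)
    t = lead_in
    for i, c in enumerate(cycles):
        nominal[i] = t
        t += c.opening_duration + c.closing_duration + c.inter_cycle_gap
    total = t - cycles[-1].inter_cycle_gap + lead_out

    onsets = nominal.copy()
    if var.timing_jitter_sd > 0:
        for _ in range(max_retries):
            onsets = nominal + var.timing_jitter_sd * rng.standard_normal(k)
            ends = onsets + np.array(
                [c.opening_duration + c.closing_duration for c in cycles]
            )
            if onsets[0] > 0 and np.all(onsets[1:] >= ends[:-1]):
                break
        else:
            raise GenerationError(
                f"timing jitter produced overlapping gestures {max_retries} times"
            )
        total = max(total, ends[-1] + lead_out)

    n_frames = int(round(total * sample_rate)) + 1
    time = np.arange(n_frames) / sample_rate

    lower = np.full(n_frames, realized.baseline)
    level = realized.baseline
    for i, c in enumerate(cycles):
        o0, o1 = onsets[i], onsets[i] + c.opening_duration
        c1 = o1 + c.closing_duration
        m = time >= o0
        lower[m] = level - c.opening_extent * _min_jerk_profile(
            (time[m] - o0) / c.opening_duration
        )
        m = time >= o1
        lower[m] = (level - c.opening_extent) + c.closing_extent * _min_jerk_profile(
            (time[m] - o1) / c.closing_duration
        )
        level += c.closing_extent - c.opening_extent

    deviation = lower - realized.baseline
    upper = -realized.upper_lip_gain * deviation

    lower_xyz = np.tile(_LOWER_LIP_REST, (n_frames, 1))
    lower_xyz[:, 2] = _LOWER_LIP_REST[2] + deviation
    upper_xyz = np.tile(_UPPER_LIP_REST, (n_frames, 1))
    upper_xyz[:, 2] = _UPPER_LIP_REST[2] + upper
    if var.noise_sd > 0:
        lip_noise = _noise(rng, (2, n_frames), var.noise_sd)
        lower_xyz[:, 2] += lip_noise[0]
        upper_xyz[:, 2] += lip_noise[1]

    markers = {"upper_lip": upper_xyz, "lower_lip": lower_xyz}
    for j, pos in enumerate(_HEAD_MARKERS_MM, start=1):
        markers[f"head_{j}"] = np.tile(pos, (n_frames, 1))

    if head_motion is not None:
        theta = np.deg2rad(head_motion.rotation_amplitude_deg) * np.sin(
            2 * np.pi * head_motion.rotation_freq_hz * time
        )
        ct, st = np.cos(theta), np.sin(theta)
        R = np.zeros((n_frames, 3, 3))
        R[:, 0, 0] = 1.0
        R[:, 1, 1], R[:, 1, 2] = ct, -st
        R[:, 2, 1], R[:, 2, 2] = st, ct
        amp = np.asarray(head_motion.translation_amplitude_mm)
        d = amp[None, :] * np.sin(2 * np.pi * head_motion.translation_freq_hz * time)[:, None]
        for name, xyz in markers.items():
            markers[name] = np.einsum("nij,nj->ni", R, xyz) + d

    truth = TrialTruth(
        opening_onsets=onsets,
        opening_offsets=onsets + np.array([c.opening_duration for c in cycles]),
        closing_offsets=onsets
        + np.array([c.opening_duration + c.closing_duration for c in cycles]),
        opening_peak_times=onsets + np.array([c.opening_duration / 2 for c in cycles]),
        opening_peak_velocities=np.array(
            [-15.0 * c.opening_extent / (8.0 * c.opening_duration) for c in cycles]
        ),
        opening_extents=np.array([c.opening_extent for c in cycles]),
        closing_extents=np.array([c.closing_extent for c in cycles]),
        amplitude_gain=gain,
        tempo_factor=tempo,
    )
    rec = MarkerRecording(
        participant_id=participant_id,
        trial_id=trial_id,
        sample_rate=sample_rate,
        markers=markers,
    )
    return SimulatedTrial(recording=rec, truth=truth)


def generate_participant(
    score: GestureScore,
    var: VariabilityModel,
    n_trials: int,
    seed: int | np.random.SeedSequence = 0,
    max_attempts: int | None = None,
    participant_id: str = "sim",
    **trial_kwargs,
) -> list[SimulatedTrial]:
    """Generate ``n_trials`` valid trials for one participant.

    Mirroring the recording protocol — where up to 12 productions were
    collected to obtain at most 10 analysable ones — up to
    ``max_attempts`` (default ``n_trials + 2``) trial realisations are
    attempted; generation failures (jitter overlap) are skipped.
    """
    if max_attempts is None:
        max_attempts = n_trials + 2
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(max_attempts)
    out: list[SimulatedTrial] = []
    for i, child in enumerate(streams):
        if len(out) == n_trials:
            break
        try:
            out.append(
                generate_trial(
                    score,
                    var,
                    seed=np.random.default_rng(child),
                    participant_id=participant_id,
                    trial_id=f"{participant_id}__t{i:02d}",
                    **trial_kwargs,
                )
            )
        except GenerationError:
            continue
    if len(out) < n_trials:
        raise GenerationError(
            f"only {len(out)}/{n_trials} trials could be generated "
            f"in {max_attempts} attempts"
        )
    return out


@dataclass(frozen=True)
class CellParams:
    """Per design-cell generative parameters."""

    n_participants: int
    mean_scale: float  # mean gesture-extent multiplier vs the template
    scale_sd: float  # between-participant SD of the multiplier
    variability: VariabilityModel = field(default_factory=VariabilityModel)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InputError("cell needs >= 1 participant")


@dataclass(frozen=True)
class CohortDesign:
    """A 2 (stutter/control) x 2 (male/female) simulated cohort."""

    cells: dict[tuple[str, str], CellParams]
    n_trials: int = 10
    score: GestureScore = field(default_factory=default_score)
    seed: int = 0

    def __post_init__(self) -> None:
        for key in self.cells:
            group, sex = key
            if group not in ("stutter", "control") or sex not in ("male", "female"):
                raise InputError(f"bad design cell {key!r}")


@dataclass
class CohortData:
    """Simulated cohort: per-participant trials, metadata and ground truth."""

    trials: dict[str, list[SimulatedTrial]]
    metas: list[ParticipantMeta]
    truth: pd.DataFrame  # per-participant programmed parameters


def template_dynamic_range(score: GestureScore | None = None) -> float:
    """Displacement dynamic range (mm) of the noise-free template.

    Measured through the same chain (head correction, filtering,
    segmentation, central-80% range) the analysis applies, so cohort
    designs can be calibrated in the units the analysis reports.
    """
    from .config import RunConfig
    from .metrics import dynamic_range
    from .pipeline import _trial_segment

    trial = generate_trial(score or default_score(), VariabilityModel(), seed=0)
    seg, _ = _trial_segment(trial.recording, RunConfig())
    return dynamic_range(seg.displacement["lower_lip"].samples)


def default_cohort_design(
    seed: int = 0,
    n_trials: int = 10,
    jitter_sd_s: float = 0.020,
    stutter_male_jitter_sd_s: float = 0.025,
    cell_dr_means_mm: dict[tuple[str, str], float] | None = None,
    dr_sd_mm: float = 2.45,
) -> CohortDesign:
    """Cohort emulating the study's group structure.

    Cell sizes follow the analysed sample (43 stuttering boys, 14
    stuttering girls, 27 control boys, 13 control girls). Per-cell mean
    gesture scales are calibrated against the template's measured
    displacement dynamic range so the programmed cell means sit at
    8.3 / 9.4 / 10.0 / 8.6 mm (stuttering boys reduced relative to
    control boys, ratio 0.83) with a between-participant SD of about
    2.45 mm. Stuttering boys also receive slightly larger timing jitter,
    emulating their higher coordination variability.
    """
    if cell_dr_means_mm is None:
        cell_dr_means_mm = {
            ("stutter", "male"): 8.3,
            ("stutter", "female"): 9.4,
            ("control", "male"): 10.0,
            ("control", "female"): 8.6,
        }
    ns = {
        ("stutter", "male"): 43,
        ("stutter", "female"): 14,
        ("control", "male"): 27,
        ("control", "female"): 13,
    }
    template_dr = template_dynamic_range()
    cells = {}
    for key, n in ns.items():
        jit = stutter_male_jitter_sd_s if key == ("stutter", "male") else jitter_sd_s
        cells[key] = CellParams(
            n_participants=n,
            mean_scale=cell_dr_means_mm[key] / template_dr,
            scale_sd=dr_sd_mm / template_dr,
            variability=VariabilityModel(
                amplitude_cv=0.10,
                timing_jitter_sd=jit,
                tempo_cv=0.03,
                noise_sd=0.05,
            ),
        )
    return CohortDesign(cells=cells, n_trials=n_trials, seed=seed)


def generate_cohort(design: CohortDesign, sentence_id: str = "BBAP") -> CohortData:
    """Generate a full cohort with per-cell parameter draws.

    Each participant's gesture scale is drawn from the cell's
    ``Normal(mean_scale, scale_sd)`` (truncated at 0.2); the scaled
    template and the cell's variability model then generate the trials.
    The returned truth table records every participant's programmed scale
    and variability parameters for recovery tests.
    """
    root = np.random.SeedSequence(design.seed)
    trials: dict[str, list[SimulatedTrial]] = {}
    metas: list[ParticipantMeta] = []
    rows = []
    cell_keys = sorted(design.cells)
    streams = root.spawn(len(cell_keys))
    for (key, cell_ss) in zip(cell_keys, streams):
        cell = design.cells[key]
        group, sex = key
        draw_rng = np.random.default_rng(cell_ss)
        p_streams = cell_ss.spawn(cell.n_participants)
        for j, pss in enumerate(p_streams):
            pid = f"{'cws' if group == 'stutter' else 'cwns'}_{sex[0]}_{j:03d}"
            scale = max(0.2, cell.mean_scale + cell.scale_sd * draw_rng.standard_normal())
            score = design.score.scaled(amplitude=scale)
            trials[pid] = generate_participant(
                score,
                cell.variability,
                n_trials=design.n_trials,
                seed=pss,
                participant_id=pid,
            )
            metas.append(ParticipantMeta(participant_id=pid, group=group, sex=sex))
            rows.append(
                {
                    "participant_id": pid,
                    "sentence_id": sentence_id,
                    "group": group,
                    "sex": sex,
                    "true_scale": scale,
                    "timing_jitter_sd": cell.variability.timing_jitter_sd,
                    "amplitude_cv": cell.variability.amplitude_cv,
                    "tempo_cv": cell.variability.tempo_cv,
                    "noise_sd": cell.variability.noise_sd,
                }
            )
    return CohortData(trials=trials, metas=metas, truth=pd.DataFrame(rows))
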