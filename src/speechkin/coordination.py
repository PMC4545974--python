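"""Lip-aperture coordination variability (the LA variability index).

The lip aperture LA(t) = upper-lip(t) - lower-lip(t) is a functional
vocal-tract variable reflecting the combined coordination of upper lip,
lower lip and jaw. Trial-to-trial consistency of the aperture trajectory
is quantified by a spatiotemporal index: each repetition's LA trajectory
is time-normalized onto a 1000-point relative-time axis with a cubic
spline, amplitude-normalized to zero mean and unit standard deviation,
and the standard deviation across repetitions is evaluated at fixed 2%
increments of relative time (50 points) and summed. Higher values mean
less consistent interarticulator coordination.

Conventions (fixed so that an independent brute-force implementation
matches bit for bit): per-trial amplitude normalization uses the
population SD (denominator n); the across-trial SD profile uses the
sample SD (denominator n-1); the 2% grid is every 20th sample of the
1000-point axis ending at the last sample (relative times ~0.02 ... 1.00),
with an optional variant that also includes relative time 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InputError, NormalizationError
from .preprocess import Trajectory
from .segmentation import TrialSet

__all__ = [
    "LAResult",
    "lip_aperture",
    "time_normalize",
    "amplitude_normalize",
    "la_index",
    "la_index_from_apertures",
]


@dataclass
class LAResult:
    """Normalized lip-aperture ensemble and its variability index."""

    normalized_trajectories: np.ndarray  # (n_trials, n_points), z-scored
    sd_profile: np.ndarray  # SD across trials at each grid point
    la_index: float  # sum of sd_profile
    n_trials: int
    grid: np.ndarray  # relative times of the sd_profile


def lip_aperture(upper: Trajectory, lower: Trajectory) -> Trajectory:
    """Sample-by-sample lip aperture: upper-lip minus lower-lip (mm)."""
    if upper.n_frames != lower.n_frames:
        raise InputError("upper/lower lip trajectories differ in length")
    if upper.sample_rate != lower.sample_rate:
        raise InputError("upper/lower lip trajectories differ in sample rate")
    return Trajectory(
        samples=upper.samples - lower.samples,
        sample_rate=upper.sample_rate,
        label="lip_aperture",
    )


def time_normalize(traj: Trajectory | np.ndarray, n_points: int = 1000) -> np.ndarray:
    """Project a trajectory onto ``n_points`` equally spaced relative times.

    A (not-a-knot) cubic spline through the samples is evaluated at
    ``n_points`` points spanning [0, 1] inclusive in relative time, so the
    first and last values are preserved exactly and polynomials of degree
    <= 3 are reproduced to machine precision.
    """
    samples = traj.samples if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if samples.size < 4:
        raise InputError("time normalization needs >= 4 samples (cubic spline)")
    if n_points < 2:
        raise InputError("n_points must be >= 2")
    rel = np.linspace(0.0, 1.0, samples.size)
    out = CubicSpline(rel, samples)(np.linspace(0.0, 1.0, n_points))
    # spline evaluation at the exact knots 0 and 1 is already exact; pin anyway
    out[0], out[-1] = samples[0], samples[-1]
    return out


def amplitude_normalize(series: np.ndarray) -> np.ndarray:
    """Z-score a series: subtract the mean, divide by the population SD."""
    series = np.asarray(series, dtype=float)
    sd = series.std()  # population convention (ddof=0)
    if sd == 0:
        raise NormalizationError("zero-variance trial cannot be amplitude-normalized")
    return (series - series.mean()) / sd


def la_index(
    trials: TrialSet,
    n_points: int = 1000,
    n_grid: int = 50,
    include_start: bool = False,
    sd_ddof: int = 1,
) -> LAResult:
    """LA variability index for a set of repetitions.

    Pipeline per trial: lip_aperture -> time_normalize(``n_points``) ->
    amplitude_normalize. The SD across trials is evaluated at ``n_grid``
    equally spaced relative-time points ending at 1.0 (every
    ``n_points / n_grid``-th sample; 2% increments by default) and summed.

    Requires at least 2 trials; the analysis floor of 7 fluent repetitions
    is enforced upstream by the pipeline.
    """
    if trials.n_trials < 2:
        raise InputError("la_index needs >= 2 trials")
    apertures = [
        lip_aperture(seg.displacement["upper_lip"], seg.displacement["lower_lip"])
        for seg in trials.segments
    ]
    return la_index_from_apertures(
        apertures,
        n_points=n_points,
        n_grid=n_grid,
        include_start=include_start,
        sd_ddof=sd_ddof,
    )


def la_index_from_apertures(
    apertures: list,
    n_points: int = 1000,
    n_grid: int = 50,
    include_start: bool = False,
    sd_ddof: int = 1,
) -> LAResult:
    """LA variability index of an ensemble of aperture trajectories.

    Accepts :class:`~speechkin.preprocess.Trajectory` objects or plain
    sample arrays (trials may have different lengths; time normalization
    puts them on a common relative-time axis).
    """
    if len(apertures) < 2:
        raise InputError("la_index needs >= 2 trials")
    if n_points % n_grid != 0:
        raise InputError("n_points must be a multiple of n_grid")
    ensemble = np.vstack(
        [amplitude_normalize(time_normalize(a, n_points)) for a in apertures]
    )
    step = n_points // n_grid
    idx = np.arange(step - 1, n_points, step)
    if include_start:
        idx = np.concatenate(([0], idx))
    sd_profile = ensemble[:, idx].std(axis=0, ddof=sd_ddof)
    return LAResult(
        normalized_trajectories=ensemble,
        sd_profile=sd_profile,
        la_index=float(sd_profile.sum()),
        n_trials=ensemble.shape[0],
        grid=idx / (n_points - 1),
    )
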