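"""Displacement smoothing and numerical differentiation.

Articulatory displacement signals are low-pass filtered with a zero-phase
Butterworth filter (default 4th order, 10 Hz cutoff — the conventional
choice for orofacial kinematics sampled at 250 Hz, where speech-movement
energy lies well below 10 Hz) and differentiated to velocity with central
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal as _signal

from .errors import InputError, ParameterError


@lru_cache(maxsize=32)
def _butter_sos(order: int, cutoff: float, fs: float) -> np.ndarray:
    return _signal.butter(order, cutoff, btype="low", fs=fs, output="sos")

__all__ = ["Trajectory", "VelocityTrace", "lowpass", "differentiate"]


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled 1-D displacement series in mm.

    Parameters
    ----------
    samples : ndarray
        Displacement in mm, one value per frame.
    sample_rate : float
        Sampling rate in Hz (positive).
    label : str
        Articulator label, e.g. ``"upper_lip"``, ``"lower_lip"`` or
        ``"lip_aperture"``.
    """

    samples: np.ndarray
    sample_rate: float
    label: str = "lower_lip"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("trajectory needs >= 2 samples in a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise InputError("trajectory contains non-finite samples")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span in seconds between the first and last frame."""
        return (self.n_frames - 1) / self.sample_rate

    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


@dataclass(frozen=True)
class VelocityTrace:
    """A velocity series in mm/s aligned frame-by-frame with its source."""

    samples: np.ndarray
    sample_rate: float
    label: str = "lower_lip"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("velocity trace needs >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InputError("velocity trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size


def lowpass(traj: Trajectory, cutoff: float = 10.0, order: int = 4) -> Trajectory:
    """Zero-phase Butterworth low-pass filter of a displacement trajectory.

    The filter is applied forward and backward (``filtfilt``), doubling the
    effective order and cancelling phase delay; DC gain is exactly 1, so
    constant signals pass unchanged. The signal is extended by odd
    reflection at both ends before filtering.

    Parameters
    ----------
    traj : Trajectory
        Input displacement.
    cutoff : float
        Cutoff frequency in Hz; must lie strictly below Nyquist.
    order : int
        Butterworth order of the one-way filter (default 4).
    """
    nyquist = traj.sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff must be in (0, {nyquist}) Hz, got {cutoff}"
        )
    sos = _butter_sos(order, cutoff, traj.sample_rate)
    filtered = _signal.sosfiltfilt(sos, traj.samples)
    return replace(traj, samples=filtered)


def differentiate(traj: Trajectory) -> VelocityTrace:
    """Differentiate displacement to velocity (mm/s).

    Central differences in the interior, one-sided differences at the two
    ends; exact for linear signals. Requires at least 3 samples.
    """
    if traj.n_frames < 3:
        raise InputError("differentiation needs >= 3 samples")
    vel = np.gradient(traj.samples) * traj.sample_rate
    return VelocityTrace(samples=vel, sample_rate=traj.sample_rate, label=traj.label)
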