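"""Reading and writing marker recordings, metadata and results tables.

All formats are plain delimited text (TSV by default; comma accepted) with
a single header row. Trajectory tables carry one row per frame with columns
``time_s`` and ``<marker>_x/_y/_z`` in mm; metadata tables carry one row
per participant. Units are fixed at millimetres and seconds throughout.

Optical trackers occasionally drop a marker for a few frames. Runs of at
most ``max_gap_frames`` consecutive missing samples (20 ms at 250 Hz) are
linearly interpolated and counted; longer runs invalidate the trial, since
they could span a substantial part of a movement cycle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, SamplingError, ValidationError

__all__ = [
    "MarkerRecording",
    "ParticipantMeta",
    "read_marker_file",
    "write_marker_file",
    "read_metadata",
    "write_metadata",
    "write_results_table",
    "read_results_table",
]

MANDATORY_MARKERS = ("upper_lip", "lower_lip")
MIN_HEAD_MARKERS = 3
MISSING_TOKEN = "NA"

GROUP_CODES = {"stutter": "stutter", "cws": "stutter", "control": "control", "cwns": "control"}
SEX_CODES = {"male": "male", "m": "male", "female": "female", "f": "female"}


@dataclass
class MarkerRecording:
    """Raw per-frame 3-D positions (mm) of named markers for one trial.

    ``markers`` maps marker name to an ``(n_frames, 3)`` array. All series
    share the same length and the time axis is implicit and uniform: frame
    ``i`` is at ``i / sample_rate`` seconds.
    """

    participant_id: str
    trial_id: str
    sample_rate: float
    markers: dict[str, np.ndarray]
    gaps_filled: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        lengths = {name: np.asarray(a).shape for name, a in self.markers.items()}
        n_set = {shape[0] for shape in lengths.values()}
        if len(n_set) != 1:
            raise InputError(f"marker series lengths differ: {lengths}")
        n = n_set.pop()
        if n < 2:
            raise InputError("recording needs at least 2 frames")
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InputError(f"marker {name!r} must be (n_frames, 3)")
            self.markers[name] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def head_markers(self) -> list[str]:
        return sorted(m for m in self.markers if m.startswith("head_"))


@dataclass(frozen=True)
class ParticipantMeta:
    """One participant's design-cell metadata."""

    participant_id: str
    group: str  # "stutter" | "control"
    sex: str  # "male" | "female"
    age_months: int | None = None
    therapy_history: bool | None = None
    severity_score: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("stutter", "control"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")


def _sniff_sep(path: Path) -> str:
    head = path.open("r").readline()
    return "," if ("," in head and "\t" not in head) else "\t"


_MARKER_COL = re.compile(r"^(?P<marker>.+)_(?P<axis>[xyz])$")


def _interpolate_gaps(values: np.ndarray, max_gap: int) -> tuple[np.ndarray, int]:
    """Linearly fill NaN runs of length <= max_gap; raise otherwise.

    Returns the filled array and the number of frames filled.
    """
    values = values.copy()
    isnan = ~np.isfinite(values)
    if not isnan.any():
        return values, 0
    # locate runs of NaN
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    n = values.size
    for run in runs:
        if run.size > max_gap:
            raise InputError(
                f"marker dropout of {run.size} consecutive frames exceeds "
                f"the {max_gap}-frame interpolation limit"
            )
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= n:
            raise InputError("marker dropout touches the recording boundary")
        values[run] = np.interp(run, [lo, hi], [values[lo], values[hi]])
    return values, int(idx.size)


def read_marker_file(
    path: str | Path,
    *,
    participant_id: str | None = None,
    trial_id: str | None = None,
    declared_rate: float | None = None,
    rate_tolerance: float = 0.001,
    max_gap_frames: int = 5,
) -> MarkerRecording:
    """Parse a delimited trajectory table into a :class:`MarkerRecording`.

    The table must have a ``time_s`` column plus ``<marker>_x/_y/_z``
    triplets (mm) for at least ``upper_lip``, ``lower_lip`` and three
    ``head_*`` markers. The sample rate is inferred from the median time
    step; every step must agree with the median — and the median with any
    declared rate — within ``rate_tolerance`` (0.1%).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")

    # group marker columns into (marker, axis) triplets
    axes: dict[str, dict[str, str]] = {}
    for col in df.columns:
        m = _MARKER_COL.match(col)
        if m:
            axes.setdefault(m["marker"], {})[m["axis"]] = col
    complete = {name: cols for name, cols in axes.items() if len(cols) == 3}
    for mandatory in MANDATORY_MARKERS:
        if mandatory not in complete:
            raise FormatError(f"{path}: missing {mandatory}_x/_y/_z columns")
    head = [m for m in complete if m.startswith("head_")]
    if len(head) < MIN_HEAD_MARKERS:
        raise FormatError(
            f"{path}: needs >= {MIN_HEAD_MARKERS} head_* markers, found {len(head)}"
        )

    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError(f"{path}: fewer than 2 frames")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise SamplingError(f"{path}: non-increasing time axis")
    if np.any(np.abs(steps - dt) > rate_tolerance * dt):
        raise SamplingError(f"{path}: non-uniform time steps (median {dt:g} s)")
    rate = 1.0 / dt
    if declared_rate is not None and abs(rate - declared_rate) > rate_tolerance * declared_rate:
        raise SamplingError(
            f"{path}: inferred rate {rate:.3f} Hz disagrees with declared "
            f"{declared_rate:g} Hz"
        )

    markers: dict[str, np.ndarray] = {}
    gaps = 0
    for name, cols in complete.items():
        xyz = np.column_stack([df[cols[a]].to_numpy(dtype=float) for a in "xyz"])
        for j in range(3):
            xyz[:, j], filled = _interpolate_gaps(xyz[:, j], max_gap_frames)
            gaps += filled
        markers[name] = xyz

    return MarkerRecording(
        participant_id=participant_id or path.stem.split("__")[0],
        trial_id=trial_id or path.stem,
        sample_rate=rate,
        markers=markers,
        gaps_filled=gaps,
    )


def write_marker_file(rec: MarkerRecording, path: str | Path, sep: str = "\t") -> Path:
    """Write a recording back to the documented trajectory-table format."""
    path = Path(path)
    cols = {"time_s": np.arange(rec.n_frames) / rec.sample_rate}
    for name in sorted(rec.markers):
        for j, axis in enumerate("xyz"):
            cols[f"{name}_{axis}"] = rec.markers[name][:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.6g")
    return path


def read_metadata(path: str | Path) -> list[ParticipantMeta]:
    """Read the participant metadata table (one row per participant)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"participant_id": str})
    for col in ("participant_id", "group", "sex"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    seen: set[str] = set()
    out: list[ParticipantMeta] = []
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        if pid in seen:
            raise ValidationError(f"{path}: duplicate participant_id {pid!r}")
        seen.add(pid)
        group = GROUP_CODES.get(str(row["group"]).strip().lower())
        if group is None:
            raise ValidationError(f"{path}: unknown group code {row['group']!r}")
        sex = SEX_CODES.get(str(row["sex"]).strip().lower())
        if sex is None:
            raise ValidationError(f"{path}: unknown sex code {row['sex']!r}")
        age = row.get("age_months")
        therapy = row.get("therapy_history")
        severity = row.get("severity_score")
        out.append(
            ParticipantMeta(
                participant_id=pid,
                group=group,
                sex=sex,
                age_months=int(age) if pd.notna(age) else None,
                therapy_history=bool(therapy) if pd.notna(therapy) else None,
                severity_score=float(severity) if pd.notna(severity) else None,
            )
        )
    return out


def write_metadata(metas: Sequence[ParticipantMeta], path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in metas],
            "group": [m.group for m in metas],
            "sex": [m.sex for m in metas],
            "age_months": [m.age_months for m in metas],
            "therapy_history": [m.therapy_history for m in metas],
            "severity_score": [m.severity_score for m in metas],
        }
    )
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)
    return path


def write_results_table(records: Sequence, path: str | Path, sep: str = "\t") -> Path:
    """Write per-participant kinematic records as a delimited table.

    One row per participant × sentence; missing measures (e.g. an LA index
    unavailable because too few trials survived) are emitted as ``NA``.
    Values round-trip losslessly at 6 significant digits.
    """
    if not records:
        raise InputError("no records to write")
    path = Path(path)
    rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in records]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN, float_format="%.6g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), na_values=[MISSING_TOKEN], dtype={"participant_id": str})
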