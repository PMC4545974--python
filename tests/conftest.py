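"""Shared fixtures: synthetic recordings, trajectory builders, tiny tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from speechkin import synthetic as syn
from speechkin.config import RunConfig
from speechkin.preprocess import Trajectory, VelocityTrace

SAMPLE_RATE = 250.0


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def score() -> syn.GestureScore:
    return syn.default_score()


@pytest.fixture
def quiet_model() -> syn.VariabilityModel:
    return syn.VariabilityModel()


def make_traj(samples, label="lower_lip", rate=SAMPLE_RATE) -> Trajectory:
    return Trajectory(samples=np.asarray(samples, float), sample_rate=rate, label=label)


def make_vel(samples, label="lower_lip", rate=SAMPLE_RATE) -> VelocityTrace:
    return VelocityTrace(samples=np.asarray(samples, float), sample_rate=rate, label=label)


def write_trial_table(path, n_frames=4, rate=SAMPLE_RATE, drop=None, time_override=None):
    """Write a minimal valid trajectory TSV; optionally drop a column."""
    t = np.arange(n_frames) / rate if time_override is None else np.asarray(time_override)
    cols = {"time_s": t}
    for name in ("upper_lip", "lower_lip", "head_1", "head_2", "head_3"):
        for axis in "xyz":
            cols[f"{name}_{axis}"] = np.linspace(0, 1, len(t)) + hash(name + axis) % 7
    df = pd.DataFrame(cols)
    if drop:
        df = df.drop(columns=[drop])
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def tiny_design() -> syn.CohortDesign:
    """Small 2x2 cohort for pipeline-level tests (2-3 participants/cell)."""
    var = syn.VariabilityModel(
        amplitude_cv=0.08, timing_jitter_sd=0.015, tempo_cv=0.02, noise_sd=0.05
    )
    cells = {
        ("stutter", "male"): syn.CellParams(3, 1.1, 0.15, var),
        ("stutter", "female"): syn.CellParams(2, 1.3, 0.15, var),
        ("control", "male"): syn.CellParams(3, 1.4, 0.15, var),
        ("control", "female"): syn.CellParams(2, 1.2, 0.15, var),
    }
    return syn.CohortDesign(cells=cells, n_trials=7, seed=42)
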