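"""Lip aperture, normalization and the LA variability index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

from speechkin.coordination import (
    amplitude_normalize,
    la_index,
    la_index_from_apertures,
    lip_aperture,
    time_normalize,
)
from speechkin.errors import InputError, NormalizationError

from conftest import make_traj

FS = 250.0


# --- lip aperture ----------------------------------------------------------


def test_identical_lips_give_zero_aperture():
    x = np.sin(np.linspace(0, 5, 100))
    la = lip_aperture(make_traj(x, "upper_lip"), make_traj(x, "lower_lip"))
    assert np.allclose(la.samples, 0)
    assert la.label == "lip_aperture"


def test_aperture_sign_convention():
    """Lower lip moving down (negative z) opens the mouth: LA goes up."""
    t = np.linspace(0, 1, 200)
    lower = -4 * np.sin(2 * np.pi * t)
    la = lip_aperture(make_traj(np.zeros(200), "upper_lip"), make_traj(lower, "lower_lip"))
    assert np.allclose(la.samples, 4 * np.sin(2 * np.pi * t))


def test_aperture_common_mode_rejection():
    rng = np.random.default_rng(0)
    u, l = rng.standard_normal(80), rng.standard_normal(80)
    base = lip_aperture(make_traj(u, "upper_lip"), make_traj(l, "lower_lip"))
    shifted = lip_aperture(
        make_traj(u + 11.3, "upper_lip"), make_traj(l + 11.3, "lower_lip")
    )
    assert np.allclose(base.samples, shifted.samples, atol=1e-12)


def test_aperture_length_mismatch_rejected():
    with pytest.raises(InputError):
        lip_aperture(make_traj(np.zeros(10), "upper_lip"), make_traj(np.zeros(11), "lower_lip"))


# --- time normalization ----------------------------------------------------


def test_time_normalize_exact_on_linear():
    x = np.linspace(2.0, 7.0, 137)
    out = time_normalize(make_traj(x), 1000)
    assert out.shape == (1000,)
    assert np.allclose(out, np.linspace(2.0, 7.0, 1000), atol=1e-9)


def test_time_normalize_preserves_endpoints_at_1000_points():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(300)
    out = time_normalize(make_traj(x), 1000)
    assert out.shape == (1000,)
    assert out[0] == x[0] and out[-1] == x[-1]


def test_time_normalize_sinusoid_close_to_analytic():
    t = np.arange(300) / FS
    f = 4.0
    x = np.sin(2 * np.pi * f * t)
    out = time_normalize(make_traj(x), 1000)
    rel = np.linspace(0, 1, 1000)
    analytic = np.sin(2 * np.pi * f * rel * t[-1])
    assert np.max(np.abs(out - analytic)) < 1e-4


def test_time_normalize_needs_four_samples():
    with pytest.raises(InputError):
        time_normalize(make_traj([1.0, 2.0, 3.0]), 10)


# --- amplitude normalization ------------------------------------------------


def test_amplitude_normalize_hand_computed():
    out = amplitude_normalize(np.array([1.0, 2.0, 3.0]))
    root = np.sqrt(3.0 / 2.0)  # population-SD z-scores of {1,2,3}
    assert np.allclose(out, [-root, 0.0, root], atol=1e-12)


def test_amplitude_normalize_is_definitional():
    rng = np.random.default_rng(2)
    out = amplitude_normalize(rng.standard_normal(500) * 3 + 7)
    assert abs(out.mean()) < 1e-12
    assert abs(out.std() - 1) < 1e-12


def test_amplitude_normalize_affine_invariant():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(100)
    assert np.allclose(amplitude_normalize(3.7 * x + 2.2), amplitude_normalize(x), atol=1e-12)


def test_flat_trial_unanalyzable():
    with pytest.raises(NormalizationError):
        amplitude_normalize(np.full(50, 5.0))


# --- the LA index ----------------------------------------------------------


def _oracle_la_index(apertures, n_points=1000, n_grid=50, include_start=False):
    """Brute-force reimplementation: explicit loops, no shared code paths."""
    import statistics

    normalized = []
    for ap in apertures:
        samples = list(ap)
        rel = [i / (len(samples) - 1) for i in range(len(samples))]
        spline = CubicSpline(rel, samples)
        grid = [j / (n_points - 1) for j in range(n_points)]
        vals = [float(spline(g)) for g in grid]
        vals[0], vals[-1] = samples[0], samples[-1]
        mu = statistics.fmean(vals)
        sd = statistics.pstdev(vals)
        normalized.append([(v - mu) / sd for v in vals])
    step = n_points // n_grid
    idx = list(range(step - 1, n_points, step))
    if include_start:
        idx = [0] + idx
    total = 0.0
    profile = []
    for j in idx:
        col = [trial[j] for trial in normalized]
        s = statistics.stdev(col)  # sample SD across trials
        profile.append(s)
        total += s
    return total, profile


def _random_ensemble(rng, n_trials=5, min_len=20, max_len=60):
    """Smooth random trials: a template plus random time-warp and noise."""
    out = []
    for _ in range(n_trials):
        n = int(rng.integers(min_len, max_len))
        t = np.linspace(0, 1, n)
        warp = t + 0.05 * rng.standard_normal() * np.sin(np.pi * t)
        x = np.sin(2 * np.pi * 2 * warp) + 0.3 * rng.standard_normal() * np.cos(np.pi * t)
        out.append(x)
    return out


def test_la_index_matches_bruteforce_oracle():
    rng = np.random.default_rng(12345)
    for _ in range(25):
        ens = _random_ensemble(rng)
        res = la_index_from_apertures(ens)
        expected, profile = _oracle_la_index(ens)
        assert res.la_index == pytest.approx(expected, abs=1e-9)
        assert np.allclose(res.sd_profile, profile, atol=1e-9)


def test_la_index_zero_for_identical_trials():
    x = np.sin(np.linspace(0, 7, 120))
    res = la_index_from_apertures([x.copy() for _ in range(6)])
    assert res.la_index == pytest.approx(0.0, abs=1e-12)
    assert res.sd_profile.shape == (50,)


def test_la_index_invariant_to_amplitude_affine_transforms():
    rng = np.random.default_rng(4)
    x = np.cumsum(rng.standard_normal(150))
    ens = [c * x + b for c, b in [(1.0, 0.0), (2.5, 3.0), (0.3, -7.0), (10.0, 0.1)]]
    res = la_index_from_apertures(ens)
    assert res.la_index == pytest.approx(0.0, abs=1e-9)


def test_la_index_invariant_to_uniform_time_dilation():
    """Dilation only resamples the shape; on cubic shapes the spline is exact."""
    coeffs = [0.3, -1.2, 2.0, 0.5]  # cubic in relative time

    def cubic(n):
        r = np.linspace(0, 1, n)
        return np.polyval(coeffs, r)

    ens = [cubic(n) for n in (40, 80, 160, 315)]
    res = la_index_from_apertures(ens)
    assert res.la_index == pytest.approx(0.0, abs=1e-9)


def test_la_index_trial_order_invariant():
    rng = np.random.default_rng(5)
    ens = _random_ensemble(rng, n_trials=8)
    a = la_index_from_apertures(ens).la_index
    b = la_index_from_apertures(ens[::-1]).la_index
    assert a == pytest.approx(b, abs=1e-12)


def test_normalized_trajectories_are_z_scored():
    rng = np.random.default_rng(6)
    res = la_index_from_apertures(_random_ensemble(rng))
    assert np.allclose(res.normalized_trajectories.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(res.normalized_trajectories.std(axis=1), 1, atol=1e-9)


def test_include_start_variant_adds_grid_point():
    rng = np.random.default_rng(7)
    ens = _random_ensemble(rng)
    res = la_index_from_apertures(ens, include_start=True)
    assert res.sd_profile.shape == (51,)
    expected, _ = _oracle_la_index(ens, include_start=True)
    assert res.la_index == pytest.approx(expected, abs=1e-9)


def test_la_index_needs_two_trials():
    with pytest.raises(InputError):
        la_index_from_apertures([np.sin(np.linspace(0, 5, 50))])
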