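"""Kinetics: running average, growth rates, kymograph, series tracking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizotrack import (
    SimulationConfig,
    build_kymograph,
    fit_trace,
    growth_rate,
    simulate_root_path,
    smooth_lengths,
    stabilize_series,
    track_series,
)
from rhizotrack.centerline import Centerline
from rhizotrack.simulator import default_tracking_roi

from conftest import make_manifest


# ---------------------------------------------------------------- smoothing

def test_running_average_worked_example():
    out = smooth_lengths(np.array([0.0, 3, 6, 9, 12]), window=3)
    assert out == pytest.approx([1.5, 3, 6, 9, 10.5])


def test_constant_series_unchanged():
    out = smooth_lengths(np.full(10, 7.0), window=5)
    assert out == pytest.approx(np.full(10, 7.0))


def test_window_one_is_identity():
    x = np.array([4.0, 1, 9, 2])
    assert smooth_lengths(x, window=1) == pytest.approx(x)


def test_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        smooth_lengths(np.arange(5.0), window=4)


def test_missing_values_excluded_from_windows():
    x = np.array([1.0, np.nan, 3.0, 5.0, 7.0])
    out = smooth_lengths(x, window=3)
    assert out[1] == pytest.approx(2.0)  # mean of 1 and 3
    assert out[3] == pytest.approx(5.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=30),
    shift=st.floats(min_value=-100, max_value=100),
)
def test_smoothing_is_shift_equivariant(values, shift):
    x = np.asarray(values)
    a = smooth_lengths(x + shift, window=3)
    b = smooth_lengths(x, window=3) + shift
    assert a == pytest.approx(b, abs=1e-6)


def test_smoothing_stays_within_window_range():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 100, size=40)
    out = smooth_lengths(x, window=5)
    assert np.all(out >= x.min()) and np.all(out <= x.max())


# ---------------------------------------------------------------- rates

def test_linear_growth_gives_constant_rate():
    t = np.arange(0, 150, 15.0)
    L = 10 + 2 * t
    assert growth_rate(L, t) == pytest.approx(np.full(10, 2.0))


def test_constant_length_gives_zero_rate():
    t = np.arange(5.0)
    assert growth_rate(np.full(5, 42.0), t) == pytest.approx(np.zeros(5))


def test_rate_requires_two_samples():
    with pytest.raises(ValueError):
        growth_rate(np.array([1.0]), np.array([0.0]))


# ---------------------------------------------------------------- kymograph

def _trace_from_points(pts):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cl = Centerline(points=pts, s=np.concatenate([[0.0], np.cumsum(seg)]))
    return fit_trace(cl)


def test_straight_traces_fill_kymograph_with_r_cap():
    traces = []
    for L in (60, 80, 100):
        pts = np.column_stack([np.arange(0, L, 0.5), np.full(2 * L, 25.0)])
        traces.append(_trace_from_points(pts))
    K, centers = build_kymograph(traces, ds_bin=5.0)
    assert np.all(K[np.isfinite(K)] == 1e4)
    assert centers[0] == 2.5


def test_circle_arc_kymograph_cells_near_true_radius():
    R = 100.0
    config = SimulationConfig(
        image_height=340, image_width=256, base_point=(30.0, 160.0),
        initial_length=math.pi * R / 2, growth_rate=0,
        path_model="circular_arc", arc_radius=R, n_frames=2,
    )
    traces = [_trace_from_points(simulate_root_path(config, i)) for i in range(2)]
    K, _ = build_kymograph(traces, ds_bin=5.0)
    # end bins feel the spline's free-end conditions; check interior cells
    interior = K[:, 2:-2]
    cells = interior[np.isfinite(interior)]
    assert cells == pytest.approx(R, rel=0.05)


def test_growing_root_present_cells_nondecreasing():
    traces = []
    for L in (50, 65, 80, 95):
        pts = np.column_stack([np.arange(0, L, 0.5), np.full(2 * L, 25.0)])
        traces.append(_trace_from_points(pts))
    K, _ = build_kymograph(traces, ds_bin=5.0)
    present = np.isfinite(K).sum(axis=1)
    assert np.all(np.diff(present) >= 0)


def test_kymograph_row_means_invariant_to_sample_order():
    pts = np.column_stack([np.arange(0, 80, 0.5), np.full(160, 25.0)])
    trace = _trace_from_points(pts)
    K1, _ = build_kymograph([trace], ds_bin=5.0)
    perm = np.random.default_rng(0).permutation(len(trace.s))
    import dataclasses
    shuffled = dataclasses.replace(
        trace, s=trace.s[perm], radius=trace.radius[perm],
        points=trace.points[perm], kappa=trace.kappa[perm],
    )
    K2, _ = build_kymograph([shuffled], ds_bin=5.0)
    assert np.allclose(K1, K2, equal_nan=True)


# ---------------------------------------------------------------- tracking

def test_track_series_recovers_lengths_and_rate(noiseless_series, tmp_path):
    config, truth, series_dir = noiseless_series
    manifest = make_manifest(series_dir, "box_001", config.n_frames)
    stab = stabilize_series(manifest, out_dir=tmp_path / "stab", max_shift=10)
    track = track_series(stab, default_tracking_roi(config), out_dir=tmp_path / "trk")
    assert not track.missing.any()
    assert np.all(np.abs(track.lengths - truth.lengths) / truth.lengths < 0.03)
    assert np.all(np.diff(track.lengths) >= -0.5)  # monotone growth (tolerance)
    summary = track.rate_summary()
    true_rate = config.growth_rate / config.frame_interval
    assert summary["mean_px_per_min"] == pytest.approx(true_rate, rel=0.05)
    assert summary["cv"] < 0.05
    assert (tmp_path / "trk" / "growth_track.csv").exists()
    assert (tmp_path / "trk" / "kymograph.csv").exists()
    assert (tmp_path / "trk" / "trace_000000.csv").exists()


def test_blanked_frames_flagged_missing(noiseless_series, tmp_path):
    import imageio.v3 as iio
    import shutil

    config, _, series_dir = noiseless_series
    work = tmp_path / "series"
    shutil.copytree(series_dir, work)
    for i in (4, 9, 14):
        blank = np.full((config.image_height, config.image_width), 166, dtype=np.uint8)
        iio.imwrite(work / f"frame_{i:06d}.png", blank)
    manifest = make_manifest(work, "box_001", config.n_frames)
    track = track_series(manifest, default_tracking_roi(config))
    assert track.missing.sum() == 3
    assert set(np.flatnonzero(track.missing)) == {4, 9, 14}
    good = ~track.missing
    assert np.isfinite(track.lengths[good]).all()


def test_single_frame_series_has_undefined_rates(noiseless_series, tmp_path):
    config, truth, series_dir = noiseless_series
    manifest = make_manifest(series_dir, "box_001", 1)
    track = track_series(manifest, default_tracking_roi(config))
    assert np.isfinite(track.lengths[0])
    assert np.isnan(track.rates).all()


def test_majority_failure_aborts(tmp_path):
    import imageio.v3 as iio

    for i in range(4):
        blank = np.full((128, 128), 166, dtype=np.uint8)
        iio.imwrite(tmp_path / f"frame_{i:06d}.png", blank)
    manifest = make_manifest(tmp_path, "box_x", 4)
    with pytest.raises(RuntimeError, match="failed"):
        track_series(manifest, default_tracking_roi(SimulationConfig()))
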