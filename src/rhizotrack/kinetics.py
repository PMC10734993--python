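"""Per-container growth kinetics: length and rate time series, curvature kymograph.

Per-frame traces are aggregated into a :class:`GrowthTrack`: raw root
lengths, a running-average smoothed length series (smoothing before
differentiation suppresses segmentation jitter in the rates), central
difference growth rates, and a radius-of-curvature kymograph — a
``n_frames x n_arc_bins`` matrix of mean R(s) per arc-length bin from the
base, time down the rows.

Frames whose segmentation or path extraction fails are flagged missing and
excluded from the smoothing windows rather than interpolated, keeping the
output auditable.  Pixels are the canonical unit (time-lapse rigs rarely
report a calibrated scale); an optional ``px_per_mm`` adds converted
columns to the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhizotrack.centerline import (
    BaseHint,
    RootTrace,
    extend_to_tips,
    extract_path,
    fit_trace,
    skeletonize_mask,
)
from rhizotrack.io_sorting import SeriesManifest, read_frame
from rhizotrack.segmentation import RegionOfInterest, binarize, crop_roi

logger = logging.getLogger(__name__)


def smooth_lengths(lengths: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running average of window ``window`` (odd).

    At the boundaries the window is clipped to the available samples, so
    the first value of ``[0, 3, 6, 9, 12]`` at ``window=3`` is
    ``mean(0, 3) = 1.5``.  NaN (missing) values are excluded from the
    windows that overlap them.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    series = pd.Series(np.asarray(lengths, dtype=float))
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    return series.rolling(window, center=True, min_periods=1).mean().to_numpy()


def growth_rate(lengths: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Central-difference derivative dL/dt, one-sided at the series ends.

    ``v[i] = (L[i+1] - L[i-1]) / (t[i+1] - t[i-1])`` for interior samples;
    units follow the inputs (px/min for minutes).
    """
    L = np.asarray(lengths, dtype=float)
    t = np.asarray(times, dtype=float)
    if L.shape != t.shape:
        raise ValueError("length and time series must have equal shape")
    if L.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    v = np.empty_like(L)
    v[0] = (L[1] - L[0]) / (t[1] - t[0])
    v[-1] = (L[-1] - L[-2]) / (t[-1] - t[-2])
    if L.size > 2:
        v[1:-1] = (L[2:] - L[:-2]) / (t[2:] - t[:-2])
    return v


def build_kymograph(
    traces: list[RootTrace | None], ds_bin: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Radius-of-curvature kymograph: mean R(s) per arc-length bin per frame.

    Returns ``(K, bin_centers)`` where ``K[i, b]`` is the mean radius over
    samples with ``s in [b*ds_bin, (b+1)*ds_bin)`` of frame i; cells beyond
    a frame's tip (and rows of missing frames) are NaN.  Row order is time
    order of ``traces``.
    """
    if not traces or all(t is None for t in traces):
        raise ValueError("need at least one trace")
    if ds_bin <= 0:
        raise ValueError("ds_bin must be positive")
    max_bin = 0
    for tr in traces:
        if tr is not None:
            max_bin = max(max_bin, int(tr.s.max() // ds_bin))
    n_bins = max_bin + 1
    K = np.full((len(traces), n_bins), np.nan)
    for i, tr in enumerate(traces):
        if tr is None:
            continue
        idx = np.minimum((tr.s // ds_bin).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        sums = np.bincount(idx, weights=tr.radius, minlength=n_bins)
        present = counts > 0
        K[i, present] = sums[present] / counts[present]
    centers = (np.arange(n_bins) + 0.5) * ds_bin
    return K, centers


@dataclass
class GrowthTrack:
    """Time series of root length, growth rate, and the curvature kymograph."""

    container_id: str
    frame_indices: np.ndarray
    times: np.ndarray                   # minutes
    lengths: np.ndarray                 # raw per-frame length, px (NaN missing)
    lengths_smooth: np.ndarray          # running average, px
    rates: np.ndarray                   # px/min (NaN where undefined)
    missing: np.ndarray                 # bool per frame
    kymograph: np.ndarray               # (n_frames, n_bins) radius px, NaN missing
    bin_centers: np.ndarray             # arc-length bin centers, px
    window: int = 5
    px_per_mm: float | None = None
    traces: list[RootTrace | None] = field(default_factory=list, repr=False)

    def rate_summary(self) -> dict[str, float]:
        """Mean and coefficient of variation of the growth rate, computed
        over frames whose smoothing window and central difference are fully
        supported (boundary estimates use clipped windows and one-sided
        differences and are biased for ramp-like series)."""
        half = self.window // 2
        lo, hi = half + 1, len(self.rates) - half - 1
        valid = np.zeros(len(self.rates), dtype=bool)
        valid[lo:hi] = True
        valid &= ~self.missing & np.isfinite(self.rates)
        v = self.rates[valid]
        if v.size == 0:
            return {"mean_px_per_min": math.nan, "cv": math.nan, "n_frames": 0}
        mean = float(v.mean())
        cv = float(v.std() / abs(mean)) if mean != 0 else math.inf
        return {"mean_px_per_min": mean, "cv": cv, "n_frames": int(v.size)}

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "container_id": self.container_id,
                "frame_index": self.frame_indices,
                "time_min": self.times,
                "length_px": self.lengths,
                "length_smooth_px": self.lengths_smooth,
                "growth_rate_px_per_min": self.rates,
                "missing": self.missing.astype(int),
            }
        )
        if self.px_per_mm:
            df["length_mm"] = df["length_px"] / self.px_per_mm
            df["growth_rate_mm_per_h"] = df["growth_rate_px_per_min"] * 60 / self.px_per_mm
        df.to_csv(path, index=False, float_format="%.6g")

    def kymograph_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.kymograph, columns=[f"{c:g}" for c in self.bin_centers])
        df.insert(0, "time_min", self.times)
        df.to_csv(path, index=False, float_format="%.6g")


def track_series(
    manifest: SeriesManifest,
    roi: RegionOfInterest,
    out_dir: str | Path | None = None,
    polarity: str = "auto",
    min_area: int = 64,
    closing_radius: int = 1,
    base_hint: BaseHint = "top",
    smoothing: float = 1.0,
    ds: float = 1.0,
    r_cap: float = 1e4,
    window: int = 5,
    ds_bin: float = 5.0,
    px_per_mm: float | None = None,
    tip_correction: bool = True,
) -> GrowthTrack:
    """Run crop → binarize → skeletonize → path → spline per frame and
    aggregate the series into a :class:`GrowthTrack`.

    A stabilized series is expected (the manifest produced by
    ``stabilize_series``).  Frames that fail segmentation or path
    extraction are flagged missing; more than half failing aborts with a
    diagnostic.  When ``out_dir`` is given, per-frame ``trace_<i:06d>.csv``
    files plus ``growth_track.csv`` and ``kymograph.csv`` are written.

    After the first successful frame the base endpoint is chosen by
    temporal consistency (nearest the previous frame's base) rather than
    the side hint, so a curling tip cannot flip the orientation.
    """
    n = len(manifest.records)
    if n == 0:
        raise ValueError("empty manifest")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    traces: list[RootTrace | None] = []
    lengths = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    failures: list[tuple[int, str]] = []
    hint: BaseHint = base_hint
    for k, rec in enumerate(manifest.records):
        try:
            frame = read_frame(rec.source_path)
            cropped = crop_roi(frame, roi)
            mask = binarize(cropped, polarity=polarity, min_area=min_area,
                            closing_radius=closing_radius)
            skeleton = skeletonize_mask(mask)
            path = extract_path(skeleton, base_hint=hint)
            if tip_correction:
                path = extend_to_tips(path, mask)
            trace = fit_trace(path, smoothing=smoothing, ds=ds, r_cap=r_cap)
        except (ValueError, FileNotFoundError) as exc:
            traces.append(None)
            missing[k] = True
            failures.append((rec.frame_index, str(exc)))
            logger.warning("frame %d failed: %s", rec.frame_index, exc)
            continue
        hint = tuple(path.points[0])
        traces.append(trace)
        lengths[k] = trace.length
        if out is not None:
            trace.to_csv(out / f"trace_{rec.frame_index:06d}.csv")

    if missing.sum() > n / 2:
        detail = ", ".join(f"{i}: {msg}" for i, msg in failures[:10])
        raise RuntimeError(
            f"{missing.sum()}/{n} frames failed tracking; first failures: {detail}"
        )

    times = np.array([r.time_min for r in manifest.records], dtype=float)
    lengths_smooth = smooth_lengths(lengths, min(window, n if n % 2 else n - 1))
    try:
        rates = growth_rate(lengths_smooth, times)
    except ValueError:
        rates = np.full(n, np.nan)   # single-frame series: rates undefined
    K, centers = build_kymograph(traces, ds_bin=ds_bin)
    track = GrowthTrack(
        container_id=manifest.container_id,
        frame_indices=np.array([r.frame_index for r in manifest.records]),
        times=times,
        lengths=lengths,
        lengths_smooth=lengths_smooth,
        rates=rates,
        missing=missing,
        kymograph=K,
        bin_centers=centers,
        window=window,
        px_per_mm=px_per_mm,
        traces=traces,
    )
    if out is not None:
        track.to_csv(out / "growth_track.csv")
        track.kymograph_to_csv(out / "kymograph.csv")
    return track
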