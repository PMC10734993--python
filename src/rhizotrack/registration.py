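"""Translation-only registration of each frame to the initial frame.

Residual jitter in a camera-on-rails acquisition is positional, not
rotational, so the transform family is pure integer translation.  Shifts
are estimated by maximizing the circular cross-correlation of the
mean-subtracted images (computed via FFT), with the peak search restricted
to a ±max_shift window.  Registering to frame 0 rather than the previous
frame avoids drift accumulation over month-long series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from rhizotrack.io_sorting import SeriesManifest
from rhizotrack.segmentation import RegionOfInterest, crop_roi

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftEstimate:
    """Estimated (drow, dcol) such that frame ≈ reference translated by it."""

    drow: int
    dcol: int
    confidence: float  # normalized correlation peak, in [0, 1]


def estimate_shift(
    frame: np.ndarray, reference: np.ndarray, max_shift: int = 20
) -> ShiftEstimate:
    """Translation maximizing cross-correlation of frame against reference.

    The returned ``(drow, dcol)`` satisfies ``frame ≈ translate(reference,
    (drow, dcol))``; translating the frame by the negated shift aligns it to
    the reference.  Constant (degenerate) inputs yield zero shift with
    confidence 0 and a warning.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {reference.shape}")
    if max_shift >= min(frame.shape) / 4:
        raise ValueError(f"max_shift {max_shift} too large for shape {frame.shape}")
    a = frame - frame.mean()
    b = reference - reference.mean()
    norm = np.linalg.norm(a) * np.linalg.norm(b)
    if norm == 0:
        warnings.warn("degenerate (constant) image in registration", stacklevel=2)
        return ShiftEstimate(0, 0, 0.0)
    # circular cross-correlation: corr[d] = sum_p a[p] * b[p - d]
    corr = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    offsets = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(offsets, offsets)]  # negative indices wrap correctly
    peak = np.unravel_index(np.argmax(window), window.shape)
    confidence = float(np.clip(window[peak] / norm, 0.0, 1.0))
    return ShiftEstimate(int(offsets[peak[0]]), int(offsets[peak[1]]), confidence)


def translate_frame(
    frame: np.ndarray, shift: tuple[int, int], fill: float | None = None
) -> np.ndarray:
    """Translate by integer ``(drow, dcol)``; vacated pixels take ``fill``
    (default: the frame's median, a robust background estimate)."""
    frame = np.asarray(frame)
    dr, dc = int(shift[0]), int(shift[1])
    if fill is None:
        fill = float(np.median(frame))
    out = np.full_like(frame, fill)
    H, W = frame.shape[:2]
    r_src = slice(max(0, -dr), min(H, H - dr))
    c_src = slice(max(0, -dc), min(W, W - dc))
    r_dst = slice(max(0, dr), min(H, H + dr))
    c_dst = slice(max(0, dc), min(W, W + dc))
    out[r_dst, c_dst] = frame[r_src, c_src]
    return out


def stabilize_series(
    manifest: SeriesManifest,
    out_dir: str | Path | None = None,
    max_shift: int = 20,
    reg_roi: RegionOfInterest | None = None,
) -> SeriesManifest:
    """Register every frame of a series to its first frame and write the
    stabilized frames.

    Frame 0 is the reference and passes through unchanged.  Each later
    frame i is translated by the negated estimated shift so it aligns to
    frame 0; the shift is recorded in the returned manifest.  Stabilized
    frames go to ``out_dir`` (default: a sibling ``<container_id>_stab/``
    directory) under their original filenames, with the updated manifest
    CSV alongside.

    ``reg_roi`` restricts the *estimation* to a static sub-rectangle (the
    full frame, label included, is the default — the label's static,
    high-contrast texture anchors the correlation well).
    """
    if not manifest.records:
        raise ValueError("cannot stabilize an empty series")
    first = Path(manifest.records[0].source_path)
    if not first.exists():
        raise FileNotFoundError(f"unreadable frame: {first}")
    if out_dir is None:
        out_dir = first.parent.parent / f"{manifest.container_id}_stab"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _read(path: Path) -> np.ndarray:
        if not path.exists():
            raise FileNotFoundError(f"unreadable frame: {path}")
        img = iio.imread(path).astype(float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        return img / 255.0

    reference = _read(first)
    ref_view = crop_roi(reference, reg_roi) if reg_roi is not None else reference
    new_records = []
    for rec in manifest.records:
        frame = _read(Path(rec.source_path))
        if rec.frame_index == manifest.records[0].frame_index:
            est = ShiftEstimate(0, 0, 1.0)
            stabilized = frame
        else:
            view = crop_roi(frame, reg_roi) if reg_roi is not None else frame
            est = estimate_shift(view, ref_view, max_shift)
            stabilized = translate_frame(frame, (-est.drow, -est.dcol))
        target = out / Path(rec.source_path).name
        iio.imwrite(target, np.round(np.clip(stabilized, 0, 1) * 255).astype(np.uint8))
        new_records.append(
            replace(rec, source_path=str(target), shift=(est.drow, est.dcol))
        )
        logger.debug("frame %d: shift (%d, %d) conf %.3f",
                     rec.frame_index, est.drow, est.dcol, est.confidence)
    stabilized_manifest = SeriesManifest(
        container_id=manifest.container_id,
        records=new_records,
        frame_interval=manifest.frame_interval,
        image_shape=manifest.image_shape,
    )
    stabilized_manifest.to_csv(out / "manifest.csv")
    return stabilized_manifest
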