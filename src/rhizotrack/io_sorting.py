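"""Demultiplexing raw captures into per-container series.

The acquisition loop images all vessels cyclically into one directory, so
capture order is global lexicographic filename order.  Each frame's printed
label identifies its container; frames are copied (never moved) into
``out_dir/<container_id>/``, undecodable frames into ``out_dir/unsorted/``,
and a per-container manifest CSV plus a plain-text anomaly report are
written.  No input frame is lost: input count = sorted + unsorted +
skipped-with-reason.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from rhizotrack.labels import decode_label

logger = logging.getLogger(__name__)

UNSORTED = "unsorted"
IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")
MANIFEST_COLUMNS = [
    "container_id", "frame_index", "time_min", "source_path", "shift_row", "shift_col",
]


@dataclass(frozen=True)
class FrameRecord:
    """One captured frame: container identity, time, stabilization shift."""

    container_id: str
    frame_index: int
    time_min: float
    source_path: str
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.container_id:
            raise ValueError("container_id must be non-empty (use 'unsorted')")


@dataclass
class SeriesManifest:
    """Ordered frame records of a single container, plus series metadata."""

    container_id: str
    records: list[FrameRecord] = field(default_factory=list)
    frame_interval: float = 15.0        # minutes
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: r.frame_index)
        ids = {r.container_id for r in self.records}
        if ids - {self.container_id}:
            raise ValueError(f"mixed container ids in manifest: {ids}")
        indices = [r.frame_index for r in self.records]
        if len(indices) != len(set(indices)):
            raise ValueError("duplicate frame_index in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "container_id": [r.container_id for r in self.records],
                "frame_index": [r.frame_index for r in self.records],
                "time_min": [r.time_min for r in self.records],
                "source_path": [r.source_path for r in self.records],
                "shift_row": [r.shift[0] for r in self.records],
                "shift_col": [r.shift[1] for r in self.records],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_interval: float = 15.0,
        image_shape: tuple[int, int] | None = None,
    ) -> "SeriesManifest":
        df = pd.read_csv(path)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
        records = [
            FrameRecord(
                container_id=str(row.container_id),
                frame_index=int(row.frame_index),
                time_min=float(row.time_min),
                source_path=str(row.source_path),
                shift=(int(row.shift_row), int(row.shift_col)),
            )
            for row in df.itertuples()
        ]
        cid = records[0].container_id if records else UNSORTED
        return cls(container_id=cid, records=records,
                   frame_interval=frame_interval, image_shape=image_shape)


def read_frame(path: str | Path) -> np.ndarray:
    """Load a frame as grayscale float in [0, 1] (RGB reduced by mean)."""
    img = iio.imread(path).astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img / 255.0


def detect_container_id(frame: np.ndarray) -> str | None:
    """Decode the container label in a frame; None when nothing validates.

    With several decodable labels in one frame, the one with the largest
    bounding box wins (a warning is logged): the nearest vessel's label is
    the largest in view.
    """
    return decode_label(frame)


def sort_frames(
    raw_dir: str | Path,
    out_dir: str | Path,
    interval_min: float = 15.0,
) -> tuple[dict[str, SeriesManifest], dict[str, int]]:
    """Sort a directory of mixed raw captures into per-container series.

    Frames are processed in lexicographic filename order (capture order);
    within each container, ``frame_index`` counts its frames in that order
    and ``time_min = frame_index * interval_min``.  Files are *copied* so
    the raw directory stays intact.  Returns the per-container manifests
    and a summary count dict; a ``sort_report.txt`` with one line per
    anomaly is written to ``out_dir``.
    """
    raw = Path(raw_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in raw.iterdir()
                   if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS)
    report_lines: list[str] = []
    buckets: dict[str, list[Path]] = {}
    skipped = 0
    for path in paths:
        try:
            frame = read_frame(path)
        except Exception as exc:  # unreadable file: skip with reason
            skipped += 1
            report_lines.append(f"skipped {path.name}: unreadable ({exc})")
            continue
        cid = detect_container_id(frame)
        if cid is None:
            report_lines.append(f"unsorted {path.name}: no decodable label")
            cid = UNSORTED
        buckets.setdefault(cid, []).append(path)

    manifests: dict[str, SeriesManifest] = {}
    n_sorted = 0
    n_unsorted = 0
    for cid, members in buckets.items():
        target_dir = out / cid
        target_dir.mkdir(exist_ok=True)
        records = []
        seen: set[str] = set()
        for idx, src in enumerate(members):
            if src.name in seen:
                raise FileExistsError(
                    f"target name collision: {src.name} appears twice for {cid}"
                )
            seen.add(src.name)
            dst = target_dir / src.name
            if not (dst.exists() and dst.stat().st_size == src.stat().st_size):
                shutil.copy2(src, dst)
            records.append(
                FrameRecord(
                    container_id=cid,
                    frame_index=idx,
                    time_min=idx * interval_min,
                    source_path=str(dst),
                )
            )
        shape = read_frame(members[0]).shape
        manifest = SeriesManifest(
            container_id=cid, records=records,
            frame_interval=interval_min, image_shape=shape,
        )
        manifest.to_csv(target_dir / "manifest.csv")
        if cid == UNSORTED:
            n_unsorted = len(records)
        else:
            n_sorted += len(records)
            manifests[cid] = manifest

    summary = {
        "input": len(paths),
        "sorted": n_sorted,
        "unsorted": n_unsorted,
        "skipped": skipped,
        "containers": len(manifests),
    }
    assert summary["input"] == n_sorted + n_unsorted + skipped
    report_lines.append(
        f"total {summary['input']} = sorted {n_sorted} + unsorted {n_unsorted} "
        f"+ skipped {skipped}; containers: {len(manifests)}"
    )
    (out / "sort_report.txt").write_text("\n".join(report_lines) + "\n")
    logger.info("sorted %d frames into %d containers (%d unsorted, %d skipped)",
                n_sorted, len(manifests), n_unsorted, skipped)
    return manifests, summary
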