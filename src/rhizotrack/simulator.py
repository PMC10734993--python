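"""Synthetic root-growth time-lapse generator with machine-readable ground truth.

Emulates the imaging geometry of a gantry robot photographing a single root
growing in a clear gel vessel: a dark root of finite width elongating at its
tip along a configurable path, a brighter gel background with Gaussian pixel
noise and a smooth illumination gradient, a per-frame integer translation
standing in for residual camera positioning jitter, and a printed container
label composited into one corner of the scene.  Every frame's true
centerline, arc length, and jitter offset are recorded so downstream stages
(registration, segmentation, centerline extraction, kinetics) can be
validated against exact truth.

Conventions
-----------
* Images are float arrays in [0, 1], row-major, origin top-left; written to
  disk as 8-bit grayscale PNG named ``frame_<index:06d>.png``.
* The root base sits near the top of the canvas and grows downward
  (increasing row), as for a plant sitting on top of the gel.
* Growth is tip-extension only: the path of frame *i* is a prefix of the
  path of frame *i+1*, so centerlines are comparable by arc length from
  the base.
* Frame 0 carries zero jitter (the camera homes at series start), so the
  recorded jitters are exactly the shifts a frame-0-referenced registration
  must recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import imageio.v3 as iio

from rhizotrack.labels import generate_label
from rhizotrack.segmentation import RegionOfInterest

_PATH_MODELS = ("straight", "circular_arc", "sinusoid")
_CENTERLINE_DS = 0.5  # arc-length sample spacing of emitted centerlines, px


class PathOutOfBoundsError(ValueError):
    """Raised when the configured growth path would leave the canvas."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic time-lapse series.

    Defaults describe the reference study condition used throughout the
    test-suite: a slowly growing dark root on a brighter gel, 15-minute
    imaging cadence, mild sensor noise and a few pixels of jitter.
    """

    image_height: int = 400
    image_width: int = 256
    base_point: tuple[float, float] = (24.0, 128.0)
    initial_length: float = 100.0       # L0, px
    growth_rate: float = 4.0            # px per frame
    path_model: str = "straight"
    arc_radius: float = 300.0           # circular_arc only, px
    sine_amplitude: float = 20.0        # sinusoid only, px
    sine_period: float = 150.0          # sinusoid only, px of vertical run
    root_width: float = 7.0             # px
    root_intensity: float = 0.25
    background_intensity: float = 0.65
    noise_sigma: float = 0.02           # intensity units
    illumination_slope: float = 0.0005  # intensity units per px (columns)
    jitter_max: int = 4                 # px, uniform integer in [-j, j]^2
    n_frames: int = 50
    frame_interval: float = 15.0        # minutes
    label_payload: str | None = None
    label_size: int = 76                # px
    label_margin: int = 10              # px gap between label and canvas edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.root_width < 3:
            raise ValueError("root_width must be >= 3 px")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.initial_length < 0 or self.growth_rate < 0:
            raise ValueError("initial_length and growth_rate must be >= 0")
        if self.path_model not in _PATH_MODELS:
            raise ValueError(f"path_model must be one of {_PATH_MODELS}")
        if self.root_intensity == self.background_intensity:
            raise ValueError("root and background intensity must differ")
        if self.noise_sigma < 0 or self.jitter_max < 0:
            raise ValueError("noise_sigma and jitter_max must be >= 0")

    def length_at(self, frame_index: int) -> float:
        return self.initial_length + frame_index * self.growth_rate


def _curve_points(config: SimulationConfig, arc_length: float) -> np.ndarray:
    """Points of the growth path from the base up to ``arc_length``.

    The path is parameterized by arc length, which is what makes frame i's
    path an exact prefix of frame i+1's.  Straight and circular paths are
    closed-form; the sinusoid inverts a numerically accumulated chord
    length.
    """
    r0, c0 = config.base_point
    n = max(2, int(math.ceil(arc_length / _CENTERLINE_DS)) + 1)
    s = np.linspace(0.0, arc_length, n)
    if config.path_model == "straight":
        return np.column_stack([r0 + s, np.full(n, c0)])
    if config.path_model == "circular_arc":
        R = float(config.arc_radius)
        theta = s / R
        # center at (r0, c0 - R): tangent at the base points straight down,
        # the root then bends toward decreasing column (away from the label)
        return np.column_stack([r0 + R * np.sin(theta), c0 - R * (1.0 - np.cos(theta))])
    # sinusoid: column oscillates with vertical run t
    t_fine = np.arange(0.0, arc_length + 0.1, 0.1)
    cols = c0 + config.sine_amplitude * np.sin(2 * np.pi * t_fine / config.sine_period)
    pts = np.column_stack([r0 + t_fine, cols])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    rows = np.interp(s, cum, pts[:, 0])
    cols_s = np.interp(s, cum, pts[:, 1])
    return np.column_stack([rows, cols_s])


def simulate_root_path(config: SimulationConfig, frame_index: int) -> np.ndarray:
    """True centerline of the root at ``frame_index``: (N, 2) (row, col) array.

    Points are spaced ~0.5 px in arc length, base first.  Raises
    :class:`PathOutOfBoundsError` (naming the first offending frame) if the
    path would leave the canvas, keeping a half-root-width margin so the
    rendered root stays inside.
    """
    if frame_index >= config.n_frames or frame_index < 0:
        raise ValueError(f"frame_index {frame_index} outside [0, {config.n_frames})")
    pts = _curve_points(config, config.length_at(frame_index))
    margin = config.root_width / 2.0
    bad = (
        (pts[:, 0] < margin) | (pts[:, 0] > config.image_height - 1 - margin)
        | (pts[:, 1] < margin) | (pts[:, 1] > config.image_width - 1 - margin)
    )
    if bad.any():
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s_exit = float(cum[int(np.argmax(bad))])
        if config.growth_rate > 0:
            first_bad = max(0, math.ceil((s_exit - config.initial_length) / config.growth_rate))
        else:
            first_bad = 0
        raise PathOutOfBoundsError(
            f"growth path leaves the canvas at frame {first_bad} "
            f"(arc length {s_exit:.1f} px)"
        )
    return pts


def polyline_length(points: np.ndarray) -> float:
    """Total chord length of an ordered (N, 2) point sequence."""
    return float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())


def _densify(points: np.ndarray, ds: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return points
    s = np.arange(0.0, total + ds, ds)
    s[-1] = min(s[-1], total)
    return np.column_stack(
        [np.interp(s, cum, points[:, 0]), np.interp(s, cum, points[:, 1])]
    )


def render_frame(
    centerline: np.ndarray,
    config: SimulationConfig,
    jitter: tuple[int, int] = (0, 0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame: root + gel background + label, translated by ``jitter``.

    Pixels within ``root_width / 2`` of the (jitter-shifted) centerline take
    ``root_intensity`` exactly; everything else takes the background level
    plus the illumination gradient plus i.i.d. Gaussian noise.  The label,
    when configured, is composited into the top-right corner of the scene
    before the translation, as a physical label on the vessel would move
    with the camera's framing.  Intensities are clipped to [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dr, dc = int(jitter[0]), int(jitter[1])
    H, W = config.image_height, config.image_width
    cols = np.arange(W, dtype=float)[None, :]
    img = config.background_intensity + config.illumination_slope * (cols - dc)
    img = np.broadcast_to(img, (H, W)).copy()
    solid = np.zeros((H, W), dtype=bool)

    if config.label_payload is not None:
        label = generate_label(config.label_payload, config.label_size)
        lr = config.label_margin + dr
        lc = W - config.label_margin - config.label_size + dc
        r_lo, r_hi = max(0, lr), min(H, lr + label.shape[0])
        c_lo, c_hi = max(0, lc), min(W, lc + label.shape[1])
        if r_hi > r_lo and c_hi > c_lo:
            img[r_lo:r_hi, c_lo:c_hi] = label[r_lo - lr: r_hi - lr, c_lo - lc: c_hi - lc]
            solid[r_lo:r_hi, c_lo:c_hi] = True

    pts = _densify(np.asarray(centerline, dtype=float), 0.25) + np.array([dr, dc], float)
    half = config.root_width / 2.0
    r_lo = max(0, int(np.floor(pts[:, 0].min() - half - 1)))
    r_hi = min(H, int(np.ceil(pts[:, 0].max() + half + 2)))
    c_lo = max(0, int(np.floor(pts[:, 1].min() - half - 1)))
    c_hi = min(W, int(np.ceil(pts[:, 1].max() + half + 2)))
    if r_hi > r_lo and c_hi > c_lo:
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        dist, _ = cKDTree(pts).query(grid, workers=-1)
        root_mask = (dist <= half).reshape(rr.shape)
        sub = img[r_lo:r_hi, c_lo:c_hi]
        sub[root_mask] = config.root_intensity
        solid[r_lo:r_hi, c_lo:c_hi] |= root_mask

    if config.noise_sigma > 0:
        noise = rng.normal(0.0, config.noise_sigma, size=(H, W))
        img[~solid] += noise[~solid]
    return np.clip(img, 0.0, 1.0)


@dataclass
class GroundTruth:
    """Per-frame truth of a generated series, with a config echo."""

    config: SimulationConfig
    lengths: np.ndarray                 # (n_frames,) true arc length, px
    jitters: np.ndarray                 # (n_frames, 2) integer (drow, dcol)
    centerlines: list[np.ndarray] = field(repr=False, default_factory=list)

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "frames": [
                {
                    "frame_index": i,
                    "true_length": float(self.lengths[i]),
                    "true_jitter": [int(self.jitters[i, 0]), int(self.jitters[i, 1])],
                    "true_centerline": np.round(self.centerlines[i], 3).tolist(),
                }
                for i in range(len(self.lengths))
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["base_point"] = tuple(cfg["base_point"])
        config = SimulationConfig(**cfg)
        frames = payload["frames"]
        return cls(
            config=config,
            lengths=np.array([f["true_length"] for f in frames]),
            jitters=np.array([f["true_jitter"] for f in frames], dtype=int),
            centerlines=[np.asarray(f["true_centerline"], dtype=float) for f in frames],
        )


def generate_series(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Write a full synthetic series to ``out_dir`` and return its ground truth.

    Emits ``frame_<index:06d>.png`` (8-bit grayscale) for each frame plus a
    ``ground_truth.json`` sidecar.  Output is bit-identical for identical
    config + seed: all randomness flows from one generator seeded with
    ``config.seed`` (jitters drawn first, then per-frame noise).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    jitters = np.zeros((config.n_frames, 2), dtype=int)
    if config.jitter_max > 0 and config.n_frames > 1:
        jitters[1:] = rng.integers(
            -config.jitter_max, config.jitter_max + 1, size=(config.n_frames - 1, 2)
        )
    lengths = np.zeros(config.n_frames)
    centerlines: list[np.ndarray] = []
    for i in range(config.n_frames):
        path = simulate_root_path(config, i)
        centerlines.append(path)
        lengths[i] = polyline_length(path)
        img = render_frame(path, config, tuple(jitters[i]), rng)
        iio.imwrite(
            out / f"frame_{i:06d}.png", np.round(img * 255).astype(np.uint8)
        )
    truth = GroundTruth(config=config, lengths=lengths, jitters=jitters, centerlines=centerlines)
    truth.save(out / "ground_truth.json")
    return truth


def default_tracking_roi(config: SimulationConfig) -> RegionOfInterest:
    """Full-frame ROI minus the right-hand strip reserved for the label.

    The label sits in the top-right corner; excluding the whole right strip
    keeps the rectangle simple and the root (which stays in the left and
    middle columns) unaffected.
    """
    if config.label_payload is None:
        return RegionOfInterest(0, 0, config.image_height, config.image_width)
    strip = config.label_size + 2 * config.label_margin + config.jitter_max
    return RegionOfInterest(0, 0, config.image_height, max(1, config.image_width - strip))
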