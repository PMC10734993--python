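"""Shared fixtures: synthetic series generated once per session."""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest

from rhizotrack import SimulationConfig, generate_series
from rhizotrack.io_sorting import FrameRecord, SeriesManifest


def make_manifest(series_dir: Path, container_id: str, n_frames: int,
                  interval: float = 15.0) -> SeriesManifest:
    """Manifest over a generated series directory (bypasses sorting)."""
    records = [
        FrameRecord(container_id, i, i * interval,
                    str(Path(series_dir) / f"frame_{i:06d}.png"))
        for i in range(n_frames)
    ]
    return SeriesManifest(container_id=container_id, records=records,
                          frame_interval=interval)


@pytest.fixture(scope="session")
def noiseless_series(tmp_path_factory):
    """20-frame noiseless straight-root series with known integer jitters."""
    out = tmp_path_factory.mktemp("noiseless_series")
    config = SimulationConfig(
        label_payload="box_001", n_frames=20, noise_sigma=0.0,
        jitter_max=6, seed=3,
    )
    truth = generate_series(config, out)
    return config, truth, out


@pytest.fixture(scope="session")
def noisy_series(tmp_path_factory):
    """20-frame series at the default noise and jitter levels."""
    out = tmp_path_factory.mktemp("noisy_series")
    config = SimulationConfig(
        label_payload="box_007", n_frames=20, seed=11,
    )
    truth = generate_series(config, out)
    return config, truth, out


@pytest.fixture()
def interleaved_raw_dir(tmp_path):
    """Factory: n containers x m frames copied into one raw capture dir."""

    def _build(n_containers: int, n_frames: int, seed0: int = 50):
        raw = tmp_path / "raw"
        raw.mkdir(exist_ok=True)
        configs = {}
        for k in range(n_containers):
            cid = f"box_{k + 1:03d}"
            config = SimulationConfig(
                label_payload=cid, n_frames=n_frames, seed=seed0 + k,
            )
            gen = tmp_path / "gen" / cid
            generate_series(config, gen)
            configs[cid] = config
            for i in range(n_frames):
                # capture order: all containers per cycle, cycles in order
                shutil.copy(gen / f"frame_{i:06d}.png",
                            raw / f"capture_{i:04d}_{k:02d}.png")
        return raw, configs

    return _build
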