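"""Machine-readable container labels: a compact CRC-protected matrix code.

Each growth vessel carries a printed square label so that raw frames can be
demultiplexed into per-container series.  The symbology used here is a
self-contained grid code designed for the axis-aligned, known-scale setting
of a camera parked squarely in front of each vessel:

* a 13x13 grid of black/white data modules encodes the payload bits,
* the grid is surrounded by a one-module white quiet zone, a one-module
  solid black finder frame, and a one-module white outer margin,
* the payload is laid out as ``length byte + ASCII bytes + CRC-16/CCITT``,
  row-major, most significant bit first; 1-bits render black.

The finder frame (a hollow black square with a white ring just inside it)
is what the image decoder searches for; the CRC rejects chance patterns and
corrupted labels.  Capacity is 18 payload bytes (169 data bits, 3 bytes of
framing/check overhead).  Decoding tries all four 90-degree rotations, so
an upside-down label still reads.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

DATA_N = 13          # data modules per side
GRID_N = DATA_N + 6  # + quiet zone, finder frame, outer margin on each side
FRAME_N = DATA_N + 4  # extent of the black finder frame (dark-pixel bbox)
MAX_PAYLOAD = (DATA_N * DATA_N) // 8 - 3  # length byte + CRC16 overhead


def crc16_ccitt(data: bytes, poly: int = 0x1021, init: int = 0xFFFF) -> int:
    """CRC-16/CCITT-FALSE over ``data``."""
    crc = init
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ poly) if (crc & 0x8000) else (crc << 1)
            crc &= 0xFFFF
    return crc


def _payload_to_bits(payload: str) -> np.ndarray:
    raw = payload.encode("ascii")
    framed = bytes([len(raw)]) + raw
    crc = crc16_ccitt(framed)
    framed += bytes([crc >> 8, crc & 0xFF])
    bits = np.unpackbits(np.frombuffer(framed, dtype=np.uint8))
    out = np.zeros(DATA_N * DATA_N, dtype=bool)
    out[: bits.size] = bits.astype(bool)
    return out


def _bits_to_payload(bits: np.ndarray) -> str | None:
    """Inverse of :func:`_payload_to_bits`; None if the CRC rejects."""
    packed = np.packbits(bits.astype(np.uint8))
    length = int(packed[0])
    if length > MAX_PAYLOAD or 1 + length + 2 > packed.size:
        return None
    framed = packed[: 1 + length].tobytes()
    crc = (int(packed[1 + length]) << 8) | int(packed[2 + length])
    if crc16_ccitt(framed) != crc:
        return None
    try:
        return framed[1:].decode("ascii")
    except UnicodeDecodeError:
        return None


def generate_label(container_id: str, size: int = 76) -> np.ndarray:
    """Render a container-id label as a float image in [0, 1].

    Parameters
    ----------
    container_id:
        Non-empty printable ASCII text, at most 18 bytes.
    size:
        Side length of the returned square image in pixels; must allow at
        least 2 px per module (size >= 38).

    Returns
    -------
    Square float array, black modules 0.0 on white 1.0.
    """
    if not container_id:
        raise ValueError("container_id must be non-empty")
    try:
        raw = container_id.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ValueError("container_id must be ASCII") from exc
    if len(raw) > MAX_PAYLOAD:
        raise ValueError(
            f"payload too long: {len(raw)} bytes exceeds label capacity {MAX_PAYLOAD}"
        )
    module_px = size // GRID_N
    if module_px < 2:
        raise ValueError(f"size {size} too small; need >= {2 * GRID_N} px")

    modules = np.zeros((GRID_N, GRID_N), dtype=bool)  # True = black
    modules[1:-1, 1:-1] = True            # finder frame block
    modules[2:-2, 2:-2] = False           # quiet zone + data area reset
    bits = _payload_to_bits(container_id).reshape(DATA_N, DATA_N)
    modules[3:-3, 3:-3] = bits

    img = np.where(np.kron(modules, np.ones((module_px, module_px), dtype=bool)), 0.0, 1.0)
    # pad to the requested size with white margin
    pad = size - img.shape[0]
    if pad > 0:
        before = pad // 2
        img = np.pad(img, ((before, pad - before), (before, pad - before)), constant_values=1.0)
    return img


def _sample_data_grid(image: np.ndarray, r0: int, c0: int, h: int, w: int) -> np.ndarray:
    """Sample the 13x13 data modules inside a detected finder-frame bbox."""
    m_r = h / FRAME_N
    m_c = w / FRAME_N
    bits = np.zeros((DATA_N, DATA_N), dtype=bool)
    for i in range(DATA_N):
        for j in range(DATA_N):
            rc = r0 + (2 + i + 0.5) * m_r
            cc = c0 + (2 + j + 0.5) * m_c
            # average over a small core of the module, robust to edge pixels
            half_r = int(m_r / 3)
            half_c = int(m_c / 3)
            block = image[
                max(0, int(rc) - half_r): int(rc) + half_r + 1,
                max(0, int(cc) - half_c): int(cc) + half_c + 1,
            ]
            bits[i, j] = block.mean() < 0.5
    return bits


def _looks_like_finder_frame(image: np.ndarray, r0: int, c0: int, h: int, w: int) -> bool:
    """Check for a hollow dark square with a light ring just inside it."""
    if h < FRAME_N or w < FRAME_N:
        return False
    if abs(h - w) > max(3, 0.1 * max(h, w)):
        return False
    m = max(1, round(h / FRAME_N))
    sub = image[r0: r0 + h, c0: c0 + w]
    if sub.shape != (h, w):
        return False
    ring = np.concatenate(
        [
            sub[:m, :].ravel(), sub[-m:, :].ravel(),
            sub[m:-m, :m].ravel(), sub[m:-m, -m:].ravel(),
        ]
    )
    inner = np.concatenate(
        [
            sub[m: 2 * m, m:-m].ravel(), sub[-2 * m: -m, m:-m].ravel(),
            sub[2 * m: -2 * m, m: 2 * m].ravel(), sub[2 * m: -2 * m, -2 * m: -m].ravel(),
        ]
    )
    if ring.size == 0 or inner.size == 0:
        return False
    return (ring < 0.5).mean() > 0.9 and (inner > 0.5).mean() > 0.8


def decode_labels(image: np.ndarray) -> list[tuple[str, tuple[int, int, int, int]]]:
    """Find and decode every label in a grayscale image.

    Returns a list of ``(payload, (r0, c0, r1, c1))`` tuples, one per label
    whose CRC validates, ordered by decreasing bounding-box area.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    dark = image < 0.5
    if not dark.any():
        return []
    labeled = cc_label(dark, connectivity=2)
    found: list[tuple[str, tuple[int, int, int, int]]] = []
    for region in regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        h, w = r1 - r0, c1 - c0
        if not _looks_like_finder_frame(image, r0, c0, h, w):
            continue
        bits = _sample_data_grid(image, r0, c0, h, w)
        for _ in range(4):
            payload = _bits_to_payload(bits.ravel())
            if payload is not None:
                found.append((payload, (r0, c0, r1, c1)))
                break
            bits = np.rot90(bits)
    found.sort(key=lambda t: (t[1][2] - t[1][0]) * (t[1][3] - t[1][1]), reverse=True)
    return found


def decode_label(image: np.ndarray) -> str | None:
    """Decode the (largest) label in an image, or None if none validates."""
    found = decode_labels(image)
    if not found:
        return None
    if len(found) > 1:
        warnings.warn(
            f"multiple labels decoded ({[p for p, _ in found]}); keeping the largest",
            stacklevel=2,
        )
        logger.warning("multiple labels decoded; keeping the largest bounding box")
    return found[0][0]
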