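"""Centerline extraction and smooth geometry of a segmented root.

The mask is thinned to a 1-px skeleton, the skeleton's longest geodesic
path between endpoint pixels becomes the ordered base-to-tip centerline
(side branches produced by thinning artifacts are discarded), and smoothing
splines in arc length yield a uniformly resampled curve with per-sample
curvature kappa(s) and radius of curvature R(s) = min(1/kappa, R_cap).

Arc length on the raw pixel path uses the standard step metric (1 for
axial moves, sqrt(2) for diagonal); after spline fitting, the smoothed
curve's own arc length supersedes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import make_smoothing_spline
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

BaseHint = str | tuple[float, float]

_SQRT2 = math.sqrt(2.0)


@dataclass
class Centerline:
    """Ordered base-to-tip point sequence with arc-length parameterization."""

    points: np.ndarray                  # (N, 2) (row, col)
    s: np.ndarray                       # (N,) arc length from base, s[0] = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.s[0] != 0 or not np.all(np.diff(self.s) > 0):
            raise ValueError("arc length must start at 0 and be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.s[-1])


@dataclass
class RootTrace:
    """Spline-smoothed centerline resampled at uniform arc-length spacing."""

    points: np.ndarray                  # (M, 2) smoothed (row, col)
    s: np.ndarray                       # (M,) uniform arc length, px
    kappa: np.ndarray                   # (M,) unsigned curvature, 1/px
    radius: np.ndarray                  # (M,) min(1/kappa, r_cap), px
    length: float                       # total arc length, px
    r_cap: float = field(default=1e4)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "s_px": self.s,
                "row": self.points[:, 0],
                "col": self.points[:, 1],
                "kappa_per_px": self.kappa,
                "radius_px": self.radius,
            }
        ).to_csv(path, index=False)


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of the mask to a 1-px-wide skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nothing to skeletonize: empty mask")
    return skeletonize(mask)


def _skeleton_graph(pixels: np.ndarray) -> tuple[csr_matrix, np.ndarray]:
    """8-connected adjacency over skeleton pixels, step-metric weights."""
    index = {tuple(p): i for i, p in enumerate(pixels)}
    rows, cols, weights = [], [], []
    for i, (r, c) in enumerate(pixels):
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half
            j = index.get((r + dr, c + dc))
            if j is not None:
                w = _SQRT2 if dr and dc else 1.0
                rows += [i, j]
                cols += [j, i]
                weights += [w, w]
    n = len(pixels)
    graph = csr_matrix((weights, (rows, cols)), shape=(n, n))
    degree = np.asarray((graph > 0).sum(axis=1)).ravel()
    return graph, degree


def extract_path(skeleton: np.ndarray, base_hint: BaseHint = "top") -> Centerline:
    """Longest geodesic endpoint-to-endpoint path through the skeleton.

    Endpoints are degree-1 pixels of the 8-connected adjacency graph; the
    geodesically farthest endpoint pair defines the centerline and shorter
    side branches are discarded.  ``base_hint`` orients the result: one of
    ``"top" | "bottom" | "left" | "right"`` (which image side the base is
    nearest) or an explicit ``(row, col)`` point; the nearer path end
    becomes index 0.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    pixels = np.argwhere(skeleton)
    if pixels.size == 0:
        raise ValueError("empty skeleton")
    if len(pixels) < 2:
        raise ValueError("skeleton too small to form a path")
    graph, degree = _skeleton_graph(pixels)
    endpoints = np.flatnonzero(degree == 1)
    if endpoints.size == 0:
        raise ValueError("cyclic skeleton: no endpoint pixels")
    dist, pred = dijkstra(graph, indices=endpoints, return_predecessors=True)
    sub = dist[:, endpoints]
    sub[~np.isfinite(sub)] = -1.0
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    src, dst = endpoints[i], endpoints[j]
    # walk predecessors back from dst to src
    order = [dst]
    while order[-1] != src:
        prev = pred[i, order[-1]]
        if prev < 0:
            raise ValueError("disconnected skeleton")
        order.append(prev)
    order.reverse()
    pts = pixels[order].astype(float)

    if _base_score(pts[-1], skeleton.shape, base_hint) < _base_score(
        pts[0], skeleton.shape, base_hint
    ):
        pts = pts[::-1]
    steps = np.where(
        (np.abs(np.diff(pts, axis=0)) == 1).all(axis=1), _SQRT2, 1.0
    )
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return Centerline(points=pts, s=s)


def _base_score(point: np.ndarray, shape: tuple[int, int], hint: BaseHint) -> float:
    """Smaller score = closer to the hinted base side/point."""
    r, c = point
    if isinstance(hint, str):
        try:
            return {
                "top": r,
                "bottom": shape[0] - 1 - r,
                "left": c,
                "right": shape[1] - 1 - c,
            }[hint]
        except KeyError:
            raise ValueError(f"unknown base_hint {hint!r}") from None
    return float(np.hypot(r - hint[0], c - hint[1]))


def extend_to_tips(centerline: Centerline, mask: np.ndarray) -> Centerline:
    """Correct skeleton endpoint retraction against the source mask.

    Morphological thinning retracts the skeleton's ends by roughly the
    local half-width before the true tip of an elongated shape, which
    systematically shortens length estimates.  For a tube of half-width h,
    the distance transform along the true centerline stays ~h until the tip
    point and falls off beyond it, so each path end is extended along its
    local tangent while the (bilinearly sampled) distance transform remains
    within half a pixel of the tube half-width.  The half-width itself is
    estimated as the median distance-transform value along the existing
    path.
    """
    mask = np.asarray(mask, dtype=bool)
    edt = ndi.distance_transform_edt(mask)

    def _sample(points: np.ndarray) -> np.ndarray:
        return ndi.map_coordinates(edt, points.T, order=1, mode="constant")

    pts = centerline.points
    half_width = float(np.median(_sample(pts)))
    step = 0.25
    max_ext = 2.0 * half_width + 2.0

    def _extension(end: np.ndarray, inward: np.ndarray) -> np.ndarray:
        tangent = end - inward
        norm = np.linalg.norm(tangent)
        if norm == 0:
            return np.empty((0, 2))
        tangent /= norm
        added = []
        p = end.copy()
        while len(added) * step < max_ext:
            p = p + tangent * step
            if not (0 <= p[0] < mask.shape[0] - 1 and 0 <= p[1] < mask.shape[1] - 1):
                break
            if _sample(p[None, :])[0] < half_width - 0.5:
                break
            added.append(p.copy())
        return np.asarray(added).reshape(-1, 2)

    span = min(len(pts) - 1, 5)
    head = _extension(pts[0], pts[span])[::-1]
    tail = _extension(pts[-1], pts[-1 - span])
    if len(head) == 0 and len(tail) == 0:
        return centerline
    new_pts = np.vstack([head, pts, tail])
    seg = np.linalg.norm(np.diff(new_pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(points=new_pts, s=s)


def fit_trace(
    centerline: Centerline,
    smoothing: float = 1.0,
    ds: float = 1.0,
    r_cap: float = 1e4,
) -> RootTrace:
    """Fit smoothing splines row(s), col(s) and resample at uniform ``ds``.

    Each coordinate is fit with a cubic penalized smoothing spline (knots
    at every sample, roughness penalty ``lam * integral(g'')^2`` with
    ``lam = smoothing * 50``).  In arc length the penalty acts as a
    low-pass filter with a cutoff of roughly ``(lam)^(1/4)`` px at the
    default — long enough to damp the sub-pixel stair-stepping of a pixel
    path, far shorter than any root-scale bend, so curvature at radii of
    tens of pixels and up passes through unbiased.  ``smoothing = 0``
    interpolates.  Curvature comes from the spline derivatives,

        kappa = |r' c'' - c' r''| / (r'^2 + c'^2)^(3/2),

    reported unsigned, with the radius of curvature capped at ``r_cap`` so
    straight segments stay finite.
    """
    n = len(centerline.points)
    if n < 4:
        raise ValueError("too short to fit: need at least 4 points")
    s_raw = centerline.s
    lam = smoothing * 50.0
    spl_r = make_smoothing_spline(s_raw, centerline.points[:, 0], lam=lam)
    spl_c = make_smoothing_spline(s_raw, centerline.points[:, 1], lam=lam)

    t = np.linspace(s_raw[0], s_raw[-1], max(400, 4 * n))
    speed = np.hypot(spl_r.derivative()(t), spl_c.derivative()(t))
    arc = cumulative_trapezoid(speed, t, initial=0.0)
    length = float(arc[-1])
    u = np.arange(0.0, length, ds)
    if length - u[-1] > 1e-9:
        u = np.append(u, length)
    t_u = np.interp(u, arc, t)

    r1, c1 = spl_r.derivative(1)(t_u), spl_c.derivative(1)(t_u)
    r2, c2 = spl_r.derivative(2)(t_u), spl_c.derivative(2)(t_u)
    denom = np.power(r1**2 + c1**2, 1.5)
    kappa = np.abs(r1 * c2 - c1 * r2) / np.where(denom > 0, denom, np.inf)
    radius = np.minimum(1.0 / np.maximum(kappa, 1.0 / r_cap), r_cap)
    points = np.column_stack([spl_r(t_u), spl_c(t_u)])
    return RootTrace(points=points, s=u, kappa=kappa, radius=radius,
                     length=length, r_cap=r_cap)
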