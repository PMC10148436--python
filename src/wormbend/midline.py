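"""Centerline extraction from the worm boundary.

The closed boundary is cut at head and tail into a dorsal and a ventral
polyline, both resampled to n points at equal arc length; centerline point
C_i is the midpoint of ventral point V_i and the dorsal point D_j selected,
within a search window of +-r indices, by the tangent pairing criterion
(the dorsal point most perpendicular to the local ventral tangent).  Body
length L is the summed Euclidean length of the centerline polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep


@dataclass
class ContourSplit:
    """Dorsal/ventral boundary sides, each n points ordered head -> tail."""

    dorsal: np.ndarray
    ventral: np.ndarray

    @property
    def n(self) -> int:
        return len(self.dorsal)


@dataclass
class Centerline:
    """Midline points head -> tail with arc length L."""

    points: np.ndarray          # (n, 2)
    L: float = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise ValueError("centerline needs at least 3 points")
        self.L = centerline_length(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def is_self_intersecting(self, min_sep_frac: float = 0.15) -> bool:
        """Coiled-posture test: a centerline crossing itself is unreliable
        for feature extraction and the frame is skipped.

        Only crossings between segments separated by at least
        ``min_sep_frac`` of the point count signal a coil — a genuine coil
        brings remote body parts together, whereas sub-pixel micro-loops
        from the pairing step involve near-adjacent segments only.
        """
        return _has_remote_crossing(self.points, min_sep_frac)


def _has_remote_crossing(points: np.ndarray, min_sep_frac: float) -> bool:
    """True when two polyline segments at least min_sep_frac*n indices apart
    properly cross (strict interior intersection, vectorized)."""
    pts = np.asarray(points, dtype=float)
    p = pts[:-1]
    d = np.diff(pts, axis=0)
    m = len(d)
    min_sep = max(2, int(round(min_sep_frac * len(pts))))

    def cross2(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    qp = p[None, :, :] - p[:, None, :]
    rxs = cross2(d[:, None, :], d[None, :, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross2(qp, d[None, :, :]) / rxs
        u = cross2(qp, d[:, None, :]) / rxs
    hit = (rxs != 0) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
    i, j = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    return bool(np.any(hit & (np.abs(i - j) >= min_sep)))


def split_contour(
    boundary: np.ndarray, head: np.ndarray, tail: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the closed boundary at head and tail into two open polylines.

    Head and tail are snapped to their nearest boundary vertices; both
    returned sides run head -> tail.  Side A is the side lying clockwise
    from the head along the boundary (an arbitrary but fixed convention —
    only cross-frame consistency matters downstream).
    """
    boundary = np.asarray(boundary, dtype=float)
    head = np.asarray(head, dtype=float)
    tail = np.asarray(tail, dtype=float)
    i_head = int(np.argmin(np.linalg.norm(boundary - head, axis=1)))
    i_tail = int(np.argmin(np.linalg.norm(boundary - tail, axis=1)))
    if i_head == i_tail:
        raise ValueError("head and tail snap to the same boundary vertex")
    n = len(boundary)
    idx_a = np.arange(i_head, i_head + (i_tail - i_head) % n + 1) % n
    idx_b = np.arange(i_tail, i_tail + (i_head - i_tail) % n + 1) % n
    side_a = boundary[idx_a]           # head -> tail along increasing index
    side_b = boundary[idx_b][::-1]     # reversed so it also runs head -> tail
    return side_a, side_b


def resample_by_distance(polyline: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation to n points at equal arc-length spacing,
    endpoints preserved exactly."""
    pts = np.asarray(polyline, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("zero-length polyline cannot be resampled")
    target = np.linspace(0.0, total, n)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    out = np.column_stack([x, y])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def make_contour_split(
    boundary: np.ndarray, head: np.ndarray, tail: np.ndarray, n: int = 120
) -> ContourSplit:
    """Split the boundary at head/tail and resample both sides to n points."""
    side_a, side_b = split_contour(boundary, head, tail)
    return ContourSplit(
        dorsal=resample_by_distance(side_a, n),
        ventral=resample_by_distance(side_b, n),
    )


def _pair_midpoints(
    V: np.ndarray, D: np.ndarray, r: int, k: int, pairing: str
) -> np.ndarray:
    """One-directional pairing: each V_i picks its D_j, midpoints returned."""
    n = len(V)
    pts = np.empty((n, 2))
    pts[0] = (V[0] + D[0]) / 2.0
    pts[-1] = (V[-1] + D[-1]) / 2.0
    for i in range(1, n - 1):
        lo, hi = max(0, i - k), min(n - 1, i + k)
        tangent = V[hi] - V[lo]
        m_lo, m_hi = max(0, i - r), min(n - 1, i + r)
        cand = D[m_lo : m_hi + 1]
        dots = (cand - V[i]) @ tangent
        if pairing == "perpendicular":
            j = m_lo + int(np.argmin(np.abs(dots)))
        else:
            j = m_lo + int(np.argmin(dots))
        pts[i] = (V[i] + D[j]) / 2.0
    return pts


def compute_centerline(
    split: ContourSplit,
    r: int = 10,
    k: int = 2,
    pairing: str = "perpendicular",
    symmetric: bool = True,
) -> Centerline:
    """Pair dorsal and ventral points and take midpoints.

    For interior i the partner index j is searched over m in [i-r, i+r]
    (clamped): pairing="perpendicular" (default) minimizes the absolute dot
    product of the local tangent V_{i+k} - V_{i-k} with D_m - V_i, i.e. the
    most perpendicular rung; pairing="literal" minimizes the signed dot
    product as the pairing equation is written.  Endpoints pair index to
    index so C_1 and C_n sit on head and tail.

    With ``symmetric`` (default) the pairing is run in both directions
    (ventral->dorsal and dorsal->ventral) and the two midpoint sets are
    averaged, making the centerline exactly invariant under swapping the
    side labels — and hence under mirror reflection of the frame.
    """
    if pairing not in ("perpendicular", "literal"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    D, V = np.asarray(split.dorsal, float), np.asarray(split.ventral, float)
    if len(D) != len(V):
        raise ValueError(f"dorsal/ventral point counts differ: {len(D)} vs {len(V)}")
    pts = _pair_midpoints(V, D, r, k, pairing)
    if symmetric:
        pts = 0.5 * (pts + _pair_midpoints(D, V, r, k, pairing))
    return Centerline(points=pts)


def smooth_polyline(points: np.ndarray, passes: int = 2) -> np.ndarray:
    """Endpoint-preserving 1-2-1 smoothing of interior points.

    Removes the sub-pixel zigzag the windowed pairing can leave near the
    worm ends without moving head or tail.
    """
    out = np.asarray(points, dtype=float).copy()
    for _ in range(passes):
        out[1:-1] = 0.25 * out[:-2] + 0.5 * out[1:-1] + 0.25 * out[2:]
    return out


def spline_resample(
    points: np.ndarray, n: int, sigma_px: float = 0.5
) -> np.ndarray:
    """Cubic smoothing-spline fit of the centerline, re-evaluated at n
    parameter-uniform points.

    ``sigma_px`` is the per-point residual the fit may spend on noise
    (total budget m * sigma^2); pixel-scale jitter that would otherwise
    dominate a second-derivative quantity like curvature is absorbed while
    the body wave (wavelength ~ body length) passes through essentially
    unchanged.  Falls back to plain arc-length resampling if the fit fails.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    pts = pts[np.concatenate([[True], seg > 1e-9])]
    if len(pts) < 4:
        return resample_by_distance(pts, n)
    try:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], s=len(pts) * sigma_px**2, k=3)
        x, y = splev(np.linspace(0.0, 1.0, n), tck)
        return np.column_stack([x, y])
    except Exception:
        return resample_by_distance(pts, n)


def centerline_length(points: np.ndarray) -> float:
    """Body length: sum of Euclidean distances between consecutive points."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def extract_centerline(
    boundary: np.ndarray,
    head: np.ndarray,
    tail: np.ndarray,
    n: int = 120,
    r: int = 10,
    k: int = 2,
    pairing: str = "perpendicular",
    smooth_passes: int = 2,
    spline_sigma_px: float = 0.5,
) -> Centerline:
    """Boundary + endpoints -> centerline, the composed per-frame step.

    On top of the raw pairing this applies light endpoint-preserving 1-2-1
    smoothing (``smooth_passes``) and then a smoothing-spline refit
    (``spline_sigma_px``) so downstream curvature is not dominated by pixel
    jitter; set both to 0 for the raw paired midline."""
    split = make_contour_split(boundary, head, tail, n=n)
    cl = compute_centerline(split, r=r, k=k, pairing=pairing)
    pts = cl.points
    if smooth_passes > 0:
        pts = smooth_polyline(pts, passes=smooth_passes)
    if spline_sigma_px > 0:
        pts = spline_resample(pts, n, sigma_px=spline_sigma_px)
    if smooth_passes > 0 or spline_sigma_px > 0:
        return Centerline(points=pts)
    return cl
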