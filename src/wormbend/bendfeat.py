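"""Per-frame geometric features of the centerline.

From a centerline this module derives the pharynx point (one tenth of the
body arc length from the head), the signed curvature at every point
(Menger three-point curvature, sign from the turn direction), inflection
points where the curvature changes sign, peak points of maximum |curvature|
between consecutive inflections, an error-checking pass that restores the
inflection/peak alternation when noise produces redundant features, and the
bend angle alpha at each peak (smaller alpha = deeper bend; the smallest
alpha over the body is the maximum bending amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .midline import Centerline


@dataclass
class FeatureSet:
    """Feature points of one frame's centerline."""

    pharynx: np.ndarray            # (x, y)
    pharynx_index: int
    kappa: np.ndarray              # signed curvature per centerline point, 1/px
    inflections: list[int]         # centerline indices, strictly increasing
    peaks: list[int]               # centerline indices, strictly increasing
    peak_points: np.ndarray        # (n_peaks, 2)
    alphas: np.ndarray             # interior angle at each peak, degrees
    max_amplitude_angle: float | None = None  # min alpha; None when no peaks

    def __post_init__(self) -> None:
        if len(self.alphas):
            self.max_amplitude_angle = float(np.min(self.alphas))


def pharynx_point(c: Centerline) -> tuple[np.ndarray, int]:
    """First centerline point at cumulative arc length >= L/10 from the head.

    The pharynx of an adult worm spans roughly the anterior tenth of the
    ~1 mm body, so one tenth of the centerline length marks its posterior
    end — the anterior anchor of the bend-counting chord.
    """
    pts = c.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = int(np.searchsorted(cum, c.L / 10.0))
    idx = max(idx, 1)  # never the head point itself
    return pts[idx], idx


def signed_curvature(
    c: Centerline | np.ndarray, smooth_window: int = 0
) -> np.ndarray:
    """Menger curvature with a turn-direction sign at each interior point.

    kappa_i is the inverse circumradius of (C_{i-1}, C_i, C_{i+1}); the sign
    is that of the cross product (C_i - C_{i-1}) x (C_{i+1} - C_i), i.e.
    positive for clockwise turning in image coordinates (y down).  Endpoints
    copy their neighbor.  ``smooth_window`` > 1 applies a centered moving
    average to the signed values.
    """
    pts = c.points if isinstance(c, Centerline) else np.asarray(c, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for curvature")
    a = pts[:-2]
    b = pts[1:-1]
    d = pts[2:]
    ab = b - a
    bd = d - b
    ad = d - a
    la = np.linalg.norm(ab, axis=1)
    lb = np.linalg.norm(bd, axis=1)
    lc = np.linalg.norm(ad, axis=1)
    if np.any(la == 0) or np.any(lb == 0):
        raise ValueError("duplicate consecutive centerline points")
    cross = ab[:, 0] * bd[:, 1] - ab[:, 1] * bd[:, 0]
    denom = la * lb * lc
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa_mid = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    kappa = np.empty(len(pts))
    kappa[1:-1] = kappa_mid
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    if smooth_window and smooth_window > 1:
        kappa = uniform_filter1d(kappa, size=smooth_window, mode="nearest")
    return kappa


def inflection_points(kappa: np.ndarray) -> list[int]:
    """Indices where the signed curvature changes sign.

    A sign change kappa_i * kappa_{i+1} < 0 records index i+1, the first
    point after the change.  A maximal run of exact zeros flanked by
    opposite signs counts as one inflection at the run's midpoint.
    """
    kappa = np.asarray(kappa, dtype=float)
    sign = np.sign(kappa)
    nz = np.nonzero(sign)[0]
    out: list[int] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] >= 0:
            continue
        if b == a + 1:
            out.append(int(b))
        else:  # zero run between opposite signs -> one inflection at midpoint
            out.append(int(round((a + 1 + b - 1) / 2.0)))
    return out


def peak_points(
    kappa: np.ndarray, inflections: list[int], min_seg_pts: int = 3
) -> list[int]:
    """Index of max |kappa| in each segment between consecutive boundaries.

    Boundaries are the head, every inflection, and the tail; segments
    shorter than min_seg_pts points yield no peak, and neither do flat
    (kappa == 0 throughout) segments.  Ties break toward the lower index.
    """
    kappa = np.asarray(kappa, dtype=float)
    n = len(kappa)
    bounds = [0] + list(inflections) + [n]
    peaks: list[int] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < min_seg_pts:
            continue
        seg = np.abs(kappa[lo:hi])
        if seg.max() == 0:
            continue
        peaks.append(lo + int(np.argmax(seg)))  # argmax ties -> lowest index
    return peaks


def _arc_positions(c: Centerline) -> np.ndarray:
    seg = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def check_feature_points(
    inflections: list[int],
    peaks: list[int],
    c: Centerline,
    kappa: np.ndarray,
    kappa_min: float | None = None,
    min_sep_frac: float = 0.02,
    min_seg_pts: int = 3,
) -> tuple[list[int], list[int]]:
    """Remove redundant feature points and restore strict alternation.

    Inflection pairs closer than min_sep (arc length, default 2% of L) merge
    into the one with the larger adjacent |kappa| contrast; peaks with
    |kappa| below kappa_min (default 0.25/L) are dropped and their flanking
    inflections re-merged.  Afterwards every pair of consecutive inflections
    brackets exactly one peak (the FeatureSet alternation invariant).
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa_min is None:
        kappa_min = 0.25 / c.L
    min_sep = min_sep_frac * c.L
    arc = _arc_positions(c)

    infl = sorted(set(int(i) for i in inflections))

    # merge inflection pairs closer than min_sep, keeping the stronger one
    def contrast(i: int) -> float:
        lo, hi = max(0, i - 2), min(len(kappa) - 1, i + 2)
        return float(np.abs(kappa[lo]) + np.abs(kappa[hi]))

    merged = True
    while merged and len(infl) > 1:
        merged = False
        for a, b in zip(infl[:-1], infl[1:]):
            if arc[b] - arc[a] < min_sep:
                infl.remove(a if contrast(a) < contrast(b) else b)
                merged = True
                break

    # recompute peaks per segment, dropping weak ones and merging the
    # flanking inflections whenever a between-inflection segment loses its
    # peak, until the alternation invariant holds
    while True:
        cand = peak_points(kappa, infl, min_seg_pts=min_seg_pts)
        cand = [p for p in cand if np.abs(kappa[p]) >= kappa_min]
        empty = None
        for a, b in zip(infl[:-1], infl[1:]):
            if not any(a <= p < b for p in cand):
                empty = (a, b)
                break
        if empty is None:
            return infl, cand
        a, b = empty
        infl.remove(a if contrast(a) < contrast(b) else b)


def bend_angles(
    peaks: list[int], inflections: list[int], c: Centerline
) -> np.ndarray:
    """Interior angle alpha (degrees) at each peak.

    The angle is formed by the segments from the peak to its two flanking
    boundaries (adjacent inflection points, or the head/tail endpoint for
    the outermost segments).  Deeper bends give smaller angles.
    """
    pts = c.points
    n = len(pts)
    bounds = np.array([0] + list(inflections) + [n - 1])
    out = np.empty(len(peaks))
    for j, p in enumerate(peaks):
        below = bounds[bounds < p]
        above = bounds[bounds > p]
        lo = int(below[-1]) if len(below) else 0
        hi = int(above[0]) if len(above) else n - 1
        v1 = pts[lo] - pts[p]
        v2 = pts[hi] - pts[p]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            out[j] = 180.0
            continue
        cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
        out[j] = float(np.degrees(np.arccos(cosang)))
    return out


def extract_features(
    c: Centerline,
    smooth_window: int = 5,
    kappa_min: float | None = None,
    min_sep_frac: float = 0.02,
    min_seg_pts: int = 3,
) -> FeatureSet:
    """Centerline -> full per-frame FeatureSet (the composed step)."""
    ph, ph_idx = pharynx_point(c)
    kappa = signed_curvature(c, smooth_window=smooth_window)
    raw_infl = inflection_points(kappa)
    raw_peaks = peak_points(kappa, raw_infl, min_seg_pts=min_seg_pts)
    infl, peaks = check_feature_points(
        raw_infl, raw_peaks, c, kappa,
        kappa_min=kappa_min, min_sep_frac=min_sep_frac, min_seg_pts=min_seg_pts,
    )
    alphas = bend_angles(peaks, infl, c)
    return FeatureSet(
        pharynx=ph,
        pharynx_index=ph_idx,
        kappa=kappa,
        inflections=infl,
        peaks=peaks,
        peak_points=c.points[peaks] if peaks else np.empty((0, 2)),
        alphas=alphas,
    )
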