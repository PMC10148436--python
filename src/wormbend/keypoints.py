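"""Head and tail localization.

Three cooperating pieces:

* the DSNT (differentiable spatial-to-numerical transform) forward math —
  softmax heatmap normalization, probability-weighted coordinate readout,
  the Euclidean + Jensen-Shannon regularized loss, and the PCK metric used
  to score keypoint predictions;
* classical first-frame identification: the sharpest boundary point marks
  the tail (smallest three-point interior angle) and the brighter end
  region marks the head, with conflict flagging when the two cues disagree;
* frame-to-frame tracking that keeps head/tail identity by minimizing the
  head-to-head plus tail-to-tail distance between consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, softmax


# ---------------------------------------------------------------------------
# DSNT coordinate regression math


@dataclass
class NormalizedHeatmap:
    """Softmax-normalized heatmap with its coordinate matrices.

    Cell (i, j) (1-based) of the coordinate matrices holds
    x_j = (2j - W - 1)/W and y_i = (2i - H - 1)/H, i.e. pixel-center
    coordinates scaled to the open interval (-1, 1).
    """

    probs: np.ndarray  # (H, W), non-negative, sums to 1
    X: np.ndarray      # (H, W)
    Y: np.ndarray      # (H, W)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape


def coordinate_matrices(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pixel-center coordinate grids for an h x w heatmap."""
    j = np.arange(1, w + 1, dtype=float)
    i = np.arange(1, h + 1, dtype=float)
    x = (2.0 * j - w - 1.0) / w
    y = (2.0 * i - h - 1.0) / h
    return np.tile(x, (h, 1)), np.tile(y[:, None], (1, w))


def normalize_heatmap(m: np.ndarray) -> NormalizedHeatmap:
    """Softmax over all cells of the raw heatmap."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("heatmap must be a non-empty 2-D array")
    if not np.all(np.isfinite(m)):
        raise ValueError("heatmap must be finite")
    probs = softmax(m, axis=None)
    X, Y = coordinate_matrices(*m.shape)
    return NormalizedHeatmap(probs=probs, X=X, Y=Y)


def dsnt_coordinates(m_norm: NormalizedHeatmap) -> tuple[float, float]:
    """Probability-weighted mean coordinate (Frobenius inner products)."""
    x = float(np.sum(m_norm.probs * m_norm.X))
    y = float(np.sum(m_norm.probs * m_norm.Y))
    return x, y


def norm_to_pixel(
    coord: tuple[float, float], image_size: tuple[int, int]
) -> tuple[float, float]:
    """Map normalized (-1, 1) coordinates to 0-based pixel centers of an
    (height, width) image."""
    h, w = image_size
    x, y = coord
    return ((x + 1.0) * w - 1.0) / 2.0, ((y + 1.0) * h - 1.0) / 2.0


def gaussian_target(
    p: tuple[float, float], shape: tuple[int, int], sigma_cells: float = 1.0
) -> np.ndarray:
    """Isotropic Gaussian of spread sigma (in heatmap cells) centered at the
    normalized coordinate p, discretized on the grid and renormalized."""
    if sigma_cells <= 0:
        raise ValueError("sigma_cells must be positive")
    h, w = shape
    X, Y = coordinate_matrices(h, w)
    # one cell spans 2/W in x and 2/H in y on the normalized axes
    dx = (X - p[0]) / (2.0 / w)
    dy = (Y - p[1]) / (2.0 / h)
    g = np.exp(-(dx**2 + dy**2) / (2.0 * sigma_cells**2))
    total = g.sum()
    if total == 0:
        raise ValueError("Gaussian target underflowed; p far outside the grid")
    return g / total


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence between two probability grids (nats)."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    m = 0.5 * (p + q)
    return float(0.5 * np.sum(rel_entr(p, m)) + 0.5 * np.sum(rel_entr(q, m)))


def dsnt_loss(
    m_norm: NormalizedHeatmap,
    p: tuple[float, float],
    lam: float = 0.0,
    sigma_cells: float = 1.0,
) -> float:
    """Euclidean distance ||p - mu||_2 plus lambda times the JS divergence
    between the normalized heatmap and a Gaussian target centered at p."""
    if lam < 0:
        raise ValueError("regularization coefficient must be >= 0")
    mu = np.array(dsnt_coordinates(m_norm))
    loss = float(np.linalg.norm(np.asarray(p, dtype=float) - mu))
    if lam > 0:
        target = gaussian_target(p, m_norm.shape, sigma_cells)
        loss += lam * js_divergence(m_norm.probs, target)
    return loss


def pck(
    predicted: np.ndarray, truth: np.ndarray, n_pixels: float = 8.0
) -> float:
    """Fraction of predictions within n pixels (inclusive) of ground truth."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if predicted.shape != truth.shape:
        raise ValueError(
            f"prediction/truth length mismatch: {predicted.shape} vs {truth.shape}"
        )
    dist = np.linalg.norm(predicted - truth, axis=1)
    return float(np.mean(dist <= n_pixels))


# ---------------------------------------------------------------------------
# Classical first-frame identification and tracking


@dataclass
class HeadTailPair:
    head: np.ndarray  # (x, y) pixels
    tail: np.ndarray
    source: str = "tracked"  # dsnt | curvature | grayscale | manual | tracked
    conflict: bool = False

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)
        if np.allclose(self.head, self.tail):
            raise ValueError("head and tail must differ")


class EndpointsNotFound(RuntimeError):
    pass


def _resample_closed(boundary: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed contour to n points at equal arc length."""
    pts = np.asarray(boundary, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def boundary_sharpness(
    boundary: np.ndarray, span_frac: float = 0.05
) -> np.ndarray:
    """Interior angle (degrees) at every vertex of the closed contour.

    The angle at vertex i is formed with the two contour points one chord
    span before and after it, the span being span_frac of the perimeter;
    those points are interpolated at exact arc-length offsets, so the result
    depends only on the contour geometry — not on where the tracing started
    or which way it ran.  Small angles mean sharp features (worm ends).
    """
    pts = np.asarray(boundary, dtype=float)
    n = len(pts)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perim = s[-1]
    if perim == 0:
        raise ValueError("degenerate contour")
    span = span_frac * perim

    def at_arc(target: np.ndarray) -> np.ndarray:
        target = np.mod(target, perim)
        x = np.interp(target, s, closed[:, 0])
        y = np.interp(target, s, closed[:, 1])
        return np.column_stack([x, y])

    fwd = at_arc(s[:n] + span) - pts
    bwd = at_arc(s[:n] - span) - pts
    dot = np.sum(fwd * bwd, axis=1)
    norms = np.linalg.norm(fwd, axis=1) * np.linalg.norm(bwd, axis=1)
    cosang = np.clip(dot / np.maximum(norms, 1e-12), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def endpoints_by_curvature(
    boundary: np.ndarray,
    span_frac: float = 0.05,
    min_separation_frac: float = 0.25,
    sharp_max_deg: float = 120.0,
    spur_min_deg: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate the two sharpest, well-separated boundary points.

    Returns (endA, endB, tail_guess): the sharper of the two (smallest
    interior angle) is the tail guess — the worm's tail tapers to a finer
    point than the blunt head.  Raises EndpointsNotFound when the contour has
    no two distinct sharp features (e.g. a circle).
    """
    boundary = np.asarray(boundary, dtype=float)
    if len(boundary) < 30:
        raise EndpointsNotFound("contour too short for endpoint detection")
    angles = boundary_sharpness(boundary, span_frac=span_frac)
    # near-zero angles are single-pixel boundary spurs (the walk doubling
    # back on itself), not body ends; a real tip subtends several degrees
    angles = np.where(angles < spur_min_deg, np.inf, angles)
    n = len(boundary)
    closed = np.vstack([boundary, boundary[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[:n]
    perim = s[-1] + seg[-1]
    i0 = int(np.argmin(angles))
    arc_dist = np.abs(s - s[i0])
    arc_dist = np.minimum(arc_dist, perim - arc_dist)
    masked = np.where(arc_dist >= min_separation_frac * perim, angles, np.inf)
    i1 = int(np.argmin(masked))
    if not (angles[i0] < sharp_max_deg and masked[i1] < sharp_max_deg):
        raise EndpointsNotFound(
            "endpoints not found: fewer than two well-separated sharp "
            f"boundary points (sharpest angles {angles[i0]:.1f} and "
            f"{masked[i1]:.1f} deg, threshold {sharp_max_deg:.0f})"
        )
    i0 = _refine_tip(boundary, s, perim, i0, span_frac)
    i1 = _refine_tip(boundary, s, perim, i1, span_frac)
    end_a, end_b = boundary[i0], boundary[i1]
    tail_guess = end_a if angles[i0] <= angles[i1] else end_b
    return end_a, end_b, tail_guess


def _refine_tip(
    boundary: np.ndarray, s: np.ndarray, perim: float, idx: int, span_frac: float
) -> int:
    """Snap a sharp-vertex hit to the geometric apex of the tip.

    On a rounded tip several vertices share a similar three-point angle and
    the sharpness argmin can land a couple of pixels off the apex; within a
    window of one chord span around the hit, the vertex farthest from the
    chord joining the window ends is the apex proper.
    """
    offset = np.mod(s - s[idx] + perim / 2.0, perim) - perim / 2.0
    window = np.nonzero(np.abs(offset) <= span_frac * perim)[0]
    if len(window) < 3:
        return idx
    pts = boundary[window]
    a = boundary[window[np.argmin(offset[window])]]
    b = boundary[window[np.argmax(offset[window])]]
    chord = b - a
    nrm = np.linalg.norm(chord)
    if nrm < 1e-9:
        return idx
    d = np.abs(chord[0] * (pts[:, 1] - a[1]) - chord[1] * (pts[:, 0] - a[0])) / nrm
    best = d.max()
    cands = window[d >= best - 1e-6]
    # near-ties resolve to the vertex closest to the sharpness hit
    return int(cands[np.argmin(np.abs(offset[cands]))])


def head_by_grayscale(
    frame: np.ndarray,
    end_a: np.ndarray,
    end_b: np.ndarray,
    radius_px: float = 6.0,
    min_contrast: float = 3.0,
    brighter_is_head: bool = True,
    mask: np.ndarray | None = None,
) -> str | None:
    """Label the head end by median brightness of the two end regions.

    The end region is a disc of ``radius_px`` around each endpoint,
    restricted to worm pixels when a ``mask`` is supplied (the worm is thin
    at its tips, so an unrestricted disc is dominated by background).
    Returns "A", "B", or None when the contrast is below min_contrast
    (ambiguous).  ``brighter_is_head`` flips the polarity: lighting
    conditions vary and the literature disagrees on which end is darker.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape

    def disc_median(c):
        x0, y0 = float(c[0]), float(c[1])
        xi = np.arange(max(0, int(x0 - radius_px)), min(w, int(x0 + radius_px) + 1))
        yi = np.arange(max(0, int(y0 - radius_px)), min(h, int(y0 + radius_px) + 1))
        if xi.size == 0 or yi.size == 0:
            raise ValueError("endpoint outside image")
        xx, yy = np.meshgrid(xi, yi)
        sel = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius_px**2
        if mask is not None:
            inside = mask[yy[sel], xx[sel]].astype(bool)
            if inside.any():
                return float(np.median(frame[yy[sel], xx[sel]][inside]))
        return float(np.median(frame[yy[sel], xx[sel]]))

    med_a, med_b = disc_median(end_a), disc_median(end_b)
    if abs(med_a - med_b) < min_contrast:
        return None
    brighter = "A" if med_a > med_b else "B"
    if brighter_is_head:
        return brighter
    return "B" if brighter == "A" else "A"


def resolve_first_frame(
    end_a: np.ndarray,
    end_b: np.ndarray,
    curvature_vote: str,
    grayscale_vote: str | None,
    assume_head: str | None = None,
) -> HeadTailPair:
    """Combine the curvature and grayscale votes into the first-frame pair.

    Both votes name the head end ("A" or "B"); grayscale may be None
    (ambiguous contrast).  Agreement yields conflict=False.  On disagreement
    the ``assume_head`` override ("brighter"/"grayscale" or
    "sharper"/"curvature"/"endA"/"endB") decides and the pair is flagged;
    without an override a RuntimeError lists both votes, mirroring the need
    for manual recognition.
    """
    ends = {"A": np.asarray(end_a, float), "B": np.asarray(end_b, float)}

    def pair(head_label: str, source: str, conflict: bool) -> HeadTailPair:
        tail_label = "B" if head_label == "A" else "A"
        return HeadTailPair(
            head=ends[head_label], tail=ends[tail_label], source=source,
            conflict=conflict,
        )

    if grayscale_vote is None:
        return pair(curvature_vote, "curvature", conflict=True)
    if curvature_vote == grayscale_vote:
        return pair(curvature_vote, "curvature", conflict=False)
    if assume_head in ("brighter", "grayscale"):
        return pair(grayscale_vote, "grayscale", conflict=True)
    if assume_head in ("sharper", "curvature"):
        return pair(curvature_vote, "curvature", conflict=True)
    if assume_head in ("endA", "endB"):
        return pair(assume_head[-1], "manual", conflict=True)
    raise RuntimeError(
        "head/tail votes conflict and no --assume-head override was given: "
        f"curvature says head={curvature_vote}, grayscale says "
        f"head={grayscale_vote}; manual recognition required"
    )


def track_head_tail(
    prev: HeadTailPair,
    candidates: tuple[np.ndarray, np.ndarray],
    tie_eps: float = 1e-9,
) -> HeadTailPair:
    """Assign the two current endpoints to head/tail by minimal motion.

    Of the two possible assignments, the one minimizing head-to-head plus
    tail-to-tail distance to the previous frame wins; exact ties keep the
    candidates' given order.
    """
    p, q = (np.asarray(c, dtype=float) for c in candidates)
    cost_pq = np.linalg.norm(p - prev.head) + np.linalg.norm(q - prev.tail)
    cost_qp = np.linalg.norm(q - prev.head) + np.linalg.norm(p - prev.tail)
    if abs(cost_pq - cost_qp) <= tie_eps:
        head, tail = p, q
    elif cost_pq < cost_qp:
        head, tail = p, q
    else:
        head, tail = q, p
    return HeadTailPair(head=head, tail=tail, source="tracked", conflict=False)
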