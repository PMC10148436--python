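"""Frame preprocessing: raw grayscale frame -> clean single-worm binary mask.

Shadow removal, optional background subtraction, 5x5 adaptive local
thresholding, morphological closing with hole filling, and small-object
removal, yielding a :class:`WormMask` with an ordered closed boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology


@dataclass
class WormMask:
    """Binary foreground of the single worm in one frame."""

    mask: np.ndarray       # bool (H, W), worm = True
    boundary: np.ndarray   # (P, 2) ordered closed contour, pixel (x, y)
    area: int

    def __post_init__(self) -> None:
        self.area = int(self.area)


class NoWormError(RuntimeError):
    """No connected component large enough to be the worm."""


def estimate_background_gray(frame: np.ndarray) -> int:
    """Most frequent gray level — the background of a sparse scene."""
    counts = np.bincount(np.asarray(frame, dtype=np.uint8).ravel(), minlength=256)
    return int(np.argmax(counts))


def remove_shadow(
    frame: np.ndarray,
    band: tuple[float, float] | None = None,
    band_half_width: float = 15.0,
) -> np.ndarray:
    """Replace shadow-band pixels by the background estimate.

    Shadows around the worm sit in a gray band between the worm and the
    background intensity.  By default the band is centered on the midpoint of
    the darkest-pixel estimate and the background mode, +- band_half_width
    gray levels; pixels inside the band become the background gray, the worm
    band is untouched.
    """
    frame = np.asarray(frame)
    bg = estimate_background_gray(frame)
    if band is None:
        worm_est = float(np.percentile(frame, 1))
        mid = (worm_est + bg) / 2.0
        band = (mid - band_half_width, mid + band_half_width)
    lo, hi = band
    out = frame.copy()
    sel = (frame.astype(float) >= lo) & (frame.astype(float) <= hi)
    out[sel] = bg
    return out


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Absolute difference |frame - background|: worm becomes bright on dark."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame.astype(np.int16) - background.astype(np.int16))
    return diff.astype(np.uint8)


def adaptive_threshold(
    frame: np.ndarray,
    window: int = 5,
    offset: float = 5.0,
    polarity: str = "dark",
) -> np.ndarray:
    """Adaptive local threshold with a moving-window mean.

    polarity="dark": foreground where pixel < local mean - offset (raw
    dark-worm frames); polarity="bright": pixel > local mean + offset
    (background-subtracted frames).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if polarity not in ("dark", "bright"):
        raise ValueError(f"unknown polarity {polarity!r}")
    # exact integer window sums: the decision "darker than local mean minus
    # offset" must not depend on floating-point summation order, or mirrored
    # frames can segment differently at threshold-tie pixels
    f = np.asarray(frame, dtype=np.int64)
    kernel = np.ones(window, dtype=np.int64)
    sums = ndimage.correlate1d(f, kernel, axis=0, mode="nearest")
    sums = ndimage.correlate1d(sums, kernel, axis=1, mode="nearest")
    area = window * window
    if polarity == "dark":
        return f * area < sums - offset * area
    return f * area > sums + offset * area


def close_and_fill(mask: np.ndarray, hole_max_px: int = 5000) -> np.ndarray:
    """3x3 morphological closing, then fill interior holes up to hole_max_px."""
    mask = np.asarray(mask, dtype=bool)
    closed = morphology.closing(mask, footprint=np.ones((3, 3), dtype=bool))
    # label background 4-connected so diagonal leaks do not merge holes w/ outside
    holes = ~closed
    lab, n = ndimage.label(holes, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border_labels = set(np.unique(lab[0, :])) | set(np.unique(lab[-1, :])) | set(
        np.unique(lab[:, 0])
    ) | set(np.unique(lab[:, -1]))
    out = closed.copy()
    for lbl in range(1, n + 1):
        if lbl in border_labels:
            continue
        sel = lab == lbl
        if sel.sum() <= hole_max_px:
            out[sel] = True
    return out


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor tracing of the outer boundary of a single component.

    Returns an ordered closed contour of boundary pixel centers as (x, y),
    8-connected, oriented clockwise in image coordinates (y down).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    # uppermost-leftmost foreground pixel; entered from the left
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    if rows.size == 1:
        return np.array([[start[1], start[0]]], dtype=float)

    def nbr(p, k):
        return (p[0] + _MOORE[k][0], p[1] + _MOORE[k][1])

    def inside(p):
        return 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]

    contour = [start]
    # backtrack direction: came from the west neighbor
    prev_dir = 6  # index of (0, -1)
    cur = start
    second = None
    limit = 4 * int(mask.sum()) + 8
    while len(contour) < limit:
        for step in range(1, 9):
            k = (prev_dir + step) % 8
            cand = nbr(cur, k)
            if inside(cand):
                break
        else:  # isolated pixel
            break
        if second is None:
            second = cand
        elif cur == start and cand == second:
            break  # Jacob's stopping criterion: start re-entered the same way
        contour.append(cand)
        prev_dir = (k + 5) % 8  # direction pointing back at cur, advanced by 1
        cur = cand
    while len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    pts = np.array([[c, r] for r, c in contour], dtype=float)
    # enforce clockwise orientation in image coordinates (positive shoelace
    # area with y pointing down)
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    return pts


def keep_worm_component(
    mask: np.ndarray, min_area: int = 100, frame_index: int | None = None
) -> WormMask:
    """Drop components below min_area, keep the largest survivor, trace it."""
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        raise NoWormError(_no_worm_msg(frame_index))
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    areas[areas < min_area] = 0
    if areas.max() == 0:
        raise NoWormError(_no_worm_msg(frame_index))
    keep = int(np.argmax(areas))
    worm = lab == keep
    boundary = trace_boundary(worm)
    return WormMask(mask=worm, boundary=boundary, area=int(worm.sum()))


def _no_worm_msg(frame_index: int | None) -> str:
    if frame_index is None:
        return "no worm found: no component reaches min_area"
    return f"no worm found in frame {frame_index}: no component reaches min_area"


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray | None = None,
    window: int = 5,
    offset: float = 5.0,
    min_area: int = 100,
    hole_max_px: int = 5000,
    shadow_removal: bool = False,
    frame_index: int | None = None,
) -> WormMask:
    """Full preprocessing chain for one frame.

    With a background frame the input is background-subtracted (worm becomes
    bright) before thresholding; otherwise the raw dark-on-bright frame is
    thresholded directly, optionally after shadow removal.
    """
    img = np.asarray(frame)
    if background is not None:
        img = subtract_background(img, background)
        polarity = "bright"
    else:
        if shadow_removal:
            img = remove_shadow(img)
        polarity = "dark"
    binary = adaptive_threshold(img, window=window, offset=offset, polarity=polarity)
    binary = close_and_fill(binary, hole_max_px=hole_max_px)
    return keep_worm_component(binary, min_area=min_area, frame_index=frame_index)
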