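"""Synthetic single-worm swim videos with exact ground truth.

Renders a dark, tapered worm on a bright field whose midline undulates as a
traveling sine wave expressed in arc length, so body length is conserved
frame to frame.  Every video carries per-frame ground-truth head/tail
coordinates, the analytic midline, and an analytically derived expected
body-bend count, making the whole downstream pipeline testable offline.

Coordinates are pixel units, x rightward, y downward, 0-based pixel centers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree


def default_half_width_profile(body_length_px: float) -> Callable[[np.ndarray], np.ndarray]:
    """Tapered half-width w(u) over normalized arc position u in [0, 1].

    Mid-body half-width is 5% of body length; the head end is blunt (~2 px)
    and the tail end sharp (~1 px), so the smallest boundary angle sits at
    the tail — the cue the classical tail-identification rule relies on.
    """
    w_mid = 0.05 * body_length_px
    u_ctrl = np.array([0.0, 0.12, 0.5, 0.88, 1.0])
    w_ctrl = np.array([2.0, 0.8 * w_mid, w_mid, 0.55 * w_mid, 1.0])
    pch = PchipInterpolator(u_ctrl, w_ctrl)

    def profile(u: np.ndarray) -> np.ndarray:
        return np.asarray(pch(np.clip(u, 0.0, 1.0)))

    return profile


@dataclass
class SwimParams:
    """Parameters of one synthetic swim video.

    Defaults emulate the acquisition the method targets: a ~1 mm adult worm
    imaged at ~4 um/px and 20 fps, swimming at ~0.5 Hz with a lateral
    amplitude of 8% of body length and one undulation wavelength on the body.
    """

    body_length_px: float = 120.0
    amplitude_px: float = 9.6
    wavelength_px: float | None = None  # default: one body length
    frequency_hz: float = 0.5
    fps: float = 20.0
    duration_s: float = 30.0
    image_size: tuple[int, int] = (200, 200)  # (height, width)
    worm_gray: int = 60
    background_gray: int = 200
    head_brightness_delta: int = 30
    noise_sd: float = 2.0
    drift_px_per_s: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    half_width_profile: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be non-negative")
        if not self.worm_gray < self.background_gray:
            raise ValueError("dark worm on bright field requires worm_gray < background_gray")
        if self.wavelength_px is None:
            self.wavelength_px = self.body_length_px
        if self.half_width_profile is None:
            self.half_width_profile = default_half_width_profile(self.body_length_px)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def max_half_width(self) -> float:
        u = np.linspace(0.0, 1.0, 201)
        return float(np.max(self.half_width_profile(u)))


@dataclass
class GroundTruth:
    """Per-frame truth for a synthetic video.

    ``expected_bend_count`` comes from the analytic midline alone (never from
    the image pipeline); ``count_tolerance`` documents the +-1 boundary effect
    of a partial half-period at the end of the video.
    """

    heads: np.ndarray          # (F, 2) pixel (x, y)
    tails: np.ndarray          # (F, 2)
    midlines: list[np.ndarray]  # F arrays of (m, 2), ordered head -> tail
    phases: np.ndarray         # (F,) wave phase at the head, radians
    analytic_distance: np.ndarray  # (F,) signed peak-to-chord distance, px
    expected_bend_count: int
    count_tolerance: int = 1

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.heads)),
                "head_x": self.heads[:, 0],
                "head_y": self.heads[:, 1],
                "tail_x": self.tails[:, 0],
                "tail_y": self.tails[:, 1],
                "phase": self.phases,
            }
        )
        df.to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "expected_bend_count": int(self.expected_bend_count),
                    "count_tolerance": int(self.count_tolerance),
                    "n_frames": int(len(self.heads)),
                },
                indent=2,
            )
        )


def make_midline(params: SwimParams, t: float, n_points: int | None = None) -> np.ndarray:
    """Analytic midline polyline at time ``t``, ordered head -> tail.

    The lateral displacement follows y(s, t) = A sin(2 pi s / lambda
    - 2 pi f t) with s the arc position from the head; the axial coordinate
    is recovered by integrating sqrt(1 - (dy/ds)^2) so the polyline arc
    length equals ``body_length_px`` (unit-speed construction).  The body is
    re-centered on the image center plus the drift offset at time t.
    """
    if not (0.0 <= t <= params.duration_s + 1e-9):
        raise ValueError(f"t={t} outside [0, {params.duration_s}]")
    L = params.body_length_px
    lam = params.wavelength_px
    A = params.amplitude_px
    slope_max = A * 2.0 * np.pi / lam
    if slope_max >= 1.0:
        raise ValueError(
            "amplitude * 2*pi / wavelength must be < 1 for an arc-length "
            f"parameterized wave (got {slope_max:.3f})"
        )
    if n_points is None:
        n_points = max(201, int(2 * L) + 1)
    s = np.linspace(0.0, L, n_points)
    phase = 2.0 * np.pi * s / lam - 2.0 * np.pi * params.frequency_hz * t
    y = A * np.sin(phase)
    dyds = A * (2.0 * np.pi / lam) * np.cos(phase)
    dxds = np.sqrt(np.maximum(1.0 - dyds**2, 0.0))
    x = np.concatenate([[0.0], np.cumsum((dxds[1:] + dxds[:-1]) / 2.0 * np.diff(s))])

    h, w = params.image_size
    cx = (w - 1) / 2.0 + params.drift_px_per_s[0] * t
    cy = (h - 1) / 2.0 + params.drift_px_per_s[1] * t
    x = x - x.mean() + cx
    y = y - y.mean() + cy

    margin = params.max_half_width + 2.0
    if x.min() < margin or y.min() < margin or x.max() > w - 1 - margin or y.max() > h - 1 - margin:
        raise ValueError(
            f"worm exceeds image bounds: requires a margin of {margin:.1f} px "
            f"inside a {h}x{w} image (x in [{x.min():.1f}, {x.max():.1f}], "
            f"y in [{y.min():.1f}, {y.max():.1f}])"
        )
    return np.column_stack([x, y])


def render_frame(
    midline: np.ndarray, params: SwimParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rasterize one frame: worm_gray inside the local half-width of the
    midline (head 10% brightened by head_brightness_delta), background_gray
    elsewhere, plus Gaussian noise, clipped to uint8."""
    midline = np.asarray(midline, dtype=float)
    if midline.ndim != 2 or midline.shape[0] < 2:
        raise ValueError("midline must contain at least two points")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    img = np.full((h, w), float(params.background_gray))

    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    max_hw = params.max_half_width

    # inset the drawn spine by the cap radii: the body is the union of discs
    # of radius w(u) centered on the spine between the caps, so the rounded
    # tips land exactly on the stated midline endpoints and the rendered
    # tip-to-tip extent equals the body length
    cap_head = float(params.half_width_profile(np.array([0.0]))[0])
    cap_tail = float(params.half_width_profile(np.array([1.0]))[0])
    lo = np.searchsorted(s, min(cap_head, L / 2))
    hi = np.searchsorted(s, max(L - cap_tail, L / 2), side="right")
    spine = midline[lo:hi]
    s_spine = s[lo:hi]
    if len(spine) < 2:
        spine, s_spine = midline, s

    x0 = max(int(np.floor(midline[:, 0].min() - max_hw - 1)), 0)
    x1 = min(int(np.ceil(midline[:, 0].max() + max_hw + 1)), w - 1)
    y0 = max(int(np.floor(midline[:, 1].min() - max_hw - 1)), 0)
    y1 = min(int(np.ceil(midline[:, 1].max() + max_hw + 1)), h - 1)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)

    tree = cKDTree(spine)
    dist, idx = tree.query(pix, k=1)
    span = max(s_spine[-1] - s_spine[0], 1e-9)
    u = (s_spine[idx] - s_spine[0]) / span
    hw = params.half_width_profile(u)
    inside = dist <= hw
    gray = np.full(pix.shape[0], float(params.worm_gray))
    gray[u <= 0.10] += params.head_brightness_delta
    sub = img[y0 : y1 + 1, x0 : x1 + 1].ravel()
    sub[inside] = gray[inside]
    img[y0 : y1 + 1, x0 : x1 + 1] = sub.reshape(ys.shape)

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def analytic_signed_distance(midline: np.ndarray) -> float:
    """Signed peak-to-chord distance of the analytic midline.

    Chord runs from the pharynx point (one tenth of arc length from the head)
    to the tail; the returned value is the signed perpendicular distance of
    largest magnitude over the body, sign = sign of the 2-D cross product
    (tail - pharynx) x (point - pharynx).  This is the generator's own
    geometry, independent of the image pipeline.
    """
    midline = np.asarray(midline, dtype=float)
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    i_ph = int(np.searchsorted(s, L / 10.0))
    ph = midline[i_ph]
    tl = midline[-1]
    chord = tl - ph
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return 0.0
    rel = midline - ph
    cross = chord[0] * rel[:, 1] - chord[1] * rel[:, 0]
    d = cross / nrm
    return float(d[np.argmax(np.abs(d))])


def count_sign_runs(
    d: Sequence[float], min_run: int = 3, threshold: float = 0.0
) -> int:
    """Count direction reversals in a signed distance signal.

    Maximal same-sign runs of samples with |d| >= threshold qualify when at
    least ``min_run`` long; the first qualifying run counts as one bend and
    each later qualifying run of opposite sign to the last counted adds one.
    Kept deliberately self-contained: this is the generator's independent
    oracle for the counting rule, not a call into the counting module.
    """
    count = 0
    last_sign = 0
    run_sign = 0
    run_len = 0
    for v in list(d) + [0.0]:  # sentinel flushes the final run
        sgn = 0 if abs(v) < threshold or v == 0 else (1 if v > 0 else -1)
        if sgn == run_sign and sgn != 0:
            run_len += 1
            continue
        if run_sign != 0 and run_len >= min_run and run_sign != last_sign:
            count += 1
            last_sign = run_sign
        run_sign, run_len = sgn, (1 if sgn != 0 else 0)
    return count


def generate_swim_video(params: SwimParams) -> tuple[np.ndarray, GroundTruth]:
    """Render all frames and compute ground truth; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    frames = np.empty((params.n_frames, *params.image_size), dtype=np.uint8)
    heads = np.empty((params.n_frames, 2))
    tails = np.empty((params.n_frames, 2))
    phases = np.empty(params.n_frames)
    dists = np.empty(params.n_frames)
    midlines: list[np.ndarray] = []
    for i in range(params.n_frames):
        t = i / params.fps
        ml = make_midline(params, t)
        frames[i] = render_frame(ml, params, rng=rng)
        midlines.append(ml)
        heads[i] = ml[0]
        tails[i] = ml[-1]
        phases[i] = -2.0 * np.pi * params.frequency_hz * t
        dists[i] = analytic_signed_distance(ml)
    threshold = 0.03 * params.body_length_px
    expected = count_sign_runs(dists, min_run=3, threshold=threshold)
    gt = GroundTruth(
        heads=heads,
        tails=tails,
        midlines=midlines,
        phases=phases,
        analytic_distance=dists,
        expected_bend_count=expected,
    )
    return frames, gt


def write_video(
    frames: np.ndarray, gt: GroundTruth, out_dir: str | Path, fmt: str = "png"
) -> Path:
    """Write frames as numbered images plus ground-truth CSV and JSON."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out / f"frame_{i:05d}.{fmt}", frame)
    gt.to_csv(out / "ground_truth.csv")
    gt.summary_json(out / "ground_truth.json")
    return out
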