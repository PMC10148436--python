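"""Body-bend counting from the signed peak-to-chord distance series.

Per frame, every curvature peak gets a signed perpendicular distance to the
chord from the pharynx point to the tail; the signed extreme (largest
magnitude) is that frame's d_max.  A bend is counted each time the series
reaches a maximum in the opposite direction from the bend last counted,
with a persistence rule: at least ``min_run`` consecutive frames around the
maximum must share its direction, and |d_max| must clear a small amplitude
floor so pixel jitter on a near-straight worm cannot flip the sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import segment as seg_mod
from .bendfeat import FeatureSet, extract_features
from .keypoints import (
    HeadTailPair,
    endpoints_by_curvature,
    head_by_grayscale,
    resolve_first_frame,
    track_head_tail,
)
from .midline import extract_centerline

logger = logging.getLogger(__name__)


@dataclass
class DistanceSeries:
    """Per-frame signed maximum peak-to-chord distance."""

    d_max: np.ndarray      # signed pixels; 0.0 when no peaks
    valid: np.ndarray      # bool; False for skipped/coiled/failed frames
    fps: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.d_max)) / self.fps

    def __len__(self) -> int:
        return len(self.d_max)


@dataclass
class BendEvent:
    frame: int
    sign: int
    amplitude: float  # |d_max| at the event frame, pixels


@dataclass
class BendResult:
    total_count: int
    events: list[BendEvent]
    min_run: int
    min_amp_frac: float


def signed_peak_distance(
    peak: np.ndarray, pharynx: np.ndarray, tail: np.ndarray
) -> float:
    """Perpendicular distance from the peak to the pharynx-tail line,
    signed by the side of the chord: sign of the 2-D cross product
    (tail - pharynx) x (peak - pharynx)."""
    peak = np.asarray(peak, dtype=float)
    pharynx = np.asarray(pharynx, dtype=float)
    tail = np.asarray(tail, dtype=float)
    chord = tail - pharynx
    nrm = float(np.linalg.norm(chord))
    if nrm == 0:
        raise ValueError("pharynx and tail coincide; chord undefined")
    rel = peak - pharynx
    cross = chord[0] * rel[1] - chord[1] * rel[0]
    return float(cross / nrm)


def max_distance(
    features: FeatureSet,
    tail: np.ndarray,
    peak_scope: str = "global",
) -> float:
    """Signed extreme of the per-peak distances for one frame.

    Positive peaks contribute their maximum, negative ones their minimum;
    the value of largest magnitude wins.  peak_scope="post-pharynx"
    restricts to peaks posterior to the pharynx index; default is the
    global body maximum.  A frame with no peaks (straight worm) yields 0.
    """
    if peak_scope not in ("global", "post-pharynx"):
        raise ValueError(f"unknown peak_scope {peak_scope!r}")
    pts = features.peak_points
    idxs = features.peaks
    if peak_scope == "post-pharynx":
        keep = [i for i, p in enumerate(idxs) if p >= features.pharynx_index]
        pts = pts[keep] if len(keep) else np.empty((0, 2))
    if len(pts) == 0:
        return 0.0
    d = np.array([signed_peak_distance(p, features.pharynx, tail) for p in pts])
    # near-exact magnitude ties break toward the most anterior peak, so the
    # choice is stable under floating-point-level perturbations (mirroring)
    absd = np.abs(d)
    candidates = np.nonzero(absd >= absd.max() - 1e-6)[0]
    return float(d[candidates[0]])


def count_bends(
    series: DistanceSeries | Sequence[float],
    L_ref: float,
    min_run: int = 3,
    min_amp_frac: float = 0.03,
    count_first: bool = True,
    valid: np.ndarray | None = None,
) -> BendResult:
    """Count direction reversals of the maximum-bend series.

    Frames with |d_max| >= min_amp_frac * L_ref form maximal same-sign runs
    (invalid frames break runs); a run qualifies when at least ``min_run``
    frames long.  The first qualifying run initializes the direction (and
    counts as one bend when ``count_first``); each later qualifying run of
    opposite sign to the last counted one adds a bend, stamped at the run's
    frame of largest |d_max| (earliest on ties).
    """
    if isinstance(series, DistanceSeries):
        d = np.asarray(series.d_max, dtype=float)
        valid_arr = np.asarray(series.valid, dtype=bool)
    else:
        d = np.asarray(series, dtype=float)
        valid_arr = (
            np.ones(len(d), dtype=bool) if valid is None else np.asarray(valid, bool)
        )
    if len(d) == 0:
        raise ValueError("empty distance series")
    threshold = min_amp_frac * L_ref

    events: list[BendEvent] = []
    last_sign = 0
    run_sign = 0
    run_frames: list[int] = []

    def flush() -> None:
        nonlocal last_sign
        if run_sign != 0 and len(run_frames) >= min_run and run_sign != last_sign:
            if last_sign != 0 or count_first:
                amps = np.abs(d[run_frames])
                best = run_frames[int(np.argmax(amps))]  # argmax tie -> earliest
                events.append(
                    BendEvent(frame=best, sign=run_sign, amplitude=float(abs(d[best])))
                )
            last_sign = run_sign

    for i in range(len(d) + 1):
        if i == len(d):
            sgn = 0
        elif not valid_arr[i] or abs(d[i]) < threshold or d[i] == 0:
            sgn = 0
        else:
            sgn = 1 if d[i] > 0 else -1
        if sgn == run_sign and sgn != 0:
            run_frames.append(i)
            continue
        flush()
        run_sign = sgn
        run_frames = [i] if sgn != 0 else []

    return BendResult(
        total_count=len(events),
        events=events,
        min_run=min_run,
        min_amp_frac=min_amp_frac,
    )


@dataclass
class FrameRecord:
    """Everything the pipeline derived from one frame (None when invalid)."""

    index: int
    valid: bool
    stage: str | None = None          # failing stage for invalid frames
    pair: HeadTailPair | None = None
    centerline_points: np.ndarray | None = None
    body_length: float | None = None
    features: FeatureSet | None = None
    d_max: float = 0.0


def process_frame(
    frame: np.ndarray,
    index: int,
    prev_pair: HeadTailPair | None,
    config: "object | None" = None,
    **kw,
) -> FrameRecord:
    """Run segment -> endpoints -> centerline -> features -> distance for
    one frame; any stage failure marks the frame invalid with its stage."""
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig(**kw)
    rec = FrameRecord(index=index, valid=False)
    try:
        rec.stage = "segment"
        wm = seg_mod.segment_frame(
            frame,
            background=cfg.background,
            window=cfg.window,
            offset=cfg.offset,
            min_area=cfg.min_area,
            hole_max_px=cfg.hole_max_px,
            shadow_removal=cfg.shadow_removal,
            frame_index=index,
        )
        rec.stage = "endpoints"
        end_a, end_b, tail_guess = endpoints_by_curvature(wm.boundary)
        if prev_pair is None:
            curvature_vote = "B" if np.allclose(tail_guess, end_a) else "A"
            grayscale_vote = head_by_grayscale(
                frame, end_a, end_b, brighter_is_head=cfg.brighter_is_head,
                mask=wm.mask,
            )
            pair = resolve_first_frame(
                end_a, end_b, curvature_vote, grayscale_vote,
                assume_head=cfg.assume_head,
            )
            if pair.conflict:
                logger.warning("frame %d: head/tail votes conflicted", index)
        else:
            pair = track_head_tail(prev_pair, (end_a, end_b))
        rec.pair = pair
        rec.stage = "centerline"
        cl = extract_centerline(
            wm.boundary, pair.head, pair.tail,
            n=cfg.n, r=cfg.r, k=cfg.k, pairing=cfg.pairing,
        )
        if cl.is_self_intersecting():
            rec.stage = "coiled"
            logger.info("frame %d skipped: coiled (self-intersecting)", index)
            return rec
        rec.centerline_points = cl.points
        rec.body_length = cl.L
        rec.stage = "features"
        feats = extract_features(
            cl,
            smooth_window=cfg.smooth_window,
            kappa_min=cfg.kappa_min,
            min_sep_frac=cfg.min_sep_frac,
            min_seg_pts=cfg.min_seg_pts,
        )
        rec.features = feats
        rec.stage = "distance"
        rec.d_max = max_distance(feats, cl.points[-1], peak_scope=cfg.peak_scope)
        rec.valid = True
        rec.stage = None
    except Exception as exc:  # noqa: BLE001 — per-frame failures never abort
        logger.warning("frame %d invalid at stage %s: %s", index, rec.stage, exc)
    return rec


def run_counter_on_video(
    frames: Sequence[np.ndarray] | np.ndarray,
    fps: float,
    config: "object | None" = None,
    **kw,
) -> tuple[DistanceSeries, BendResult, list[FrameRecord]]:
    """Full pipeline over a video: per-frame records, the distance series,
    and the bend count.  Raises when more than max_invalid_frac of the
    frames fail a stage."""
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig(**kw)
    if fps <= 0:
        raise ValueError("fps must be positive")
    records: list[FrameRecord] = []
    prev_pair: HeadTailPair | None = None
    for i, frame in enumerate(frames):
        rec = process_frame(frame, i, prev_pair, config=cfg)
        records.append(rec)
        if rec.valid and rec.pair is not None:
            prev_pair = rec.pair
    n = len(records)
    if n == 0:
        raise ValueError("no frames")
    invalid = [r for r in records if not r.valid]
    if len(invalid) > cfg.max_invalid_frac * n:
        stages = {}
        for r in invalid:
            stages[r.stage] = stages.get(r.stage, 0) + 1
        raise RuntimeError(
            f"{len(invalid)}/{n} frames invalid (> {cfg.max_invalid_frac:.0%}); "
            f"failures by stage: {stages}"
        )
    series = DistanceSeries(
        d_max=np.array([r.d_max for r in records]),
        valid=np.array([r.valid for r in records]),
        fps=fps,
    )
    lengths = [r.body_length for r in records if r.body_length is not None]
    L_ref = float(np.median(lengths)) if lengths else 1.0
    result = count_bends(
        series,
        L_ref,
        min_run=cfg.min_run,
        min_amp_frac=cfg.min_amp_frac,
        count_first=cfg.count_first,
    )
    return series, result, records
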