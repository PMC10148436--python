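"""Frame input: video files or ordered image-sequence directories.

Image sequences (PNG/TIFF, sorted by filename) are the guaranteed path.
Video files (AVI/MP4) are decoded through imageio when a suitable plugin
is available; without one a clear error points at the sequence path.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

_SEQ_EXT = {".png", ".tif", ".tiff"}


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        frame = np.round(frame[..., :3].mean(axis=-1))
    return frame.astype(np.uint8)


def read_frames(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Load all frames as a (F, H, W) uint8 array.

    Returns (frames, fps); fps is None for image-sequence directories and
    for containers whose metadata lacks it.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input not found: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _SEQ_EXT)
        if not files:
            raise ValueError(f"no PNG/TIFF frames in directory {p}")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
        return frames, None
    try:
        raw = iio.imread(p, index=None)
    except Exception as exc:
        raise RuntimeError(
            f"could not decode {p} (video codec support may be missing in "
            "this environment); supply a PNG/TIFF frame directory instead"
        ) from exc
    frames = np.stack([_to_gray(f) for f in np.atleast_3d(raw)])
    fps = None
    try:
        meta = iio.immeta(p)
        fps = float(meta["fps"]) if "fps" in meta else None
    except Exception:
        pass
    return frames, fps


def read_background(path: str | Path) -> np.ndarray:
    """Load a worm-free background frame as grayscale uint8."""
    return _to_gray(iio.imread(Path(path)))
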