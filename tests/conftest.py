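import logging

import numpy as np
import pytest

from wormbend.bendcount import run_counter_on_video
from wormbend.synthgen import SwimParams, generate_swim_video

logging.getLogger("wormbend").setLevel(logging.ERROR)

FREQS = (0.25, 0.5, 1.0)


@pytest.fixture(scope="session")
def short_video():
    """6 s swim at 0.5 Hz — quick end-to-end input for unit-level tests."""
    params = SwimParams(frequency_hz=0.5, duration_s=6.0, seed=11)
    frames, gt = generate_swim_video(params)
    return params, frames, gt


@pytest.fixture(scope="session")
def swim_videos():
    """The three 30 s reference swims (0.25/0.5/1.0 Hz at 20 fps)."""
    out = {}
    for f in FREQS:
        params = SwimParams(frequency_hz=f, seed=3)
        frames, gt = generate_swim_video(params)
        out[f] = (params, frames, gt)
    return out


@pytest.fixture(scope="session")
def swim_results(swim_videos):
    """Full pipeline output for each reference swim (computed once)."""
    out = {}
    for f, (params, frames, gt) in swim_videos.items():
        out[f] = run_counter_on_video(frames, params.fps)
    return out


@pytest.fixture
def straight_line_120():
    """120 collinear unit-spaced points, the hand-computable centerline."""
    return np.column_stack([np.arange(120.0), np.zeros(120)])
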