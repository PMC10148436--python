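"""Pipeline configuration: every tunable default in one auditable place.

A flat TOML file with keys mirroring the CLI flags can override any field;
unknown keys are rejected so typos never silently fall back to defaults.
The full configuration is echoed verbatim into every output summary.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np


@dataclass
class PipelineConfig:
    # segmentation
    window: int = 5                  # adaptive-threshold moving window (px)
    offset: float = 5.0              # gray levels below/above the local mean
    min_area: int = 100              # smallest component kept (px)
    hole_max_px: int = 5000          # largest interior hole filled (px)
    shadow_removal: bool = False
    # centerline
    n: int = 120                     # resampled points per side / centerline
    r: int = 10                      # dorsal search half-window (indices)
    k: int = 2                       # tangent index increment
    pairing: str = "perpendicular"   # or "literal"
    # features
    smooth_window: int = 5           # curvature moving-average (points)
    kappa_min: float | None = None   # default 0.25 / L at run time
    min_sep_frac: float = 0.02       # inflection merge distance, fraction of L
    min_seg_pts: int = 3
    # head/tail
    brighter_is_head: bool = True
    assume_head: str | None = None   # brighter|sharper|endA|endB override
    # counting
    min_run: int = 3                 # persistence (frames)
    min_amp_frac: float = 0.03       # amplitude floor, fraction of L
    count_first: bool = True
    peak_scope: str = "global"       # or "post-pharynx"
    # run control
    max_invalid_frac: float = 0.5
    fps: float | None = None
    seed: int = 0
    # runtime-only: worm-free background frame (never serialized)
    background: np.ndarray | None = field(default=None, repr=False, compare=False)

    _RUNTIME_ONLY = ("background",)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name in self._RUNTIME_ONLY:
                continue
            out[f.name] = getattr(self, f.name)
        return out

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat TOML file; explicit keyword overrides win over the
        file, the file wins over defaults.  Unknown keys are an error."""
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)} - set(cls._RUNTIME_ONLY)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
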