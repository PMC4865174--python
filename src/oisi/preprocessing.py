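"""Frame stacks → fractional-change response maps.

The intrinsic-signal response of one trial is the pixelwise ratio of the
mean of the last three recorded frames (the strongest intrinsic signal) to
the first recorded frame (pre-response baseline).  Maps are averaged across
the repeats of each eye × spatial-frequency condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import tifffile

from .synthetic_data import FrameStack

__all__ = [
    "ResponseMap",
    "spatial_bin",
    "frame_ratio",
    "condition_mean",
    "response_magnitude",
    "write_response_map",
    "read_response_map",
]

STAGE_RAW = "raw_ratio"
STAGE_DENOISED = "denoised"
STAGE_SMOOTHED = "smoothed"

#: value scales: "ratio" maps hold R/R0 (magnitude = |1 - value|),
#: "magnitude" maps hold |ΔR/R0| directly (magnitude = |value|).
SCALE_RATIO = "ratio"
SCALE_MAGNITUDE = "magnitude"


@dataclass
class ResponseMap:
    """2-D map of fractional reflectance change for one condition."""

    values: np.ndarray  # (height, width)
    pixel_size_um: float = 84.0
    eye: str = ""
    sf_cpd: float = float("nan")
    stage: str = STAGE_RAW
    scale: str = SCALE_RATIO

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "ResponseMap":
        return replace(self, values=values, stage=self.stage if stage is None else stage)


def response_magnitude(rmap: ResponseMap) -> np.ndarray:
    """Response magnitude map: |1 - value| on the ratio scale, |value| otherwise."""
    if rmap.scale == SCALE_RATIO:
        return np.abs(1.0 - rmap.values)
    return np.abs(rmap.values)


def spatial_bin(stack: FrameStack, factor: int) -> FrameStack:
    """Mean-pool each frame over factor×factor blocks.

    Trailing rows/columns not filling a complete block are cropped (padding
    would fabricate reflectance values); pixel size scales by ``factor``.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("bin factor must be an integer >= 1")
    if factor == 1:
        return stack
    t, f, h, w = stack.values.shape
    hb, wb = h // factor, w // factor
    if hb < 1 or wb < 1:
        raise ValueError("bin factor larger than image")
    cropped = stack.values[:, :, : hb * factor, : wb * factor]
    binned = cropped.reshape(t, f, hb, factor, wb, factor).mean(axis=(3, 5))
    return FrameStack(
        values=binned,
        frame_duration_s=stack.frame_duration_s,
        pixel_size_um=stack.pixel_size_um * factor,
        illumination_wavelength_nm=stack.illumination_wavelength_nm,
        eye=stack.eye,
        sf_cpd=stack.sf_cpd,
    )


def frame_ratio(stack: FrameStack, n_response_frames: int = 3) -> List[ResponseMap]:
    """Per-trial ratio maps: mean of the last ``n_response_frames`` / first frame.

    ``n_response_frames`` defaults to three (the strongest-signal frames) and
    is overridable only explicitly.
    """
    if n_response_frames < 1:
        raise ValueError("n_response_frames must be >= 1")
    if stack.n_frames < n_response_frames + 1:
        raise ValueError(
            f"need >= {n_response_frames + 1} frames "
            f"(1 baseline + {n_response_frames} response), got {stack.n_frames}"
        )
    baseline = stack.values[:, 0]
    bad = np.argwhere(baseline <= 0)
    if bad.size:
        trial, y, x = bad[0]
        raise ValueError(f"non-positive baseline pixel at trial={trial}, y={y}, x={x}")
    response = stack.values[:, -n_response_frames:].mean(axis=1)
    ratios = response / baseline
    return [
        ResponseMap(
            values=ratios[t],
            pixel_size_um=stack.pixel_size_um,
            eye=stack.eye,
            sf_cpd=stack.sf_cpd,
            stage=STAGE_RAW,
            scale=SCALE_RATIO,
        )
        for t in range(stack.n_trials)
    ]


def condition_mean(maps: Sequence[ResponseMap]) -> ResponseMap:
    """Pixelwise arithmetic mean across the trials of one condition."""
    if len(maps) < 1:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("maps have mismatched dimensions")
        if (m.eye, m.stage, m.scale) != (first.eye, first.stage, first.scale) or not (
            m.sf_cpd == first.sf_cpd or (np.isnan(m.sf_cpd) and np.isnan(first.sf_cpd))
        ):
            raise ValueError("maps have mismatched condition labels")
    mean = np.mean([m.values for m in maps], axis=0)
    return first.with_values(mean)


def write_response_map(rmap: ResponseMap, path: str | Path) -> None:
    """Write as single-page 32-bit float TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, rmap.values.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": rmap.pixel_size_um,
                "eye": rmap.eye,
                "sf_cpd": rmap.sf_cpd,
                "stage": rmap.stage,
                "scale": rmap.scale,
            },
            indent=2,
        )
        + "\n"
    )


def read_response_map(path: str | Path) -> ResponseMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ResponseMap(values=values, **meta)
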