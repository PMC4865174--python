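"""Binocular-zone ROI, spatial-frequency tuning curves, and visual acuity.

Acuity is defined operationally: normalize the SF tuning curve by its
maximum, least-squares fit a line segment to the descending limb in
(log10 SF, normalized magnitude) coordinates, and report the SF at which
the fitted line crosses zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .preprocessing import ResponseMap, response_magnitude

__all__ = [
    "ROIMask",
    "TuningCurve",
    "AcuityEstimate",
    "delineate_roi",
    "compute_tuning",
    "normalize_tuning",
    "estimate_acuity",
    "save_tuning_curve",
    "save_acuity_estimate",
    "save_roi_mask",
    "load_roi_mask",
]

MIN_ROI_PIXELS = 25


@dataclass
class ROIMask:
    """Binocular-zone region of interest."""

    mask: np.ndarray  # 2-D boolean
    provenance: str = "auto"  # "auto" | "manual"
    z_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if int(self.mask.sum()) < MIN_ROI_PIXELS:
            raise ValueError(f"ROI must contain at least {MIN_ROI_PIXELS} pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TuningCurve:
    """Mean response magnitude inside the ROI per spatial frequency."""

    sf_values_cpd: np.ndarray
    magnitudes: np.ndarray
    eye: str = ""
    normalized: bool = False
    n_trials: Optional[int] = None

    def __post_init__(self) -> None:
        self.sf_values_cpd = np.asarray(self.sf_values_cpd, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.sf_values_cpd.shape != self.magnitudes.shape or self.sf_values_cpd.ndim != 1:
            raise ValueError("sf_values_cpd and magnitudes must be 1-D of equal length")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be >= 0")
        if np.any(np.diff(self.sf_values_cpd) <= 0) or np.any(self.sf_values_cpd <= 0):
            raise ValueError("sf_values_cpd must be positive and strictly increasing")


@dataclass
class AcuityEstimate:
    """Line-segment fit in (log10 SF, normalized magnitude) and its x-intercept."""

    acuity_cpd: float
    slope: float
    intercept: float
    segment_indices: Tuple[int, ...]
    r_squared: float
    censored: bool
    noise_floor: float


def delineate_roi(
    maps: Sequence[ResponseMap],
    z_threshold: float = 2.0,
    manual_mask: Optional[np.ndarray] = None,
) -> ROIMask:
    """Delineate the binocular zone from low-SF response maps of one eye.

    Auto mode: z-score the mean response-magnitude map over pixels,
    threshold at ``z_threshold``, keep the largest connected component and
    fill holes.  A ``manual_mask`` overrides detection entirely.
    """
    if manual_mask is not None:
        return ROIMask(mask=np.asarray(manual_mask, dtype=bool), provenance="manual")
    if len(maps) < 1:
        raise ValueError("need at least one map")
    mag = np.mean([response_magnitude(m) for m in maps], axis=0)
    sd = mag.std()
    if sd == 0:
        raise ValueError("uniform map: no structure to threshold")
    z = (mag - mag.mean()) / sd
    mask = z >= z_threshold
    if not mask.any():
        raise ValueError(f"empty ROI at z_threshold={z_threshold}; lower the threshold")
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    return ROIMask(mask=mask, provenance="auto", z_threshold=float(z_threshold))


def compute_tuning(
    maps: Sequence[ResponseMap],
    roi: ROIMask,
    expected_sfs: Optional[Sequence[float]] = None,
    n_trials: Optional[int] = None,
) -> TuningCurve:
    """SF tuning curve: ROI-mean response magnitude per condition map.

    ``expected_sfs`` (e.g. the protocol grid) makes missing conditions an
    explicit error listing the absent SFs.
    """
    if len(maps) < 1:
        raise ValueError("need at least one condition map")
    eye = maps[0].eye
    for m in maps:
        if m.values.shape != roi.mask.shape:
            raise ValueError("map and ROI dimensions differ")
        if m.eye != eye:
            raise ValueError("maps from different eyes")
    maps = sorted(maps, key=lambda m: m.sf_cpd)
    sfs = np.array([m.sf_cpd for m in maps])
    if expected_sfs is not None:
        expected = np.asarray(expected_sfs, dtype=float)
        missing = [float(s) for s in expected if not np.any(np.isclose(sfs, s))]
        if missing:
            raise ValueError(f"missing SF conditions: {missing}")
    magnitudes = np.array([response_magnitude(m)[roi.mask].mean() for m in maps])
    return TuningCurve(sf_values_cpd=sfs, magnitudes=magnitudes, eye=eye, normalized=False, n_trials=n_trials)


def normalize_tuning(curve: TuningCurve) -> TuningCurve:
    """Divide every magnitude by the maximal amplitude among SFs."""
    peak = curve.magnitudes.max()
    if peak <= 0:
        raise ValueError("all-zero tuning curve: nothing to normalize")
    return TuningCurve(
        sf_values_cpd=curve.sf_values_cpd,
        magnitudes=curve.magnitudes / peak,
        eye=curve.eye,
        normalized=True,
        n_trials=curve.n_trials,
    )


def estimate_acuity(curve: TuningCurve, noise_floor: float = 0.05) -> AcuityEstimate:
    """Acuity = x-intercept of an OLS line through the descending limb.

    Segment: from the peak (argmax; ties broken toward the lowest SF)
    through the first subsequent point with magnitude <= ``noise_floor``
    inclusive, or through the last SF when none falls below the floor.
    The fit is magnitude vs log10(SF); the acuity is 10^(−intercept/slope),
    flagged censored when it exceeds the highest tested SF.
    """
    if not curve.normalized:
        raise ValueError("estimate_acuity expects a normalized tuning curve")
    m = curve.magnitudes
    sf = curve.sf_values_cpd
    p = int(np.argmax(m))
    end = len(m) - 1
    for i in range(p + 1, len(m)):
        if m[i] <= noise_floor:
            end = i
            break
    if end - p + 1 < 2:
        raise ValueError("descending segment has fewer than 2 points")
    seg = slice(p, end + 1)
    x = np.log10(sf[seg])
    y = m[seg]
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("non-descending tuning limb")
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    acuity = 10.0 ** (-intercept / slope)
    censored = bool(acuity > sf[-1] * (1 + 1e-12))
    return AcuityEstimate(
        acuity_cpd=float(acuity),
        slope=float(slope),
        intercept=float(intercept),
        segment_indices=tuple(range(p, end + 1)),
        r_squared=float(r_squared),
        censored=censored,
        noise_floor=float(noise_floor),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_tuning_curve(curve: TuningCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sf_cpd": curve.sf_values_cpd,
            "magnitude": curve.magnitudes,
            "eye": curve.eye,
            "normalized": curve.normalized,
            "n_trials": curve.n_trials,
        }
    ).to_csv(path, index=False)


def save_acuity_estimate(est: AcuityEstimate, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "acuity_cpd": est.acuity_cpd,
                "slope": est.slope,
                "intercept": est.intercept,
                "segment_indices": list(est.segment_indices),
                "r_squared": est.r_squared,
                "censored": est.censored,
                "noise_floor": est.noise_floor,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def save_roi_mask(roi: ROIMask, path: str | Path) -> None:
    tifffile.imwrite(path, roi.mask.astype(np.uint8) * 255)


def load_roi_mask(path: str | Path, provenance: str = "manual") -> ROIMask:
    return ROIMask(mask=tifffile.imread(path) > 0, provenance=provenance)
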