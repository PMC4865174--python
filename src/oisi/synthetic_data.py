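"""Synthetic intrinsic-signal optical imaging recordings with known ground truth.

Emulates widefield reflectance imaging of mouse primary visual cortex under
~700 nm illumination during monocular grating stimulation: a stimulus-evoked
reflectance *dip* confined to an elliptical binocular zone, a hemodynamic
time course in which the first stored frame carries no response and the last
three carry the strongest signal, and three noise sources — per-pixel white
noise, spatially correlated vascular-like patterns, and global multiplicative
drift.

The ground-truth spatial-frequency tuning is piecewise linear in log10(SF):
a plateau at the response amplitude up to ``peak_sf_cpd``, then a straight
descending limb reaching zero exactly at ``acuity_cpd``.  Because the
downstream acuity estimator is the x-intercept of a line fitted in
(log10 SF, normalized magnitude) coordinates, the true acuity is analytically
identifiable: on noiseless data any recovery failure indicates a pipeline
bug rather than model mismatch.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import h5py
import numpy as np
import tifffile
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import ndimage as ndi

__all__ = [
    "StimulusProtocol",
    "EyeTruth",
    "RoiGeometry",
    "NoiseParams",
    "GroundTruth",
    "FrameStack",
    "make_default_protocol",
    "true_tuning",
    "roi_profile",
    "roi_half_max_mask",
    "simulate_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_frame_stack",
    "read_frame_stack",
    "write_frame_stack_tiff",
    "save_recordings",
    "load_recordings",
]

#: Canonical eye labels: the eye contralateral / ipsilateral to the imaged hemisphere.
CONTRA = "contra"
IPSI = "ipsi"


class StimulusProtocol(BaseModel):
    """Per-eye drifting-grating stimulus schedule.

    Defaults encode the standard acuity-mapping protocol: ten spatial
    frequencies log-spaced from 0.0303 to 1.0 cycles/degree, drifting at
    1.5 Hz, each shown 16 times (orientation/direction variants folded into
    the repeats), 5 s of stimulus followed by 10 s of gray screen.
    """

    model_config = ConfigDict(frozen=True)

    sf_values_cpd: Tuple[float, ...]
    temporal_frequency_hz: float = 1.5
    n_repeats: int = 16
    n_orientations: int = 16
    stimulus_duration_s: float = 5.0
    interstimulus_gray_s: float = 10.0
    eyes: Tuple[str, str] = (CONTRA, IPSI)

    @field_validator("sf_values_cpd")
    @classmethod
    def _sf_increasing_positive(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        arr = np.asarray(v, dtype=float)
        if arr.size < 1 or np.any(arr <= 0):
            raise ValueError("sf_values_cpd must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("sf_values_cpd must be strictly increasing")
        return tuple(float(x) for x in arr)

    @field_validator("n_repeats")
    @classmethod
    def _repeats(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_repeats must be >= 1")
        return v

    @field_validator("stimulus_duration_s", "interstimulus_gray_s", "temporal_frequency_hz")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("durations and temporal frequency must be > 0")
        return v


def make_default_protocol() -> StimulusProtocol:
    """Return the default 10-SF protocol (geometric series 0.0303 → 1.0 cpd)."""
    sfs = np.geomspace(0.0303, 1.0, 10)
    return StimulusProtocol(sf_values_cpd=tuple(float(s) for s in sfs))


class EyeTruth(BaseModel):
    """Ground-truth tuning for one eye: plateau amplitude, peak SF, cutoff."""

    model_config = ConfigDict(frozen=True)

    acuity_cpd: float
    peak_sf_cpd: float
    response_amplitude: float = 2e-3

    @model_validator(mode="after")
    def _check(self) -> "EyeTruth":
        if not (self.acuity_cpd > self.peak_sf_cpd > 0):
            raise ValueError("requires acuity_cpd > peak_sf_cpd > 0")
        if self.response_amplitude < 0:
            raise ValueError("response_amplitude must be >= 0")
        return self


class RoiGeometry(BaseModel):
    """Elliptical binocular-zone footprint, in pixels of the generated grid."""

    model_config = ConfigDict(frozen=True)

    center_yx: Tuple[float, float] = (16.0, 17.0)
    axes_yx: Tuple[float, float] = (7.0, 5.0)
    taper_px: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "RoiGeometry":
        if min(self.axes_yx) <= 0 or self.taper_px < 0:
            raise ValueError("axes must be > 0 and taper_px >= 0")
        return self


class NoiseParams(BaseModel):
    """Noise model: per-pixel white, vascular-like correlated, global drift.

    ``white_sd`` is the per-pixel, per-frame SD of additive white noise;
    ``vascular_sd`` the SD of a static-within-trial anisotropic correlated
    pattern (Gaussian white field smoothed with an anisotropic kernel of
    ``vascular_corr_px`` SD, 3:1 aspect); ``drift_sd`` the SD of a per-frame
    global multiplicative AR(1) drift with correlation ``drift_rho``.  Drift
    emulates slow vasomotion-like fluctuations (~0.1 Hz), so consecutive 1 s
    frames are strongly correlated: ``drift_rho`` defaults to 0.98 and only
    the frame-to-frame decorrelation survives the frame ratio.  All SDs are
    on the same scale as the baseline reflectance (default 1).
    """

    model_config = ConfigDict(frozen=True)

    white_sd: float = 2e-3
    vascular_sd: float = 5e-4
    vascular_corr_px: float = 3.0
    drift_sd: float = 2e-3
    drift_rho: float = 0.98

    @model_validator(mode="after")
    def _check(self) -> "NoiseParams":
        for name in ("white_sd", "vascular_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vascular_corr_px <= 0:
            raise ValueError("vascular_corr_px must be > 0")
        if not (0 <= self.drift_rho < 1):
            raise ValueError("drift_rho must be in [0, 1)")
        return self

    def noiseless(self) -> "NoiseParams":
        return self.model_copy(update={"white_sd": 0.0, "vascular_sd": 0.0, "drift_sd": 0.0})


class GroundTruth(BaseModel):
    """Full generative description of one synthetic recording session."""

    model_config = ConfigDict(frozen=True)

    eyes: Dict[str, EyeTruth] = Field(
        default_factory=lambda: {
            CONTRA: EyeTruth(acuity_cpd=0.5, peak_sf_cpd=0.0303, response_amplitude=2e-3),
            IPSI: EyeTruth(acuity_cpd=0.35, peak_sf_cpd=0.0303, response_amplitude=1.4e-3),
        }
    )
    roi: RoiGeometry = Field(default_factory=RoiGeometry)
    noise: NoiseParams = Field(default_factory=NoiseParams)
    hemodynamic_weights: Tuple[float, ...] = (0.0, 0.5, 1.0, 1.0, 1.0)
    baseline_reflectance: float = 1.0
    image_shape: Tuple[int, int] = (32, 32)
    pixel_size_um: float = 84.0
    frame_duration_s: float = 1.0
    illumination_wavelength_nm: float = 700.0
    seed: int = 0

    @field_validator("hemodynamic_weights")
    @classmethod
    def _weights(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if len(v) < 4:
            raise ValueError("need >= 4 frames (silent first frame + last three response frames)")
        if v[0] != 0.0:
            raise ValueError("first hemodynamic weight must be 0 (no response in first frame)")
        if any(w <= 0 for w in v[-3:]):
            raise ValueError("last three hemodynamic weights must be > 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "GroundTruth":
        if self.baseline_reflectance <= 0:
            raise ValueError("baseline_reflectance must be > 0 (reflectance is positive)")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small")
        return self

    @property
    def n_frames(self) -> int:
        return len(self.hemodynamic_weights)


@dataclass
class FrameStack:
    """Raw trials × frames × pixels recording for one eye × SF condition."""

    values: np.ndarray  # (trials, frames, height, width), positive reflectance
    frame_duration_s: float = 1.0
    pixel_size_um: float = 84.0
    illumination_wavelength_nm: float = 700.0
    eye: str = CONTRA
    sf_cpd: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (trials, frames, height, width)")
        if self.values.shape[1] < 2:
            raise ValueError("need >= 2 frames (baseline + response)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values <= 0):
            raise ValueError("reflectance values must be > 0")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def shape_yx(self) -> Tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]


# ---------------------------------------------------------------------------
# Ground-truth tuning and spatial profile
# ---------------------------------------------------------------------------

def true_tuning(sf_cpd: float, gt: GroundTruth, eye: str) -> float:
    """Ground-truth response magnitude at ``sf_cpd`` for one eye.

    Piecewise linear in log10(SF): amplitude A for sf <= peak_sf, a straight
    limb from A at peak_sf down to 0 at the acuity, 0 beyond.
    """
    if sf_cpd <= 0:
        raise ValueError("sf_cpd must be > 0")
    et = gt.eyes[eye]
    if sf_cpd <= et.peak_sf_cpd:
        return float(et.response_amplitude)
    if sf_cpd >= et.acuity_cpd:
        return 0.0
    frac = (math.log10(et.acuity_cpd) - math.log10(sf_cpd)) / (
        math.log10(et.acuity_cpd) - math.log10(et.peak_sf_cpd)
    )
    return float(et.response_amplitude * frac)


def roi_profile(shape: Tuple[int, int], roi: RoiGeometry) -> np.ndarray:
    """Spatial response footprint: 1 inside the ellipse, cosine taper outside.

    The taper spans ``taper_px`` pixels of elliptical radius (measured in
    units of the geometric-mean axis), so the profile crosses 0.5 half a
    taper width outside the nominal ellipse.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = roi.center_yx
    ay, ax = roi.axes_yx
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    tau = roi.taper_px / math.sqrt(ay * ax)
    profile = np.zeros(shape, dtype=float)
    profile[r <= 1.0] = 1.0
    if tau > 0:
        band = (r > 1.0) & (r < 1.0 + tau)
        profile[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - 1.0) / tau))
    return profile


def roi_half_max_mask(shape: Tuple[int, int], roi: RoiGeometry) -> np.ndarray:
    """Boolean support of the ground-truth profile at half maximum."""
    return roi_profile(shape, roi) >= 0.5


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _ar1_drift(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal SD ``sd``."""
    d = np.empty(n)
    d[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        d[i] = rho * d[i - 1] + rng.normal(0.0, innov_sd)
    return d


def _vascular_pattern(rng: np.random.Generator, shape: Tuple[int, int], params: NoiseParams) -> np.ndarray:
    """Static anisotropic correlated pattern with SD ``vascular_sd``."""
    raw = rng.standard_normal(shape)
    if params.vascular_sd == 0.0:
        return np.zeros(shape)
    smooth = ndi.gaussian_filter(raw, sigma=(params.vascular_corr_px, params.vascular_corr_px / 3.0), mode="reflect")
    sd = smooth.std()
    if sd == 0.0:
        return np.zeros(shape)
    return smooth * (params.vascular_sd / sd)


def simulate_recording(protocol: StimulusProtocol, gt: GroundTruth) -> Dict[Tuple[str, float], FrameStack]:
    """Generate one FrameStack per (eye, SF) condition.

    Each trial frame f is

        R0 * (1 - w[f] * T(sf, eye) * P(y, x)) * (1 + drift[f])
             + vascular(y, x) + white(f, y, x)

    with w the hemodynamic weights, T the ground-truth tuning, P the
    elliptical spatial profile, drift a per-trial AR(1) scalar series,
    vascular a per-trial static correlated pattern, and white per-pixel
    per-frame noise.  With all noise SDs 0 the stack is an exact
    deterministic function of (protocol, gt); identical seeds give
    bit-identical stacks.
    """
    min_sf = min(protocol.sf_values_cpd)
    for eye in protocol.eyes:
        if eye not in gt.eyes:
            raise ValueError(f"ground truth missing eye {eye!r}")
        if gt.eyes[eye].acuity_cpd < min_sf:
            raise ValueError(
                f"ground-truth acuity {gt.eyes[eye].acuity_cpd} cpd for eye {eye!r} is "
                f"below the lowest protocol SF {min_sf} cpd: nothing to recover"
            )

    rng = np.random.default_rng(gt.seed)
    h, w = gt.image_shape
    weights = np.asarray(gt.hemodynamic_weights)
    profile = roi_profile(gt.image_shape, gt.roi)
    r0 = gt.baseline_reflectance

    stacks: Dict[Tuple[str, float], FrameStack] = {}
    for eye in protocol.eyes:
        for sf in protocol.sf_values_cpd:
            amp = true_tuning(sf, gt, eye)
            clean = r0 * (1.0 - weights[:, None, None] * amp * profile[None, :, :])
            trials = np.empty((protocol.n_repeats, gt.n_frames, h, w))
            for t in range(protocol.n_repeats):
                drift = _ar1_drift(rng, gt.n_frames, gt.noise.drift_sd, gt.noise.drift_rho)
                vascular = _vascular_pattern(rng, gt.image_shape, gt.noise)
                white = rng.normal(0.0, gt.noise.white_sd, size=(gt.n_frames, h, w)) \
                    if gt.noise.white_sd > 0 else np.zeros((gt.n_frames, h, w))
                trials[t] = clean * (1.0 + drift[:, None, None]) + vascular[None, :, :] + white
            stacks[(eye, sf)] = FrameStack(
                values=trials,
                frame_duration_s=gt.frame_duration_s,
                pixel_size_um=gt.pixel_size_um,
                illumination_wavelength_nm=gt.illumination_wavelength_nm,
                eye=eye,
                sf_cpd=float(sf),
            )
    return stacks


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(gt.model_dump_json(indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Parse a ground-truth manifest; malformed files raise naming the field."""
    return GroundTruth.model_validate_json(Path(path).read_text())


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    Path(path).write_text(protocol.model_dump_json(indent=2) + "\n")


def read_protocol(path: str | Path) -> StimulusProtocol:
    return StimulusProtocol.model_validate_json(Path(path).read_text())


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a FrameStack to HDF5 (/values + scalar attributes)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=stack.values)
        ds.attrs["dims"] = "trial,frame,y,x"
        f.attrs["frame_duration_s"] = stack.frame_duration_s
        f.attrs["pixel_size_um"] = stack.pixel_size_um
        f.attrs["illumination_wavelength_nm"] = stack.illumination_wavelength_nm
        f.attrs["eye"] = stack.eye
        f.attrs["sf_cpd"] = stack.sf_cpd


def read_frame_stack(path: str | Path) -> FrameStack:
    with h5py.File(path, "r") as f:
        return FrameStack(
            values=f["values"][()],
            frame_duration_s=float(f.attrs["frame_duration_s"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            illumination_wavelength_nm=float(f.attrs["illumination_wavelength_nm"]),
            eye=str(f.attrs["eye"]),
            sf_cpd=float(f.attrs["sf_cpd"]),
        )


def write_frame_stack_tiff(stack: FrameStack, path: str | Path, trial: int = 0) -> None:
    """Write one trial as a multi-page 32-bit float TIFF."""
    tifffile.imwrite(path, stack.values[trial].astype(np.float32))


def _stack_filename(eye: str, sf_cpd: float) -> str:
    return f"stack_{eye}_sf{sf_cpd:.6f}.h5"


def save_recordings(stacks: Dict[Tuple[str, float], FrameStack], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (eye, sf), stack in stacks.items():
        write_frame_stack(stack, outdir / _stack_filename(eye, sf))


def load_recordings(indir: str | Path) -> Dict[Tuple[str, float], FrameStack]:
    indir = Path(indir)
    stacks: Dict[Tuple[str, float], FrameStack] = {}
    pattern = re.compile(r"stack_(.+)_sf([0-9.]+)\.h5$")
    for p in sorted(indir.glob("stack_*_sf*.h5")):
        if pattern.match(p.name):
            stack = read_frame_stack(p)
            stacks[(stack.eye, stack.sf_cpd)] = stack
    if not stacks:
        raise FileNotFoundError(f"no frame stacks found in {indir}")
    return stacks
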