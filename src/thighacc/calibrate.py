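"""Two-step calibration: device autocalibration and individual orientation.

Step 1 (device-specific): still periods of a worn accelerometer should
measure exactly 1 g regardless of orientation. Per-axis gain and offset
are estimated by iteratively re-weighted least squares that pulls
still-epoch mean vectors onto the unit sphere — the classic
sphere-fitting autocalibration. It needs still data in several distinct
orientations, otherwise the fit is underdetermined and identity
parameters are returned with a warning flag.

Step 2 (individual-specific): sensor placement on the thigh is never
perfectly aligned with the segment axis. During upright locomotion the
mean acceleration direction of a well-mounted sensor sits at a
characteristic attitude — close to the longitudinal axis, tipped
forward by the natural gait lean of the thigh (~20°). The minimal
rotation mapping the median reference direction onto that canonical
attitude corrects the mounting error without erasing the gait lean
itself (mapping onto +U would silently subtract ~20° from every
orientation feature and break the absolute angle thresholds
downstream). A negative longitudinal component during reference
reveals upside-down mounting, corrected by a 180° flip about the
anteroposterior axis before the fine rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .preprocess import EpochFeatures, extract_features
from .signal_core import TriaxialRecording

__all__ = [
    "CalibrationParams",
    "autocalibrate_device",
    "individual_calibration",
    "apply_calibration",
]

STILL_SD_THRESHOLD_G = 0.013
MIN_DISTINCT_ORIENTATIONS = 3
ORIENTATION_ANGLE_DEG = 15.0
MIN_REFERENCE_EPOCHS = 60
#: canonical forward lean of the thigh during level walking (degrees);
#: the individual rotation maps the observed walking attitude onto this
REFERENCE_LEAN_DEG = 20.0
#: half-width (degrees) of the trim window around the median locomotion
#: lean used to isolate walking from minority stairs-like gait
LEAN_TRIM_DEG = 10.0


@dataclass
class CalibrationParams:
    """Per-axis gain/offset plus an orientation rotation.

    Applied as ``sample' = rotation @ ((sample − offset) / gain)``.
    Gains outside [0.5, 2] or offsets beyond 0.5 g are rejected as
    implausible for a functioning sensor.
    """

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    residual: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.any(self.gain < 0.5) or np.any(self.gain > 2.0):
            raise ValueError(f"gains {self.gain} outside sanity bounds [0.5, 2.0]")
        if np.any(np.abs(self.offset) > 0.5):
            raise ValueError(f"offsets {self.offset} exceed 0.5 g sanity bound")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = 1)")

    @classmethod
    def identity(cls, flags: list[str] | None = None) -> "CalibrationParams":
        return cls(flags=list(flags or []))

    def compose_rotation(self, extra: np.ndarray) -> "CalibrationParams":
        return CalibrationParams(
            self.gain.copy(), self.offset.copy(), np.asarray(extra) @ self.rotation,
            self.residual, list(self.flags),
        )

    def to_json(self, path) -> None:
        payload = {
            "gain": self.gain.tolist(),
            "offset": self.offset.tolist(),
            "rotation": self.rotation.tolist(),
            "residual": self.residual,
            "flags": self.flags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["gain"]), np.array(d["offset"]), np.array(d["rotation"]),
            float(d.get("residual", 0.0)), list(d.get("flags", [])),
        )


def _still_vectors(
    features: list[EpochFeatures], still_sd_threshold_g: float
) -> np.ndarray:
    return np.array(
        [f.mean_g for f in features if f.sd_raw_g < still_sd_threshold_g and not f.degenerate]
    )


def _distinct_orientations(vectors: np.ndarray, min_angle_deg: float) -> int:
    """Greedy count of mutually separated unit directions."""
    if len(vectors) == 0:
        return 0
    units = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    picked: list[np.ndarray] = []
    cos_min = np.cos(np.radians(min_angle_deg))
    for u in units:
        if all(float(u @ p) < cos_min for p in picked):
            picked.append(u)
    return len(picked)


def autocalibrate_device(
    rec: TriaxialRecording,
    still_sd_threshold_g: float = STILL_SD_THRESHOLD_G,
    features: list[EpochFeatures] | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CalibrationParams:
    """Sphere-fit gain/offset estimation from still epochs.

    Minimises the residuals ``‖(v − offset) / gain‖ − 1`` over the still
    mean vectors by iterative damped least squares (trust-region
    Levenberg–Marquardt-style via :func:`scipy.optimize.least_squares`),
    stopping when the parameter step falls below ``tol`` or after
    ``max_iter`` iterations. With fewer than three distinct still
    orientations the fit is underdetermined ("sphere fit
    underdetermined"): identity parameters are returned with a warning
    flag.
    """
    if features is None:
        features = extract_features(rec)
    stills = _still_vectors(features, still_sd_threshold_g)
    if (
        len(stills) < MIN_DISTINCT_ORIENTATIONS
        or _distinct_orientations(stills, ORIENTATION_ANGLE_DEG) < MIN_DISTINCT_ORIENTATIONS
    ):
        return CalibrationParams.identity(flags=["sphere fit underdetermined"])

    def residuals(params: np.ndarray) -> np.ndarray:
        g, o = params[:3], params[3:]
        return np.linalg.norm((stills - o) / g, axis=1) - 1.0

    fit = least_squares(
        residuals,
        x0=np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
        bounds=([0.5] * 3 + [-0.5] * 3, [2.0] * 3 + [0.5] * 3),
        xtol=tol,
        max_nfev=max_iter * 10,
    )
    gain, offset = fit.x[:3], fit.x[3:]
    residual = float(np.sqrt(np.mean(residuals(fit.x) ** 2)))
    return CalibrationParams(gain, offset, np.eye(3), residual)


def _rotation_between(direction: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal (Rodrigues) rotation mapping one unit direction onto another."""
    d = direction / np.linalg.norm(direction)
    e_u = np.asarray(target, dtype=float)
    c = float(np.clip(d @ e_u, -1.0, 1.0))
    axis = np.cross(d, e_u)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3)
    axis = axis / s
    angle = np.arctan2(s, c)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


#: 180° flip about the anteroposterior (W) axis: upside-down remounting.
FLIP_ABOUT_W = np.diag([-1.0, -1.0, 1.0])


def individual_calibration(
    features: list[EpochFeatures],
    config=None,
    reference_lean_deg: float = REFERENCE_LEAN_DEG,
) -> CalibrationParams:
    """Placement-error rotation from upright-locomotion reference epochs.

    Reference epochs are active, with walking-band cadence, and with the
    mean vector close to the longitudinal axis in either direction
    (inclination < 45° or > 135° — the latter admits upside-down
    mounting, which would otherwise be invisible to the pre-pass). The
    median reference direction is rotated onto the canonical gait
    attitude (``reference_lean_deg`` forward of +U in the sagittal
    plane). Requires at least 60 reference epochs, else identity with a
    flag.
    """
    from .classify import ClassifierConfig

    config = config or ClassifierConfig()
    lo, hi = config.walk_band_hz
    broad = [
        f
        for f in features
        if f.sd_corrected_g >= config.sigma_stationary_g
        and lo <= f.cadence_hz <= hi
        and (f.inclination_deg < config.theta_sit_deg or f.inclination_deg > 180 - config.theta_sit_deg)
        and not f.degenerate
    ]
    if len(broad) < MIN_REFERENCE_EPOCHS:
        return CalibrationParams.identity(flags=["too few reference epochs"])
    units = np.array([f.mean_g for f in broad])
    units /= np.linalg.norm(units, axis=1, keepdims=True)

    # stage 1: flip detection on the broad upright-locomotion set
    rotation = np.eye(3)
    flags: list[str] = []
    if np.median(units[:, 0]) < 0:
        flags.append("upside-down mounting detected")
        units = units @ FLIP_ABOUT_W.T
        rotation = FLIP_ABOUT_W

    # stage 2: isolate the dominant gait attitude. An absolute lean cut
    # would be circular (a rotated mounting shifts every lean), so trim
    # relative to the median lean of the locomotion set — walking
    # dominates locomotion time, and minority high-lean gait (stairs
    # bouts) falls outside the trim window.
    lean_obs = np.degrees(np.arctan2(units[:, 2], units[:, 0]))
    med_lean = np.median(lean_obs)
    keep = np.abs(lean_obs - med_lean) <= LEAN_TRIM_DEG
    if int(keep.sum()) < MIN_REFERENCE_EPOCHS:
        return CalibrationParams.identity(flags=flags + ["too few reference epochs"])
    med = np.median(units[keep], axis=0)
    med = med / np.linalg.norm(med)

    lean = np.radians(reference_lean_deg)
    canonical = np.array([np.cos(lean), 0.0, np.sin(lean)])
    rotation = _rotation_between(med, canonical) @ rotation
    return CalibrationParams(np.ones(3), np.zeros(3), rotation, 0.0, flags)


def apply_calibration(rec: TriaxialRecording, cal: CalibrationParams) -> TriaxialRecording:
    """``sample' = rotation @ ((sample − offset) / gain)``; preserves the
    epoch count and time base."""
    corrected = (rec.samples - cal.offset) / cal.gain
    rotated = corrected @ cal.rotation.T
    return TriaxialRecording(rec.device, rec.start_time, rec.fs_hz, rotated)
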