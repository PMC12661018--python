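"""Raw-recording data model, CSV I/O, resampling and device emulation.

A recording is a uniformly sampled triaxial acceleration time series in
units of g (1 g = 9.80665 m/s²) on body-fixed axes

* ``U`` — longitudinal thigh axis, aligned with gravity when standing
  upright, positive toward the knee;
* ``V`` — mediolateral;
* ``W`` — anteroposterior, positive forward.

Timestamps are implied by a uniform grid ``start_time + i / fs_hz``;
clock imperfections (offset, drift) are modelled explicitly in
:mod:`thighacc.sync`, never via per-sample stamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "DeviceModel",
    "TriaxialRecording",
    "read_recording",
    "write_recording",
    "downsample",
    "apply_device_model",
    "WIDE_RANGE_REFERENCE",
]

#: relative slack allowed on inter-sample gaps before a recording is
#: declared non-uniform (gaps larger than ``2 / fs`` abort reading).
_GAP_FACTOR = 2.0


@dataclass(frozen=True)
class DeviceModel:
    """Static description of an accelerometer model.

    Parameters
    ----------
    name : str
        Human-readable model name.
    dynamic_range_g : float
        Half-range of the sensor in g; ``4.0`` means the device measures
        ±4 g and saturates (clips) beyond.
    fs_nominal_hz : float
        Nominal sampling frequency.
    sd_correction : tuple of float
        ``(c2, c1, c0)`` coefficients of the quadratic correction applied
        to the standard-deviation feature to compensate for saturation on
        narrow-range devices. ``(0, 1, 0)`` is the identity.
    """

    name: str
    dynamic_range_g: float
    fs_nominal_hz: float
    sd_correction: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if not self.dynamic_range_g > 0:
            raise ValueError(f"dynamic_range_g must be > 0, got {self.dynamic_range_g}")
        if not self.fs_nominal_hz > 0:
            raise ValueError(f"fs_nominal_hz must be > 0, got {self.fs_nominal_hz}")
        if len(self.sd_correction) != 3:
            raise ValueError("sd_correction must be (c2, c1, c0)")


#: idealised wide-range reference device (no visible saturation at human
#: accelerations); used by the simulator as the ground-truth sensor.
WIDE_RANGE_REFERENCE = DeviceModel("reference-wide", dynamic_range_g=16.0, fs_nominal_hz=25.0)


@dataclass
class TriaxialRecording:
    """Uniformly sampled triaxial acceleration in g.

    ``samples`` is an ``(N, 3)`` array on axes (U, V, W). Sample ``i`` is
    taken at ``start_time + i / fs_hz`` (UTC seconds). All samples must be
    finite; the device's dynamic-range bound is established by
    :func:`apply_device_model`, not enforced here, so that ideal
    (pre-saturation) signals can use the same container.
    """

    device: DeviceModel
    start_time: float
    fs_hz: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (N, 3), got {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, ``N / fs`` seconds."""
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        """Implied sample times relative to ``start_time`` (seconds)."""
        return np.arange(self.n_samples) / self.fs_hz

    @property
    def u(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def w(self) -> np.ndarray:
        return self.samples[:, 2]

    def with_samples(self, samples: np.ndarray) -> "TriaxialRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


def read_recording(path, device: DeviceModel) -> TriaxialRecording:
    """Read a recording CSV with header ``time,u,v,w``.

    ``time`` may be float seconds or ISO-8601; it must be strictly
    increasing and uniform (gaps above ``2 / fs`` raise). The sampling
    frequency is estimated as ``(N - 1) / (t_last - t_first)``.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty recording file: {path}") from None
    expected = ["time", "u", "v", "w"]
    if list(frame.columns) != expected:
        raise ValueError(f"expected header {expected}, got {list(frame.columns)} in {path}")
    if len(frame) == 0:
        raise ValueError(f"empty recording file: {path}")

    t = pd.to_numeric(frame["time"], errors="coerce")
    if t.isna().any():
        # fall back to ISO-8601 timestamps
        t_dt = pd.to_datetime(frame["time"], errors="coerce", utc=True, format="ISO8601")
        if t_dt.isna().any():
            line = int(t_dt.isna().idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"malformed time value at line {line} of {path}")
        t = t_dt.astype("int64") / 1e9
    t = t.to_numpy(dtype=float)

    axes = np.empty((len(frame), 3))
    for j, col in enumerate(("u", "v", "w")):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ValueError(f"malformed value in column '{col}' at line {line} of {path}")
        axes[:, j] = vals.to_numpy(dtype=float)

    if len(t) == 1:
        return TriaxialRecording(device, float(t[0]), device.fs_nominal_hz, axes)

    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise ValueError(f"time not strictly increasing at line {line} of {path}")
    fs = (len(t) - 1) / (t[-1] - t[0])
    if np.any(dt > _GAP_FACTOR / fs):
        line = int(np.argmax(dt > _GAP_FACTOR / fs)) + 3
        raise ValueError(f"non-uniform sampling: gap at line {line} of {path} exceeds 2/fs")
    return TriaxialRecording(device, float(t[0]), float(fs), axes)


def write_recording(rec: TriaxialRecording, path) -> None:
    """Write the CSV dialect read by :func:`read_recording` (float seconds,
    9 decimal places — round-trip stable to 1e-9 g)."""
    t = rec.start_time + rec.times
    frame = pd.DataFrame(
        {"time": t, "u": rec.u, "v": rec.v, "w": rec.w}
    )
    frame.to_csv(path, index=False, float_format="%.9f")


def downsample(rec: TriaxialRecording, fs_target_hz: float) -> TriaxialRecording:
    """Resample to a lower rate: anti-alias low-pass then linear interpolation.

    The anti-alias filter is a 4th-order zero-phase Butterworth with cutoff
    ``0.8 · (fs_target / 2)``. Output length is
    ``floor((N − 1) · fs_target / fs_src) + 1`` so the target grid never
    extrapolates. Equal-rate calls return the samples unchanged.
    """
    if fs_target_hz > rec.fs_hz:
        raise ValueError(
            f"cannot upsample: target {fs_target_hz} Hz > source {rec.fs_hz} Hz"
        )
    if np.isclose(fs_target_hz, rec.fs_hz):
        return replace(rec, samples=rec.samples.copy())

    cutoff = 0.8 * (fs_target_hz / 2.0)
    sos = sps.butter(4, cutoff, btype="low", fs=rec.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0)

    n_out = int(np.floor((rec.n_samples - 1) * fs_target_hz / rec.fs_hz)) + 1
    t_src = rec.times
    t_out = np.arange(n_out) / fs_target_hz
    out = np.column_stack(
        [np.interp(t_out, t_src, filtered[:, j]) for j in range(3)]
    )
    return TriaxialRecording(rec.device, rec.start_time, float(fs_target_hz), out)


def apply_device_model(ideal: TriaxialRecording, device: DeviceModel) -> TriaxialRecording:
    """Emulate a device observing an ideal signal: saturation clipping.

    Samples are clipped to ``±device.dynamic_range_g`` and the device
    metadata is attached. Idempotent (a projection)."""
    r = device.dynamic_range_g
    clipped = np.clip(ideal.samples, -r, r)
    return TriaxialRecording(device, ideal.start_time, ideal.fs_hz, clipped)
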