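"""Low-pass filtering, windowed feature extraction and SD correction.

Features live on a 1-s epoch grid: epoch ``i`` summarises the 2-s window
``[i, i+2)`` seconds from the recording start, so consecutive windows
overlap by exactly 1 s and a recording of duration ``T`` seconds yields
``floor(T) − 1`` epochs. The classifier downstream consumes only these
derived features, never raw samples, which is what makes chunked
processing possible.

Per epoch:

* ``mean_g`` — mean of the low-pass-filtered axes (gravity estimate);
* ``sd_raw_g`` — standard deviation of the filtered vector magnitude
  about its window mean (movement intensity);
* ``sd_corrected_g`` — ``sd_raw`` passed through the device's quadratic
  saturation correction;
* ``inclination_deg`` — angle between the mean vector and +U
  (thigh vs gravity; ~0° standing, ~90° thigh horizontal);
* ``forward_lean_deg`` — signed angle of the mean vector in the U–W
  (sagittal) plane, positive forward;
* ``cadence_hz`` — dominant periodicity of the U axis over a centred
  4-s context, restricted to 0.3–4 Hz; 0 when no clear spectral line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_core import DeviceModel, TriaxialRecording

__all__ = [
    "EpochFeatures",
    "lowpass_filter",
    "extract_features",
    "correct_sd",
    "calibrate_sd_polynomial",
    "features_to_frame",
    "DEFAULT_CUTOFF_HZ",
]

#: default low-pass cutoff (Hz): inside the human-movement band and below
#: the 6.25 Hz Nyquist frequency of a 12.5 Hz recording.
DEFAULT_CUTOFF_HZ = 5.0

#: cadence search band (Hz) and peak-prominence rule: the spectral peak
#: must exceed 3× the median in-band power, else cadence is reported as 0.
CADENCE_BAND_HZ = (0.3, 4.0)
CADENCE_PEAK_FACTOR = 3.0
#: a spectral line must concentrate this share of band power within
#: ±CADENCE_LOBE_HZ of the peak, else the movement counts as aperiodic
CADENCE_LOBE_HZ = 0.35
CADENCE_CONCENTRATION = 0.5


@dataclass
class EpochFeatures:
    epoch_index: int
    t_center_s: float
    mean_g: tuple[float, float, float]
    sd_raw_g: float
    sd_corrected_g: float
    inclination_deg: float
    forward_lean_deg: float
    cadence_hz: float
    degenerate: bool = False  # zero mean vector: orientation undefined


def lowpass_filter(rec: TriaxialRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> TriaxialRecording:
    """4th-order zero-phase (forward–backward) Butterworth low-pass.

    Zero-phase filtering keeps features time-aligned with annotations.
    Note the effective magnitude response is squared, so a sine at the
    cutoff comes out at 1/2 amplitude, not 1/√2.
    """
    nyq = rec.fs_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz) for fs={rec.fs_hz} Hz"
        )
    sos = sps.butter(4, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    return rec.with_samples(sps.sosfiltfilt(sos, rec.samples, axis=0))


def _cadence(u: np.ndarray, fs: float) -> float:
    """Dominant frequency of a detrended segment in the cadence band.

    Two rules gate the peak: it must exceed 3× the median in-band power,
    and the power within ±0.35 Hz of it must hold at least half the band
    power (a genuine gait line is narrow; broadband irregular movement
    spreads its energy across the band and is reported as cadence 0).
    Welch averaging (2-s segments, 50% overlap) stabilises the spectrum;
    zero-padding localises the peak well below the raw bin width.
    """
    x = u - u.mean()
    n = len(x)
    if n < 8 or not np.any(x):
        return 0.0
    nperseg = min(int(2 * fs), n)
    nfft = int(2 ** np.ceil(np.log2(nperseg)) * 16)  # zero-pad for peak resolution
    freqs, spec = sps.welch(
        x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft, detrend="linear"
    )
    band = (freqs >= CADENCE_BAND_HZ[0]) & (freqs <= CADENCE_BAND_HZ[1])
    if not np.any(band):
        return 0.0
    p = spec[band]
    f = freqs[band]
    med = np.median(p)
    k = int(np.argmax(p))
    if med <= 0 or p[k] < CADENCE_PEAK_FACTOR * med:
        return 0.0
    near = np.abs(f - f[k]) <= CADENCE_LOBE_HZ
    if p[near].sum() < CADENCE_CONCENTRATION * p.sum():
        return 0.0
    return float(f[k])


def extract_features(
    rec: TriaxialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> list[EpochFeatures]:
    """Per-second features from 2-s windows with 1-s overlap.

    Filtering is applied once, upstream of both the mean and the SD.
    Cadence uses a 4-s context window centred on the epoch, clipped at
    the recording edges. The trailing partial window is dropped.
    """
    if rec.duration_s < 2.0:
        raise ValueError(f"recording of {rec.duration_s:.2f} s is shorter than one 2-s window")
    filt = lowpass_filter(rec, cutoff_hz)
    fs = rec.fs_hz
    n = rec.n_samples
    n_epochs = int(np.floor(rec.duration_s)) - 1

    coeffs = rec.device.sd_correction
    out: list[EpochFeatures] = []
    mags = np.linalg.norm(filt.samples, axis=1)
    for i in range(n_epochs):
        a = int(round(i * fs))
        b = min(int(round((i + 2) * fs)), n)
        win = filt.samples[a:b]
        mean = win.mean(axis=0)
        sd_raw = float(mags[a:b].std())
        norm = float(np.linalg.norm(mean))
        if norm == 0.0:
            incl, lean, degenerate = 0.0, 0.0, True
        else:
            incl = float(np.degrees(np.arccos(np.clip(mean[0] / norm, -1.0, 1.0))))
            lean = float(np.degrees(np.arctan2(mean[2], mean[0])))
            degenerate = False
        ca = max(int(round((i - 1) * fs)), 0)
        cb = min(int(round((i + 3) * fs)), n)
        cadence = _cadence(filt.samples[ca:cb, 0], fs)
        out.append(
            EpochFeatures(
                epoch_index=i,
                t_center_s=i + 1.0,
                mean_g=(float(mean[0]), float(mean[1]), float(mean[2])),
                sd_raw_g=sd_raw,
                sd_corrected_g=correct_sd(sd_raw, rec.device),
                inclination_deg=incl,
                forward_lean_deg=lean,
                cadence_hz=cadence,
                degenerate=degenerate,
            )
        )
    return out


def correct_sd(sd_raw_g: float, device: DeviceModel) -> float:
    """Quadratic saturation correction of the SD feature.

    Narrow-range sensors clip high-intensity movement, deflating the SD
    that the decision tree thresholds on; ``max(0, c2·sd² + c1·sd + c0)``
    restores it. Identity coefficients pass through unchanged.
    """
    if sd_raw_g < 0:
        raise ValueError("sd_raw_g must be non-negative")
    c2, c1, c0 = device.sd_correction
    return max(0.0, c2 * sd_raw_g**2 + c1 * sd_raw_g + c0)


def calibrate_sd_polynomial(paired) -> tuple[float, float, float]:
    """Least-squares quadratic mapping clipped SD → reference SD.

    ``paired`` is a sequence of ``(sd_clipped, sd_reference)`` pairs from
    co-recorded (or simulated) narrow-range and wide-range devices; the
    returned ``(c2, c1, c0)`` plug into :class:`DeviceModel.sd_correction`.
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise ValueError("need at least 10 (sd_clipped, sd_reference) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(np.round(x, 12))) < 3:
        raise ValueError("degenerate design: need at least 3 distinct clipped-SD values")
    c2, c1, c0 = np.polyfit(x, y, 2)
    return float(c2), float(c1), float(c0)


def features_to_frame(features: list[EpochFeatures]) -> pd.DataFrame:
    """Feature table with the documented CSV column layout."""
    return pd.DataFrame(
        {
            "epoch": [f.epoch_index for f in features],
            "t_center": [f.t_center_s for f in features],
            "mean_u": [f.mean_g[0] for f in features],
            "mean_v": [f.mean_g[1] for f in features],
            "mean_w": [f.mean_g[2] for f in features],
            "sd_raw": [f.sd_raw_g for f in features],
            "sd_corr": [f.sd_corrected_g for f in features],
            "inclination": [f.inclination_deg for f in features],
            "forward_lean": [f.forward_lean_deg for f in features],
            "cadence": [f.cadence_hz for f in features],
        }
    )
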