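"""Multi-device clock alignment: heel-drop anchors + cross-correlation drift.

Device clocks differ from the reference clock by a constant offset plus a
constant-rate (parts-per-million) drift — a linear two-parameter model
``t_dev = offset + (1 + drift·1e-6) · t_ref``. Deliberate heel-drop
impacts produce unmistakable spikes used as coarse anchors; gait
periodicity shared between co-located devices then refines the model via
windowed normalised cross-correlation of the band-passed longitudinal
axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import TriaxialRecording

__all__ = [
    "SyncModel",
    "detect_heel_drops",
    "fit_sync_model",
    "refine_by_xcorr",
    "apply_sync",
]

HEEL_DROP_THRESHOLD_G = 2.5
GROUP_WINDOW_S = 2.0
MIN_PEAKS_PER_CLUSTER = 3
XCORR_WINDOW_S = 120.0
XCORR_BAND_HZ = (0.5, 3.0)
#: minimum normalised correlation peak for a window lag to be trusted
XCORR_MIN_PEAK = 0.3
#: residual-lag search bound (s) after coarse alignment; keeps the
#: near-periodic gait signal from aliasing the lag by whole stride periods
XCORR_MAX_LAG_S = 0.3


@dataclass
class SyncModel:
    """Linear clock model ``t_dev = offset_s + (1 + drift_ppm·1e-6)·t_ref``."""

    offset_s: float
    drift_ppm: float
    anchors_used: int = 0
    residual_s: float = 0.0

    @property
    def scale(self) -> float:
        return 1.0 + self.drift_ppm * 1e-6

    def to_reference(self, t_dev: np.ndarray) -> np.ndarray:
        """Map device-clock times onto the reference clock (strictly
        increasing for |drift| < 1e6 ppm)."""
        return (np.asarray(t_dev) - self.offset_s) / self.scale

    def to_device(self, t_ref: np.ndarray) -> np.ndarray:
        return np.asarray(t_ref) * self.scale + self.offset_s

    def inverse(self) -> "SyncModel":
        return SyncModel(
            offset_s=-self.offset_s / self.scale,
            drift_ppm=(1.0 / self.scale - 1.0) * 1e6,
            anchors_used=self.anchors_used,
            residual_s=self.residual_s,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "offset_s": self.offset_s,
                    "drift_ppm": self.drift_ppm,
                    "anchors_used": self.anchors_used,
                    "residual_s": self.residual_s,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SyncModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def detect_heel_drops(
    rec: TriaxialRecording,
    amplitude_threshold_g: float = HEEL_DROP_THRESHOLD_G,
    group_window_s: float = GROUP_WINDOW_S,
) -> list[float]:
    """Anchor times from heel-drop spike clusters on the U axis.

    Samples with |U| above threshold are clustered when closer than
    ``group_window_s``; a cluster counts only with at least three
    distinct peaks (the protocol calls for three heel-drops). Returns
    the time of the first peak of each retained cluster, sorted.
    """
    u = np.abs(rec.u)
    exceed = np.flatnonzero(u >= amplitude_threshold_g)
    if len(exceed) == 0:
        return []
    # distinct peaks: local maxima of |U| above threshold, ≥100 ms apart
    min_dist = max(int(0.1 * rec.fs_hz), 1)
    peaks, _ = sps.find_peaks(u, height=amplitude_threshold_g, distance=min_dist)
    if len(peaks) == 0:
        # a single saturated sample can fail find_peaks' strict inequality
        peaks = exceed[np.concatenate([[True], np.diff(exceed) > min_dist])]
    anchors = []
    cluster = [peaks[0]]
    gap = group_window_s * rec.fs_hz
    for p in peaks[1:]:
        if p - cluster[-1] <= gap:
            cluster.append(p)
        else:
            if len(cluster) >= MIN_PEAKS_PER_CLUSTER:
                anchors.append(cluster[0] / rec.fs_hz)
            cluster = [p]
    if len(cluster) >= MIN_PEAKS_PER_CLUSTER:
        anchors.append(cluster[0] / rec.fs_hz)
    return sorted(float(a) for a in anchors)


def fit_sync_model(anchors_dev, anchors_ref) -> SyncModel:
    """Least-squares line through matched anchor pairs.

    Anchors are matched by order (the protocol places drop groups
    before, during and after the session). Two anchors give an exact
    fit; the residual is the largest absolute deviation of the fitted
    device times from the observed ones.
    """
    dev = np.asarray(list(anchors_dev), dtype=float)
    ref = np.asarray(list(anchors_ref), dtype=float)
    if len(dev) != len(ref):
        raise ValueError(f"mismatched anchor counts: {len(dev)} device vs {len(ref)} reference")
    if len(dev) < 2:
        raise ValueError(f"insufficient anchors: need at least 2, got {len(dev)}")
    design = np.column_stack([ref, np.ones(len(ref))])
    (slope, intercept), *_ = np.linalg.lstsq(design, dev, rcond=None)
    fitted = design @ np.array([slope, intercept])
    residual = float(np.max(np.abs(fitted - dev)))
    return SyncModel(
        offset_s=float(intercept),
        drift_ppm=float((slope - 1.0) * 1e6),
        anchors_used=len(dev),
        residual_s=residual,
    )


def _bandpass(x: np.ndarray, fs: float, band=XCORR_BAND_HZ) -> np.ndarray:
    hi = min(band[1], 0.45 * fs)
    sos = sps.butter(2, [band[0], hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _window_lag(
    a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float = XCORR_MAX_LAG_S
) -> float | None:
    """Lag (s) of b relative to a maximising normalised cross-correlation
    within ±``max_lag_s``, with sub-sample parabolic refinement; None
    when no trustworthy peak. The search bound matters: gait is nearly
    periodic, so unconstrained correlation of well-aligned windows can
    lock onto a peak one stride period away."""
    if a.std() == 0 or b.std() == 0:
        return None
    a = (a - a.mean()) / (a.std() * np.sqrt(len(a)))
    b = (b - b.mean()) / (b.std() * np.sqrt(len(b)))
    corr = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(len(b), len(a), mode="full")
    window = np.abs(lags) <= max_lag_s * fs
    if not np.any(window):
        return None
    idx = np.flatnonzero(window)
    k = int(idx[np.argmax(corr[idx])])
    if corr[k] < XCORR_MIN_PEAK:
        return None
    lag = float(lags[k])
    if 0 < k < len(corr) - 1:  # parabolic sub-sample interpolation
        denom = corr[k - 1] - 2 * corr[k] + corr[k + 1]
        if denom < 0:
            lag += 0.5 * float((corr[k - 1] - corr[k + 1]) / denom)
    return lag / fs


def refine_by_xcorr(
    rec_dev: TriaxialRecording,
    rec_ref: TriaxialRecording,
    coarse: SyncModel,
    window_s: float = XCORR_WINDOW_S,
    max_lag_s: float = XCORR_MAX_LAG_S,
) -> SyncModel:
    """Refine a coarse clock model from shared gait periodicity.

    The device recording is first aligned with the coarse model; for
    evenly spaced windows the residual lag of the band-passed U axes is
    measured by normalised cross-correlation, and a line through
    (window centre, residual lag) updates offset and drift. Residuals
    are compared on the same scale — the measured window lags the
    coarse model leaves behind versus the lag-fit residuals of the
    refined model — and the refined model is adopted only when it
    reduces them; windows without signal (flat or uncorrelated) are
    skipped, and if every window is skipped the coarse model is
    returned unchanged.
    """
    aligned = apply_sync(rec_dev, coarse)
    fs = rec_ref.fs_hz
    span = min(aligned.duration_s, rec_ref.duration_s)
    if span < 3 * window_s:
        window_s = max(span / 3.0, 10.0)
    n_windows = max(int(span // window_s), 3)
    u_dev = _bandpass(aligned.u, aligned.fs_hz)
    u_ref = _bandpass(rec_ref.u, fs)

    centres, lags = [], []
    for w in range(n_windows):
        t0 = w * (span - window_s) / max(n_windows - 1, 1)
        a0, a1 = int(t0 * fs), int((t0 + window_s) * fs)
        d0, d1 = int(t0 * aligned.fs_hz), int((t0 + window_s) * aligned.fs_hz)
        seg_ref = u_ref[a0:a1]
        seg_dev = u_dev[d0:d1]
        if len(seg_ref) < 8 or len(seg_dev) < 8:
            continue
        lag = _window_lag(seg_ref, seg_dev, fs, max_lag_s)
        if lag is None:
            continue
        centres.append(t0 + window_s / 2.0)
        lags.append(lag)

    if len(lags) < 2:
        return coarse

    lags_arr = np.asarray(lags)
    design = np.column_stack([centres, np.ones(len(centres))])
    (slope, intercept), *_ = np.linalg.lstsq(design, lags_arr, rcond=None)
    # residual lag model: lag(t_ref) = intercept + slope·t_ref
    residual_before = float(np.max(np.abs(lags_arr)))
    residual_after = float(np.max(np.abs(design @ np.array([slope, intercept]) - lags_arr)))
    if residual_after >= residual_before:
        return coarse
    return SyncModel(
        offset_s=coarse.offset_s + float(intercept) * coarse.scale,
        drift_ppm=((1.0 + slope) * coarse.scale - 1.0) * 1e6,
        anchors_used=coarse.anchors_used,
        residual_s=residual_after,
    )


def apply_sync(rec: TriaxialRecording, model: SyncModel) -> TriaxialRecording:
    """Resample a device recording onto the reference clock's uniform grid.

    Device sample ``i`` occurs at reference time ``(i/fs − offset)/scale``;
    the output grid is uniform at the same rate on the reference clock,
    covering the mapped span, with linear interpolation between device
    samples.
    """
    t_ref_of_dev = model.to_reference(rec.times)
    n = rec.n_samples
    out_t = np.arange(n) / rec.fs_hz  # reference-clock grid from t_ref = 0
    samples = np.column_stack(
        [np.interp(out_t, t_ref_of_dev, rec.samples[:, j]) for j in range(3)]
    )
    return TriaxialRecording(rec.device, rec.start_time, rec.fs_hz, samples)
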