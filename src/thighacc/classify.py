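"""Fixed decision tree over epoch features producing per-second behaviour labels.

The tree splits first on movement intensity (corrected SD) into
stationary vs active; stationary epochs split on inclination into
sedentary (sitting/lying, thigh near horizontal) vs standing; active
epochs are assigned, in order, to cycling (large forward lean with slow
pedalling periodicity), running (fast cadence or very high intensity),
stair climbing (walking-band cadence with forward lean above an
individually estimated threshold), walking (walking-band cadence) and
otherwise "move" — brief irregular activity without a clear gait line.

The walk-vs-stairs split is the only individually estimated threshold:
it is taken from the upper quantile of the participant's own walking
forward-lean distribution plus a fixed offset, falling back to a fixed
default when too little walking-like data is available (short recordings
yield uncertain thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_CUTOFF_HZ, EpochFeatures, extract_features
from .signal_core import TriaxialRecording

__all__ = [
    "BEHAVIOURS",
    "ClassifierConfig",
    "EpochLabelSeries",
    "StairsThreshold",
    "estimate_stairs_threshold",
    "classify_epoch",
    "smooth_labels",
    "classify_features",
    "classify_recording",
    "classify_recording_chunked",
    "aggregate_daily",
    "DailySummary",
]

#: the behaviour label set; "excluded" marks epochs dropped from analysis.
BEHAVIOURS = ("sedentary", "stand", "move", "walk", "run", "stairs", "cycle")
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ClassifierConfig:
    """All decision-tree thresholds and smoothing settings.

    None of these constants are canonical — they are lineage conventions
    exposed for sensitivity analysis. Units: g for SD thresholds, degrees
    for angles, Hz for cadence bands, epochs/seconds for smoothing.
    """

    sigma_stationary_g: float = 0.1      # below: stationary
    theta_sit_deg: float = 45.0          # stationary inclination split
    sigma_run_g: float = 0.72            # SD route into run
    f_run_hz: float = 2.5                # cadence route into run
    walk_band_hz: tuple[float, float] = (0.6, 2.5)
    theta_cycle_deg: float = 40.0        # forward lean for cycling
    cycle_band_hz: tuple[float, float] = (0.3, 2.0)
    stairs_quantile: float = 0.95
    stairs_offset_deg: float = 2.0
    theta_stairs_fallback_deg: float = 25.0
    min_epochs_for_individual_threshold: int = 60
    median_filter_epochs: int = 5
    min_bout_s: dict = field(
        default_factory=lambda: {"run": 2, "cycle": 15, "stairs": 4}
    )
    min_bout_default_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("sigma_stationary_g", "theta_sit_deg", "sigma_run_g", "f_run_hz",
                     "theta_cycle_deg", "stairs_offset_deg", "theta_stairs_fallback_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.walk_band_hz[0] < self.walk_band_hz[1]:
            raise ValueError("walk_band_hz lower bound must be below upper bound")
        if self.median_filter_epochs % 2 != 1:
            raise ValueError("median_filter_epochs must be odd")

    def min_bout_for(self, label: str) -> float:
        return float(self.min_bout_s.get(label, self.min_bout_default_s))


@dataclass
class EpochLabelSeries:
    """Per-second behaviour labels on the epoch grid starting at ``t0_s``."""

    labels: list[str]
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(BEHAVIOURS) - {EXCLUDED}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t0_s + np.arange(len(self.labels)), "label": self.labels}
        )


@dataclass(frozen=True)
class StairsThreshold:
    """Individually estimated walk-vs-stairs forward-lean threshold."""

    value_deg: float
    fallback: bool
    n_reference_epochs: int


def _in_band(x: float, band: tuple[float, float]) -> bool:
    return band[0] <= x <= band[1]


def classify_epoch(f: EpochFeatures, theta_stairs_deg: float, config: ClassifierConfig) -> str:
    """Assign one epoch by the fixed decision tree (evaluated in order)."""
    if f.sd_corrected_g < config.sigma_stationary_g:
        return "sedentary" if f.inclination_deg >= config.theta_sit_deg else "stand"
    if f.forward_lean_deg >= config.theta_cycle_deg and _in_band(f.cadence_hz, config.cycle_band_hz):
        return "cycle"
    if f.cadence_hz >= config.f_run_hz or f.sd_corrected_g >= config.sigma_run_g:
        return "run"
    if f.forward_lean_deg >= theta_stairs_deg and _in_band(f.cadence_hz, config.walk_band_hz):
        return "stairs"
    if _in_band(f.cadence_hz, config.walk_band_hz):
        return "walk"
    return "move"


def estimate_stairs_threshold(
    features: list[EpochFeatures], config: ClassifierConfig | None = None
) -> StairsThreshold:
    """Walk-vs-stairs forward-lean threshold from the participant's own data.

    Reference epochs are those the tree provisionally classifies as *walk*
    under the fallback threshold (a one-round pre-pass that keeps cycling,
    running and clearly stairs-like epochs out of the reference set). The
    threshold is the ``stairs_quantile`` of their forward lean plus
    ``stairs_offset_deg``. With fewer than
    ``min_epochs_for_individual_threshold`` reference epochs the fixed
    fallback is returned and flagged: short recordings give uncertain
    individual thresholds.
    """
    if not features:
        raise ValueError("empty feature list")
    config = config or ClassifierConfig()
    ref = [
        f.forward_lean_deg
        for f in features
        if classify_epoch(f, config.theta_stairs_fallback_deg, config) == "walk"
    ]
    if len(ref) < config.min_epochs_for_individual_threshold:
        return StairsThreshold(config.theta_stairs_fallback_deg, True, len(ref))
    q = float(np.quantile(ref, config.stairs_quantile))
    return StairsThreshold(q + config.stairs_offset_deg, False, len(ref))


def _mode_window(window: list[str], centre: str) -> str:
    counts: dict[str, int] = {}
    for lab in window:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab in window if counts[lab] == best]
    if centre in winners:
        return centre
    return winners[0]  # earliest occurrence in the window breaks ties


def _bouts(labels: list[str]) -> list[tuple[int, int, str]]:
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def smooth_labels(raw: EpochLabelSeries, config: ClassifierConfig | None = None) -> EpochLabelSeries:
    """Modal filter then minimum-bout absorption.

    An odd-length majority filter removes isolated flickers; afterwards
    any bout shorter than its class's minimum duration is absorbed into
    the longer neighbouring bout (earlier neighbour on ties). Series
    shorter than the filter window are returned unchanged.
    """
    config = config or ClassifierConfig()
    w = config.median_filter_epochs
    labels = list(raw.labels)
    if len(labels) < w:
        return EpochLabelSeries(labels, raw.t0_s)
    half = w // 2
    filtered = []
    for i in range(len(labels)):
        a, b = max(0, i - half), min(len(labels), i + half + 1)
        filtered.append(_mode_window(labels[a:b], labels[i]))

    # absorb implausibly short bouts, shortest first, until stable
    while True:
        bouts = _bouts(filtered)
        if len(bouts) <= 1:
            break
        short = [
            (b - a, idx)
            for idx, (a, b, lab) in enumerate(bouts)
            if (b - a) < config.min_bout_for(lab)
        ]
        if not short:
            break
        _, idx = min(short)
        a, b, _ = bouts[idx]
        left = bouts[idx - 1] if idx > 0 else None
        right = bouts[idx + 1] if idx < len(bouts) - 1 else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            target = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        filtered[a:b] = [target[2]] * (b - a)
    return EpochLabelSeries(filtered, raw.t0_s)


def classify_features(
    features: list[EpochFeatures],
    config: ClassifierConfig | None = None,
    theta_stairs: StairsThreshold | None = None,
    smooth: bool = True,
    t0_s: float = 0.0,
) -> EpochLabelSeries:
    """Threshold estimation + per-epoch tree + smoothing over a feature list."""
    config = config or ClassifierConfig()
    if theta_stairs is None:
        theta_stairs = estimate_stairs_threshold(features, config)
    raw = EpochLabelSeries(
        [classify_epoch(f, theta_stairs.value_deg, config) for f in features], t0_s
    )
    return smooth_labels(raw, config) if smooth else raw


def classify_recording(
    rec: TriaxialRecording,
    config: ClassifierConfig | None = None,
    cal=None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> EpochLabelSeries:
    """Full pipeline: calibration → filter → features → tree → smoothing."""
    if cal is not None:
        from .calibrate import apply_calibration

        rec = apply_calibration(rec, cal)
    features = extract_features(rec, cutoff_hz)
    return classify_features(features, config, t0_s=rec.start_time)


def classify_recording_chunked(
    rec: TriaxialRecording,
    config: ClassifierConfig | None = None,
    cal=None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    chunk_s: float = 600.0,
) -> EpochLabelSeries:
    """Chunked pipeline, label-identical to :func:`classify_recording`.

    Features are computed per chunk with overlap margins wide enough that
    filter transients and the 4-s cadence context match the whole-recording
    computation; the stairs threshold is then estimated once globally and
    smoothing runs over the concatenated series.
    """
    config = config or ClassifierConfig()
    if cal is not None:
        from .calibrate import apply_calibration

        rec = apply_calibration(rec, cal)
    fs = rec.fs_hz
    n_epochs = int(math.floor(rec.duration_s)) - 1
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch window")
    margin_s = 4.0  # beyond the 1-s cadence context: room for filter edge decay
    features: list[EpochFeatures] = []
    e = 0
    while e < n_epochs:
        e_hi = min(e + int(chunk_s), n_epochs)
        a = max(0.0, e - margin_s)
        b = min(rec.duration_s, e_hi + 2 + margin_s)
        ia, ib = int(round(a * fs)), int(round(b * fs))
        sub = replace(rec, samples=rec.samples[ia:ib])
        sub_feats = extract_features(sub, cutoff_hz)
        off = int(round(a))  # chunk starts on an integer second
        for f in sub_feats:
            gi = f.epoch_index + off
            if e <= gi < e_hi:
                f.epoch_index = gi
                f.t_center_s = gi + 1.0
                features.append(f)
        e = e_hi
    return classify_features(features, config, t0_s=rec.start_time)


@dataclass
class DailySummary:
    """Minutes per behaviour per 24-h window plus the across-day mean."""

    per_day: pd.DataFrame          # one row per complete 24-h window
    partial_day: pd.Series | None  # trailing incomplete window, if any
    mean: pd.Series | None         # mean over complete days; None if none

    def total_minutes(self) -> float:
        tot = float(self.per_day.drop(columns="day", errors="ignore").to_numpy().sum())
        if self.partial_day is not None:
            tot += float(self.partial_day.sum())
        return tot


def aggregate_daily(labels: EpochLabelSeries) -> DailySummary:
    """Minutes per behaviour per calendar-day window from the series start.

    Each 1-s epoch contributes 1/60 minute to its behaviour. Windows are
    consecutive 24-h blocks from ``t0``; the mean is taken across complete
    windows only (a 36-h recording contributes one complete day). The
    trailing partial window is reported separately, never in the mean.
    """
    if len(labels) < 1:
        raise ValueError("empty label series")
    cols = list(BEHAVIOURS) + [EXCLUDED]
    day_len = 86400
    rows = []
    partial = None
    for d0 in range(0, len(labels), day_len):
        chunk = labels.labels[d0 : d0 + day_len]
        counts = {c: 0.0 for c in cols}
        for lab in chunk:
            counts[lab] += 1.0
        minutes = {c: counts[c] / 60.0 for c in cols}
        if len(chunk) == day_len:
            rows.append({"day": d0 // day_len, **minutes})
        else:
            partial = pd.Series(minutes)
    per_day = pd.DataFrame(rows, columns=["day"] + cols)
    mean = per_day[cols].mean() if len(per_day) else None
    return DailySummary(per_day=per_day, partial_day=partial, mean=mean)
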