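"""Synthetic thigh-accelerometer signals with known ground truth.

The generator is deliberately minimal: each behaviour is a gravity unit
vector at a characteristic thigh inclination plus, where the behaviour is
periodic, a sinusoid at its cadence on the longitudinal (U) and
anteroposterior (W) axes, plus Gaussian sensor noise, then device
saturation. This is not a biomechanical gait model — the downstream
classifier consumes only intensity, orientation and cadence features, so
these constructions exercise every branch of the tree while keeping the
truth exactly known. "Move" is generated as intermittent bursts of
band-limited noise (irregular activity with no clear spectral line)
between stand-like postures.

Also provided: heel-drop spike injection for synchronisation anchors,
drifted-clock device copies, and noisy rater annotation tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .classify import BEHAVIOURS, EpochLabelSeries
from .evaluate import AnnotationTrack, Interval, NON_BEHAVIOUR_LABELS
from .signal_core import DeviceModel, TriaxialRecording, apply_device_model

__all__ = [
    "BehaviourProfile",
    "BehaviourParams",
    "BehaviourScript",
    "simulate_recording",
    "inject_heel_drops",
    "derive_drifted_copy",
    "simulate_annotations",
    "lab_script",
    "validation_script",
]


@dataclass(frozen=True)
class BehaviourProfile:
    """Signal model of one behaviour.

    ``inclination_deg`` is the mean thigh angle from gravity;
    ``cadence_hz`` the dominant periodic frequency (0 for static or
    aperiodic behaviours); ``periodic_amplitude_g`` the sinusoid (or, for
    "move", burst-noise) amplitude; ``forward_lean`` fixes the sign of
    the anteroposterior gravity component (False → random sign per
    segment).
    """

    inclination_deg: float
    inclination_jitter_deg: float
    cadence_hz: float
    periodic_amplitude_g: float
    noise_sd_g: float
    forward_lean: bool
    burst: bool = False  # intermittent noise bursts instead of a sinusoid


def _default_profiles() -> dict[str, BehaviourProfile]:
    return {
        "sedentary": BehaviourProfile(75.0, 2.0, 0.0, 0.0, 0.02, True),
        "stand": BehaviourProfile(10.0, 2.0, 0.0, 0.0, 0.02, False),
        "move": BehaviourProfile(15.0, 3.0, 0.75, 0.3, 0.02, False, burst=True),
        "walk": BehaviourProfile(20.0, 2.0, 1.8, 0.35, 0.03, True),
        "run": BehaviourProfile(25.0, 2.0, 2.8, 1.2, 0.05, True),
        "stairs": BehaviourProfile(35.0, 2.0, 1.6, 0.4, 0.03, True),
        "cycle": BehaviourProfile(55.0, 2.0, 1.1, 0.3, 0.03, True),
    }


@dataclass
class BehaviourParams:
    """Per-behaviour signal profiles (see :func:`_default_profiles`)."""

    profiles: dict[str, BehaviourProfile] = field(default_factory=_default_profiles)

    def __getitem__(self, behaviour: str) -> BehaviourProfile:
        if behaviour not in self.profiles:
            raise KeyError(f"unknown behaviour '{behaviour}'")
        return self.profiles[behaviour]


@dataclass
class BehaviourScript:
    """Ordered behaviour segments defining a session."""

    segments: list[tuple[str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for behaviour, dur in self.segments:
            if behaviour not in BEHAVIOURS:
                raise ValueError(f"unknown behaviour '{behaviour}'")
            if not dur > 0:
                raise ValueError(f"segment duration must be positive, got {dur}")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))


def lab_script() -> BehaviourScript:
    """Structured laboratory session: six behaviours of one minute each
    separated by 15-s standing breaks (≈7.5 min total)."""
    order = ["sedentary", "stand", "walk", "stairs", "run", "cycle"]
    segments: list[tuple[str, float]] = []
    for b in order:
        segments.append((b, 60.0))
        segments.append(("stand", 15.0))
    return BehaviourScript(segments)


def validation_script(minutes_per_behaviour: float = 5.0) -> BehaviourScript:
    """All seven behaviours back-to-back, equal durations."""
    return BehaviourScript(
        [(b, minutes_per_behaviour * 60.0) for b in BEHAVIOURS]
    )


def _slow_jitter(rng: np.random.Generator, n: int, fs: float, sd_deg: float) -> np.ndarray:
    """Per-second posture wander, linearly interpolated to the sample grid."""
    n_sec = max(int(np.ceil(n / fs)) + 1, 2)
    knots = rng.normal(0.0, sd_deg, n_sec)
    t = np.arange(n) / fs
    return np.interp(t, np.arange(n_sec, dtype=float), knots)


def _burst_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """On/off envelope of irregular activity bursts (0.8–1.8 s on,
    0.2–0.5 s off), smoothed to avoid step transients. Durations vary
    widely so the envelope itself has no stable periodicity."""
    env = np.zeros(n)
    t = 0.0
    on = True
    while t * fs < n:
        dur = rng.uniform(0.8, 1.8) if on else rng.uniform(0.2, 0.5)
        a, b = int(t * fs), min(int((t + dur) * fs), n)
        if on:
            env[a:b] = 1.0
        t += dur
        on = not on
    # 0.1-s raised-cosine smoothing of the edges; a residual floor keeps
    # the behaviour visibly active between bursts (shifting weight, small
    # adjustments) rather than dropping to a standing-still signal
    k = max(int(0.1 * fs), 1)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.maximum(np.convolve(env, kernel, mode="same"), 0.4)


def _segment_samples(
    behaviour: str,
    profile: BehaviourProfile,
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n) / fs
    incl = np.radians(profile.inclination_deg + _slow_jitter(rng, n, fs, profile.inclination_jitter_deg))
    sign = 1.0 if profile.forward_lean else float(rng.choice([-1.0, 1.0]))
    azim = np.radians(rng.normal(0.0, 5.0))  # small fixed mediolateral tilt
    # unit gravity vector per sample (magnitude exactly 1 before noise)
    g_u = np.cos(incl)
    g_v = np.sin(incl) * np.sin(azim)
    g_w = np.sin(incl) * np.cos(azim) * sign
    samples = np.column_stack([g_u, g_v, g_w])

    amp = profile.periodic_amplitude_g
    if amp > 0 and profile.burst:
        # white bursts: spectrally flat, so the cadence detector sees no
        # line; the analysis chain's own low-pass shapes them downstream
        env = _burst_envelope(rng, n, fs)
        for axis in (0, 2):
            samples[:, axis] += env * amp * rng.normal(0.0, 1.0, n)
    elif amp > 0 and profile.cadence_hz > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        samples[:, 0] += amp * np.sin(2 * np.pi * profile.cadence_hz * t + phase)
        samples[:, 2] += 0.5 * amp * np.cos(2 * np.pi * profile.cadence_hz * t + phase)

    samples += rng.normal(0.0, profile.noise_sd_g, (n, 3))
    return samples


def simulate_recording(
    script: BehaviourScript,
    params: BehaviourParams | None = None,
    fs_hz: float = 25.0,
    device: DeviceModel | None = None,
    seed: int = 0,
) -> tuple[TriaxialRecording, EpochLabelSeries]:
    """Generate a recording plus per-second ground-truth labels.

    Deterministic given ``seed``. The generator grid must satisfy Nyquist
    for every scripted cadence; violating Nyquist is the job of the
    device under test (via :func:`thighacc.signal_core.downsample`), not
    of the truth generator. Returned truth has one label per whole
    second, so labelled seconds sum exactly to the script duration.
    """
    params = params or BehaviourParams()
    device = device or DeviceModel("sens-plus", 4.0, fs_hz)
    max_cadence = max(
        (params[b].cadence_hz for b, _ in script.segments), default=0.0
    )
    if fs_hz < 2 * max_cadence:
        raise ValueError(
            f"fs {fs_hz} Hz below Nyquist for scripted cadence {max_cadence} Hz"
        )
    ss = np.random.SeedSequence([seed, script.seed])
    children = ss.spawn(len(script.segments))

    chunks = []
    truth: list[str] = []
    t_accum = 0.0
    n_accum = 0
    for (behaviour, dur), child in zip(script.segments, children):
        t_accum += dur
        n_end = int(round(t_accum * fs_hz))
        n = n_end - n_accum
        n_accum = n_end
        rng = np.random.default_rng(child)
        chunks.append(_segment_samples(behaviour, params[behaviour], n, fs_hz, rng))
        truth.extend([behaviour] * int(round(dur)))

    samples = np.vstack(chunks)
    ideal = TriaxialRecording(device, 0.0, fs_hz, samples)
    return apply_device_model(ideal, device), EpochLabelSeries(truth, 0.0)


def inject_heel_drops(
    rec: TriaxialRecording,
    times_s,
    n_drops: int = 3,
    amplitude_g: float = 3.0,
    spacing_s: float = 0.25,
    width_s: float = 0.08,
) -> TriaxialRecording:
    """Superimpose heel-drop spike groups on the U axis at anchor times.

    Each anchor gets ``n_drops`` biphasic spikes (a ``width_s`` positive
    impact lobe followed by a smaller negative rebound of the same
    width), ``spacing_s`` apart. The lobe spans at least two samples at
    25 Hz so the spike survives the interpolation involved in clock
    resampling. Device clipping is re-applied, so amplitudes beyond the
    dynamic range saturate exactly as on hardware.
    """
    samples = rec.samples.copy()
    span = rec.duration_s
    for anchor in times_s:
        if not 0.0 <= anchor < span:
            raise ValueError(f"anchor {anchor} s outside recording span [0, {span:.2f}) s")
        for k in range(n_drops):
            t0 = anchor + k * spacing_s
            i0 = int(np.ceil(t0 * rec.fs_hz - 1e-9))
            i1 = int(np.ceil((t0 + width_s) * rec.fs_hz - 1e-9))
            i2 = int(np.ceil((t0 + 2 * width_s) * rec.fs_hz - 1e-9))
            i1 = max(i1, i0 + 1)  # positive lobe covers at least one sample
            samples[i0:min(i1, rec.n_samples), 0] += amplitude_g
            samples[min(i1, rec.n_samples):min(i2, rec.n_samples), 0] -= 0.6 * amplitude_g
    out = TriaxialRecording(rec.device, rec.start_time, rec.fs_hz, samples)
    return apply_device_model(out, rec.device)


def derive_drifted_copy(
    rec: TriaxialRecording,
    offset_s: float,
    drift_ppm: float,
    seed: int = 0,
    noise_sd_g: float = 0.0,
) -> TriaxialRecording:
    """The same physical signal seen by a device with an imperfect clock.

    The copy's clock reads ``t_obs = t_true · (1 + drift_ppm·1e-6) +
    offset_s``; the copy samples its own nominal uniform grid, so its
    sample ``i`` (clock time ``i/fs``) holds the signal at true time
    ``(i/fs − offset_s) / (1 + drift_ppm·1e-6)``, obtained by linear
    interpolation, plus independent sensor noise.
    """
    if abs(drift_ppm) >= 1000:
        raise ValueError(f"|drift_ppm| must be < 1000, got {drift_ppm}")
    scale = 1.0 + drift_ppm * 1e-6
    tau = rec.times
    t_true = (tau - offset_s) / scale
    out = np.column_stack(
        [np.interp(t_true, rec.times, rec.samples[:, j]) for j in range(3)]
    )
    if noise_sd_g > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        out = out + rng.normal(0.0, noise_sd_g, out.shape)
    return TriaxialRecording(rec.device, rec.start_time, rec.fs_hz, out)


def simulate_annotations(
    truth: EpochLabelSeries,
    boundary_jitter_s: float = 0.0,
    confusion_rate: float = 0.0,
    uncertain_rate: float = 0.0,
    seed: int = 0,
    rater: str = "r1",
) -> AnnotationTrack:
    """A noisy human rater's interval annotation of the ground truth.

    Segment boundaries are perturbed by N(0, jitter); each epoch is then
    independently relabelled to a random other behaviour with probability
    ``confusion_rate`` and marked "uncertain" with probability
    ``uncertain_rate``. Deterministic given ``seed``.
    """
    for name, rate in (("confusion_rate", confusion_rate), ("uncertain_rate", uncertain_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, hash(rater) & 0x7FFFFFFF]))
    n = len(truth)

    # interval boundaries from the truth, jittered but kept ordered
    bounds = [0.0]
    labels = []
    for i in range(1, n):
        if truth.labels[i] != truth.labels[i - 1]:
            b = i + (rng.normal(0.0, boundary_jitter_s) if boundary_jitter_s > 0 else 0.0)
            bounds.append(float(np.clip(b, bounds[-1], n)))
            labels.append(truth.labels[i - 1])
    bounds.append(float(n))
    labels.append(truth.labels[n - 1])

    # rasterise back to epochs (majority of each second)
    per_epoch = []
    seg = 0
    for i in range(n):
        mid = i + 0.5
        while seg < len(labels) - 1 and mid >= bounds[seg + 1]:
            seg += 1
        per_epoch.append(labels[seg])

    # independent per-epoch corruption
    others = {b: [o for o in BEHAVIOURS if o != b] for b in BEHAVIOURS}
    out = []
    for lab in per_epoch:
        if uncertain_rate > 0 and rng.random() < uncertain_rate:
            out.append("uncertain")
        elif confusion_rate > 0 and rng.random() < confusion_rate:
            out.append(str(rng.choice(others[lab])))
        else:
            out.append(lab)

    intervals = []
    start = 0
    for i in range(1, n + 1):
        if i == n or out[i] != out[start]:
            intervals.append(
                Interval(truth.t0_s + start, truth.t0_s + i, out[start], rater)
            )
            start = i
    return AnnotationTrack(intervals)
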