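"""Simulate a structured laboratory session and look at the raw signal.

Builds the default scripted protocol (six behaviours of one minute each
with 15-s standing breaks), generates the thigh-worn accelerometer
signal at 25 Hz, and prints per-behaviour signal summaries.
"""

import numpy as np

from thighacc import simulate_recording
from thighacc.preprocess import extract_features
from thighacc.simulator import lab_script

script = lab_script()
rec, truth = simulate_recording(script, fs_hz=25.0, seed=0)
print(f"session: {rec.duration_s / 60:.1f} min at {rec.fs_hz} Hz, "
      f"{rec.n_samples} samples, device ±{rec.device.dynamic_range_g:g} g")

features = extract_features(rec)
print(f"{len(features)} one-second epochs (2-s windows, 1-s overlap)\n")
print(f"{'behaviour':<10} {'epochs':>6} {'SD (g)':>8} {'incl (deg)':>10} {'cadence (Hz)':>12}")
for beh in ("sedentary", "stand", "walk", "stairs", "run", "cycle"):
    rows = [f for f in features if truth.labels[min(f.epoch_index, len(truth) - 1)] == beh]
    sd = np.median([f.sd_raw_g for f in rows])
    incl = np.median([f.inclination_deg for f in rows])
    cad = np.median([f.cadence_hz for f in rows])
    print(f"{beh:<10} {len(rows):>6} {sd:>8.3f} {incl:>10.1f} {cad:>12.2f}")

print("\nSD separates stationary (<0.1 g) from active behaviours; inclination")
print("separates sitting (~75 deg) from standing (~10 deg); cadence and forward")
print("lean separate the gait classes downstream.")
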