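"""Does halving the sampling frequency change classification?

Classifies the same simulated session at the native 25 Hz and after
anti-aliased downsampling to 12.5 Hz, then compares per-class recall
and overall balanced accuracy between the two rates.
"""

from thighacc import classify_recording, downsample, simulate_recording
from thighacc.classify import BEHAVIOURS, EpochLabelSeries
from thighacc.evaluate import class_metrics, confusion
from thighacc.simulator import validation_script

rec25, truth = simulate_recording(validation_script(3.0), fs_hz=25.0, seed=1)
rec12 = downsample(rec25, 12.5)

reports = {}
for name, rec in (("25 Hz", rec25), ("12.5 Hz", rec12)):
    labels = classify_recording(rec)
    cm = confusion(EpochLabelSeries(truth.labels[: len(labels)], 0.0), labels)
    reports[name] = class_metrics(cm)

print(f"{'behaviour':<10} {'recall @25':>11} {'recall @12.5':>13}")
for beh in BEHAVIOURS:
    r25 = reports["25 Hz"].per_class.loc[beh, "recall"]
    r12 = reports["12.5 Hz"].per_class.loc[beh, "recall"]
    print(f"{beh:<10} {r25:>11.3f} {r12:>13.3f}")

ba25 = reports["25 Hz"].overall_balanced_accuracy
ba12 = reports["12.5 Hz"].overall_balanced_accuracy
print(f"\noverall balanced accuracy: {ba25:.3f} at 25 Hz, {ba12:.3f} at 12.5 Hz")
print(f"gap: {abs(ba25 - ba12):.3f} — halving the rate costs almost nothing here,")
print("because daily-movement frequency content sits well below the 6.25 Hz")
print("Nyquist limit of the lower rate.")
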