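"""Generate one synthetic night and look at its ground truth.

The generator produces an 8-h, 200-Hz, 3-axis head-acceleration recording
with a known hypnogram, true heartbeat times, and gross-movement bursts.
"""

import numpy as np

from bcgsleep import SynthConfig, generate_recording

cfg = SynthConfig(seed=42, duration_h=8.0)
rec, truth = generate_recording(cfg, subject_id="demo", night_id="night2")

stages = np.asarray(truth.hypnogram.stages)
print(f"recording: {len(rec)} samples at {rec.fs:.0f} Hz ({rec.duration_s/3600:.1f} h)")
print(f"true beats: {len(truth.beat_times)} "
      f"(mean RR {np.mean(np.diff(truth.beat_times)):.3f} s)")
print(f"movement bursts: {len(truth.bursts)}")
print("stage proportions (fraction of epochs):")
for s in ("WAKE", "REM", "LIGHT", "DEEP"):
    print(f"  {s:<6} {np.mean(stages == s):.3f}")

# Proportions should show a LIGHT plurality with REM/DEEP/WAKE minorities,
# like a scored human night; the exact values vary with the seed.
half = len(stages) // 2
print(f"DEEP fraction, first half {np.mean(stages[:half] == 'DEEP'):.3f} "
      f"vs second half {np.mean(stages[half:] == 'DEEP'):.3f} "
      "(deep sleep concentrates early in the night)")
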