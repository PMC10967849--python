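"""Generate synthetic two-leg IMU gait and inspect the embedded truth.

Builds five seconds of level walking (five 1 s cycles at 200 Hz, 30
channels) and prints the ground-truth event timeline the generator embeds:
six events per cycle in the canonical chronology, with heel strikes
placed exactly at the falling zero crossings of the foot gyro Z channel.
"""

import numpy as np

from imugait import GaitCycleSpec, generate_cycle

spec = GaitCycleSpec(cycle_period=1.0, sample_rate=200.0, noise_sigma_gyro=0.05, seed=7)
stream, truth = generate_cycle(spec, n_cycles=5)

print(f"stream: {stream.n_samples} samples x {stream.data.shape[1]} channels "
      f"at {stream.sample_rate:.0f} Hz")
print(f"truth timeline: {len(truth)} events ({len(truth) // 5} per cycle)\n")
print("first cycle:")
for e in truth.events[:6]:
    print(f"  sample {e.sample_index:4d}  t = {e.sample_index / 200:.3f} s  {e.label}")

foot = stream.channel("foot_l_gz")
hs = [e.sample_index for e in truth if e.label == "L-HS"]
print("\nfoot_l_gz around each L-HS truth index:")
for idx in hs[1:3]:
    vals = " -> ".join(f"{foot[k]:+.3f}" for k in range(idx - 1, idx + 2))
    print(f"  samples {idx - 1}..{idx + 1}: {vals} rad/s")
print("\nThe signal falls through zero steeply (~0.24 rad/s per sample against")
print("0.05 rad/s noise), so the heel-strike detector localizes each event to")
print("within a sample or two of the truth index.")
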