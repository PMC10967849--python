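"""Plan hip-flexion assistance profiles from gait events and motion state.

The force pulse F(t) = A sin(pi t/Ta + alpha) sin(pi t/Ta) + f starts at
toe off, ends at heel strike (Ta = swing period) and its phase shift
alpha is solved so the peak lands on the predicted hip-flexion maximum.
Each upcoming cycle is predicted by carrying the previous cycle's event
intervals forward; any cycle whose majority motion state is not level
walking gets a zero-force profile for safety.
"""

import numpy as np

from imugait import GaitCycleSpec, generate_cycle, plan

spec = GaitCycleSpec(seed=11)
stream, timeline = generate_cycle(spec, n_cycles=8)

# first half level walking, second half stairs: assistance must switch off
states = np.full(stream.n_samples, "LW", dtype=object)
states[stream.n_samples // 2 :] = "US"

assist = plan(states, timeline, A=40.0, f=2.0, sample_rate=spec.sample_rate)
frame = assist.to_frame()
print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

active = frame[frame.A_N > 0]
print(f"\n{len(active)} of {len(frame)} profiles carry force (the LW cycles);")
print("for each, the pulse spans [TO, HS] and peaks at the predicted HMax:")
p = assist.profiles[1]
t = np.linspace(0, p.Ta, 5)
print(f"  profile {p.side}{p.cycle_index}: F at t = {np.round(t, 2).tolist()} s -> "
      f"{np.round(p.force_at(t), 1).tolist()} N")
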