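"""Build the calibration stimulus timelines and a simulated subject response.

The protocol drives one finger at a time: an on-off phase (rest <-> maximum
force, 1 s transitions) used for training, and a graded phase
(0.8 * Fmax * sin^2 arcs) used for evaluation.
"""

import numpy as np

import echoforce as ef

oo = ef.build_onoff_timeline()      # 5 fingers x 5 reps x (4.5+1+4.5+1) s
gr = ef.build_graded_timeline()     # 5 fingers x 5 reps x (4.5+1.5) s
session = ef.concatenate_timelines([oo, gr, oo, gr])

print(f"on-off phase : {oo.duration:6.1f} s  ({oo.n_samples} samples at 30 Hz)")
print(f"graded phase : {gr.duration:6.1f} s  ({gr.n_samples} samples)")
print(f"full session : {session.duration:6.1f} s  (OO1 GR1 OO2 GR2)")
print(f"graded peak  : {gr.values.max():.2f} of Fmax")

# a cooperative but imperfect subject: response lag, per-flexion gain
# variability, sensor noise
trace = ef.simulate_force_response(gr, fmax=20.0, seed=0)
err = ef.nrmse(trace.forces[:, 0], gr.values[:, 0] * 20.0)
print(f"\nsimulated little-finger tracking error vs stimulus: {err:.1%}")
print("(the gap between what was asked and what was 'pressed' -- the noise")
print(" floor any stimulus-trained decoder inherits)")

mask = ef.steady_segment_mask(oo)
print(f"\nsteady-segment mask keeps {mask.sum()} of {oo.n_samples} on-off "
      "samples (last 2/3 of each plateau and rest period)")
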