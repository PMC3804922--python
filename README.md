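# echoforce

Fingertip-force decoding from B-mode ultrasound image features, with
sensorless on-off calibration and incremental (streaming) retraining —
exercisable end to end on a bundled synthetic forearm-image simulator.

## The problem

Forearm ultrasound is a rich, harmless window onto the muscles that drive
the fingers: pressing a finger deforms a localized region of the B-mode
image, and the deformation grows approximately linearly with the applied
force. That makes ultrasound a candidate human-machine interface for
prosthetics and rehabilitation — *if* calibration can be kept short,
sensor-free, and repairable on the fly (an amputee can imagine pressing a
finger, but cannot produce graded ground-truth forces, and the transducer
can slip mid-session). This package implements and tests that pipeline:

* **Features** — a uniform grid of circular ROIs (radius 20 px, centers
  50 px apart; 181 ROIs on the default 700×660 geometry). Each ROI yields
  the least-squares plane coefficients (α, β, γ) of its gray values —
  local mean gradients and mean intensity — concatenated into a feature
  vector of dimension d = 3·181 = 543, then low-pass filtered (causal
  first-order Butterworth, 1 Hz).
* **Decoder** — per-finger ridge regression, g = wᵀv with
  w = (XᵀX + λI)⁻¹Xᵀy and λ = 1. All fingers share one regularized
  inverse A; a new sample updates A in O(d²) via Sherman–Morrison
  (A′ = A − Ax′x′ᵀA / (1 + x′ᵀAx′), b′ = b + x′y′), so streaming training
  is exactly equivalent to batch refitting.
* **Protocol** — an *on-off* phase (rest ↔ maximum force per finger,
  5×5×(4.5+1+4.5+1) s = 275 s) trains the decoder using only the visual
  stimulus as ground truth; a *graded* phase (0.8·Fmax·sin² arcs,
  5×5×(4.5+1.5) s = 150 s) evaluates interpolation to intermediate forces.
  Accuracy is nRMSE (RMS error / target range).
* **Online engine** — per-frame train/predict with persistent filter and
  model state; after a probe shift degrades the prediction, one further
  on-off round restores it.

Since no imaging data accompany the method, the `ussim` module synthesizes
speckle images whose local intensity varies linearly with each finger's
force — the property the decoder relies on — plus a simulated subject
(response lag, per-press gain variability, sensor noise). See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import echoforce as ef
from echoforce import sessions

scene = ef.make_scene(width=400, height=360, seed=11)      # synthetic forearm
phases = sessions.synthesize_experiment(scene, fmax=20.0,  # 20 N per finger
                                        n_reps=2, n_sessions=1, seed=42)
oo, gr = phases["OO1"], phases["GR1"]

# train on steady on-off extremes only, stimulus as ground truth (no sensor)
X, Y = sessions.onoff_training_set(oo, mode="stimulus")
report = ef.evaluate_transfer(X, Y, gr.X, gr.Y_stim, mode="stimulus")
for finger, err in zip(report.fingers, report.mean_nrmse):
    print(f"{finger:>7s}: graded-phase nRMSE {err:6.2%}")
```

prints

```
 little: graded-phase nRMSE  4.06%
   ring: graded-phase nRMSE  3.73%
 middle: graded-phase nRMSE  3.64%
  index: graded-phase nRMSE  3.71%
  thumb: graded-phase nRMSE  3.76%
```

i.e. a decoder that never saw an intermediate force — and never saw a
force sensor — predicts the full graded range to within ~4% of it; the
residual is the simulated subject's response lag and per-press gain
variability, not the decoder. The `examples/` directory has one short
script per capability (protocol, simulator, features, transfer, online
retraining); `echoforce --help` exposes the same workflow as a command
line (`simulate`, `extract`, `train`, `evaluate`, `learning-curve`,
`retrain-demo`).

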