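# Methods

`echoforce` implements a sensorless ultrasound human-machine interface for
fingertip-force decoding: first-order spatial features over a fixed grid of
circular regions of interest (ROIs) on B-mode images of the forearm, linear
ridge decoders from features to per-finger forces, a calibration protocol
that trains only on rest and maximum effort, and a streaming engine based on
rank-one inverse updates. Because no imaging data are distributed with the
method, the package bundles a synthetic image simulator that reproduces the
one property the decoder relies on — locally linear image/force coupling —
and every quantitative claim in the test suite is made on that simulator.

## Calibration protocol

Two stimulus phases drive one finger at a time, in the fixed order little,
ring, middle, index, thumb:

* **On-off phase** — per finger slot: a 1 s linear ramp from rest to
  maximum, a 4.5 s plateau at maximum, a 1 s ramp down, and 4.5 s of rest.
  The five-finger cycle is repeated 5 times:
  5 × 5 × (4.5 + 1 + 4.5 + 1) s = 275 s per phase at the 30 Hz frame rate.
  Transition shape is not constrained by the protocol's arithmetic; a
  linear ramp is used, and transitions are excluded from training anyway
  (below).
* **Graded phase** — per finger slot: a squared-sinusoid arc
  0.8·Fmax·sin²(π t / 4.5 s), t ∈ [0, 4.5 s], followed by 1.5 s of rest;
  5 × 5 × (4.5 + 1.5) s = 150 s per phase. The arc is sampled on an
  inclusive endpoint grid; with an odd per-flexion sample count (135 at
  30 Hz) the 0.8 peak is attained exactly, otherwise to O(1/n²).
  A full experiment is OO1, GR1, OO2, GR2 = 850 s.

Only the **last two-thirds** of each on-off plateau and rest period enter
training sets (`steady_segment_mask`), excluding the transitions and the
subject's settling time.

Fmax is each finger's maximum comfortable force in newtons (default 20 N in
the synthetic experiments, the order of a comfortable fingertip press).

### Simulated subject

A timeline is turned into forces by: a per-flexion gain ~ Normal(1, 0.05)
(each press over- or under-shoots as a whole), a first-order response lag
with time constant 0.2 s, scaling by Fmax, additive Normal(0, 0.02·Fmax)
sensor noise, and clipping to [0, 1.2·Fmax]. The three imperfection
parameters are the tunable realism dials; at zero the trace equals the
stimulus exactly. The defaults were chosen once so that the simulated
stimulus-tracking error is a few percent of the range — the visual order of
published stimulus-following force recordings — and are not fitted to any
dataset. No fatigue, tremor spectra, or psychophysical force-control model
is attempted.

## Synthetic images

A scene is a speckle-like baseline (Gaussian-smoothed uniform noise,
rescaled to mean 120, SD 30, clipped to [0, 255]) plus one localized
Gaussian pattern per finger (SD ≈ 60 px, peak 1, well-separated centers,
slight random anisotropy). In the default `linear` mode a frame is

    clip(baseline + Σ_f force_f · gain · pattern_f + Normal(0, noise_sd))

with gain 40 intensity units per unit normalized force and pixel noise
SD 2. This makes the image/force relationship linear *by construction* —
deliberately so: local-and-linear coupling is the empirical property of
forearm ultrasound under fingertip force that the whole method rests on,
and the simulator's job is to realize it, not to model acoustics. A `warp`
mode (force-scaled displacement field resampling the baseline) exists as a
nonlinear stress-test variant. There is no wave propagation, attenuation,
time-gain compensation or labeled anatomy; consequently, passing tests
show the *algorithmic* claims (equivalences, interpolation from extremes,
recovery after shifts) — they cannot certify performance on real tissue,
where linearity holds only approximately and drift, out-of-plane motion
and intensity nonstationarity are present.

The baseline and patterns live on a canvas padded 128 px beyond the field
of view. A **probe shift** translates the crop window, so all content
moves and fresh speckle enters at the vacated margin, as new tissue would;
shifts are exact group operations (shift then inverse shift restores the
frame bit-for-bit in the noise-free case). Clipping to [0, 255] is applied
last; at the default gain ≥ 99% of pixels stay unclipped at unit force,
and exact-linearity tests scale the speckle down so none clip.

## Features

The content mask of the default geometry is a 700 × 660 px rectangle minus
a 50 × 50 px bottom-right corner notch (emulating a scanner UI overlay).
ROI centers lie on a square lattice with step 50 px, origin (25, 25)
(= radius + 5 px margin from the image origin); a lattice point is kept iff
its full disc of radius 20 px lies inside the mask, which the
implementation checks by binary erosion of the mask with the disc
footprint. This yields 181 ROIs — 182 lattice points minus the one whose
disc touches the notch — and a feature dimension d = 3·181 = 543. (181 is
prime, so no full rectangular lattice can produce it; the notch is what
makes the standard count reachable.) Coordinates are 0-based with
x = column, y = row; disc membership is (x−x_i)² + (y−y_i)² ≤ r².

Per ROI centered at (x_i, y_i), the gray values are approximated by the
least-squares plane α(x_i−x) + β(y_i−y) + γ. Because the pixel disc is
symmetric about its center the normal equations decouple:

    γ = mean(g),  α = −Σ g·(x−x_i) / Σ(x−x_i)²,  β = −Σ g·(y−y_i) / Σ(y−y_i)²

which the tests verify against a generic three-column least-squares solve
to 1e−9. Features are the concatenation (α₁, β₁, γ₁, α₂, …).

All signals — features, forces, and stimulus targets alike — are low-pass
filtered with a **causal, single-pass first-order Butterworth at 1 Hz**
(bilinear design, state initialized from the first sample so constants
pass unchanged). Causality is deliberate: a zero-phase (forward-backward)
filter would be unusable in the streaming engine, and using the same
causal filter offline keeps the offline and online pipelines bit-for-bit
comparable. The price is the filter's phase lag, which both the features
and the targets incur equally.

## Decoding

Per-finger decoding is linear, g = wᵀv, with the ridge solution

    w = (XᵀX + λ I_d)⁻¹ Xᵀy,  λ = 1.

All fingers share the inputs X, hence one regularized inverse
A = (XᵀX + λI)⁻¹ (d × d) serves every finger; only the cross-moments
b = Xᵀy differ (stored as a d × k matrix B, weights W = A·B recomputed
lazily). λ = 1 on unscaled features (γ ≈ 120 gray levels) is a very weak
prior — with thousands of samples the fit is essentially regularized least
squares, and λ's role is to keep the empty and small-sample models
well-posed.

A new pair (x′, y′) is absorbed by the Sherman–Morrison rank-one update

    A′ = A − A x′x′ᵀA / (1 + x′ᵀA x′),  b′ = b + x′ y′

at O(d²) cost independent of how many samples were seen — the property
that makes per-frame (30 Hz) retraining feasible. The empty model is
A = I/λ, B = 0 and predicts 0 for every finger. Numerics: the batch
inverse is computed by a symmetric positive-definite solve and
symmetrized; the denominator 1 + x′ᵀAx′ is guarded (it is positive for SPD
A); A is re-symmetrized every 1000 updates to cap round-off drift (drift
stays < 1e−8 over 10⁴ updates in the tests). Streaming and batch fits
agree to ~1e−6 relative on every tested system, and the model is invariant
to the order of training pairs at the same tolerance.

Accuracy is nRMSE: RMS error divided by the range of the *test* targets
(not the whole session — the evaluated segment defines the task's range).
Folds in which a finger's test targets are constant are skipped with a
warning. Cross-validation follows the train-on-10%/test-on-90% scheme,
repeated 50 times with counter-derived per-repetition seeds.

Two ground-truth modes mirror the two analyses the protocol supports:
**force** (the simulated sensor's newtons, zero for inactive fingers) and
**stimulus** (the timeline fraction × Fmax — the sensorless scenario an
amputee could actually perform). On synthetic data force-mode errors are
optimistic: the decoder is asked to reproduce the very forces that
generated the images, so only pixel/sensor noise remains (≲ 0.1% nRMSE).
Stimulus mode inherits the subject's lag and gain variability (~4% nRMSE
at the defaults) and is the regime comparable with sensorless operation,
an order of magnitude below within-phase errors only because the simulator
lacks the other human variability sources.

The **safety index** between extreme-force feature clusters C_i, C_j is
s_ij = max{σ_i} / ‖C̄_i − C̄_j‖: the largest per-dimension standard
deviation of cluster i (sample convention, n−1) over the distance between
the cluster centroids. Centroid-to-centroid distance is the reading that
makes the index a single scalar per pair; the index is asymmetric by
construction. Small values (a few percent here) mean the on-off patterns
are trivially separable in feature space.

## Online engine

`process_frame` extracts features, advances the causal filters one sample,
and either updates the model (training mode, target required) or only
predicts. Filter states persist across mode switches — the physical signal
is continuous — and the target filter advances only on frames that carry a
target (prediction frames have none). The model therefore depends only on
the multiset of training pairs as filtered, which is what the
retention/equivalence tests assert. Training targets are stimulus × Fmax:
the bars shown to the subject, not a sensor.

`run_learning_curve` replays an on-off stream pair by pair and scores the
graded set at per-repetition checkpoints (per-sample checkpoints are a
parameter away; per-repetition keeps runtime low). With only one finger's
plateau and no rest anchor the intercept is unconstrained and that
finger's graded error exceeds 50%; with no data at all the model predicts
0 and the error is exactly nrmse(0, truth). After one full on-off round
the curve is flat: additional rounds revisit already-spanned directions.

`run_retraining_scenario` trains one on-off repetition per finger, scores
a squared-sinusoid stimulus, shifts the scene 60 px (the transducer
slips), rescores, streams one more on-off round on the shifted scene
(appending knowledge — the model is never reset; a reset is possible but
off by default), and rescores. On synthetic scenes the mean error inflates
far beyond 2× after the shift and returns to within 1.5× of the baseline
after the single retraining round. Because d greatly exceeds the number of
distinct training directions, one linear map can serve both the original
and the shifted scene simultaneously — the same over-parameterization that
makes on-demand retraining work.

## Problem sizes and reproducibility

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning, so every simulation, session, and evaluation is exactly
reproducible. The test suite runs its stochastic scenario checks on
reduced fields of view (300–400 px, 29–55 ROIs) with 2 protocol
repetitions; `scripts/acceptance.py` runs the full 700 × 660 / 181-ROI /
d = 543 geometry, also with 2 repetitions per phase — the error regimes
are insensitive to going from 2 to the protocol's 5 repetitions, since the
learning curve is flat after the first round. Known limitations: the
simulator's linearity-by-construction (see above), a subject model with no
fatigue or learning effects, integer-pixel probe shifts only, and no
probe-motion compensation — the method's answer to probe motion is
retraining, not image registration.
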