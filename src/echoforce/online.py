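"""Frame-by-frame session engine, learning curves and probe-shift recovery.

The streaming engine mirrors the offline pipeline exactly: per frame it
extracts plane-fit features, advances the causal 1 Hz Butterworth filters
(whose state persists across mode switches — the physical signal is
continuous), and either absorbs the (features, target) pair via a
Sherman-Morrison update (training mode) or just predicts (prediction
mode). Because the filters are causal and the incremental update is
algebraically equivalent to a batch refit, feeding identical frames
through :func:`process_frame` or through the offline pipeline yields the
same model and predictions up to round-off. Mode switches never reset the
model or the filters, so knowledge accumulates across arbitrary
train/predict interleavings.

Targets during training are the *stimulus* values scaled by Fmax — the
bars shown to the subject, not a force sensor — matching the sensorless
calibration scenario.

:func:`run_learning_curve` replays an on-off stream and scores the graded
phase after each protocol repetition; :func:`run_retraining_scenario`
trains briefly, perturbs the scene with a probe shift, and shows that one
further on-off round restores the accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import seedseq
from scipy import signal as sig

from . import features as feat
from . import sessions, stimulus as stim, ussim
from .errors import InvalidInputError
from .regress import RidgeModel, nrmse, predict, update_incremental


class _CausalFilterBank:
    """Per-channel first-order Butterworth state, advanced one sample at a time."""

    def __init__(self, n_channels: int, cutoff: float = 1.0, fs: float = 30.0):
        self.b, self.a = sig.butter(1, cutoff, fs=fs)
        self._zi_unit = sig.lfilter_zi(self.b, self.a)
        self.zi = None  # (1, n_channels) once initialized from the first sample
        self.n_channels = n_channels

    def step(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.zi is None:
            self.zi = self._zi_unit[:, None] * x[None, :]
        y, self.zi = sig.lfilter(self.b, self.a, x[None, :], axis=0, zi=self.zi)
        return y[0]


@dataclass
class SessionState:
    """Mutable state of one online session."""

    grid: feat.ROIGrid
    model: RidgeModel
    mode: str = "prediction"                 # "training" | "prediction"
    feature_filter: _CausalFilterBank = None
    target_filter: _CausalFilterBank = None
    frame_count: int = 0
    event_log: list = field(default_factory=list)

    @classmethod
    def create(cls, grid: feat.ROIGrid, n_fingers: int = 5, lam: float = 1.0,
               cutoff: float = 1.0, fs: float = 30.0,
               mode: str = "prediction") -> "SessionState":
        return cls(
            grid=grid,
            model=RidgeModel(d=grid.feature_dim, k=n_fingers, lam=lam),
            mode=mode,
            feature_filter=_CausalFilterBank(grid.feature_dim, cutoff, fs),
            target_filter=_CausalFilterBank(n_fingers, cutoff, fs),
        )

    def set_mode(self, mode: str) -> None:
        """Switch training/prediction; model and filter states persist."""
        if mode not in ("training", "prediction"):
            raise InvalidInputError(f"unknown mode {mode!r}")
        if mode != self.mode:
            self.event_log.append((self.frame_count, f"mode -> {mode}"))
        self.mode = mode


def process_frame(state: SessionState, frame, target=None) -> np.ndarray:
    """Process one frame; returns the per-finger force prediction.

    In training mode ``target`` (k-vector, newtons — typically stimulus
    fraction x Fmax) is filtered and absorbed together with the filtered
    features before predicting; in prediction mode ``target`` is ignored.
    Per-frame arithmetic is O(d^2) in training and O(d k) in prediction.
    """
    x = state.feature_filter.step(feat.extract_features(frame, state.grid))
    if state.mode == "training":
        if target is None:
            raise InvalidInputError("training mode requires a target vector")
        y = state.target_filter.step(np.asarray(target, dtype=float))
        update_incremental(state.model, x, y)
    state.frame_count += 1
    return predict(state.model, x)


@dataclass
class LearningCurve:
    """Per-finger graded-phase error after each training checkpoint."""

    fingers: tuple[str, ...]
    samples_seen: np.ndarray       # (c,) cumulative training samples
    errors: np.ndarray             # (c, k) per-finger nRMSE

    def final(self) -> np.ndarray:
        return self.errors[-1]


def repetition_checkpoints(timeline: stim.StimulusTimeline,
                           selection: np.ndarray | None = None) -> np.ndarray:
    """Sample counts at the end of each full protocol cycle (repetition).

    ``selection`` restricts to a subset of samples (e.g. a steady-segment
    mask); checkpoints then count selected samples up to each boundary.
    """
    boundaries = np.flatnonzero(np.diff(timeline.repetition_index)) + 1
    boundaries = np.append(boundaries, timeline.n_samples)
    if selection is None:
        return boundaries
    csum = np.cumsum(selection.astype(int))
    return np.array([csum[b - 1] for b in boundaries])


def run_learning_curve(train_X, train_Y, eval_X, eval_Y, checkpoints,
                       lam: float = 1.0,
                       fingers: tuple[str, ...] = stim.FINGERS) -> LearningCurve:
    """Stream training pairs one by one, scoring the eval set at checkpoints.

    The model starts empty (predicting 0 everywhere), so a finger with no
    training data scores exactly ``nrmse(0, truth)``. On the standard
    protocol the curve flattens after one full on-off round: later
    repetitions only revisit already-spanned feature directions.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_Y = np.atleast_2d(np.asarray(train_Y, dtype=float))
    eval_X = np.asarray(eval_X, dtype=float)
    eval_Y = np.atleast_2d(np.asarray(eval_Y, dtype=float))
    k = train_Y.shape[1]
    model = RidgeModel(d=train_X.shape[1], k=k, lam=lam)
    checkpoints = np.asarray(checkpoints, dtype=int)
    errors = np.empty((len(checkpoints), k))
    pos = 0
    for c, stop in enumerate(checkpoints):
        while pos < stop:
            update_incremental(model, train_X[pos], train_Y[pos])
            pos += 1
        pred = predict(model, eval_X)
        errors[c] = [nrmse(pred[:, j], eval_Y[:, j]) for j in range(k)]
    return LearningCurve(fingers=tuple(fingers[:k]),
                         samples_seen=checkpoints, errors=errors)


@dataclass
class RetrainReport:
    """Per-finger errors before a probe shift, after it, and after retraining."""

    fingers: tuple[str, ...]
    err_before: np.ndarray
    err_shifted: np.ndarray
    err_retrained: np.ndarray

    def summary(self) -> str:
        rows = [f"{f:>8s}  {b:6.2%}  {s:6.2%}  {r:6.2%}"
                for f, b, s, r in zip(self.fingers, self.err_before,
                                      self.err_shifted, self.err_retrained)]
        header = f"{'finger':>8s}  {'before':>6s}  {'shift':>6s}  {'retrain':>6s}"
        return "\n".join([header] + rows)


def _evaluate_on_scene(state: SessionState, scene, timeline, fmax, seed,
                       **subject_kwargs):
    """Predict through the engine over a fresh stimulus; per-finger nRMSE
    against the filtered stimulus targets."""
    phase = sessions.synthesize_phase(scene, timeline, fmax, seed=seed,
                                      grid=state.grid, **subject_kwargs)
    state.set_mode("prediction")
    normalized = phase.force_trace.forces / phase.force_trace.fmax
    preds = np.empty_like(phase.Y_stim)
    render_seed = seedseq(seed).spawn(3)[2]
    for i, frame in enumerate(ussim.render_session(scene, normalized,
                                                   seed=render_seed)):
        preds[i] = process_frame(state, frame)
    k = phase.Y_stim.shape[1]
    return np.array([nrmse(preds[:, j], phase.Y_stim[:, j]) for j in range(k)])


def _train_one_round(state: SessionState, scene, fmax, seed, fs=30.0,
                     **subject_kwargs):
    """Stream one on-off repetition per finger through the engine in
    training mode, with stimulus x Fmax as the target."""
    timeline = stim.build_onoff_timeline(n_fingers=scene.n_fingers, n_reps=1,
                                         fs=fs)
    subject_seed, render_seed = seedseq(seed).spawn(2)
    trace = stim.simulate_force_response(timeline, fmax, seed=subject_seed,
                                         **subject_kwargs)
    targets = timeline.values * trace.fmax
    normalized = trace.forces / trace.fmax
    state.set_mode("training")
    for i, frame in enumerate(ussim.render_session(scene, normalized,
                                                   seed=render_seed)):
        process_frame(state, frame, target=targets[i])


def run_retraining_scenario(
    scene: ussim.SceneState,
    fmax=20.0,
    shift: tuple[int, int] = (60, 0),
    seed=None,
    fs: float = 30.0,
    grid: feat.ROIGrid | None = None,
    **subject_kwargs,
) -> RetrainReport:
    """Train briefly, perturb the probe position, retrain, and compare.

    One on-off repetition per finger trains the engine; accuracy is then
    scored on a squared-sinusoid stimulus. The scene is shifted by
    ``shift`` pixels (the transducer slips), the evaluation repeated on
    the degraded input, one further on-off round is streamed on the
    shifted scene (appending knowledge, never resetting), and the
    evaluation repeated once more. Returns the three per-finger nRMSE sets.
    """
    if grid is None:
        grid = feat.build_roi_grid(
            feat.default_content_mask(scene.width, scene.height))
    fmax_arr = np.broadcast_to(np.atleast_1d(np.asarray(fmax, float)),
                               (scene.n_fingers,)).copy()
    seeds = seedseq(seed).spawn(5)
    state = SessionState.create(grid, n_fingers=scene.n_fingers, fs=fs)

    eval_timeline = stim.build_graded_timeline(n_fingers=scene.n_fingers,
                                               n_reps=1, fs=fs)

    _train_one_round(state, scene, fmax_arr, seeds[0], fs=fs, **subject_kwargs)
    err_before = _evaluate_on_scene(state, scene, eval_timeline, fmax_arr,
                                    seeds[1], **subject_kwargs)

    shifted = ussim.apply_probe_shift(scene, *shift)
    err_shifted = _evaluate_on_scene(state, shifted, eval_timeline, fmax_arr,
                                     seeds[2], **subject_kwargs)

    _train_one_round(state, shifted, fmax_arr, seeds[3], fs=fs, **subject_kwargs)
    err_retrained = _evaluate_on_scene(state, shifted, eval_timeline, fmax_arr,
                                       seeds[4], **subject_kwargs)

    fingers = stim.FINGERS[:scene.n_fingers]
    return RetrainReport(fingers=tuple(fingers), err_before=err_before,
                         err_shifted=err_shifted, err_retrained=err_retrained)
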