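"""End-to-end synthesis of calibration sessions on a synthetic scene.

Glue between the simulator and the learning modules: build a stimulus
phase, simulate the subject's force response, render one frame per
sample, extract plane-fit features and low-pass filter every signal
(features, forces and stimulus targets alike, 1 Hz causal Butterworth)
— yielding the matrices the regression and online modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import seedseq

from . import features as feat
from . import stimulus as stim
from . import ussim


@dataclass
class PhaseData:
    """One synthesized phase: stimulus, forces, and conditioned matrices."""

    name: str                      # e.g. "OO1", "GR1"
    timeline: stim.StimulusTimeline
    force_trace: stim.ForceTrace
    X: np.ndarray                  # (n, d) filtered features
    Y_force: np.ndarray            # (n, k) filtered simulated sensor forces, N
    Y_stim: np.ndarray             # (n, k) filtered stimulus * fmax, N
    X_raw: np.ndarray              # (n, d) unfiltered features

    @property
    def steady_mask(self) -> np.ndarray:
        return stim.steady_segment_mask(self.timeline)


def synthesize_phase(
    scene: ussim.SceneState,
    timeline: stim.StimulusTimeline,
    fmax,
    seed=None,
    grid: feat.ROIGrid | None = None,
    name: str = "",
    lag_tau: float = 0.2,
    gain_sd: float = 0.05,
    noise_sd_frac: float = 0.02,
    cutoff: float = 1.0,
) -> PhaseData:
    """Simulate one stimulus phase end to end on ``scene``.

    ``seed`` drives both the subject model and the per-frame pixel noise
    (two independent child streams). Set ``lag_tau = gain_sd =
    noise_sd_frac = 0`` and a zero-noise scene for the noiseless regime in
    which the feature/force relationship is exactly linear.
    """
    if grid is None:
        grid = feat.build_roi_grid(
            feat.default_content_mask(scene.width, scene.height))
    subject_seed, render_seed = seedseq(seed).spawn(2)
    trace = stim.simulate_force_response(
        timeline, fmax, lag_tau=lag_tau, gain_sd=gain_sd,
        noise_sd_frac=noise_sd_frac, seed=subject_seed)
    normalized = trace.forces / trace.fmax
    frames = ussim.render_session(scene, normalized, seed=render_seed)
    X_raw = feat.extract_feature_matrix(frames, grid)
    fs = timeline.sample_rate
    return PhaseData(
        name=name,
        timeline=timeline,
        force_trace=trace,
        X=feat.lowpass_filter(X_raw, cutoff=cutoff, fs=fs),
        Y_force=feat.lowpass_filter(trace.forces, cutoff=cutoff, fs=fs),
        Y_stim=feat.lowpass_filter(timeline.values * trace.fmax,
                                   cutoff=cutoff, fs=fs),
        X_raw=X_raw,
    )


def synthesize_experiment(
    scene: ussim.SceneState,
    fmax,
    n_reps: int = 5,
    n_sessions: int = 2,
    seed=None,
    grid: feat.ROIGrid | None = None,
    fs: float = 30.0,
    **subject_kwargs,
) -> dict[str, PhaseData]:
    """Synthesize the full protocol: OO1, GR1, OO2, GR2 (by default).

    Returns phases keyed by name. Each session is an on-off phase followed
    by a graded phase; with the standard timing and 5 repetitions the four
    phases span 275 + 150 + 275 + 150 = 850 s.
    """
    if grid is None:
        grid = feat.build_roi_grid(
            feat.default_content_mask(scene.width, scene.height))
    n = scene.n_fingers
    streams = seedseq(seed).spawn(2 * n_sessions)
    phases: dict[str, PhaseData] = {}
    for s in range(1, n_sessions + 1):
        oo = stim.build_onoff_timeline(n_fingers=n, n_reps=n_reps, fs=fs)
        gr = stim.build_graded_timeline(n_fingers=n, n_reps=n_reps, fs=fs)
        phases[f"OO{s}"] = synthesize_phase(
            scene, oo, fmax, seed=streams[2 * s - 2], grid=grid,
            name=f"OO{s}", **subject_kwargs)
        phases[f"GR{s}"] = synthesize_phase(
            scene, gr, fmax, seed=streams[2 * s - 1], grid=grid,
            name=f"GR{s}", **subject_kwargs)
    return phases


def onoff_training_set(phase: PhaseData, mode: str = "stimulus"):
    """Steady-segment (last two-thirds) training pairs from an on-off phase."""
    mask = phase.steady_mask
    Y = phase.Y_stim if mode == "stimulus" else phase.Y_force
    return phase.X[mask], Y[mask]


def build_onoff_clusters(phase: PhaseData) -> "ClusterSet":
    """Group steady on-off feature samples into rest + per-finger clusters."""
    from .regress import ClusterSet

    mask = phase.steady_mask
    labels = phase.timeline.phase_labels
    finger_idx = phase.timeline.finger_index
    clusters = {"rest": phase.X[mask & (labels == stim.PHASE_REST)]}
    for f, name in enumerate(phase.timeline.fingers):
        sel = mask & (labels == stim.PHASE_ON) & (finger_idx == f)
        clusters[name] = phase.X[sel]
    return ClusterSet(clusters)
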