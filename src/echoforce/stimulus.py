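"""Stimulus timelines and a simulated subject following them.

The calibration protocol alternates two kinds of visual stimulus, both
presented finger by finger (little, ring, middle, index, thumb):

* an *on-off* phase in which each finger is driven from rest to maximum
  force and back (1 s linear transitions around a 4.5 s plateau, 4.5 s of
  rest in between), the whole cycle repeated a number of times — with the
  defaults this lasts 5 x 5 x (4.5 + 1 + 4.5 + 1) = 275 s;
* a *graded* phase in which the target force follows a squared-sinusoid
  arc peaking at a configurable fraction (0.8 by default) of the finger's
  maximum force, 4.5 s per flexion with 1.5 s of rest — 150 s total with
  the defaults.

Timelines store the target force as a fraction of each finger's maximum
comfortable force ``Fmax``; :func:`simulate_force_response` turns a
timeline into newtons the way a cooperative subject would, with a
first-order response lag, per-flexion gain variability and sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidInputError, InvalidParameterError, PhaseError

FINGERS: tuple[str, ...] = ("little", "ring", "middle", "index", "thumb")

#: phase label values used in :attr:`StimulusTimeline.phase_labels`
PHASE_REST = "rest"
PHASE_TRANSITION = "transition"
PHASE_ON = "on"
PHASE_GRADED = "graded"


@dataclass
class StimulusTimeline:
    """Per-sample, per-finger target force fractions with phase annotations.

    ``values[t, f]`` is the target force of finger ``f`` at sample ``t`` as a
    fraction of that finger's Fmax, in [0, 1]. At most one finger is active
    at any sample. ``phase_labels`` tags each sample as ``rest``,
    ``transition``, ``on`` or ``graded``; ``repetition_index`` and
    ``finger_index`` identify the protocol slot the sample belongs to.
    """

    sample_rate: float
    fingers: tuple[str, ...]
    values: np.ndarray
    phase_labels: np.ndarray
    repetition_index: np.ndarray
    finger_index: np.ndarray
    kind: str = "onoff"  # "onoff" | "graded" | "mixed"

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_fingers(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Nominal duration in seconds (samples / sample rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.fingers))
        df.insert(0, "time_s", self.times)
        df["phase_label"] = self.phase_labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ForceTrace:
    """Measured (here: simulated) fingertip forces in newtons."""

    sample_rate: float
    forces: np.ndarray  # (n, k) newtons
    fmax: np.ndarray  # (k,) newtons

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.fmax = np.asarray(self.fmax, dtype=float)

    def to_frame(self, fingers: tuple[str, ...] = FINGERS) -> pd.DataFrame:
        df = pd.DataFrame(self.forces, columns=list(fingers[: self.forces.shape[1]]))
        df.insert(0, "time_s", np.arange(len(df)) / self.sample_rate)
        return df

    def to_csv(self, path, fingers: tuple[str, ...] = FINGERS) -> None:
        self.to_frame(fingers).to_csv(path, index=False)


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {value!r}")


def _finger_labels(n_fingers: int) -> tuple[str, ...]:
    if n_fingers <= len(FINGERS):
        return FINGERS[:n_fingers]
    return FINGERS + tuple(f"finger{i}" for i in range(len(FINGERS), n_fingers))


def build_onoff_timeline(
    n_fingers: int = 5,
    n_reps: int = 5,
    t_on: float = 4.5,
    t_off: float = 4.5,
    t_trans: float = 1.0,
    fs: float = 30.0,
) -> StimulusTimeline:
    """Build the on-off calibration stimulus.

    Per finger slot: linear ramp 0→1 over ``t_trans``, plateau at exactly 1
    for ``t_on``, ramp back down over ``t_trans``, rest at exactly 0 for
    ``t_off``. Fingers cycle little→ring→middle→index→thumb, the cycle
    repeated ``n_reps`` times, for a total of
    ``n_fingers * n_reps * (t_on + t_off + 2 * t_trans)`` seconds.
    """
    _check_positive(n_fingers=n_fingers, n_reps=n_reps, t_on=t_on, t_off=t_off,
                    t_trans=t_trans, fs=fs)
    n_tr = int(round(t_trans * fs))
    n_on = int(round(t_on * fs))
    n_off = int(round(t_off * fs))
    if min(n_tr, n_on, n_off) < 1:
        raise InvalidParameterError("every segment must span at least one sample")

    up = np.arange(1, n_tr + 1) / n_tr            # ends exactly at 1
    down = up[::-1] - 1.0 / n_tr                  # starts just below 1, ends at 0
    slot_values = np.concatenate([up, np.ones(n_on), down, np.zeros(n_off)])
    slot_labels = np.concatenate([
        np.full(n_tr, PHASE_TRANSITION),
        np.full(n_on, PHASE_ON),
        np.full(n_tr, PHASE_TRANSITION),
        np.full(n_off, PHASE_REST),
    ])
    return _assemble(slot_values, slot_labels, n_fingers, n_reps, fs, kind="onoff")


def build_graded_timeline(
    n_fingers: int = 5,
    n_reps: int = 5,
    t_flex: float = 4.5,
    t_rest: float = 1.5,
    peak_fraction: float = 0.8,
    fs: float = 30.0,
) -> StimulusTimeline:
    """Build the graded stimulus: squared-sinusoid flexions.

    Each flexion follows ``peak_fraction * sin^2(pi * t / t_flex)`` for
    ``t`` in [0, t_flex] — zero at both ends, maximal at the midpoint —
    followed by ``t_rest`` at rest. The arc is sampled on an inclusive
    grid, so with an odd per-flexion sample count (the case at the default
    30 Hz) the peak value is attained exactly.
    """
    _check_positive(n_fingers=n_fingers, n_reps=n_reps, t_flex=t_flex,
                    t_rest=t_rest, fs=fs)
    if not 0 < peak_fraction <= 1:
        raise InvalidParameterError(
            f"peak_fraction must be in (0, 1], got {peak_fraction!r}")
    n_flex = int(round(t_flex * fs))
    n_rest = int(round(t_rest * fs))
    if min(n_flex, n_rest) < 1:
        raise InvalidParameterError("every segment must span at least one sample")

    t = np.linspace(0.0, t_flex, n_flex)
    arc = peak_fraction * np.sin(np.pi * t / t_flex) ** 2
    slot_values = np.concatenate([arc, np.zeros(n_rest)])
    slot_labels = np.concatenate([
        np.full(n_flex, PHASE_GRADED),
        np.full(n_rest, PHASE_REST),
    ])
    return _assemble(slot_values, slot_labels, n_fingers, n_reps, fs, kind="graded")


def _assemble(slot_values, slot_labels, n_fingers, n_reps, fs, kind):
    n_slot = len(slot_values)
    n_total = n_slot * n_fingers * n_reps
    values = np.zeros((n_total, n_fingers))
    labels = np.empty(n_total, dtype=object)
    rep_idx = np.empty(n_total, dtype=int)
    fin_idx = np.empty(n_total, dtype=int)
    pos = 0
    for rep in range(n_reps):
        for f in range(n_fingers):
            sl = slice(pos, pos + n_slot)
            values[sl, f] = slot_values
            labels[sl] = slot_labels
            rep_idx[sl] = rep
            fin_idx[sl] = f
            pos += n_slot
    return StimulusTimeline(
        sample_rate=fs,
        fingers=_finger_labels(n_fingers),
        values=values,
        phase_labels=labels.astype(str),
        repetition_index=rep_idx,
        finger_index=fin_idx,
        kind=kind,
    )


def concatenate_timelines(timelines: list[StimulusTimeline]) -> StimulusTimeline:
    """Concatenate phases into one session timeline (e.g. OO1, GR1, OO2, GR2)."""
    if not timelines:
        raise InvalidInputError("need at least one timeline")
    fs = timelines[0].sample_rate
    k = timelines[0].n_fingers
    for tl in timelines:
        if tl.sample_rate != fs or tl.n_fingers != k:
            raise InvalidInputError("timelines must share sample_rate and fingers")
    kinds = {tl.kind for tl in timelines}
    return StimulusTimeline(
        sample_rate=fs,
        fingers=timelines[0].fingers,
        values=np.concatenate([tl.values for tl in timelines]),
        phase_labels=np.concatenate([tl.phase_labels for tl in timelines]),
        repetition_index=np.concatenate([tl.repetition_index for tl in timelines]),
        finger_index=np.concatenate([tl.finger_index for tl in timelines]),
        kind=kinds.pop() if len(kinds) == 1 else "mixed",
    )


def _contiguous_runs(mask: np.ndarray):
    """Yield (start, stop) for maximal True runs of a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def steady_segment_mask(timeline: StimulusTimeline,
                        keep_fraction: float = 2.0 / 3.0) -> np.ndarray:
    """Select the steady tail of every plateau and rest period.

    Returns a boolean mask keeping the last ``keep_fraction`` of each
    contiguous ``on`` and ``rest`` run; transition samples are always
    excluded. Only meaningful for on-off timelines — samples near the
    transitions would otherwise contaminate the extreme-force training set.
    """
    if not 0 < keep_fraction <= 1:
        raise InvalidParameterError(
            f"keep_fraction must be in (0, 1], got {keep_fraction!r}")
    if np.any(timeline.phase_labels == PHASE_GRADED):
        raise PhaseError("steady_segment_mask applies to on-off timelines only")
    mask = np.zeros(timeline.n_samples, dtype=bool)
    for label in (PHASE_ON, PHASE_REST):
        runs = timeline.phase_labels == label
        for start, stop in _contiguous_runs(runs):
            n_keep = int(round((stop - start) * keep_fraction))
            if n_keep:
                mask[stop - n_keep:stop] = True
    return mask


def _flexion_runs(values_f: np.ndarray):
    return _contiguous_runs(values_f > 0)


def simulate_force_response(
    timeline: StimulusTimeline,
    fmax,
    lag_tau: float = 0.2,
    gain_sd: float = 0.05,
    noise_sd_frac: float = 0.02,
    seed=None,
) -> ForceTrace:
    """Simulate a cooperative subject's force output for a stimulus.

    The target fraction is scaled by a per-flexion gain ~ Normal(1, gain_sd)
    (one draw per contiguous flexion — subjects over- or under-shoot each
    press as a whole), passed through a first-order lag with time constant
    ``lag_tau`` seconds, scaled to newtons by that finger's ``fmax``, and
    corrupted with additive Normal(0, noise_sd_frac * fmax) sensor noise.
    Forces are clipped to [0, 1.2 * fmax]. With all three imperfections at
    zero the output equals ``timeline.values * fmax`` exactly.
    """
    if lag_tau < 0:
        raise InvalidParameterError(f"lag_tau must be >= 0, got {lag_tau!r}")
    fmax = np.atleast_1d(np.asarray(fmax, dtype=float))
    if fmax.size == 1:
        fmax = np.full(timeline.n_fingers, fmax[0])
    if fmax.shape != (timeline.n_fingers,) or np.any(fmax <= 0):
        raise InvalidParameterError("fmax must be positive, one value per finger")

    rng = np.random.default_rng(seed)
    dt = 1.0 / timeline.sample_rate
    alpha = 1.0 if lag_tau == 0 else dt / (lag_tau + dt)

    scaled = timeline.values.copy()
    for f in range(timeline.n_fingers):
        for start, stop in _flexion_runs(timeline.values[:, f]):
            gain = rng.normal(1.0, gain_sd) if gain_sd > 0 else 1.0
            scaled[start:stop, f] *= gain

    # first-order lag y[i] = y[i-1] + alpha (u[i] - y[i-1]), y[0] = u[0]
    b, a = [alpha], [1.0, alpha - 1.0]
    lagged = np.empty_like(scaled)
    for f in range(timeline.n_fingers):
        zi = [(1.0 - alpha) * scaled[0, f]]
        lagged[:, f], _ = signal.lfilter(b, a, scaled[:, f], zi=zi)

    forces = lagged * fmax
    if noise_sd_frac > 0:
        forces = forces + rng.normal(0.0, noise_sd_frac * fmax,
                                     size=forces.shape)
    forces = np.clip(forces, 0.0, 1.2 * fmax)
    return ForceTrace(sample_rate=timeline.sample_rate, forces=forces, fmax=fmax)


def timeline_from_csv(path, fs: float | None = None) -> StimulusTimeline:
    """Load a timeline from the package CSV dialect (see :meth:`to_csv`)."""
    df = pd.read_csv(path)
    finger_cols = [c for c in df.columns if c not in ("time_s", "phase_label")]
    times = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 30.0
    labels = df["phase_label"].to_numpy(dtype=str)
    values = df[finger_cols].to_numpy(dtype=float)
    kind = "graded" if np.any(labels == PHASE_GRADED) else "onoff"
    return StimulusTimeline(
        sample_rate=float(fs),
        fingers=tuple(finger_cols),
        values=values,
        phase_labels=labels,
        repetition_index=np.zeros(len(df), dtype=int),
        finger_index=np.argmax(values, axis=1),
        kind=kind,
    )
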