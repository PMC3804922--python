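"""Synthetic B-mode-like image sequences driven by finger forces.

No imaging data accompany the method, so this module is the package's data
source. It emulates the one property of forearm ultrasound that the
decoder relies on: gray-level structure that changes *locally* and
approximately *linearly* with each finger's applied force (each flexor
muscle projects to its own neighbourhood of the image). A scene is a
speckle-like baseline plus one localized spatial pattern per finger, added
in proportion to the normalized force:

    frame = clip(baseline + sum_f force_f * gain * pattern_f + noise)

The baseline and patterns live on a canvas padded beyond the field of
view; a probe shift translates the crop window, so previously unseen
speckle enters at the vacated margin, as new tissue would. The default
``linear`` mode makes the feature/force relationship linear by
construction (the regime the decoder assumes); ``warp`` mode instead
deforms the baseline with a force-scaled displacement field, a nonlinear
stress-test variant.

No acoustic physics is simulated — no wave propagation, attenuation or
time-gain compensation — and no anatomical structures are labeled.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._seeding import seedseq
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, InvalidInputError, InvalidParameterError

#: canvas padding (px) on each side of the field of view; bounds probe shifts
DEFAULT_PAD = 128

# fractional (x, y) positions of per-finger pattern centers for up to 5 fingers;
# chosen well separated so distinct fingers imprint distinct image regions
_CENTER_LAYOUT = [(0.20, 0.25), (0.80, 0.25), (0.50, 0.50),
                  (0.20, 0.75), (0.80, 0.75)]


@dataclass
class Frame:
    """One rendered grayscale frame, intensities in [0, 255]."""

    pixels: np.ndarray
    timestamp: float = 0.0

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SceneState:
    """Simulator state from which frames are rendered.

    ``baseline`` and ``patterns`` views expose the current field of view
    (shape ``(height, width)``); the underlying canvas is larger by ``pad``
    on every side so the crop window can translate under probe shifts.
    ``probe_offset`` is the accumulated (dx, dy) content translation in
    pixels. ``pattern_gain`` is in intensity units per unit normalized
    force; patterns take values in [-1, 1] with >= 80% of their absolute
    mass inside a disc of radius << the image width around their centroid.
    """

    width: int
    height: int
    pattern_gain: float
    noise_sd: float
    mode: str
    probe_offset: tuple[int, int]
    pad: int
    canvas_baseline: np.ndarray      # (height + 2 pad, width + 2 pad)
    canvas_patterns: np.ndarray      # (k, height + 2 pad, width + 2 pad)
    pattern_centers: np.ndarray      # (k, 2) (x, y) in field-of-view coords
    seed: int | None = None

    @property
    def n_fingers(self) -> int:
        return self.canvas_patterns.shape[0]

    def _crop(self, canvas: np.ndarray) -> np.ndarray:
        dx, dy = self.probe_offset
        r0 = self.pad - dy
        c0 = self.pad - dx
        return canvas[r0:r0 + self.height, c0:c0 + self.width]

    @property
    def baseline(self) -> np.ndarray:
        """Speckle baseline as seen through the current field of view."""
        return self._crop(self.canvas_baseline)

    @property
    def patterns(self) -> np.ndarray:
        """Per-finger patterns as seen through the current field of view."""
        return np.stack([self._crop(p) for p in self.canvas_patterns])

    def metadata(self) -> dict:
        return {
            "width": self.width, "height": self.height,
            "n_fingers": self.n_fingers, "pattern_gain": self.pattern_gain,
            "noise_sd": self.noise_sd, "mode": self.mode,
            "probe_offset": list(self.probe_offset), "pad": self.pad,
            "seed": self.seed,
        }


def _spread_centers(n, width, height, rng, min_dist=100.0):
    if n <= len(_CENTER_LAYOUT):
        frac = np.array(_CENTER_LAYOUT[:n])
        jitter = rng.uniform(-15, 15, size=(n, 2))
        return frac * [width, height] + jitter
    # rejection-sample extra centers in the central box
    centers = list(np.array(_CENTER_LAYOUT) * [width, height])
    while len(centers) < n:
        cand = rng.uniform([0.1 * width, 0.1 * height],
                           [0.9 * width, 0.9 * height])
        if all(np.hypot(*(cand - c)) >= min_dist for c in centers):
            centers.append(cand)
    return np.array(centers[:n])


def make_scene(
    width: int = 700,
    height: int = 660,
    n_fingers: int = 5,
    pattern_gain: float = 40.0,
    noise_sd: float = 2.0,
    mode: str = "linear",
    seed=None,
    pad: int = DEFAULT_PAD,
    pattern_sigma: float = 60.0,
) -> SceneState:
    """Create a reproducible synthetic scene.

    The baseline is Gaussian-smoothed uniform noise rescaled to mean 120,
    SD 30 and clipped to [0, 255] — speckle-like texture at the intensity
    scale of a typical B-mode image. Each finger's pattern is a Gaussian
    blob (SD ``pattern_sigma`` px, peak 1, slight random anisotropy) at
    well-separated centers, so distinct fingers deform distinct regions.
    """
    if mode not in ("linear", "warp"):
        raise InvalidParameterError(f"mode must be 'linear' or 'warp', got {mode!r}")
    if width < 64 or height < 64:
        raise GeometryError(
            f"image {width}x{height} too small to host a region-of-interest grid")
    rng = np.random.default_rng(seed)
    H, W = height + 2 * pad, width + 2 * pad

    raw = ndimage.gaussian_filter(rng.uniform(size=(H, W)), sigma=3.0)
    raw = (raw - raw.mean()) / raw.std()
    baseline = np.clip(120.0 + 30.0 * raw, 0.0, 255.0)

    centers = _spread_centers(n_fingers, width, height, rng)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    patterns = np.empty((n_fingers, H, W))
    for f, (cx, cy) in enumerate(centers):
        sx = pattern_sigma * rng.uniform(0.85, 1.15)
        sy = pattern_sigma * rng.uniform(0.85, 1.15)
        patterns[f] = np.exp(-0.5 * (((xx - (cx + pad)) / sx) ** 2
                                     + ((yy - (cy + pad)) / sy) ** 2))

    return SceneState(
        width=width, height=height, pattern_gain=float(pattern_gain),
        noise_sd=float(noise_sd), mode=mode, probe_offset=(0, 0), pad=pad,
        canvas_baseline=baseline, canvas_patterns=patterns,
        pattern_centers=centers,
        seed=seed if isinstance(seed, int) else None,
    )


def render_frame(
    scene: SceneState,
    normalized_forces,
    rng=None,
    timestamp: float = 0.0,
) -> Frame:
    """Render one frame for the given normalized forces (fractions of Fmax).

    In ``linear`` mode the patterns are added in proportion to the forces;
    in ``warp`` mode the baseline is resampled through a force-scaled
    displacement field. Additive Gaussian pixel noise (SD ``scene.noise_sd``)
    is drawn from ``rng`` (an int seed or Generator); clipping to [0, 255]
    is applied last.
    """
    f = np.asarray(normalized_forces, dtype=float)
    if f.shape != (scene.n_fingers,):
        raise InvalidInputError(
            f"expected {scene.n_fingers} forces, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise InvalidInputError("forces must be finite")

    base = scene._crop(scene.canvas_baseline)
    if scene.mode == "linear":
        img = base.copy()
        for i in range(scene.n_fingers):
            if f[i] != 0.0:
                img += (f[i] * scene.pattern_gain) * scene._crop(scene.canvas_patterns[i])
    else:  # warp: displacement field scaling with force (nonlinear variant)
        h, w = base.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        disp_scale = scene.pattern_gain / 4.0  # px of displacement at unit force
        ux = np.zeros_like(base)
        uy = np.zeros_like(base)
        for i in range(scene.n_fingers):
            if f[i] != 0.0:
                p = scene._crop(scene.canvas_patterns[i])
                gy, gx = np.gradient(p)
                norm = max(np.abs(gx).max(), np.abs(gy).max(), 1e-12)
                ux += f[i] * disp_scale * gx / norm
                uy += f[i] * disp_scale * gy / norm
        img = ndimage.map_coordinates(base, [yy + uy, xx + ux], order=1,
                                      mode="nearest")

    if scene.noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        img = img + gen.normal(0.0, scene.noise_sd, size=img.shape)
    return Frame(pixels=np.clip(img, 0.0, 255.0), timestamp=timestamp)


def apply_probe_shift(scene: SceneState, dx: int, dy: int) -> SceneState:
    """Return a scene whose rendered content is translated by (dx, dy) px.

    Models the transducer slipping on the skin: everything under the probe
    appears displaced and fresh speckle enters at the vacated margin.
    """
    new_dx = scene.probe_offset[0] + int(dx)
    new_dy = scene.probe_offset[1] + int(dy)
    if abs(new_dx) > scene.pad or abs(new_dy) > scene.pad:
        raise InvalidParameterError(
            f"accumulated probe offset ({new_dx}, {new_dy}) exceeds the "
            f"scene padding ({scene.pad} px)")
    shifted = dataclasses.replace(scene, probe_offset=(new_dx, new_dy))
    in_view = [
        0 <= cx + new_dx < scene.width and 0 <= cy + new_dy < scene.height
        for cx, cy in scene.pattern_centers
    ]
    if not any(in_view):
        warnings.warn("probe shift moved every finger pattern out of the "
                      "field of view; the scene is degenerate", stacklevel=2)
    return shifted


def render_session(scene: SceneState, normalized_forces: np.ndarray, seed=None):
    """Yield frames for an (n, k) array of per-sample normalized forces.

    One child generator per frame (spawned from ``seed``) keeps rendering
    reproducible regardless of chunking.
    """
    normalized_forces = np.asarray(normalized_forces, dtype=float)
    streams = seedseq(seed).spawn(len(normalized_forces))
    for i, row in enumerate(normalized_forces):
        yield render_frame(scene, row, rng=np.random.default_rng(streams[i]),
                           timestamp=i / 30.0)


def simulate_session(scene, timeline, force_trace, out_dir, seed=None):
    """Render one frame per sample and write a PNG sequence + traces CSV.

    Frames are written as ``frame_%06d.png`` (8-bit grayscale), alongside
    ``session.csv`` (time, per-finger stimulus fraction and force in N) and
    a ``session.json`` metadata sidecar. Returns the output directory.
    """
    if force_trace.sample_rate != timeline.sample_rate:
        raise InvalidInputError("force trace and timeline must share sample_rate")
    if len(force_trace.forces) != timeline.n_samples:
        raise InvalidInputError("force trace and timeline must share length")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    normalized = force_trace.forces / force_trace.fmax
    for i, frame in enumerate(render_session(scene, normalized, seed=seed)):
        iio.imwrite(out / f"frame_{i:06d}.png",
                    np.round(frame.pixels).astype(np.uint8))

    df = pd.DataFrame({"time_s": timeline.times})
    for j, name in enumerate(timeline.fingers):
        df[f"stim_{name}"] = timeline.values[:, j]
    for j, name in enumerate(timeline.fingers):
        df[f"force_{name}"] = force_trace.forces[:, j]
    df["phase_label"] = timeline.phase_labels
    df.to_csv(out / "session.csv", index=False)

    meta = scene.metadata()
    meta.update({
        "n_frames": int(timeline.n_samples),
        "render_seed": seed if isinstance(seed, (int, type(None))) else str(seed),
        "fmax": [float(v) for v in force_trace.fmax],
    })
    (out / "session.json").write_text(json.dumps(meta, indent=2))
    return out


def load_frames(frame_dir) -> list[Frame]:
    """Load a ``frame_%06d.png`` sequence back into frames."""
    paths = sorted(Path(frame_dir).glob("frame_*.png"))
    if not paths:
        raise InvalidInputError(f"no frame_*.png files under {frame_dir}")
    return [Frame(pixels=np.asarray(iio.imread(p), dtype=float), timestamp=i / 30.0)
            for i, p in enumerate(paths)]
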