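"""First-order spatial features on a uniform grid of circular ROIs.

The decoder summarizes each frame by least-squares plane fits over a fixed
lattice of circular regions of interest (ROIs). For the i-th ROI centered
at (x_i, y_i), the gray values g(x, y) inside the disc are approximated by

    g(x, y) ≈ alpha_i (x_i - x) + beta_i (y_i - y) + gamma_i

so alpha/beta are (sign-flipped) mean gray-level gradients along the image
axes and gamma is the mean intensity. Because the pixel disc is symmetric
about its center, the three-parameter least-squares problem decouples:

    gamma = mean(g)
    alpha = sum(g * (x_i - x)) / sum((x_i - x)^2)
    beta  = sum(g * (y_i - y)) / sum((y_i - y)^2)

Features from all ROIs are concatenated (alpha_1, beta_1, gamma_1,
alpha_2, ...) into a vector of dimension 3 * |ROIs|; with the default
geometry (700x660 field of view, spacing 50 px, radius 20 px, a 50x50
corner notch masked out) there are 181 ROIs and d = 543.

Coordinates are 0-based with x = column and y = row; a pixel belongs to a
disc iff (x - x_i)^2 + (y - y_i)^2 <= radius^2. Feature and force time
series are conditioned with a causal first-order Butterworth low-pass
(1 Hz cutoff by default) — causal so the offline pipeline and the
streaming engine apply the identical filter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import GeometryError, InvalidInputError, InvalidParameterError

DEFAULT_SPACING = 50
DEFAULT_RADIUS = 20
#: lattice origin offset from the image origin, in px (see build_roi_grid)
LATTICE_MARGIN_EXTRA = 5


def default_content_mask(width: int = 700, height: int = 660,
                         notch: int = 50) -> np.ndarray:
    """Binary content mask: full rectangle minus a bottom-right corner notch.

    The notch emulates a scanner UI overlay occluding the image corner; at
    the default geometry it excludes exactly one lattice point, giving the
    standard 181-ROI grid.
    """
    mask = np.ones((height, width), dtype=bool)
    if notch > 0:
        mask[height - notch:, width - notch:] = False
    return mask


def _disc_offsets(radius: int):
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx ** 2 + dy ** 2 <= r ** 2
    return dx[keep], dy[keep]


@dataclass
class ROIGrid:
    """A lattice of circular ROIs fully contained in a content mask."""

    centers: np.ndarray          # (m, 2) int, (x, y) = (col, row)
    radius: int
    spacing: int
    mask: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_rois(self) -> int:
        return len(self.centers)

    @property
    def feature_dim(self) -> int:
        """Length of the extracted feature vector, 3 per ROI."""
        return 3 * self.n_rois

    @property
    def image_shape(self):
        return None if self.mask is None else self.mask.shape

    def _plan(self, frame_shape):
        """Precompute flat pixel indices and shared plane-fit weights."""
        key = tuple(frame_shape)
        if key in self._cache:
            return self._cache[key]
        h, w = frame_shape
        dx, dy = _disc_offsets(self.radius)
        cols = self.centers[:, 0][:, None] + dx[None, :]
        rows = self.centers[:, 1][:, None] + dy[None, :]
        if cols.min() < 0 or rows.min() < 0 or cols.max() >= w or rows.max() >= h:
            raise InvalidInputError(
                f"grid does not fit a {h}x{w} frame (disc out of bounds)")
        idx = rows * w + cols
        # x_i - x = -dx; the disc is symmetric so the 3-parameter LS decouples
        w_alpha = (-dx) / np.sum(dx.astype(float) ** 2)
        w_beta = (-dy) / np.sum(dy.astype(float) ** 2)
        w_gamma = np.full(len(dx), 1.0 / len(dx))
        plan = (idx, w_alpha, w_beta, w_gamma)
        self._cache[key] = plan
        return plan

    def to_json(self, path=None) -> str:
        payload = {
            "centers": self.centers.tolist(),
            "radius": self.radius,
            "spacing": self.spacing,
            "image_shape": list(self.image_shape) if self.mask is not None else None,
            "mask_sha256": (hashlib.sha256(np.packbits(self.mask).tobytes()).hexdigest()
                            if self.mask is not None else None),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ROIGrid":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(centers=np.asarray(payload["centers"], dtype=int),
                   radius=int(payload["radius"]), spacing=int(payload["spacing"]),
                   mask=None)


def build_roi_grid(mask: np.ndarray, spacing: int = DEFAULT_SPACING,
                   radius: int = DEFAULT_RADIUS) -> ROIGrid:
    """Enumerate lattice centers whose full disc lies inside the mask.

    The lattice starts at ``(radius + 5, radius + 5)`` from the image
    origin with step ``spacing`` in both axes; a lattice point is kept iff
    every pixel of its disc is inside the mask (checked via binary erosion
    of the mask by the disc footprint). Deterministic by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        raise GeometryError("content mask is empty")
    if spacing <= 0 or radius <= 0:
        raise InvalidParameterError("spacing and radius must be positive")
    h, w = mask.shape
    dx, dy = _disc_offsets(radius)
    footprint = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
    footprint[dy + radius, dx + radius] = True
    fits = ndimage.binary_erosion(mask, structure=footprint, border_value=0)

    origin = radius + LATTICE_MARGIN_EXTRA
    xs = np.arange(origin, w, spacing)
    ys = np.arange(origin, h, spacing)
    centers = [(x, y) for y in ys for x in xs if fits[y, x]]
    if not centers:
        raise GeometryError(
            f"no disc of radius {radius} on the spacing-{spacing} lattice "
            f"fits inside the {h}x{w} mask")
    return ROIGrid(centers=np.asarray(centers, dtype=int), radius=int(radius),
                   spacing=int(spacing), mask=mask)


def _frame_pixels(frame) -> np.ndarray:
    pixels = getattr(frame, "pixels", frame)
    return np.asarray(pixels, dtype=float)


def fit_roi_plane(frame, center, radius: int):
    """Least-squares plane fit over one circular ROI → (alpha, beta, gamma)."""
    pixels = _frame_pixels(frame)
    h, w = pixels.shape
    cx, cy = int(center[0]), int(center[1])
    dx, dy = _disc_offsets(radius)
    cols, rows = cx + dx, cy + dy
    if cols.min() < 0 or rows.min() < 0 or cols.max() >= w or rows.max() >= h:
        raise InvalidInputError(
            f"disc at ({cx}, {cy}) radius {radius} extends outside the frame")
    g = pixels[rows, cols]
    gamma = g.mean()
    alpha = g @ (-dx) / np.sum(dx.astype(float) ** 2)
    beta = g @ (-dy) / np.sum(dy.astype(float) ** 2)
    return float(alpha), float(beta), float(gamma)


def extract_features(frame, grid: ROIGrid) -> np.ndarray:
    """Extract the concatenated plane-fit features of one frame.

    Returns a vector of length ``grid.feature_dim`` ordered
    (alpha_1, beta_1, gamma_1, alpha_2, ...).
    """
    pixels = _frame_pixels(frame)
    if grid.image_shape is not None and pixels.shape != grid.image_shape:
        raise InvalidInputError(
            f"frame shape {pixels.shape} does not match grid mask "
            f"shape {grid.image_shape}")
    idx, w_alpha, w_beta, w_gamma = grid._plan(pixels.shape)
    patches = pixels.ravel()[idx]                      # (m, n_disc_pixels)
    feats = np.empty((grid.n_rois, 3))
    feats[:, 0] = patches @ w_alpha
    feats[:, 1] = patches @ w_beta
    feats[:, 2] = patches @ w_gamma
    return feats.ravel()


def extract_feature_matrix(frames, grid: ROIGrid) -> np.ndarray:
    """Stack :func:`extract_features` over an iterable of frames → (n, d)."""
    return np.array([extract_features(f, grid) for f in frames])


def lowpass_filter(series, cutoff: float = 1.0, fs: float = 30.0) -> np.ndarray:
    """Causal first-order Butterworth low-pass, applied per channel.

    The filter state is initialized from the first sample so a constant
    input passes through unchanged (no start-up transient). A single
    forward pass keeps the offline conditioning identical to what a
    streaming implementation can do; the price is the filter's phase lag.
    """
    if cutoff <= 0 or fs <= 0:
        raise InvalidParameterError("cutoff and fs must be positive")
    if cutoff >= fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    b, a = signal.butter(1, cutoff, fs=fs)
    zi = signal.lfilter_zi(b, a)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j], _ = signal.lfilter(b, a, x[:, j], zi=zi * x[0, j])
    return out[:, 0] if squeeze else out


def features_to_csv(features: np.ndarray, path) -> None:
    """Write an (n, 3m) feature matrix as CSV (a_0001, b_0001, c_0001, ...)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    m = features.shape[1] // 3
    cols = []
    for i in range(1, m + 1):
        cols += [f"a_{i:04d}", f"b_{i:04d}", f"c_{i:04d}"]
    pd.DataFrame(features, columns=cols).to_csv(path, index=False)


def features_from_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
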