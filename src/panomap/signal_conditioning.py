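"""Conditioning of raw fluorescence movies and blending weight masks.

Voltage-sensitive-dye movies arrive as H x W x T intensity arrays with a
foreground mask marking pixels that carry physiological signal.  The
standard conditioning chain, applied in order, is:

1. per-pixel min-max normalization of the optical action potentials,
2. spatial binning with a 3 x 3 box kernel restricted to the foreground,
3. a 100th-order zero-phase FIR low-pass at 100 Hz,
4. first-order (linear) drift removal.

Because epicardial curvature degrades signal-to-noise toward the edge of
each camera's field, every camera mask also yields a radial weight
gradient — 1 at the innermost pixels falling to 0.5 at the outermost
foreground pixels — used later when blending overlapping cameras.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal
from skimage.draw import polygon2mask

from .errors import SignalError

__all__ = [
    "OpticalMovie",
    "WeightMask",
    "normalize_traces",
    "spatial_bin",
    "design_lowpass",
    "filter_temporal",
    "remove_drift",
    "mask_region",
    "build_weight_mask",
    "condition_movie",
]


@dataclass
class OpticalMovie:
    """Fluorescence movie from one optical-mapping camera.

    ``frames`` is (H, W, T); ``mask`` is the (H, W) binary foreground.
    ``camera_id`` names the physical camera (A-D in the four-camera rig).
    """

    frames: np.ndarray
    sampling_rate: float
    camera_id: str = "A"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] < 2:
            raise SignalError("frames must be (H, W, T) with T >= 2")
        if self.sampling_rate <= 0:
            raise SignalError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[:2], dtype=np.uint8)
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.mask.shape != self.frames.shape[:2]:
            raise SignalError("mask shape must match frame shape")

    @property
    def n_samples(self) -> int:
        return self.frames.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0


@dataclass
class WeightMask:
    """Radial blending weights: 1 at the mask center, 0.5 at its edge."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        fg = self.weights > 0
        if fg.any():
            w = self.weights[fg]
            if w.min() < 0.5 - 1e-9 or w.max() > 1.0 + 1e-9:
                raise SignalError("foreground weights must lie in [0.5, 1]")


def normalize_traces(movie: OpticalMovie) -> OpticalMovie:
    """Map each foreground pixel trace to [0, 1] by its temporal min-max.

    Foreground pixels with a constant trace carry no physiology; they are
    moved to the background with a warning.
    """
    frames = movie.frames.copy()
    mask = movie.mask.copy()
    fg = mask.astype(bool)
    lo = frames.min(axis=2)
    hi = frames.max(axis=2)
    flat = fg & (hi == lo)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant-trace pixel(s) moved to background"
        )
        mask[flat] = 0
        fg = mask.astype(bool)
    rng = np.where(hi > lo, hi - lo, 1.0)
    frames = (frames - lo[..., None]) / rng[..., None]
    frames[~fg] = 0.0
    return replace(movie, frames=frames, mask=mask)


def spatial_bin(movie: OpticalMovie, kernel: int = 3) -> OpticalMovie:
    """Box-average each frame over a ``kernel`` x ``kernel`` window.

    The average is restricted to foreground pixels so background never
    bleeds into the signal; the mask itself is unchanged.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise SignalError("kernel must be an odd positive integer")
    if kernel == 1:
        return replace(movie, frames=movie.frames.copy())
    fg = movie.mask.astype(bool)
    frames = np.where(fg[..., None], movie.frames, 0.0)
    num = ndimage.uniform_filter(frames, size=(kernel, kernel, 1),
                                 mode="constant")
    den = ndimage.uniform_filter(fg.astype(float), size=kernel,
                                 mode="constant")
    out = np.zeros_like(frames)
    np.divide(num, den[..., None], out=out, where=den[..., None] > 0)
    out[~fg] = 0.0
    return replace(movie, frames=out)


def design_lowpass(order: int, cutoff_hz: float, sampling_rate: float
                   ) -> np.ndarray:
    """Hamming-windowed linear-phase FIR low-pass (``order`` + 1 taps)."""
    if sampling_rate <= 2 * cutoff_hz:
        raise SignalError("sampling rate too low for the requested passband")
    return signal.firwin(order + 1, cutoff_hz, fs=sampling_rate,
                         window="hamming")


def filter_temporal(
    movie: OpticalMovie,
    order: int = 100,
    passband: tuple[float, float] = (0.0, 100.0),
) -> OpticalMovie:
    """Zero-phase FIR band-pass along time (default 0-100 Hz, order 100).

    A lower passband edge of 0 degenerates to a low-pass at the upper
    edge.  The even-order linear-phase kernel is applied centered
    (edge-replicated), so the group delay is compensated and features are
    not shifted in time; the DC gain is unity.
    """
    lo, hi = passband
    if lo > 0:
        taps = signal.firwin(order + 1, [lo, hi], fs=movie.sampling_rate,
                             pass_zero=False, window="hamming")
        if movie.sampling_rate <= 2 * hi:
            raise SignalError("sampling rate too low for the requested passband")
    else:
        taps = design_lowpass(order, hi, movie.sampling_rate)
    frames = ndimage.convolve1d(movie.frames, taps, axis=2, mode="nearest")
    frames[~movie.mask.astype(bool)] = 0.0
    return replace(movie, frames=frames)


def remove_drift(movie: OpticalMovie) -> OpticalMovie:
    """Subtract the least-squares line from each trace, keeping its mean."""
    t = np.arange(movie.n_samples, dtype=float)
    t0 = t - t.mean()
    denom = np.dot(t0, t0)
    frames = movie.frames
    slope = frames @ t0 / denom  # (H, W)
    out = frames - slope[..., None] * t0[None, None, :]
    out[~movie.mask.astype(bool)] = 0.0
    return replace(movie, frames=out)


def mask_region(movie: OpticalMovie, polygon: np.ndarray) -> OpticalMovie:
    """Remove the foreground inside a simple polygon (atria, artifacts...).

    ``polygon`` is an (N, 2) list of (u, v) pixel vertices.  A degenerate
    (zero-area) polygon removes nothing.
    """
    verts = np.asarray(polygon, dtype=float).reshape(-1, 2)
    if len(verts) >= 3 and _self_intersects(verts):
        raise SignalError("invalid polygon: self-intersecting")
    mask = movie.mask.copy()
    if len(verts) >= 3:
        poly = polygon2mask(mask.shape, verts[:, ::-1])
        mask[poly] = 0
    frames = movie.frames.copy()
    frames[~mask.astype(bool)] = 0.0
    return replace(movie, frames=frames, mask=mask)


def _self_intersects(verts: np.ndarray) -> bool:
    n = len(verts)
    segs = [(verts[i], verts[(i + 1) % n]) for i in range(n)]

    def crosses(a, b, c, d):
        def orient(p, q, r):
            return np.sign((q[0] - p[0]) * (r[1] - p[1])
                           - (q[1] - p[1]) * (r[0] - p[0]))
        return (orient(a, b, c) * orient(a, b, d) < 0
                and orient(c, d, a) * orient(c, d, b) < 0)

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent via wraparound
            if crosses(*segs[i], *segs[j]):
                return True
    return False


def build_weight_mask(mask: np.ndarray) -> WeightMask:
    """Radial blending gradient over a binary mask.

    With ``d`` the Euclidean distance of each foreground pixel to the
    nearest background pixel, weights are

        w = 0.5 + 0.5 * (d - d_min) / (d_max - d_min)

    so the outermost foreground pixels get exactly 0.5 and the deepest
    interior pixel exactly 1.  A mask with uniform depth (e.g. a single
    pixel) gets weight 1 everywhere.  Background weights are 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise SignalError("empty mask")
    d = ndimage.distance_transform_edt(mask)
    dmin = d[mask].min()
    dmax = d[mask].max()
    w = np.zeros(mask.shape, dtype=float)
    if dmax > dmin:
        w[mask] = 0.5 + 0.5 * (d[mask] - dmin) / (dmax - dmin)
    else:
        w[mask] = 1.0
    return WeightMask(weights=w)


def condition_movie(
    movie: OpticalMovie,
    *,
    bin_kernel: int = 3,
    filter_order: int = 100,
    passband: tuple[float, float] = (0.0, 100.0),
    drift_removal: bool = True,
    normalize_first: bool = True,
    remove_polygons: list[np.ndarray] | None = None,
) -> OpticalMovie:
    """Full conditioning chain in the standard order.

    normalize -> 3x3 spatial binning -> zero-phase FIR 0-100 Hz ->
    first-order drift removal, with optional polygon region removal
    first.  ``normalize_first=False`` moves normalization to the end of
    the chain instead.
    """
    out = movie
    for poly in remove_polygons or []:
        out = mask_region(out, poly)
    if normalize_first:
        out = normalize_traces(out)
    out = spatial_bin(out, bin_kernel)
    out = filter_temporal(out, filter_order, passband)
    if drift_removal:
        out = remove_drift(out)
    if not normalize_first:
        out = normalize_traces(out)
    return out
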