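"""Electrophysiological maps from projected optical signals.

Operates on per-face (or per-pixel) fluorescence traces after surface
projection:

* **Activation maps** — time of the maximum temporal derivative of the
  optical action-potential upstroke (the standard optical-mapping
  convention), refined to sub-sample precision by a parabolic fit; a
  50 %-amplitude-crossing alternative is available behind a flag.
* **APD maps** — action potential duration at a repolarization level
  (APD80 by default): time from activation until the trace first falls
  below ``peak - level * (peak - baseline)``, interpolated linearly
  between samples.
* **Dominant frequency** — Welch periodogram peak within a physiological
  band, the standard summary of fibrillatory rate.
* **Phase** — instantaneous phase of the analytic (Hilbert-transform)
  signal of each mean-subtracted trace, wrapped to (-pi, pi].
* **Phase singularities** — points where the phase winds by +-2*pi
  around a 2x2 pixel loop; these topological defects mark rotor cores
  of reentrant spiral waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, welch

from .errors import SignalError
from .reconstruction import SurfaceMesh

__all__ = [
    "ScalarSurfaceMap",
    "PhaseField",
    "PhaseSingularity",
    "activation_times",
    "apd_map",
    "dominant_frequency_map",
    "compute_phase",
    "detect_phase_singularities",
]


@dataclass
class ScalarSurfaceMap:
    """One scalar per mesh face; NaN marks missing faces.

    ``kind`` is "activation" (ms), "apd" (ms) or "df" (Hz).
    """

    values: np.ndarray
    kind: str
    mesh: SurfaceMesh | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class PhaseField:
    """Per-trace instantaneous phase in (-pi, pi]."""

    phase: np.ndarray  # (N, T)
    sampling_rate: float


@dataclass
class PhaseSingularity:
    """A +-1 topological defect of a 2D wrapped-phase frame.

    ``location`` is the (x, y) center of the 2x2 loop carrying the
    charge; ``chirality`` is the sign of the winding.
    """

    location: tuple[float, float]
    chirality: int
    frame: int = 0


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def activation_times(
    signals: np.ndarray,
    sampling_rate: float,
    window: tuple[float, float] | None = None,
    *,
    method: str = "max_derivative",
) -> ScalarSurfaceMap:
    """Activation time (ms) of each trace.

    ``window`` restricts the search to (t_start_ms, t_end_ms).  The
    default method takes the maximum of the first difference with
    parabolic sub-sample refinement; ``method="midpoint"`` takes the
    first 50 %-of-range upstroke crossing instead.  Flat traces are
    missing.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n, T = signals.shape
    dt_ms = 1000.0 / sampling_rate
    t0, t1 = window if window is not None else (0.0, (T - 1) * dt_ms)
    i0 = max(int(np.ceil(t0 / dt_ms)), 0)
    i1 = min(int(np.floor(t1 / dt_ms)), T - 1)
    if i1 <= i0:
        raise SignalError("activation window too short")
    out = np.full(n, np.nan)
    for r in range(n):
        tr = signals[r]
        if not np.all(np.isfinite(tr)) or tr.max() == tr.min():
            continue
        if method == "midpoint":
            mid = 0.5 * (tr.max() + tr.min())
            above = np.flatnonzero(tr[i0:i1 + 1] >= mid)
            if len(above) == 0 or above[0] == 0:
                out[r] = (i0 + (above[0] if len(above) else 0)) * dt_ms
                continue
            k = i0 + above[0]
            frac = (mid - tr[k - 1]) / (tr[k] - tr[k - 1])
            out[r] = (k - 1 + frac) * dt_ms
            continue
        d = np.gradient(tr)
        seg = d[i0:i1 + 1]
        k = int(np.argmax(seg)) + i0
        # parabolic refinement on the derivative peak
        if 0 < k < T - 1 and d[k] > 0:
            denom = d[k - 1] - 2 * d[k] + d[k + 1]
            shift = 0.0 if denom == 0 else 0.5 * (d[k - 1] - d[k + 1]) / denom
            shift = np.clip(shift, -0.5, 0.5)
        else:
            shift = 0.0
        if d[k] <= 0:
            continue
        out[r] = (k + shift) * dt_ms
    return ScalarSurfaceMap(values=out, kind="activation")


def apd_map(
    signals: np.ndarray,
    sampling_rate: float,
    activation: ScalarSurfaceMap | None = None,
    level: float = 0.8,
) -> ScalarSurfaceMap:
    """Action potential duration (ms) at ``level`` repolarization.

    APD = first time after the AP peak at which the trace falls below
    ``peak - level * (peak - baseline)`` (baseline = trace minimum),
    linearly interpolated between samples, minus the activation time.
    Traces that never recover within the record are missing.  APD is
    invariant to affine rescaling of the trace.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if activation is None:
        activation = activation_times(signals, sampling_rate)
    n, T = signals.shape
    dt_ms = 1000.0 / sampling_rate
    out = np.full(n, np.nan)
    for r in range(n):
        t_act = activation.values[r]
        tr = signals[r]
        if not np.isfinite(t_act) or not np.all(np.isfinite(tr)):
            continue
        k_pk = int(np.argmax(tr))
        peak = tr[k_pk]
        base = tr.min()
        if peak == base:
            continue
        thresh = peak - level * (peak - base)
        below = np.flatnonzero(tr[k_pk:] < thresh)
        if len(below) == 0:
            continue
        k = k_pk + below[0]
        if k == 0:
            continue
        frac = (tr[k - 1] - thresh) / (tr[k - 1] - tr[k])
        t_cross = (k - 1 + frac) * dt_ms
        if t_cross <= t_act:
            continue
        out[r] = t_cross - t_act
    return ScalarSurfaceMap(values=out, kind="apd")


def dominant_frequency_map(
    signals: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.5, 50.0),
    *,
    nperseg: int | None = None,
) -> ScalarSurfaceMap:
    """Welch-periodogram peak frequency (Hz) of each trace within ``band``.

    All-zero (or constant) traces are missing.  Records of at least a
    couple of seconds give a usable frequency resolution.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n, T = signals.shape
    if nperseg is None:
        nperseg = min(T, max(256, T // 2))
    out = np.full(n, np.nan)
    finite = np.all(np.isfinite(signals), axis=1)
    varying = signals.max(axis=1) > signals.min(axis=1)
    rows = np.flatnonzero(finite & varying)
    if len(rows):
        freqs, psd = welch(signals[rows] - signals[rows].mean(axis=1,
                                                              keepdims=True),
                           fs=sampling_rate, nperseg=nperseg, axis=1)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        if not sel.any():
            raise SignalError("frequency band outside the resolvable range")
        fb = freqs[sel]
        out[rows] = fb[np.argmax(psd[:, sel], axis=1)]
    return ScalarSurfaceMap(values=out, kind="df")


def compute_phase(signals: np.ndarray, sampling_rate: float) -> PhaseField:
    """Hilbert-transform instantaneous phase of mean-subtracted traces.

    Constant traces have undefined phase and are returned as NaN rows.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n, T = signals.shape
    if T < 4:
        raise SignalError("trace too short for phase analysis")
    phase = np.full((n, T), np.nan)
    ok = np.all(np.isfinite(signals), axis=1) & (
        signals.max(axis=1) > signals.min(axis=1)
    )
    if ok.any():
        x = signals[ok] - signals[ok].mean(axis=1, keepdims=True)
        phase[ok] = _wrap(np.angle(hilbert(x, axis=1)))
    return PhaseField(phase=phase, sampling_rate=sampling_rate)


def detect_phase_singularities(
    phase_frame: np.ndarray,
    *,
    frame: int = 0,
    tol: float = 1e-6,
) -> list[PhaseSingularity]:
    """Topological charges of a 2D wrapped-phase image.

    For every 2x2 pixel loop the four wrapped phase differences are
    summed; a total of +-2*pi (within ``tol``) marks a singularity at
    the loop center with that chirality.  Loops containing NaN phase are
    skipped.
    """
    p = np.asarray(phase_frame, dtype=float)
    if p.ndim != 2:
        raise SignalError("phase frame must be 2D")
    # loop p[y,x] -> p[y,x+1] -> p[y+1,x+1] -> p[y+1,x] -> back
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])
    winding = d1 + d2 + d3 + d4
    out: list[PhaseSingularity] = []
    ys, xs = np.nonzero(np.abs(np.abs(winding) - 2 * np.pi) < tol)
    for y, x in zip(ys, xs):
        out.append(PhaseSingularity(
            location=(x + 0.5, y + 0.5),
            chirality=int(np.sign(winding[y, x])),
            frame=frame,
        ))
    return out
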