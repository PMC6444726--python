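"""Pseudolinescans (kymographs) and wave-speed estimation.

A user-supplied polyline path is resampled at 1-pixel arc-length steps; the
intensity at each (position, time) sample is the mean over a short segment
perpendicular to the local path direction, bilinearly interpolated.  The
wave speed is the inverse slope of a least-squares line through per-position
arrival times: the default arrival rule is the first crossing of half of the
position's own ΔF/F maximum, which is robust to amplitude gradients along
the path.  Regression over all valid positions (rather than two-point
differencing) buys noise robustness; fits with r² < 0.8 should be treated
as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .io import MovieStack
from .traces import lower_quartile_baseline

ARRIVAL_RULES = ("half-max", "peak", "onset-2sd")

#: minimum ΔF/F peak, in units of the position's robust noise SD, for a
#: position to count as having a detectable arrival
_DETECT_SNR = 4.0


@dataclass
class Pseudolinescan:
    """Position-along-path × time intensity map."""

    path: np.ndarray             # waypoints, (row, col)
    samples: np.ndarray          # S×T
    position_spacing: float      # μm between successive positions
    frame_interval: float        # s

    @property
    def n_positions(self) -> int:
        return self.samples.shape[0]

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.n_positions) * self.position_spacing


@dataclass
class WaveFit:
    """Propagation-speed estimate from arrival-time regression."""

    speed: float | None          # μm s⁻¹; None when undefined
    direction: int               # +1 along increasing arc length, −1 reverse
    arrival_times: np.ndarray    # s per position (NaN where undetectable)
    fit_r2: float
    reason: str | None = None    # set when speed is undefined


def _resample_path(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at 1-px arc-length steps; return points and unit
    tangents."""
    pts = np.asarray(path, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total < 2.0:
        raise ValueError("path must be at least 2 px long")
    s = np.arange(0.0, total + 1e-9, 1.0)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rows = np.interp(s, cum, pts[:, 0])
    cols = np.interp(s, cum, pts[:, 1])
    samples = np.stack([rows, cols], axis=1)
    tang = np.gradient(samples, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return samples, tang


def extract_linescan(movie: MovieStack, path, width: int = 1) -> Pseudolinescan:
    """Build the kymograph for ``path`` with perpendicular averaging width
    ``width`` pixels (bilinear interpolation)."""
    if width < 1:
        raise ValueError("width must be ≥ 1")
    samples, tang = _resample_path(np.asarray(path, dtype=float))
    H, W = movie.frame_shape
    if (samples[:, 0].min() < 0 or samples[:, 0].max() > H - 1
            or samples[:, 1].min() < 0 or samples[:, 1].max() > W - 1):
        raise ValueError("path extends outside the frame")
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    # coords[(r/c), position, offset]
    coords = samples[:, :, None] + normal[:, :, None] * offsets[None, None, :]
    coords = np.clip(coords.transpose(1, 0, 2),
                     0, np.array([H - 1, W - 1], dtype=float)[:, None, None])
    S = len(samples)
    out = np.empty((S, movie.n_frames))
    for t in range(movie.n_frames):
        vals = ndi.map_coordinates(np.asarray(movie.data[t], dtype=float),
                                   coords.reshape(2, -1), order=1)
        out[:, t] = vals.reshape(S, width).mean(axis=1)
    return Pseudolinescan(np.asarray(path, dtype=float), out,
                          movie.pixel_size, movie.frame_interval)


def _position_dfof(samples: np.ndarray) -> np.ndarray:
    """Per-position ΔF/F of the kymograph (lower-quartile baseline)."""
    out = np.empty_like(samples, dtype=float)
    for i, trace in enumerate(samples):
        f0 = lower_quartile_baseline(trace)
        if f0 <= 0:
            f0 = max(trace.mean(), 1e-12)
        out[i] = (trace - f0) / f0
    return out


def estimate_speed(linescan: Pseudolinescan, threshold_rule: str = "half-max",
                   ) -> WaveFit:
    """Wave speed from per-position arrival times.

    Arrival per position: first frame where its ΔF/F exceeds half of its own
    maximum (``half-max``), the frame of the maximum (``peak``), or the
    first frame above twice the robust noise SD (``onset-2sd``).  Speed is
    1/|slope| of the least-squares line of arrival time on arc-length
    position; simultaneous activation (near-zero slope) yields an undefined
    speed with a reason rather than infinity.
    """
    if threshold_rule not in ARRIVAL_RULES:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    dfof = _position_dfof(linescan.samples)
    times = np.arange(linescan.samples.shape[1]) * linescan.frame_interval

    arrivals = np.full(linescan.n_positions, np.nan)
    for i, y in enumerate(dfof):
        peak = y.max()
        noise_sd = 1.4826 * np.median(np.abs(y - np.median(y)))
        if peak <= _DETECT_SNR * noise_sd or peak <= 0:
            continue
        ipk = int(np.argmax(y))
        if threshold_rule == "peak":
            arrivals[i] = times[ipk]
            continue
        level = peak / 2.0 if threshold_rule == "half-max" else 2.0 * noise_sd
        # first crossing of the rising phase: walk back from the peak to the
        # last sub-level frame, so an isolated early noise spike cannot fake
        # an arrival
        below = np.nonzero(y[:ipk + 1] < level)[0]
        arrivals[i] = times[below[-1] + 1] if len(below) else times[0]

    valid = np.isfinite(arrivals)
    if valid.sum() < 5:
        raise ValueError(f"only {int(valid.sum())} positions have a detectable "
                         "arrival; need ≥ 5")
    x = linescan.positions_um[valid]
    t = arrivals[valid]
    res = stats.linregress(x, t)
    slope, r2 = res.slope, float(res.rvalue**2)
    # below ~half a frame interval across the whole path, the front is
    # indistinguishable from simultaneous activation
    if abs(slope) * (x.max() - x.min()) < linescan.frame_interval / 2.0:
        return WaveFit(None, 0, arrivals, r2, reason="simultaneous activation")
    return WaveFit(1.0 / abs(slope), int(np.sign(slope)), arrivals, r2)
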