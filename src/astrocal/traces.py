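"""ΔF/F traces, Gaussian event fitting (FWHM) and condition-level ECDFs.

ΔF/F is computed as (F − F0)/F0 where F is the background-subtracted,
spatially averaged fluorescence within an ROI and F0 is the average of the
lower quartile of all F in the time series — i.e. the mean over frames whose
F lies at or below the 25th percentile (linear-interpolation percentile,
ties at the cutoff included).  Individual calcium events are fit with a
Gaussian a·exp(−(t−μ)²/(2σ²)) + b and summarized by their full width at
half maximum, FWHM = 2·sqrt(2 ln 2)·σ.  An offset term b is included even
though the ideal transient has none, because real baselines drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import MovieStack

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: frames of padding added on each side of a detected event interval when it
#: becomes a Gaussian-fit candidate window
WINDOW_PAD = 3


@dataclass
class Trace:
    """Per-ROI fluorescence time series and its ΔF/F."""

    roi_id: int
    F: np.ndarray
    F0: float
    dFoF: np.ndarray
    frame_interval: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.F)) * self.frame_interval


@dataclass
class CalciumEvent:
    """A fitted Gaussian calcium transient."""

    roi_id: int
    peak_time: float     # s
    amplitude: float     # ΔF/F units
    sigma: float         # s
    fwhm: float          # s, = 2·sqrt(2 ln 2)·sigma
    fit_rss: float


@dataclass
class EcdfSummary:
    """Right-continuous empirical CDF of one variable in one condition."""

    variable: str
    condition: str
    values: np.ndarray   # sorted

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if len(self.values) == 0:
            raise ValueError("ECDF needs at least one value")

    def __call__(self, x) -> np.ndarray | float:
        res = np.searchsorted(self.values, np.asarray(x), side="right") / len(self.values)
        return float(res) if np.isscalar(x) else res


def lower_quartile_baseline(F: np.ndarray) -> float:
    """Mean of the frames with F at or below the 25th percentile."""
    F = np.asarray(F, dtype=float)
    q25 = np.percentile(F, 25)
    return float(F[F <= q25].mean())


def auto_background_roi(movie: MovieStack, rois) -> frozenset:
    """Default background region: the lowest-decile mean-intensity pixels
    outside all ROIs (the cell-free PEG surface in patterned cultures)."""
    mean_img = movie.data.mean(axis=0)
    mask = np.ones(movie.frame_shape, dtype=bool)
    for px in rois:
        for r, c in px:
            mask[r, c] = False
    vals = mean_img[mask]
    cutoff = np.percentile(vals, 10)
    keep = mask & (mean_img <= cutoff)
    return frozenset(zip(*[a.tolist() for a in np.nonzero(keep)]))


def compute_trace(movie: MovieStack, roi, background_roi=None,
                  roi_id: int = 0) -> Trace:
    """ΔF/F trace for one ROI.

    F(t) = mean over ROI pixels of frame t minus mean over background pixels
    (no subtraction when ``background_roi`` is None); F0 = lower-quartile
    average of F; dFoF = (F − F0)/F0.  A non-positive F0 (background exceeds
    signal) is rejected with a diagnostic.
    """
    roi = frozenset(roi)
    if not roi:
        raise ValueError("ROI is empty")
    rr, cc = zip(*sorted(roi))
    F = movie.data[:, rr, cc].mean(axis=1).astype(float)
    if background_roi:
        background_roi = frozenset(background_roi)
        if roi & background_roi:
            raise ValueError("ROI and background ROI must be disjoint")
        br, bc = zip(*sorted(background_roi))
        F = F - movie.data[:, br, bc].mean(axis=1)
    F0 = lower_quartile_baseline(F)
    if F0 <= 0:
        raise ValueError(f"F0 = {F0:.4g} ≤ 0: background exceeds ROI signal; "
                         "check the background region")
    return Trace(roi_id, F, F0, (F - F0) / F0, movie.frame_interval)


def _gauss(t, a, mu, sigma, b):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) + b


def fit_events(trace: Trace, candidate_windows) -> list[CalciumEvent]:
    """Least-squares Gaussian fit of ΔF/F in each candidate window.

    Windows are (start_frame, end_frame) inclusive; windows shorter than
    5 frames are skipped with a warning; fits with non-positive amplitude or
    that fail to converge are excluded.
    """
    out: list[CalciumEvent] = []
    t_all = trace.times
    for (lo, hi) in candidate_windows:
        lo = max(int(lo), 0)
        hi = min(int(hi), len(t_all) - 1)
        if hi - lo + 1 < 5:
            warnings.warn(f"window ({lo},{hi}) shorter than 5 frames; skipped",
                          stacklevel=2)
            continue
        t = t_all[lo:hi + 1]
        y = trace.dFoF[lo:hi + 1]
        a0 = float(y.max() - y.min())
        if a0 <= 0:
            continue
        p0 = [a0, t[int(np.argmax(y))], (t[-1] - t[0]) / 6.0, float(y.min())]
        try:
            popt, _ = curve_fit(_gauss, t, y, p0=p0, xtol=1e-8, ftol=1e-8,
                                maxfev=10_000)
        except RuntimeError:
            continue
        a, mu, sigma, b = popt
        sigma = abs(float(sigma))
        if a <= 0 or sigma == 0:
            continue
        rss = float(np.sum((y - _gauss(t, *popt)) ** 2))
        out.append(CalciumEvent(trace.roi_id, float(mu), float(a), sigma,
                                GAUSS_FWHM * sigma, rss))
    return out


def windows_from_events(events, n_frames: int, pad: int = WINDOW_PAD):
    """Candidate fit windows from detected event intervals, padded ``pad``
    frames on each side."""
    return [(max(ev.t_start - pad, 0), min(ev.t_end + pad, n_frames - 1))
            for ev in events]


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------

ECDF_VARIABLES = ("roi_size_um2", "max_dfof", "fwhm_s")


def summarize_events(movie: MovieStack, events, background_roi=None,
                     ) -> pd.DataFrame:
    """Per detected event: ROI size, max ΔF/F (per-ROI over the whole series
    and per-event within the fit window) and fitted FWHM.

    The event's OR-projection footprint is the ROI.  Returns one row per
    event; events whose Gaussian fit fails carry NaN FWHM.
    """
    if background_roi is None and events:
        background_roi = auto_background_roi(movie, [e.footprint_2d for e in events])
    rows = []
    for ev in events:
        try:
            trace = compute_trace(movie, ev.footprint_2d, background_roi,
                                  roi_id=ev.event_id)
        except ValueError as exc:
            warnings.warn(f"event {ev.event_id}: {exc}; skipped", stacklevel=2)
            continue
        lo, hi = windows_from_events([ev], movie.n_frames)[0]
        fits = fit_events(trace, [(lo, hi)])
        rows.append({
            "event_id": ev.event_id,
            "roi_size_um2": ev.area_um2,
            "max_dfof": float(trace.dFoF.max()),
            "max_dfof_event": float(trace.dFoF[lo:hi + 1].max()),
            "fwhm_s": fits[0].fwhm if fits else np.nan,
            "t_start_s": ev.t_start * movie.frame_interval,
            "duration_s": (ev.t_end - ev.t_start + 1) * movie.frame_interval,
        })
    cols = ["event_id", "roi_size_um2", "max_dfof", "max_dfof_event",
            "fwhm_s", "t_start_s", "duration_s"]
    return pd.DataFrame(rows, columns=cols)


def ks_distance(a: EcdfSummary, b: EcdfSummary) -> float:
    """Two-sample Kolmogorov–Smirnov distance sup |ECDF_a − ECDF_b|."""
    grid = np.concatenate([a.values, b.values])
    return float(np.max(np.abs(a(grid) - b(grid))))


def build_ecdfs(event_tables: dict[str, pd.DataFrame],
                variables=ECDF_VARIABLES,
                ) -> tuple[dict[tuple[str, str], EcdfSummary], pd.DataFrame]:
    """ECDF per (condition, variable) plus pairwise KS distances.

    ``event_tables`` maps condition name → per-event table (columns must
    include the requested variables).  Conditions with no events are
    rejected.  KS distance here is descriptive, not a hypothesis test.
    """
    ecdfs: dict[tuple[str, str], EcdfSummary] = {}
    for cond, table in event_tables.items():
        if len(table) == 0:
            raise ValueError(f"condition {cond!r} has no events")
        for var in variables:
            vals = table[var].dropna().to_numpy()
            if len(vals) == 0:
                raise ValueError(f"condition {cond!r} has no finite {var!r}")
            ecdfs[(cond, var)] = EcdfSummary(var, cond, vals)
    rows = []
    conds = list(event_tables)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1:]:
            for var in variables:
                rows.append({"condition_a": c1, "condition_b": c2,
                             "variable": var,
                             "ks_distance": ks_distance(ecdfs[(c1, var)],
                                                        ecdfs[(c2, var)])})
    return ecdfs, pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                              "variable", "ks_distance"])


def average_response(traces, stimulus_time: float = 0.0) -> pd.DataFrame:
    """Mean ΔF/F time course across ROIs with per-frame standard error.

    All traces must share length and frame interval.  The time axis is
    re-zeroed at ``stimulus_time``.  With a single trace the SEM is
    undefined and reported as NaN.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    T = len(traces[0].F)
    dt = traces[0].frame_interval
    for tr in traces:
        if len(tr.F) != T or tr.frame_interval != dt:
            raise ValueError("all traces must share T and frame_interval")
    stack = np.stack([tr.dFoF for tr in traces])
    mean = stack.mean(axis=0)
    if len(traces) >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(traces))
    else:
        sem = np.full(T, np.nan)
    return pd.DataFrame({"time_s": np.arange(T) * dt - stimulus_time,
                         "mean_dfof": mean, "sem_dfof": sem})
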