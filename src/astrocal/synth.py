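"""Synthetic dual-channel calcium-imaging movies with full ground truth.

The generator emulates recordings from micropatterned neuron–astrocyte
co-cultures: circular cell-attachment sites rendered as hard-edged disks,
astrocyte microdomain events as multiplicative ΔF/F transients with Gaussian
time course on a fixed spatial footprint, propagating calcium waves that
activate pixels along a polyline path with an arc-length/speed delay, and
additive Gaussian read noise plus optional Poisson shot noise.

The pixel model is

    signal(t, r, c) = background + Σ_i b_i · disk_i(r, c) · (1 + Σ_j a_j g_j(t))

where ``b_i`` is cell *i*'s baseline intensity and ``a_j g_j(t)`` the ΔF/F
contribution of event/wave *j* active at that pixel (Gaussian kernel of
width ``sigma_t`` centred on the peak/arrival time).  Hard-edged disks make
footprint ground truth unambiguous for precision/recall scoring, and the
Gaussian temporal kernel means the downstream FWHM fit has the closed-form
truth ``FWHM = 2·sqrt(2 ln 2)·sigma_t``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import MovieStack

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-σ Gaussian

DEFAULT_BACKGROUND = 30.0


# ---------------------------------------------------------------------------
# Ground-truth record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """A circular cell-attachment site."""

    cell_id: int
    cell_class: str              # "neuron" | "astrocyte"
    center: tuple[int, int]      # (row, col), pixels
    radius: float                # pixels
    channel: str                 # "green" | "red"
    baseline_intensity: float    # fluorescence units

    def __post_init__(self) -> None:
        if self.cell_class not in ("neuron", "astrocyte"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.channel not in ("green", "red"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.radius <= 0:
            raise ValueError("cell radius must be > 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean disk mask: pixel included iff its centre lies within
        ``radius`` of the cell centre (Euclidean)."""
        rr, cc = np.ogrid[: frame_shape[0], : frame_shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class EventSpec:
    """A microdomain calcium event: Gaussian ΔF/F transient on a fixed
    spatial footprint inside one host cell."""

    event_id: int
    cell_id: int
    footprint: frozenset        # of (row, col) pixels
    onset_time: float           # s
    peak_time: float            # s
    amplitude: float            # ΔF/F units
    sigma_t: float              # s

    def __post_init__(self) -> None:
        if not self.footprint:
            raise ValueError("event footprint must be non-empty")
        if self.amplitude <= 0:
            raise ValueError("event amplitude must be > 0")
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be > 0")
        if self.peak_time < self.onset_time:
            raise ValueError("peak_time must be ≥ onset_time")

    @property
    def fwhm(self) -> float:
        return GAUSS_FWHM * self.sigma_t

    def kernel(self, times: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((times - self.peak_time) ** 2)
                                       / (2.0 * self.sigma_t**2))

    def active_frames(self, times: np.ndarray) -> np.ndarray:
        """Frame indices where the kernel is at or above its half maximum."""
        return np.nonzero(np.abs(times - self.peak_time)
                          <= GAUSS_FWHM / 2.0 * self.sigma_t)[0]


@dataclass(frozen=True)
class WaveSpec:
    """A calcium wave travelling along a polyline path at constant speed.

    Each pixel under the path receives the Gaussian event kernel delayed by
    its arrival time ``start_time + arc_length_μm / speed``.
    """

    path: tuple                  # ordered ((row, col), ...) waypoints, pixels
    speed: float                 # μm s⁻¹
    start_time: float            # s
    amplitude: float             # ΔF/F units
    width_t: float               # s, temporal Gaussian width

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("wave speed must be > 0")
        if len(self.path) < 2:
            raise ValueError("wave path needs ≥ 2 waypoints")
        if self.amplitude <= 0 or self.width_t <= 0:
            raise ValueError("amplitude and width_t must be > 0")

    def rasterize(self, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (pixels, arrival_times): unique path pixels (N×2 int array)
        and the arrival time (s) of the wave front at each pixel.

        The polyline is sampled at quarter-pixel arc-length steps; where
        several samples land on one pixel the earliest arrival wins.
        """
        pts = np.asarray(self.path, dtype=float)
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        total = seg_len.sum()
        if total <= 0:
            raise ValueError("wave path has zero length")
        s = np.arange(0.0, total + 0.125, 0.25)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        rows = np.interp(s, cum, pts[:, 0])
        cols = np.interp(s, cum, pts[:, 1])
        pix = np.stack([np.rint(rows), np.rint(cols)], axis=1).astype(int)
        arrival = self.start_time + s * pixel_size / self.speed
        # first arrival per unique pixel
        order = np.argsort(arrival, kind="stable")
        pix, arrival = pix[order], arrival[order]
        _, first = np.unique(pix, axis=0, return_index=True)
        return pix[first], arrival[first]


@dataclass(frozen=True)
class NoiseSpec:
    """Imaging noise: Poisson shot noise (``poisson_gain`` electrons per
    fluorescence unit; 0 disables it) followed by additive Gaussian read
    noise.  Both streams are sub-seeded from ``seed`` by spawning a numpy
    ``SeedSequence`` (child 0 → Poisson, child 1 → Gaussian)."""

    gaussian_sd: float = 0.0
    poisson_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_gain < 0:
            raise ValueError("noise parameters must be ≥ 0")


@dataclass
class GroundTruth:
    """Everything the generator knows: cells, events, waves, calibration and
    the preset parameters used (``meta``)."""

    cells: list
    events: list
    waves: list
    frame_interval: float
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {c.cell_id for c in self.cells}
        for ev in self.events:
            if ev.cell_id not in ids:
                raise ValueError(f"event {ev.event_id} references unknown cell "
                                 f"{ev.cell_id}")

    # -- lossless YAML round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "frame_interval": float(self.frame_interval),
            "pixel_size": float(self.pixel_size),
            "meta": self.meta,
            "cells": [
                {"cell_id": c.cell_id, "cell_class": c.cell_class,
                 "center": [int(c.center[0]), int(c.center[1])],
                 "radius": float(c.radius), "channel": c.channel,
                 "baseline_intensity": float(c.baseline_intensity)}
                for c in self.cells],
            "events": [
                {"event_id": e.event_id, "cell_id": e.cell_id,
                 "footprint": sorted([int(r), int(c)] for r, c in e.footprint),
                 "onset_time": float(e.onset_time), "peak_time": float(e.peak_time),
                 "amplitude": float(e.amplitude), "sigma_t": float(e.sigma_t)}
                for e in self.events],
            "waves": [
                {"path": [[float(r), float(c)] for r, c in w.path],
                 "speed": float(w.speed), "start_time": float(w.start_time),
                 "amplitude": float(w.amplitude), "width_t": float(w.width_t)}
                for w in self.waves],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        cells = [CellSpec(c["cell_id"], c["cell_class"], tuple(c["center"]),
                          c["radius"], c["channel"], c["baseline_intensity"])
                 for c in d["cells"]]
        events = [EventSpec(e["event_id"], e["cell_id"],
                            frozenset((r, c) for r, c in e["footprint"]),
                            e["onset_time"], e["peak_time"], e["amplitude"],
                            e["sigma_t"])
                  for e in d["events"]]
        waves = [WaveSpec(tuple((r, c) for r, c in w["path"]), w["speed"],
                          w["start_time"], w["amplitude"], w["width_t"])
                 for w in d["waves"]]
        return cls(cells, events, waves, d["frame_interval"], d["pixel_size"],
                   d.get("meta", {}))

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Movie synthesis
# ---------------------------------------------------------------------------

def clean_frame_sums(cells, events, waves, shape, pixel_size, frame_interval,
                     background: float = DEFAULT_BACKGROUND) -> np.ndarray:
    """Analytic spatial sum of each noiseless frame (used by conservation
    checks): static scene total plus every active contribution."""
    T, H, W = shape
    times = np.arange(T) * frame_interval
    by_id = {c.cell_id: c for c in cells}
    static = background * H * W + sum(
        c.baseline_intensity * int(c.mask((H, W)).sum()) for c in cells)
    total = np.full(T, float(static))
    for ev in events:
        b = by_id[ev.cell_id].baseline_intensity
        total += b * len(ev.footprint) * ev.kernel(times)
    basemap = _basemap(cells, (H, W), 0.0)
    for wv in waves:
        pix, arrival = wv.rasterize(pixel_size)
        for (r, c), t0 in zip(pix, arrival):
            total += basemap[r, c] * wv.amplitude * np.exp(
                -((times - t0) ** 2) / (2.0 * wv.width_t**2))
    return total


def _basemap(cells, frame_shape, background):
    base = np.full(frame_shape, float(background))
    for cell in cells:
        r, c = cell.center
        if not (0 <= r < frame_shape[0] and 0 <= c < frame_shape[1]):
            raise ValueError(f"cell {cell.cell_id} centre {cell.center} outside frame")
        base[cell.mask(frame_shape)] += cell.baseline_intensity
    return base


def generate_movie(cells, events, waves, noise: NoiseSpec,
                   shape: tuple[int, int, int], pixel_size: float = 1.0,
                   frame_interval: float = 0.5, channel: str = "green",
                   background: float = DEFAULT_BACKGROUND,
                   ) -> tuple[MovieStack, GroundTruth]:
    """Render a movie from cell/event/wave specs.

    Identical specs and seed give bit-identical movies.  Footprints outside
    the frame or outside their host cell are rejected; intensities driven
    negative by noise are clipped at zero with a warning.
    """
    T, H, W = shape
    if min(shape) < 1:
        raise ValueError("movie shape dimensions must be positive")
    times = np.arange(T) * frame_interval
    by_id = {c.cell_id: c for c in cells}

    base = _basemap(cells, (H, W), background)
    data = np.repeat(base[None], T, axis=0)

    for ev in events:
        host = by_id.get(ev.cell_id)
        if host is None:
            raise ValueError(f"event {ev.event_id} references unknown cell {ev.cell_id}")
        fp = np.array(sorted(ev.footprint), dtype=int)
        if (fp < 0).any() or (fp[:, 0] >= H).any() or (fp[:, 1] >= W).any():
            raise ValueError(f"event {ev.event_id} footprint outside frame")
        host_mask = host.mask((H, W))
        if not host_mask[fp[:, 0], fp[:, 1]].all():
            raise ValueError(f"event {ev.event_id} footprint outside host cell "
                             f"{ev.cell_id}")
        data[:, fp[:, 0], fp[:, 1]] += (host.baseline_intensity
                                        * ev.kernel(times)[:, None])

    for wv in waves:
        pix, arrival = wv.rasterize(pixel_size)
        if (pix < 0).any() or (pix[:, 0] >= H).any() or (pix[:, 1] >= W).any():
            raise ValueError("wave path outside frame")
        local_base = base[pix[:, 0], pix[:, 1]] - background
        kern = wv.amplitude * np.exp(-((times[:, None] - arrival[None, :]) ** 2)
                                     / (2.0 * wv.width_t**2))
        data[:, pix[:, 0], pix[:, 1]] += local_base[None, :] * kern

    if noise.poisson_gain > 0 or noise.gaussian_sd > 0:
        ss = np.random.SeedSequence(noise.seed)
        child_p, child_g = ss.spawn(2)
        if noise.poisson_gain > 0:
            rng = np.random.default_rng(child_p)
            data = rng.poisson(data * noise.poisson_gain).astype(float) / noise.poisson_gain
        if noise.gaussian_sd > 0:
            rng = np.random.default_rng(child_g)
            data = data + rng.normal(0.0, noise.gaussian_sd, size=data.shape)
        if (data < 0).any():
            warnings.warn("noise drove some intensities negative; clipped at 0",
                          stacklevel=2)
            data = np.clip(data, 0.0, None)

    truth = GroundTruth(list(cells), list(events), list(waves),
                        frame_interval, pixel_size,
                        meta={"background": background, "shape": list(shape),
                              "channel": channel})
    return MovieStack(data, pixel_size, frame_interval, channel), truth


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------
#
# The three culture conditions contrast astrocyte activity patterns:
#   A_alone      — astrocyte monoculture: rare events that sweep most of the
#                  cell (wave-like, large OR-footprint), modest rate;
#   NA_same      — neurons and astrocytes in one chamber: frequent,
#                  spatially restricted microdomain events;
#   N_A_adjacent — neurons in the adjacent chamber, axons crossing grooves:
#                  microdomain activity like NA_same but with lower ΔF/F
#                  amplitude.
# Rates/amplitudes are free parameters chosen to realize these published
# orderings; exact per-condition numbers were never reported.

CONDITION_PRESETS: dict[str, dict] = {
    "A_alone": dict(rate_per_cell_per_min=0.5, footprint_radius=(14.0, 18.0),
                    amplitude=(1.2, 1.8), sigma_t=(1.5, 2.5)),
    "NA_same": dict(rate_per_cell_per_min=3.0, footprint_radius=(3.0, 5.0),
                    amplitude=(1.6, 2.4), sigma_t=(0.8, 1.6)),
    "N_A_adjacent": dict(rate_per_cell_per_min=3.0, footprint_radius=(3.0, 5.0),
                         amplitude=(0.6, 1.0), sigma_t=(0.8, 1.6)),
}

_FRAME = dict(shape=(240, 256, 256), pixel_size=1.0, frame_interval=0.5,
              background=DEFAULT_BACKGROUND, gaussian_sd=5.0, poisson_gain=0.0)

_ASTRO_CENTERS = [(64, 32), (64, 96), (64, 160), (64, 224),
                  (192, 32), (192, 96), (192, 160), (192, 224)]
_NEURON_CENTERS = [(128, 48), (128, 112), (128, 176), (128, 240 - 16),
                   (32, 128), (224, 128)]
_ASTRO_RADIUS = 22.0
_ASTRO_BASELINE = 120.0
_NEURON_RADIUS = 9.0
_NEURON_BASELINE = 100.0
_NEURON_RATE_PER_MIN = 2.0
_NEURON_AMPLITUDE = 1.2
_NEURON_SIGMA_T = 0.6


def _disk_pixels(center, radius, clip_mask):
    rr, cc = np.nonzero(clip_mask)
    keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return frozenset(zip(rr[keep].tolist(), cc[keep].tolist()))


def _draw_events(rng, cells, preset, duration_s, frame_shape, start_id=0):
    events = []
    eid = start_id
    n_per_cell = max(1, round(preset["rate_per_cell_per_min"] * duration_s / 60.0))
    for cell in cells:
        mask = cell.mask(frame_shape)
        for _ in range(n_per_cell):
            r_fp = rng.uniform(*preset["footprint_radius"])
            max_off = max(cell.radius - r_fp, 0.0)
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            ctr = (cell.center[0] + off * np.sin(ang),
                   cell.center[1] + off * np.cos(ang))
            fp = _disk_pixels(ctr, r_fp, mask)
            if not fp:  # footprint fell outside the rasterized disk
                fp = _disk_pixels(cell.center, r_fp, mask)
            sigma_t = rng.uniform(*preset["sigma_t"])
            peak = rng.uniform(5.0 + 3 * sigma_t, duration_s - 5.0 - 3 * sigma_t)
            events.append(EventSpec(eid, cell.cell_id, fp,
                                    onset_time=peak - 3 * sigma_t, peak_time=peak,
                                    amplitude=rng.uniform(*preset["amplitude"]),
                                    sigma_t=sigma_t))
            eid += 1
    return events


def generate_condition_set(condition: str, seed: int,
                           ) -> tuple[dict[str, MovieStack], GroundTruth]:
    """Generate the dual-channel movie pair for one culture condition.

    Returns ``({"green": MovieStack, "red": MovieStack}, GroundTruth)``.
    The green channel carries astrocytes (GCaMP6-like), the red channel
    neurons (R-GECO-like); ``A_alone`` has an empty red channel.
    """
    if condition not in CONDITION_PRESETS:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(CONDITION_PRESETS)}")
    preset = CONDITION_PRESETS[condition]
    T, H, W = _FRAME["shape"]
    duration = T * _FRAME["frame_interval"]

    ss = np.random.SeedSequence([seed, zlib.crc32(condition.encode()) % (2**31)])
    ev_seed, g_noise, r_noise = ss.spawn(3)
    rng = np.random.default_rng(ev_seed)

    astro = [CellSpec(i, "astrocyte", ctr, _ASTRO_RADIUS, "green", _ASTRO_BASELINE)
             for i, ctr in enumerate(_ASTRO_CENTERS)]
    cells = list(astro)
    neuron = []
    if condition != "A_alone":
        neuron = [CellSpec(100 + i, "neuron", ctr, _NEURON_RADIUS, "red",
                           _NEURON_BASELINE)
                  for i, ctr in enumerate(_NEURON_CENTERS)]
        cells += neuron

    events = _draw_events(rng, astro, preset, duration, (H, W))
    n_preset = dict(rate_per_cell_per_min=_NEURON_RATE_PER_MIN,
                    footprint_radius=(_NEURON_RADIUS, _NEURON_RADIUS),
                    amplitude=(_NEURON_AMPLITUDE, _NEURON_AMPLITUDE),
                    sigma_t=(_NEURON_SIGMA_T, _NEURON_SIGMA_T))
    n_events = _draw_events(rng, neuron, n_preset, duration, (H, W),
                            start_id=10_000) if neuron else []

    def render(chan, chan_cells, chan_events, noise_ss):
        noise = NoiseSpec(_FRAME["gaussian_sd"], _FRAME["poisson_gain"],
                          seed=int(noise_ss.generate_state(1)[0] % (2**31)))
        movie, _ = generate_movie(chan_cells, chan_events, [], noise,
                                  (T, H, W), _FRAME["pixel_size"],
                                  _FRAME["frame_interval"], channel=chan,
                                  background=_FRAME["background"])
        return movie

    movies = {"green": render("green", astro, events, g_noise),
              "red": render("red", neuron, n_events, r_noise)}
    truth = GroundTruth(cells, events + n_events, [],
                        _FRAME["frame_interval"], _FRAME["pixel_size"],
                        meta={"condition": condition, "seed": seed,
                              "preset": {k: list(v) if isinstance(v, tuple) else v
                                         for k, v in preset.items()},
                              "background": _FRAME["background"],
                              "gaussian_sd": _FRAME["gaussian_sd"],
                              "shape": list(_FRAME["shape"])})
    return movies, truth
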