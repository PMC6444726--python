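"""Movie, table and configuration I/O.

Conventions used throughout the package: pixel coordinates are 0-based
``(row, col)``; time is ``frame_index * frame_interval`` with frame 0 at
t = 0.  Physical calibration (pixel size in μm, frame interval in s) lives
in the run configuration, never in TIFF tags — tags, if present, are
ignored with a logged notice to avoid writer-dialect ambiguity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class MovieStack:
    """A T×H×W fluorescence record with physical calibration.

    Parameters
    ----------
    data:
        Non-negative array of shape (T, H, W); frames in acquisition order.
    pixel_size:
        μm per pixel (square pixels assumed).
    frame_interval:
        Seconds per frame.
    channel:
        Free-form label, e.g. ``"green"`` (GCaMP6-like) or ``"red"``
        (R-GECO-like).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = "green"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be T×H×W, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all movie dimensions must be ≥ 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval


def read_movie(path: str | Path, pixel_size: float, frame_interval: float,
               channel: str = "green") -> MovieStack:
    """Read a multi-page grayscale TIFF as a :class:`MovieStack`.

    Integer input is preserved losslessly.  RGB / multi-sample pages are
    rejected; a truncated file raises an error naming the failing page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    frames = []
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        raise IOError(f"failed to read TIFF structure of {path} "
                      f"(file truncated or corrupt): {exc}") from exc
    with tif:
        i = 0
        try:
            if tif.pages[0].tags.get("XResolution") is not None:
                log.info("ignoring TIFF resolution tags in %s; calibration "
                         "comes from the run configuration", path)
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                if arr.ndim != 2:
                    raise ValueError(
                        f"page {i} of {path} is not single-sample grayscale "
                        f"(shape {arr.shape}); RGB/multi-channel TIFFs are "
                        "not supported")
                frames.append(arr)
        except tifffile.TiffFileError as exc:
            raise IOError(f"failed to read page {i} of {path} "
                          f"(file truncated or corrupt): {exc}") from exc
        except ValueError:
            raise
        except Exception as exc:  # corrupt or truncated page / IFD chain
            raise IOError(f"failed to read page {i} of {path} "
                          f"(file truncated or corrupt): {exc}") from exc
    data = np.stack(frames, axis=0)
    return MovieStack(data, pixel_size, frame_interval, channel)


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as multi-page 16-bit grayscale TIFF (values clipped and
    rounded to the uint16 range)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  overwrite: bool = False) -> dict[str, str]:
    """Write named tables as UTF-8 CSV files with a ``# schema_version``
    comment line and return a manifest mapping filename → sha256.

    The manifest itself is written as ``manifest.json``.  Existing files are
    only replaced when ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        target = out_dir / fname
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
        with open(target, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# schema_version={SCHEMA_VERSION}\n")
            table.to_csv(fh, index=False)
        manifest[fname] = _sha256(target)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "pixel_size": (float, 0.0, None),
    "frame_interval": (float, 0.0, None),
    "lowpass_sigma": (float, -1e-12, None),
    "k": (float, 0.0, None),
    "min_voxels": (int, 1, None),
    "connectivity": (int, None, None),
    "segmentation_threshold": (float, None, None),
    "min_area": (int, 1, None),
    "geometry_file": (str, None, None),
    "out_dir": (str, None, None),
    "seed": (int, 0, None),
}

_CONFIG_DEFAULTS = {
    "pixel_size": 1.0,
    "frame_interval": 0.5,
    "lowpass_sigma": 2.0,
    "k": 2.0,
    "min_voxels": 20,
    "connectivity": 26,
    "segmentation_threshold": None,
    "min_area": 20,
    "geometry_file": None,
    "out_dir": "results",
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated run configuration shared by all pipeline stages.

    Unknown keys are rejected rather than ignored so that typos in a config
    file cannot silently fall back to defaults.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        for key, (typ, lo, hi) in _CONFIG_FIELDS.items():
            val = merged[key]
            if val is None:
                continue
            val = typ(val)
            if lo is not None and val <= lo and typ is float:
                raise ValueError(f"config key {key}={val} out of range (must be > {lo})")
            if lo is not None and typ is int and val < lo:
                raise ValueError(f"config key {key}={val} out of range (must be ≥ {lo})")
            merged[key] = val
        if merged["connectivity"] not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)
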