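"""Cell-body segmentation and manual soma ROIs.

Cells are segmented from a reference image (temporal mean by default) by an
explicit intensity threshold combined with marker-based watershed: touching
cells are split at smoothed local maxima of the distance transform.  The
threshold is a numeric parameter rather than an interactive step so runs are
reproducible; an Otsu suggestion is logged for guidance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

# Seeding parameters for the watershed split: the distance transform is
# smoothed with a fixed 3-px Gaussian before peak picking and peaks closer
# than 4 px are merged, suppressing over-segmentation from pixel-scale
# roughness of the foreground boundary.
_SEED_SMOOTH_SIGMA = 3.0
_SEED_MIN_DISTANCE = 4


@dataclass
class LabelMask:
    """H×W integer label image; 0 = background, 1..n = cells."""

    labels: np.ndarray
    provenance: str = "auto"     # "auto" | "manual"

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of region centroids in (row, col)."""
        return np.array(ndi.center_of_mass(self.labels > 0, self.labels,
                                           range(1, self.n_regions + 1)),
                        dtype=float).reshape(-1, 2)


@dataclass
class RoiSet:
    """Named pixel sets (somata, event footprints) within one frame shape."""

    rois: list = field(default_factory=list)   # (roi_id, frozenset pixels, class)
    frame_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("roi_ids must be unique")
        H, W = self.frame_shape
        for roi_id, pixels, _ in self.rois:
            if not pixels:
                raise ValueError(f"ROI {roi_id} is empty")
            for r, c in pixels:
                if not (0 <= r < H and 0 <= c < W):
                    raise ValueError(f"ROI {roi_id} pixel {(r, c)} outside frame")

    def __len__(self) -> int:
        return len(self.rois)

    def pixels(self, roi_id):
        for rid, px, _ in self.rois:
            if rid == roi_id:
                return px
        raise KeyError(roi_id)

    def write(self, path: str | Path) -> None:
        doc = {"frame_shape": list(self.frame_shape),
               "rois": [{"roi_id": rid,
                         "pixels": sorted([int(r), int(c)] for r, c in px),
                         "cell_class": cls}
                        for rid, px, cls in self.rois]}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RoiSet":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        rois = [(r["roi_id"], frozenset((a, b) for a, b in r["pixels"]),
                 r.get("cell_class")) for r in doc["rois"]]
        return cls(rois, tuple(doc["frame_shape"]))


def segment_cells(reference_image: np.ndarray, threshold: float,
                  min_area: int = 1) -> LabelMask:
    """Threshold + watershed segmentation of cell bodies.

    Foreground is ``reference_image >= threshold``; touching cells are split
    by watershed seeded at smoothed local maxima of the Euclidean distance
    transform; components smaller than ``min_area`` pixels are removed and
    labels renumbered consecutively from 1.
    """
    img = np.asarray(reference_image, dtype=float)
    if min_area < 1:
        raise ValueError("min_area must be ≥ 1")
    if img.max() > img.min():
        log.info("Otsu threshold suggestion for this image: %.3f",
                 threshold_otsu(img))
    fg = img >= threshold
    if not fg.any():
        warnings.warn("empty foreground: no pixel reaches the threshold",
                      stacklevel=2)
        return LabelMask(np.zeros(img.shape, dtype=np.int32))

    dist = ndi.distance_transform_edt(fg)
    smooth = ndi.gaussian_filter(dist, _SEED_SMOOTH_SIGMA)
    peaks = peak_local_max(smooth, min_distance=_SEED_MIN_DISTANCE,
                           labels=fg, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: fall back to connected components
        labels, _ = ndi.label(fg)
    else:
        labels = watershed(-smooth, markers, mask=fg)

    # drop small regions, renumber consecutively
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_area:
            out[region] = next_id
            next_id += 1
    return LabelMask(out)


def circle_rois(centers, radius: float, frame_shape: tuple[int, int],
                cell_class: str | None = "neuron") -> RoiSet:
    """Disk ROIs for manually encircled somata.

    A pixel belongs to an ROI iff its centre lies within ``radius`` of the
    ROI centre (Euclidean); disks are clipped to the frame.  Centres outside
    the frame are rejected with a message naming them.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    H, W = frame_shape
    rois = []
    for i, (r0, c0) in enumerate(centers):
        if not (0 <= r0 < H and 0 <= c0 < W):
            raise ValueError(f"ROI centre {(r0, c0)} outside frame {frame_shape}")
        rr, cc = np.ogrid[:H, :W]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        px = frozenset(zip(*[a.tolist() for a in np.nonzero(mask)]))
        rois.append((i, px, cell_class))
    return RoiSet(rois, frame_shape)
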