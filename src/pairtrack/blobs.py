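"""Blob extraction: from grayscale frames to connected foreground components.

A *blob* is one connected component of the thresholded foreground in one
frame.  Blobs are either single animals (``individual``) or several
overlapping animals (``crossing``); only individual blobs enter fragments.

Conventions: pixels, origin top-left, x to the right, y down, frames
0-based, all intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import InvalidInputError

__all__ = ["Blob", "segment_frame", "classify_blob", "extract_crop"]

INDIVIDUAL = "individual"
CROSSING = "crossing"


@dataclass
class Blob:
    """One connected foreground component in one frame.

    ``pixels`` is an optional (n, 2) integer array of (y, x) coordinates
    used for overlap-based linking; detection-table inputs omit it and the
    linker falls back to centroid distance.  ``true_identity`` carries the
    generator's ground-truth label on synthetic data and is never consulted
    by the tracking pipeline itself.
    """

    frame_index: int
    centroid: tuple[float, float]          # (x, y), pixels
    pixel_count: int
    bounding_box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    crop: np.ndarray                        # L x L grayscale in [0, 1]
    kind: str = INDIVIDUAL
    pixels: np.ndarray | None = None
    true_identity: int | None = None
    _pixel_set: frozenset = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        x, y = self.centroid
        x0, y0, x1, y1 = self.bounding_box
        if not (x0 <= x < x1 and y0 <= y < y1):
            raise InvalidInputError(
                f"centroid {self.centroid} outside bounding box {self.bounding_box}"
            )
        if self.pixel_count <= 0:
            raise InvalidInputError("blob must contain at least one pixel")
        if self.pixel_count > (x1 - x0) * (y1 - y0):
            raise InvalidInputError("pixel_count exceeds bounding-box area")

    @property
    def is_crossing(self) -> bool:
        return self.kind == CROSSING

    def pixel_set(self) -> frozenset:
        """Frozenset of linearised pixel coordinates, cached; empty if unknown."""
        if self._pixel_set is None:
            if self.pixels is None:
                object.__setattr__(self, "_pixel_set", frozenset())
            else:
                enc = self.pixels[:, 0].astype(np.int64) << 20 | self.pixels[:, 1]
                object.__setattr__(self, "_pixel_set", frozenset(enc.tolist()))
        return self._pixel_set

    def overlap(self, other: "Blob") -> int:
        """Number of shared pixels with ``other`` (0 if either lacks pixels)."""
        return len(self.pixel_set() & other.pixel_set())

    def distance_to(self, other: "Blob") -> float:
        dx = self.centroid[0] - other.centroid[0]
        dy = self.centroid[1] - other.centroid[1]
        return float(np.hypot(dx, dy))


def extract_crop(frame: np.ndarray, centroid: tuple[float, float], side: int) -> np.ndarray:
    """Square crop of ``side`` pixels centered on ``centroid``, zero-padded."""
    h, w = frame.shape
    cx, cy = int(round(centroid[0])), int(round(centroid[1]))
    half = side // 2
    out = np.zeros((side, side), dtype=np.float32)
    y0, y1 = cy - half, cy - half + side
    x0, x1 = cx - half, cx - half + side
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    if sy0 < sy1 and sx0 < sx1:
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = frame[sy0:sy1, sx0:sx1]
    return out


def segment_frame(
    frame: np.ndarray,
    intensity_threshold: float,
    roi_mask: np.ndarray | None = None,
    occlusion_mask: np.ndarray | None = None,
    *,
    min_blob_area: int = 10,
    crop_size: int = 24,
    frame_index: int = 0,
) -> list[Blob]:
    """Threshold a grayscale frame and return its foreground blobs.

    Pixels outside ``roi_mask`` (where given) and pixels inside
    ``occlusion_mask`` are treated as background before connected-component
    labelling, so no information is extracted from them.  Components smaller
    than ``min_blob_area`` are discarded.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise InvalidInputError("frame must be a non-empty 2-D grayscale array")
    if not (0.0 <= intensity_threshold <= 1.0):
        raise InvalidInputError("intensity_threshold must lie in [0, 1]")
    foreground = frame > intensity_threshold
    if roi_mask is not None:
        if roi_mask.shape != frame.shape:
            raise InvalidInputError("roi_mask shape differs from frame shape")
        foreground &= roi_mask.astype(bool)
    if occlusion_mask is not None:
        if occlusion_mask.shape != frame.shape:
            raise InvalidInputError("occlusion_mask shape differs from frame shape")
        foreground &= ~occlusion_mask.astype(bool)

    labels = measure.label(foreground, connectivity=2)
    blobs: list[Blob] = []
    for region in measure.regionprops(labels):
        if region.area < min_blob_area:
            continue
        cy, cx = region.centroid
        y0, x0, y1, x1 = region.bbox
        blobs.append(
            Blob(
                frame_index=frame_index,
                centroid=(float(cx), float(cy)),
                pixel_count=int(region.area),
                bounding_box=(x0, y0, x1, y1),
                crop=extract_crop(frame, (cx, cy), crop_size),
                pixels=np.asarray(region.coords, dtype=np.int64),
            )
        )
    return blobs


def classify_blob(
    blob: Blob,
    median_individual_area: float,
    crossing_area_factor: float,
    prev_blobs: list[Blob] | None = None,
) -> str:
    """Label a blob ``individual`` or ``crossing``.

    A blob is a crossing if its area exceeds ``crossing_area_factor`` times
    the median single-animal area, or if its pixel set overlaps two or more
    distinct blobs alive in the previous frame (two animals merging).
    """
    if median_individual_area <= 0:
        raise InvalidInputError("median_individual_area must be positive")
    if blob.pixel_count > crossing_area_factor * median_individual_area:
        return CROSSING
    if prev_blobs:
        n_overlaps = sum(1 for p in prev_blobs if blob.overlap(p) > 0)
        if n_overlaps >= 2:
            return CROSSING
    return INDIVIDUAL
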