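"""Core domain types and pixel-geometry primitives.

Conventions used throughout the package: pixel coordinates are 0-based and
half-open (a box spans ``[x0, x1) x [y0, y1)``), with x increasing rightward
and y downward, as is standard for raster images.  A "heat map" here is the
detection-evidence image of the fusion pipeline — a per-frame grid in [0, 1]
marking pixels covered by detector bounding boxes — not a statistical
density plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "FrameRef",
    "BoundingBox",
    "BoundingBoxDetection",
    "HeatMap",
    "Homography",
    "CandidateSignature",
    "rasterize_boxes",
    "warp_heatmap",
    "box_center_distance",
]

HeatMapKind = Literal["per_detector_binary", "combined", "accumulated"]


@dataclass(frozen=True)
class FrameRef:
    """A single frame of a survey video sequence.

    ``index`` is the frame counter t; ``timestamp`` is seconds since survey
    start; ``shape`` is (height, width) in pixels.
    """

    survey_id: str
    index: int
    timestamp: float
    shape: tuple[int, int] = (512, 640)

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be >= 0, got {self.index}")
        h, w = self.shape
        if h <= 0 or w <= 0:
            raise ValueError(f"frame shape must be positive, got {self.shape}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate box: ({self.x0},{self.y0})-({self.x1},{self.y1})"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def clipped(self, shape: tuple[int, int]) -> "BoundingBox | None":
        """Intersect with frame bounds (h, w); None if nothing remains."""
        h, w = shape
        x0, y0 = max(self.x0, 0.0), max(self.y0, 0.0)
        x1, y1 = min(self.x1, float(w)), min(self.y1, float(h))
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)


@dataclass(frozen=True)
class BoundingBoxDetection:
    """One detector output on one frame: a box, a class label and a
    confidence in [0, 1]."""

    frame: FrameRef
    box: BoundingBox
    label: str
    confidence: float
    detector_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class HeatMap:
    """Detection-evidence grid in [0, 1] matching the frame shape.

    ``kind`` records the pipeline stage: a single detector's binary
    rasterization, the ensemble average, or the temporal accumulator.
    """

    frame: FrameRef
    values: np.ndarray
    kind: HeatMapKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.frame.shape:
            raise ValueError(
                f"heat map shape {self.values.shape} != frame shape {self.frame.shape}"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("heat map values must lie in [0, 1]")


@dataclass(frozen=True)
class Homography:
    """3x3 planar projective map sending source-frame pixels (x, y) to
    target-frame pixels, normalized so the bottom-right entry is 1."""

    matrix: np.ndarray
    source_frame: FrameRef | None = None
    target_frame: FrameRef | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "matrix", m / m[2, 2])

    @classmethod
    def identity(cls, source: FrameRef | None = None, target: FrameRef | None = None) -> "Homography":
        return cls(np.eye(3), source, target)

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Homography":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix), self.target_frame, self.source_frame)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points through the homography."""
        pts = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def compose(self, inner: "Homography") -> "Homography":
        """self ∘ inner: apply ``inner`` first, then ``self``."""
        return Homography(self.matrix @ inner.matrix, inner.source_frame, self.target_frame)


@dataclass
class CandidateSignature:
    """A connected super-threshold accumulator region passing the size gate.

    ``pixel_mask`` is a boolean array over the frame; the bounding box of the
    mask must have width and height within the configured gate (3-30 px by
    default) for the candidate to exist.
    """

    frame: FrameRef
    pixel_mask: np.ndarray
    box: BoundingBox
    centroid: tuple[float, float]
    mean_heat: float

    @property
    def area(self) -> int:
        return int(self.pixel_mask.sum())


def rasterize_boxes(
    boxes: Sequence[BoundingBox], shape: tuple[int, int], frame: FrameRef | None = None
) -> HeatMap:
    """Rasterize boxes to a binary heat map: 1 inside any box, else 0.

    Boxes are clipped to the frame; overlaps do not sum above 1.  A pixel is
    inside a box iff its center (i + 0.5) falls in the half-open interval,
    so a box of integer width w covers exactly w pixel columns wherever its
    subpixel position lies.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"empty frame shape {shape}")
    if frame is None:
        frame = FrameRef("", 0, 0.0, (h, w))
    values = np.zeros((h, w), dtype=np.float64)
    for box in boxes:
        clipped = box.clipped((h, w))
        if clipped is None:
            continue
        # first/last pixel whose center lies in [lo, hi)
        y0 = int(math.ceil(clipped.y0 - 0.5))
        y1 = int(math.ceil(clipped.y1 - 0.5))
        x0 = int(math.ceil(clipped.x0 - 0.5))
        x1 = int(math.ceil(clipped.x1 - 0.5))
        values[max(y0, 0):max(y1, 0), max(x0, 0):max(x1, 0)] = 1.0
    return HeatMap(frame, values, "per_detector_binary")


def warp_heatmap(
    heatmap: HeatMap, h: Homography, out_shape: tuple[int, int] | None = None,
    out_frame: FrameRef | None = None,
) -> HeatMap:
    """Resample a heat map into the target coordinate space of ``h``.

    Bilinear interpolation; pixels that map outside the source grid read 0;
    output is clamped to [0, 1].
    """
    if out_shape is None:
        out_shape = heatmap.frame.shape
    if np.array_equal(h.matrix, np.eye(3)) and tuple(out_shape) == heatmap.values.shape:
        warped = heatmap.values.copy()  # exact: no resampling noise
    else:
        # skimage's warp takes the output->input map; h sends source->target.
        inv = ProjectiveTransform(matrix=np.linalg.inv(h.matrix))
        warped = warp(
            heatmap.values, inv, output_shape=out_shape, order=1, mode="constant",
            cval=0.0, preserve_range=True,
        )
        np.clip(warped, 0.0, 1.0, out=warped)
    if out_frame is None:
        out_frame = (
            h.target_frame
            if h.target_frame is not None and h.target_frame.shape == tuple(out_shape)
            else FrameRef(heatmap.frame.survey_id, heatmap.frame.index,
                          heatmap.frame.timestamp, tuple(out_shape))
        )
    return HeatMap(out_frame, warped, heatmap.kind)


def box_center_distance(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance between box centers, in pixels."""
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by)
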