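"""Detector interface: loading externally produced detections, the
ensemble confidence filter, and a classical blob detector.

The trained neural detectors whose outputs this pipeline fuses are external
to the package; their per-frame bounding boxes enter through the CSV/JSON
dialect below.  ``detect_blobs`` is a classical intensity-threshold detector
so the full pipeline can run on thermal frames without any trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import BoundingBox, BoundingBoxDetection, FrameRef

__all__ = [
    "DetectorOutputSet",
    "DETECTION_CSV_COLUMNS",
    "filter_by_confidence",
    "detect_blobs",
    "load_detections",
    "save_detections",
]

DETECTION_CSV_COLUMNS = [
    "survey_id", "frame", "detector_id", "label", "x0", "y0", "x1", "y1", "confidence",
]

#: 8-connectivity structuring element for connected components.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectorOutputSet:
    """All detections of one detector over a frame sequence, keyed by
    frame index."""

    detector_id: str
    by_frame: dict[int, list[BoundingBoxDetection]] = field(default_factory=dict)

    def frames(self) -> list[int]:
        return sorted(self.by_frame)

    def detections(self, frame_index: int) -> list[BoundingBoxDetection]:
        return self.by_frame.get(frame_index, [])

    def all_detections(self) -> list[BoundingBoxDetection]:
        return [d for i in self.frames() for d in self.by_frame[i]]

    def add(self, det: BoundingBoxDetection) -> None:
        self.by_frame.setdefault(det.frame.index, []).append(det)


def filter_by_confidence(
    dets: DetectorOutputSet, threshold: float = 0.05
) -> DetectorOutputSet:
    """Drop detections with confidence strictly below ``threshold``.

    Detections exactly at the threshold are retained ("below" is read
    strictly).  Order within each frame is preserved.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    out = DetectorOutputSet(dets.detector_id)
    for idx, frame_dets in dets.by_frame.items():
        kept = [d for d in frame_dets if d.confidence >= threshold]
        if kept:
            out.by_frame[idx] = kept
    return out


def detect_blobs(
    frame_values: np.ndarray,
    frame: FrameRef,
    intensity_threshold: float,
    min_width: int = 3,
    max_width: int = 30,
    detector_id: str = "blob",
    label: str = "koala",
) -> list[BoundingBoxDetection]:
    """Detect compact warm regions in a 16-bit grayscale frame.

    Connected components of pixels above ``intensity_threshold`` whose
    bounding-box width and height both lie in [min_width, max_width] become
    detections.  Confidence is the component's mean excess intensity over
    the threshold, normalized by the frame's maximum excess, so the warmest
    blob in a frame scores 1.
    """
    values = np.asarray(frame_values, dtype=np.float64)
    mask = values > intensity_threshold
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    max_excess = float(values[mask].max() - intensity_threshold)
    detections: list[BoundingBoxDetection] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = sl
        h, w = ys.stop - ys.start, xs.stop - xs.start
        if not (min_width <= w <= max_width and min_width <= h <= max_width):
            continue
        # mean excess over the component's own pixels
        region = values[sl][labels[sl] == lab]
        conf = float((region.mean() - intensity_threshold) / max_excess) if max_excess > 0 else 1.0
        detections.append(
            BoundingBoxDetection(
                frame=frame,
                box=BoundingBox(float(xs.start), float(ys.start), float(xs.stop), float(ys.stop)),
                label=label,
                confidence=min(max(conf, 0.0), 1.0),
                detector_id=detector_id,
            )
        )
    return detections


def _frame_ref(survey_id: str, index: int, shape: tuple[int, int], fps: float) -> FrameRef:
    return FrameRef(survey_id, index, index / fps if fps > 0 else float(index), shape)


def save_detections(dets: DetectorOutputSet, path, dialect: str = "csv") -> None:
    """Write a detector output set in the package's CSV or JSON dialect.

    Floats are written with ``repr`` precision so a load/save round trip is
    bit-exact.
    """
    rows = [
        {
            "survey_id": d.frame.survey_id,
            "frame": d.frame.index,
            "detector_id": d.detector_id,
            "label": d.label,
            "x0": d.box.x0, "y0": d.box.y0, "x1": d.box.x1, "y1": d.box.y1,
            "confidence": d.confidence,
        }
        for d in dets.all_detections()
    ]
    if dialect == "csv":
        # repr keeps shortest round-trip float precision
        for row in rows:
            for key in ("x0", "y0", "x1", "y1", "confidence"):
                row[key] = repr(float(row[key]))
        df = pd.DataFrame(rows, columns=DETECTION_CSV_COLUMNS)
        df.to_csv(path, index=False)
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_detections(
    path,
    dialect: str = "csv",
    frame_shape: tuple[int, int] = (512, 640),
    fps: float = 9.0,
) -> dict[str, DetectorOutputSet]:
    """Parse a detection file into per-detector output sets.

    Malformed rows raise with the offending row number; confidences outside
    [0, 1] are rejected.
    """
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(DETECTION_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
        records = df.to_dict("records")
    elif dialect == "json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out: dict[str, DetectorOutputSet] = {}
    for i, row in enumerate(records):
        try:
            conf = float(row["confidence"])
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence {conf} outside [0,1]")
            det = BoundingBoxDetection(
                frame=_frame_ref(str(row["survey_id"]), int(row["frame"]), frame_shape, fps),
                box=BoundingBox(float(row["x0"]), float(row["y0"]),
                                float(row["x1"]), float(row["y1"])),
                label=str(row["label"]),
                confidence=conf,
                detector_id=str(row["detector_id"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed detection row {i + 1}: {exc}") from exc
        out.setdefault(det.detector_id, DetectorOutputSet(det.detector_id)).add(det)
    return out
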