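"""Georeferencing, signature classification, and ground-truth matching.

Pixel positions are projected to ground coordinates with a nadir pinhole
model: the offset from the principal point, scaled by the ground sampling
distance (GSD, metres per pixel), rotated by the aircraft heading, and added
to the aircraft's ground position.  Distances between geographic positions
use a WGS84 local tangent-plane (east/north) approximation, which is
accurate to well under a metre over the ~1 km extent of a survey site.

Tracked events are classified by a rule cascade mirroring how a human
reviewer separates signature types in thermal footage: vehicles and people
by size/speed templates, macropods (kangaroo-like) by open terrain plus
rapid motion or width over 20 px, candidate animals by the 3-30 px size
gate plus minimal motion, and everything else as "other".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracking import TrackedEvent

__all__ = [
    "CameraModel",
    "TelemetryRow",
    "TerrainMask",
    "GroundEvent",
    "GroundTruthAnimal",
    "ClassifierConfig",
    "gsd_from_optics",
    "latlon_to_enu",
    "enu_to_latlon",
    "pixel_to_ground",
    "ground_to_pixel",
    "classify_event",
    "match_to_ground_truth",
]

#: WGS84 semi-major axis, metres.
_WGS84_A = 6378137.0


@dataclass(frozen=True)
class CameraModel:
    """Nadir-pointing camera characterized by its ground sampling distance.

    GSD can be given directly, or derived from focal length, pixel pitch
    and altitude via :func:`gsd_from_optics`.
    """

    gsd_m_per_px: float
    frame_shape: tuple[int, int] = (512, 640)

    def __post_init__(self) -> None:
        if self.gsd_m_per_px <= 0:
            raise ValueError(f"GSD must be positive, got {self.gsd_m_per_px}")

    @property
    def principal_point(self) -> tuple[float, float]:
        h, w = self.frame_shape
        return (w / 2.0, h / 2.0)


def gsd_from_optics(focal_length_mm: float, pixel_pitch_um: float, altitude_m: float) -> float:
    """GSD = altitude * pitch / focal length (nadir, flat ground)."""
    if min(focal_length_mm, pixel_pitch_um, altitude_m) <= 0:
        raise ValueError("optics parameters must be positive")
    return altitude_m * (pixel_pitch_um * 1e-6) / (focal_length_mm * 1e-3)


@dataclass(frozen=True)
class TelemetryRow:
    """One flight-log record: aircraft state at a frame."""

    frame: int
    timestamp: float
    lat: float
    lon: float
    alt_agl: float
    heading_deg: float


def latlon_to_enu(lat: float, lon: float, lat0: float, lon0: float) -> tuple[float, float]:
    """Local tangent-plane east/north offsets (m) of (lat, lon) from origin."""
    east = math.radians(lon - lon0) * _WGS84_A * math.cos(math.radians(lat0))
    north = math.radians(lat - lat0) * _WGS84_A
    return east, north


def enu_to_latlon(east: float, north: float, lat0: float, lon0: float) -> tuple[float, float]:
    lat = lat0 + math.degrees(north / _WGS84_A)
    lon = lon0 + math.degrees(east / (_WGS84_A * math.cos(math.radians(lat0))))
    return lat, lon


def pixel_to_ground(
    pixel: tuple[float, float], telemetry: TelemetryRow, camera: CameraModel
) -> tuple[float, float]:
    """Project a frame pixel to (lat, lon) under the nadir pinhole model.

    Image "up" (-y) points along the aircraft heading; +x points to the
    aircraft's right.  Heading is degrees clockwise from true north.
    """
    cx, cy = camera.principal_point
    right = (pixel[0] - cx) * camera.gsd_m_per_px
    forward = -(pixel[1] - cy) * camera.gsd_m_per_px
    theta = math.radians(telemetry.heading_deg)
    east = forward * math.sin(theta) + right * math.cos(theta)
    north = forward * math.cos(theta) - right * math.sin(theta)
    return enu_to_latlon(east, north, telemetry.lat, telemetry.lon)


def ground_to_pixel(
    latlon: tuple[float, float], telemetry: TelemetryRow, camera: CameraModel
) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_ground` under the same telemetry."""
    east, north = latlon_to_enu(latlon[0], latlon[1], telemetry.lat, telemetry.lon)
    theta = math.radians(telemetry.heading_deg)
    forward = east * math.sin(theta) + north * math.cos(theta)
    right = east * math.cos(theta) - north * math.sin(theta)
    cx, cy = camera.principal_point
    return (cx + right / camera.gsd_m_per_px, cy - forward / camera.gsd_m_per_px)


@dataclass
class TerrainMask:
    """Boolean open-terrain raster in world coordinates.

    ``mask[r, c]`` is True on open ground (grass fields), False under
    canopy; the affine places pixel (0, 0)'s center at ``origin_en`` with
    ``cell_m`` metres per cell, east along columns and north along rows.
    """

    mask: np.ndarray
    origin_en: tuple[float, float]
    cell_m: float
    origin_latlon: tuple[float, float]

    def is_open(self, lat: float, lon: float) -> bool:
        east, north = latlon_to_enu(lat, lon, *self.origin_latlon)
        c = int(round((east - self.origin_en[0]) / self.cell_m))
        r = int(round((north - self.origin_en[1]) / self.cell_m))
        if 0 <= r < self.mask.shape[0] and 0 <= c < self.mask.shape[1]:
            return bool(self.mask[r, c])
        return False


@dataclass
class GroundTruthAnimal:
    animal_id: str
    survey_id: str
    lat: float
    lon: float
    collared: bool = True


@dataclass
class GroundEvent:
    """A tracked event placed on the ground with a classification label."""

    event: TrackedEvent
    lat: float
    lon: float
    label: str = "candidate"
    matched_animal_id: str | None = None


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the signature-classification rule cascade.

    Motion thresholds are camera-compensated pixels per frame: "minimal"
    movement (arboreal animal swaying at most) vs "rapid" movement (a
    fleeing macropod).  ``kangaroo_min_width_px`` is the width above which
    an open-terrain signature is macropod-sized.
    """

    min_size_px: float = 3.0
    max_size_px: float = 30.0
    kangaroo_min_width_px: float = 20.0
    rapid_motion_px: float = 4.0
    minimal_motion_px: float = 1.0
    #: (min_width, max_width, min_speed) templates for vehicles and people
    car_template: tuple[float, float, float] = (31.0, 200.0, 0.0)
    human_template: tuple[float, float, float] = (5.0, 15.0, 1.5)


def classify_event(
    ge: GroundEvent,
    terrain: TerrainMask | None,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Label one ground event via the rule cascade.

    Order: car -> human -> kangaroo -> candidate -> other.  Terrain rules
    are skipped (treated as not-open) when no mask is available.
    """
    ev = ge.event
    width = ev.mean_width
    height = ev.mean_height
    disp = ev.displacement_px_per_frame
    on_open = terrain.is_open(ge.lat, ge.lon) if terrain is not None else False

    lo, hi, speed = config.car_template
    if lo <= width <= hi and lo <= height <= hi and disp >= speed:
        return "car"
    lo, hi, speed = config.human_template
    if on_open and lo <= width <= hi and lo <= height <= hi and disp >= speed:
        return "human"
    if on_open and (disp > config.rapid_motion_px or width > config.kangaroo_min_width_px):
        return "kangaroo"
    if (
        config.min_size_px <= width <= config.max_size_px
        and config.min_size_px <= height <= config.max_size_px
        and disp <= config.minimal_motion_px
    ):
        return "candidate"
    return "other"


def match_to_ground_truth(
    events: Sequence[GroundEvent],
    animals: Sequence[GroundTruthAnimal],
    radius_m: float = 15.0,
) -> tuple[list[tuple[GroundEvent, GroundTruthAnimal]], list[GroundEvent], list[GroundTruthAnimal]]:
    """Greedily match candidate events to surveyed animal positions.

    Only events labelled "candidate" are eligible.  Pairs within
    ``radius_m`` are accepted closest-first, one-to-one.  Unmatched
    candidate events are relabelled "other" (signatures whose source could
    not be identified).  Returns (matched pairs, all events, undetected
    animals).
    """
    if animals:
        lat0, lon0 = animals[0].lat, animals[0].lon
    elif events:
        lat0, lon0 = events[0].lat, events[0].lon
    else:
        return [], [], []

    eligible = [e for e in events if e.label == "candidate"]
    pairs = []
    for ei, e in enumerate(eligible):
        ee, en = latlon_to_enu(e.lat, e.lon, lat0, lon0)
        for ai, a in enumerate(animals):
            ae, an = latlon_to_enu(a.lat, a.lon, lat0, lon0)
            d = math.hypot(ee - ae, en - an)
            if d <= radius_m:
                pairs.append((d, ei, ai))
    pairs.sort()

    matched: list[tuple[GroundEvent, GroundTruthAnimal]] = []
    used_e: set[int] = set()
    used_a: set[int] = set()
    for d, ei, ai in pairs:
        if ei in used_e or ai in used_a:
            continue
        used_e.add(ei)
        used_a.add(ai)
        eligible[ei].matched_animal_id = animals[ai].animal_id
        matched.append((eligible[ei], animals[ai]))
    for ei, e in enumerate(eligible):
        if ei not in used_e:
            e.label = "other"
    undetected = [a for ai, a in enumerate(animals) if ai not in used_a]
    return matched, list(events), undetected
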