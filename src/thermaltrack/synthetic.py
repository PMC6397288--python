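"""Synthetic aerial thermal survey generator.

Emulates the data a low-altitude drone survey produces, so every pipeline
stage can be exercised end-to-end with known ground truth and no trained
detector: a textured cool canopy with a disjoint open-terrain strip, warm
compact animal blobs fixed in the canopy, larger fast-moving macropod-like
distractors (plus optional car- and human-like objects) on open ground, a
translating and slowly rotating camera flying a lawnmower pattern whose
exact per-frame homographies are returned, flight telemetry, and noisy mock
detectors with configurable miss and false-positive rates standing in for
the trained neural ensemble.

Everything is deterministic given the config seed: the same config yields
bit-identical frames, truth, telemetry and detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .detectors import DetectorOutputSet, save_detections, load_detections
from .georeference import TelemetryRow, TerrainMask, enu_to_latlon
from .model import BoundingBox, BoundingBoxDetection, FrameRef, Homography

__all__ = [
    "SceneConfig",
    "DetectorNoiseModel",
    "GroundTruthRecord",
    "SurveyBundle",
    "generate_survey",
    "run_mock_detector",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic survey.

    Camera defaults mirror a typical small-drone thermal payload flown at
    survey altitude: 640x512 frames at 9 Hz from 60 m above ground at
    8 m/s in a lawnmower pattern.  The GSD ties pixels to metres and,
    with speed and frame rate, fixes the inter-frame translation
    magnitude (speed / fps / gsd pixels).
    """

    survey_id: str = "synthetic"
    seed: int = 0
    # world
    extent_m: tuple[float, float] = (200.0, 150.0)  # (east, north)
    open_terrain_frac: float = 0.25  # southern strip of open ground
    # camera
    frame_shape: tuple[int, int] = (512, 640)  # (h, w)
    gsd_m_per_px: float = 0.08
    altitude_m: float = 60.0
    speed_m_per_s: float = 8.0
    fps: float = 9.0
    n_frames: int = 120
    transect_overlap: float = 0.2  # fraction of swath shared by neighbours
    heading_jitter_deg: float = 0.15  # per-frame rotation noise, std
    # background thermal texture (16-bit counts)
    canopy_mean: float = 7000.0
    open_mean: float = 6800.0
    texture_std: float = 80.0
    texture_smooth_px: float = 2.0
    sensor_noise_std: float = 0.0  # per-frame uncorrelated read noise
    # objects
    n_animals: int = 10
    animal_width_px: tuple[float, float] = (3.0, 30.0)
    #: minimum ground distance between animals (one animal per tree crown)
    min_separation_m: float = 8.0
    animal_contrast: float = 1500.0
    occlusion_prob: float = 0.0  # per-animal per-frame Bernoulli invisibility
    n_kangaroos: int = 2
    kangaroo_width_px: tuple[float, float] = (21.0, 28.0)
    kangaroo_speed_m_per_s: float = 4.0
    n_cars: int = 0
    car_size_px: tuple[float, float] = (40.0, 60.0)
    n_humans: int = 0
    human_width_px: float = 8.0
    human_speed_m_per_s: float = 1.5
    # geographic anchor of the world origin (south-west corner)
    origin_lat: float = -27.26
    origin_lon: float = 152.98

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("world extent must be positive")
        if self.fps <= 0 or self.gsd_m_per_px <= 0:
            raise ValueError("fps and GSD must be positive")
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must be in [0,1]")
        if self.animal_width_px[0] <= 0:
            raise ValueError("animal widths must be positive")

    @property
    def px_per_frame(self) -> float:
        """Inter-frame camera translation in pixels."""
        return self.speed_m_per_s / self.fps / self.gsd_m_per_px


@dataclass(frozen=True)
class DetectorNoiseModel:
    """Stochastic model of one imperfect detector.

    ``miss_rate`` is the per-visible-object per-frame probability of no
    detection; ``false_positive_rate`` the Poisson mean of spurious boxes
    per frame.  Confidences are Beta-distributed, with true detections
    skewed high and false ones low (some falling under the 0.05 filter).
    """

    detector_id: str = "mock"
    miss_rate: float = 0.0
    false_positive_rate: float = 0.0
    box_jitter_px: float = 0.0
    true_conf_beta: tuple[float, float] = (8.0, 2.0)
    false_conf_beta: tuple[float, float] = (1.2, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0,1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")


@dataclass
class GroundTruthRecord:
    """One scene object: its class, world path, and per-frame pixel boxes."""

    object_id: str
    cls: str  # animal | kangaroo | car | human
    #: east/north metres per frame (static objects repeat one position)
    path_en: np.ndarray
    lat: float
    lon: float
    #: frame index -> fully-in-view pixel box
    boxes: dict[int, BoundingBox] = field(default_factory=dict)
    #: frame index -> visibility (in view and not occluded)
    visible: dict[int, bool] = field(default_factory=dict)

    def visible_frames(self) -> list[int]:
        return sorted(f for f, v in self.visible.items() if v)


@dataclass
class SurveyBundle:
    """Everything one synthetic survey produces."""

    config: SceneConfig
    frames: list[np.ndarray]
    frame_refs: list[FrameRef]
    truth: list[GroundTruthRecord]
    telemetry: list[TelemetryRow]
    #: homographies[i] maps frame i-1 pixels onto frame i; entry 0 is None
    homographies: list[Homography | None]
    terrain: TerrainMask
    detections: dict[str, DetectorOutputSet] = field(default_factory=dict)


def _camera_path(cfg: SceneConfig, rng: np.random.Generator):
    """Lawnmower waypoint path: (east, north) metres and heading per frame.

    Transects run east-west, advancing north by the swath spacing; heading
    is 90 deg (due east) on even transects, 270 on odd, with small
    per-frame jitter."""
    h, w = cfg.frame_shape
    swath_m = w * cfg.gsd_m_per_px
    spacing = swath_m * (1.0 - cfg.transect_overlap)
    margin_e = (h / 2.0) * cfg.gsd_m_per_px  # frame 'forward' extent
    margin_n = swath_m / 2.0
    e_lo, e_hi = margin_e, max(cfg.extent_m[0] - margin_e, margin_e + 1.0)
    step = cfg.speed_m_per_s / cfg.fps

    pos = np.zeros((cfg.n_frames, 2))
    headings = np.zeros(cfg.n_frames)
    e, n = e_lo, margin_n
    direction = 1
    for t in range(cfg.n_frames):
        pos[t] = (e, n)
        headings[t] = (90.0 if direction > 0 else 270.0) + rng.normal(0.0, cfg.heading_jitter_deg)
        e += direction * step
        if e > e_hi or e < e_lo:
            e = min(max(e, e_lo), e_hi)
            n += spacing
            direction *= -1
    return pos, headings


def _pose_matrix(pe: float, pn: float, heading_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Affine sending frame pixels (x, y, 1) to world coords (east, north, 1)
    in world-pixel units.  Image up (-y) points along the heading; +x points
    to the aircraft's right."""
    h, w = shape
    cx, cy = w / 2.0, h / 2.0
    th = math.radians(heading_deg)
    c, s = math.cos(th), math.sin(th)
    # east  = pe + forward*sin + right*cos,  north = pn + forward*cos - right*sin
    # with forward = -(y - cy), right = (x - cx)
    return np.array([
        [c, -s, pe - cx * c + cy * s],
        [-s, -c, pn + cx * s + cy * c],
        [0.0, 0.0, 1.0],
    ])


def _stamp_blob(img: np.ndarray, cx: float, cy: float, w: float, h: float, amp: float) -> None:
    """Additively stamp a warm elliptical blob with a ~1 px soft edge."""
    rx, ry = w / 2.0, h / 2.0
    x0, x1 = int(math.floor(cx - rx - 1)), int(math.ceil(cx + rx + 1))
    y0, y1 = int(math.floor(cy - ry - 1)), int(math.ceil(cy + ry + 1))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, img.shape[1]), min(y1, img.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    r = np.sqrt(((xs + 0.5 - cx) / rx) ** 2 + ((ys + 0.5 - cy) / ry) ** 2)
    profile = np.clip((1.0 - r) * max(rx, ry) + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] += amp * profile


def generate_survey(cfg: SceneConfig) -> SurveyBundle:
    """Render a full synthetic survey from a config.

    Returns frames (uint16), ground truth with per-frame boxes, telemetry,
    the exact per-frame homographies, and the open-terrain mask.
    """
    rng = np.random.default_rng(cfg.seed)
    gsd = cfg.gsd_m_per_px
    nx = int(round(cfg.extent_m[0] / gsd))
    ny = int(round(cfg.extent_m[1] / gsd))
    if nx <= 0 or ny <= 0:
        raise ValueError("world extent too small for the configured GSD")

    # --- background texture: smoothed noise, canopy vs an open southern strip
    open_rows = int(round(ny * cfg.open_terrain_frac))
    world = rng.normal(0.0, cfg.texture_std, size=(ny, nx))
    if cfg.texture_smooth_px > 0:
        world = ndimage.gaussian_filter(world, cfg.texture_smooth_px)
        world *= cfg.texture_std / max(world.std(), 1e-9)
    base = np.full((ny, nx), cfg.canopy_mean)
    if open_rows > 0:
        base[:open_rows, :] = cfg.open_mean  # rows index north from origin
    world = world + base

    terrain_mask = np.zeros((ny, nx), dtype=bool)
    terrain_mask[:open_rows, :] = True
    terrain = TerrainMask(
        mask=terrain_mask,
        origin_en=(0.0, 0.0),
        cell_m=gsd,
        origin_latlon=(cfg.origin_lat, cfg.origin_lon),
    )

    # --- camera path and per-frame poses
    pos_m, headings = _camera_path(cfg, rng)
    poses = [
        _pose_matrix(pos_m[t, 0] / gsd, pos_m[t, 1] / gsd, headings[t], cfg.frame_shape)
        for t in range(cfg.n_frames)
    ]
    homographies: list[Homography | None] = [None]
    frame_refs = [
        FrameRef(cfg.survey_id, t, t / cfg.fps, cfg.frame_shape)
        for t in range(cfg.n_frames)
    ]
    for t in range(1, cfg.n_frames):
        m = np.linalg.inv(poses[t]) @ poses[t - 1]
        homographies.append(
            Homography(m, source_frame=frame_refs[t - 1], target_frame=frame_refs[t])
        )

    # --- place objects
    truth: list[GroundTruthRecord] = []
    canopy_n_lo = open_rows * gsd  # metres north of origin where canopy starts
    sizes: dict[str, np.ndarray] = {}
    placed: list[tuple[float, float, float]] = []  # (e, n, radius_m)
    for i in range(cfg.n_animals):
        w_px = rng.uniform(*cfg.animal_width_px)
        h_px = min(w_px * rng.uniform(0.8, 1.2), cfg.animal_width_px[1])
        radius_m = max(w_px, h_px) / 2.0 * gsd
        # rejection-sample so signatures of distinct animals never merge
        for _ in range(200):
            e = rng.uniform(0.05, 0.95) * cfg.extent_m[0]
            n = canopy_n_lo + rng.uniform(0.05, 0.95) * (cfg.extent_m[1] - canopy_n_lo)
            if all(
                math.hypot(e - pe, n - pn)
                >= max(cfg.min_separation_m, radius_m + pr + 3 * gsd)
                for pe, pn, pr in placed
            ):
                break
        placed.append((e, n, radius_m))
        lat, lon = enu_to_latlon(e, n, cfg.origin_lat, cfg.origin_lon)
        rec = GroundTruthRecord(
            object_id=f"animal_{i:03d}", cls="animal",
            path_en=np.tile([e, n], (cfg.n_frames, 1)), lat=lat, lon=lon,
        )
        truth.append(rec)
        sizes[rec.object_id] = np.array([w_px, h_px])

    def _moving(cls: str, count: int, wrange, speed: float, aspect=1.0):
        for i in range(count):
            e = rng.uniform(0.05, 0.95) * cfg.extent_m[0]
            n = rng.uniform(0.1, 0.9) * max(canopy_n_lo, 1e-6)
            ang = rng.uniform(0, 2 * math.pi)
            vel = speed * np.array([math.cos(ang), math.sin(ang)])
            times = np.arange(cfg.n_frames) / cfg.fps
            path = np.array([e, n]) + times[:, None] * vel
            mid = path[cfg.n_frames // 2]
            lat, lon = enu_to_latlon(mid[0], mid[1], cfg.origin_lat, cfg.origin_lon)
            rec = GroundTruthRecord(
                object_id=f"{cls}_{i:03d}", cls=cls, path_en=path, lat=lat, lon=lon
            )
            w = rng.uniform(*wrange) if isinstance(wrange, tuple) else float(wrange)
            sizes[rec.object_id] = np.array([w, w * aspect])
            truth.append(rec)

    _moving("kangaroo", cfg.n_kangaroos, cfg.kangaroo_width_px, cfg.kangaroo_speed_m_per_s, 0.9)
    _moving("car", cfg.n_cars, cfg.car_size_px, 2.0, 0.5)
    _moving("human", cfg.n_humans, cfg.human_width_px, cfg.human_speed_m_per_s, 1.0)

    occlusion = {
        rec.object_id: rng.random(cfg.n_frames) < cfg.occlusion_prob
        for rec in truth if rec.cls == "animal"
    }

    # --- render frames
    h, w = cfg.frame_shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    pix = np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5, np.ones(h * w)])
    frames: list[np.ndarray] = []
    telemetry: list[TelemetryRow] = []
    for t in range(cfg.n_frames):
        world_xy = poses[t] @ pix
        # world array is indexed [north_row, east_col]; -0.5 centers samples
        coords = np.stack([world_xy[1] - 0.5, world_xy[0] - 0.5])
        frame = ndimage.map_coordinates(
            world, coords, order=1, mode="constant", cval=cfg.canopy_mean
        ).reshape(h, w)

        inv_pose = np.linalg.inv(poses[t])
        for rec in truth:
            e, n = rec.path_en[t]
            px, py, _ = inv_pose @ np.array([e / gsd, n / gsd, 1.0])
            bw, bh = sizes[rec.object_id]
            box = BoundingBox(px - bw / 2, py - bh / 2, px + bw / 2, py + bh / 2)
            in_view = 0 <= box.x0 and box.x1 <= w and 0 <= box.y0 and box.y1 <= h
            occluded = rec.cls == "animal" and bool(occlusion[rec.object_id][t])
            if in_view:
                rec.boxes[t] = box
            rec.visible[t] = in_view and not occluded
            if rec.visible[t]:
                _stamp_blob(frame, px, py, bw, bh, cfg.animal_contrast)
        if cfg.sensor_noise_std > 0:
            frame = frame + rng.normal(0.0, cfg.sensor_noise_std, size=frame.shape)
        frames.append(np.clip(frame, 0, 65535).astype(np.uint16))

        lat, lon = enu_to_latlon(pos_m[t, 0], pos_m[t, 1], cfg.origin_lat, cfg.origin_lon)
        telemetry.append(TelemetryRow(
            frame=t, timestamp=t / cfg.fps, lat=lat, lon=lon,
            alt_agl=cfg.altitude_m, heading_deg=float(headings[t]),
        ))

    return SurveyBundle(
        config=cfg, frames=frames, frame_refs=frame_refs, truth=truth,
        telemetry=telemetry, homographies=homographies, terrain=terrain,
    )


def run_mock_detector(bundle: SurveyBundle, noise: DetectorNoiseModel) -> DetectorOutputSet:
    """Simulate an imperfect single-class detector over a survey.

    Every visible truth object (of any warm class — the detector cannot
    tell a koala from a kangaroo) yields a jittered box with probability
    1 - miss_rate; spurious boxes are added per frame from a Poisson
    process.  Deterministic given the noise seed.
    """
    rng = np.random.default_rng(noise.seed)
    out = DetectorOutputSet(noise.detector_id)
    h, w = bundle.config.frame_shape
    a_t, b_t = noise.true_conf_beta
    a_f, b_f = noise.false_conf_beta
    for t, frame_ref in enumerate(bundle.frame_refs):
        for rec in bundle.truth:
            if not rec.visible.get(t, False):
                continue
            if rng.random() < noise.miss_rate:
                continue
            box = rec.boxes[t]
            j = rng.normal(0.0, noise.box_jitter_px, size=4) if noise.box_jitter_px > 0 else np.zeros(4)
            x0, y0 = box.x0 + j[0], box.y0 + j[1]
            x1, y1 = max(box.x1 + j[2], x0 + 1.0), max(box.y1 + j[3], y0 + 1.0)
            out.add(BoundingBoxDetection(
                frame=frame_ref,
                box=BoundingBox(x0, y0, x1, y1),
                label="koala",
                confidence=float(rng.beta(a_t, b_t)),
                detector_id=noise.detector_id,
            ))
        for _ in range(rng.poisson(noise.false_positive_rate)):
            fw = rng.uniform(3.0, 30.0)
            fh = rng.uniform(3.0, 30.0)
            cx = rng.uniform(fw / 2, w - fw / 2)
            cy = rng.uniform(fh / 2, h - fh / 2)
            out.add(BoundingBoxDetection(
                frame=frame_ref,
                box=BoundingBox(cx - fw / 2, cy - fh / 2, cx + fw / 2, cy + fh / 2),
                label="koala",
                confidence=float(rng.beta(a_f, b_f)),
                detector_id=noise.detector_id,
            ))
    return out


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(bundle: SurveyBundle, directory) -> dict:
    """Write a survey bundle to a directory of plain files.

    Frames become zero-padded single-page 16-bit TIFFs; truth, telemetry
    and homographies become CSVs; the terrain mask a bilevel TIFF; and a
    YAML manifest lists every file with a config echo for provenance.
    Read-back with :func:`read_fixture` reproduces the bundle exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    frame_files = {}
    for t, frame in enumerate(bundle.frames):
        name = f"frame_{t:05d}.tif"
        tifffile.imwrite(directory / name, frame)
        frame_files[t] = name

    pd.DataFrame(
        [
            {"frame": r.frame, "timestamp": r.timestamp, "lat": r.lat, "lon": r.lon,
             "alt_agl": r.alt_agl, "heading_deg": r.heading_deg}
            for r in bundle.telemetry
        ],
        columns=["frame", "timestamp", "lat", "lon", "alt_agl", "heading_deg"],
    ).to_csv(directory / "telemetry.csv", index=False)

    pd.DataFrame(
        [
            {"object_id": r.object_id, "class": r.cls, "lat": r.lat, "lon": r.lon}
            for r in bundle.truth
        ],
        columns=["object_id", "class", "lat", "lon"],
    ).to_csv(directory / "objects.csv", index=False)

    box_rows = []
    for r in bundle.truth:
        for t in sorted(r.visible):
            box = r.boxes.get(t)
            box_rows.append({
                "frame": t, "object_id": r.object_id,
                "x0": box.x0 if box else "", "y0": box.y0 if box else "",
                "x1": box.x1 if box else "", "y1": box.y1 if box else "",
                "visible": int(r.visible[t]),
            })
    pd.DataFrame(
        box_rows, columns=["frame", "object_id", "x0", "y0", "x1", "y1", "visible"]
    ).to_csv(directory / "truth_boxes.csv", index=False)

    path_rows = []
    for r in bundle.truth:
        if r.cls == "animal":
            continue  # static: objects.csv position suffices
        for t in range(len(r.path_en)):
            path_rows.append({"object_id": r.object_id, "frame": t,
                              "east_m": r.path_en[t, 0], "north_m": r.path_en[t, 1]})
    pd.DataFrame(
        path_rows, columns=["object_id", "frame", "east_m", "north_m"]
    ).to_csv(directory / "object_paths.csv", index=False)

    hom_rows = []
    for t, hmg in enumerate(bundle.homographies):
        if hmg is None:
            continue
        m = hmg.matrix.ravel()
        hom_rows.append({"frame": t, **{f"h{i}{j}": m[i * 3 + j] for i in range(3) for j in range(3)}})
    hom_cols = ["frame"] + [f"h{i}{j}" for i in range(3) for j in range(3)]
    pd.DataFrame(hom_rows, columns=hom_cols).to_csv(directory / "homographies.csv", index=False)

    tifffile.imwrite(directory / "terrain_mask.tif", bundle.terrain.mask.astype(np.uint8))

    det_files = {}
    for det_id, dets in bundle.detections.items():
        name = f"detections_{det_id}.csv"
        save_detections(dets, directory / name)
        det_files[det_id] = name

    manifest = {
        "survey_id": cfg.survey_id,
        "n_frames": cfg.n_frames,
        "frames": frame_files,
        "telemetry": "telemetry.csv",
        "objects": "objects.csv",
        "truth_boxes": "truth_boxes.csv",
        "object_paths": "object_paths.csv",
        "homographies": "homographies.csv",
        "terrain_mask": "terrain_mask.tif",
        "detections": det_files,
        "config": asdict(cfg),
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_fixture(directory) -> SurveyBundle:
    """Reconstruct a survey bundle written by :func:`write_fixture`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    raw_cfg = dict(manifest["config"])
    for key in ("extent_m", "frame_shape", "animal_width_px", "kangaroo_width_px",
                "car_size_px"):
        raw_cfg[key] = tuple(raw_cfg[key])
    cfg = SceneConfig(**raw_cfg)

    frames = [
        np.asarray(tifffile.imread(directory / manifest["frames"][t]))
        for t in range(manifest["n_frames"])
    ]
    frame_refs = [
        FrameRef(cfg.survey_id, t, t / cfg.fps, cfg.frame_shape)
        for t in range(cfg.n_frames)
    ]

    tel = pd.read_csv(directory / manifest["telemetry"], float_precision="round_trip")
    telemetry = [
        TelemetryRow(int(r.frame), float(r.timestamp), float(r.lat), float(r.lon),
                     float(r.alt_agl), float(r.heading_deg))
        for r in tel.itertuples()
    ]

    objs = pd.read_csv(directory / manifest["objects"], float_precision="round_trip")
    boxes = pd.read_csv(directory / manifest["truth_boxes"], float_precision="round_trip")
    paths = pd.read_csv(directory / manifest["object_paths"], float_precision="round_trip")
    truth: list[GroundTruthRecord] = []
    for _, row in objs.iterrows():
        truth.append(GroundTruthRecord(
            object_id=str(row["object_id"]), cls=str(row["class"]),
            path_en=np.zeros((cfg.n_frames, 2)), lat=float(row["lat"]), lon=float(row["lon"]),
        ))
    by_id = {r.object_id: r for r in truth}
    from .georeference import latlon_to_enu

    for rec in truth:
        if rec.cls == "animal":
            e, n = latlon_to_enu(rec.lat, rec.lon, cfg.origin_lat, cfg.origin_lon)
            rec.path_en = np.tile([e, n], (cfg.n_frames, 1))
    for r in paths.itertuples():
        by_id[str(r.object_id)].path_en[int(r.frame)] = (float(r.east_m), float(r.north_m))
    for r in boxes.itertuples():
        rec = by_id[str(r.object_id)]
        t = int(r.frame)
        if not (isinstance(r.x0, float) and math.isnan(r.x0)):
            rec.boxes[t] = BoundingBox(float(r.x0), float(r.y0), float(r.x1), float(r.y1))
        rec.visible[t] = bool(int(r.visible))

    homs = pd.read_csv(directory / manifest["homographies"], float_precision="round_trip")
    homographies: list[Homography | None] = [None] * cfg.n_frames
    for r in homs.itertuples():
        t = int(r.frame)
        m = np.array([[r.h00, r.h01, r.h02], [r.h10, r.h11, r.h12], [r.h20, r.h21, r.h22]])
        homographies[t] = Homography(m, source_frame=frame_refs[t - 1], target_frame=frame_refs[t])

    mask = np.asarray(tifffile.imread(directory / manifest["terrain_mask"])).astype(bool)
    terrain = TerrainMask(mask=mask, origin_en=(0.0, 0.0), cell_m=cfg.gsd_m_per_px,
                          origin_latlon=(cfg.origin_lat, cfg.origin_lon))

    detections = {}
    for det_id, name in manifest["detections"].items():
        sets = load_detections(directory / name, frame_shape=cfg.frame_shape, fps=cfg.fps)
        detections[det_id] = sets[det_id]

    return SurveyBundle(
        config=cfg, frames=frames, frame_refs=frame_refs, truth=truth,
        telemetry=telemetry, homographies=homographies, terrain=terrain,
        detections=detections,
    )
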