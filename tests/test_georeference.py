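"""Nadir projection, local geodesy, classification, and truth matching."""

import math

import numpy as np
import pytest

from thermaltrack.georeference import (
    CameraModel,
    ClassifierConfig,
    GroundEvent,
    GroundTruthAnimal,
    TelemetryRow,
    TerrainMask,
    classify_event,
    enu_to_latlon,
    gsd_from_optics,
    latlon_to_enu,
    match_to_ground_truth,
    pixel_to_ground,
    ground_to_pixel,
)
from thermaltrack.tracking import TrackedEvent

CAMERA = CameraModel(gsd_m_per_px=0.08, frame_shape=(512, 640))
TEL = TelemetryRow(frame=0, timestamp=0.0, lat=-27.26, lon=152.98,
                   alt_agl=60.0, heading_deg=0.0)


def _event(width=8.0, height=8.0, disp=0.3):
    return TrackedEvent(
        track_id=0, first_frame=0, last_frame=9, length=10,
        centroid=(320.0, 256.0), centroid_frame=4,
        mean_width=width, mean_height=height, displacement_px_per_frame=disp,
    )


class TestProjection:
    def test_principal_point_maps_to_aircraft_position(self):
        lat, lon = pixel_to_ground(CAMERA.principal_point, TEL, CAMERA)
        assert lat == pytest.approx(TEL.lat, abs=1e-12)
        assert lon == pytest.approx(TEL.lon, abs=1e-12)

    def test_offset_scales_by_gsd(self):
        # 100 px right of center at heading 0 (north-up) is 8 m east
        px = (CAMERA.principal_point[0] + 100, CAMERA.principal_point[1])
        lat, lon = pixel_to_ground(px, TEL, CAMERA)
        east, north = latlon_to_enu(lat, lon, TEL.lat, TEL.lon)
        assert east == pytest.approx(8.0, abs=1e-6)
        assert north == pytest.approx(0.0, abs=1e-6)

    def test_heading_rotation_matches_rotation_matrix(self):
        cx, cy = CAMERA.principal_point
        offset = np.array([37.0, -21.0])  # (right, forward) px
        for heading in (0.0, 45.0, 90.0, 180.0, 263.0):
            tel = TelemetryRow(0, 0.0, TEL.lat, TEL.lon, 60.0, heading)
            lat, lon = pixel_to_ground((cx + offset[0], cy - offset[1]), tel, CAMERA)
            east, north = latlon_to_enu(lat, lon, TEL.lat, TEL.lon)
            th = math.radians(heading)
            rot = np.array([[math.cos(th), math.sin(th)],
                            [-math.sin(th), math.cos(th)]])
            expected = rot.T @ (offset * CAMERA.gsd_m_per_px)  # (east, north)
            # rotation by heading: forward->north at 0, forward->east at 90
            exp_east = offset[1] * CAMERA.gsd_m_per_px * math.sin(th) + offset[0] * CAMERA.gsd_m_per_px * math.cos(th)
            exp_north = offset[1] * CAMERA.gsd_m_per_px * math.cos(th) - offset[0] * CAMERA.gsd_m_per_px * math.sin(th)
            assert east == pytest.approx(exp_east, abs=1e-6)
            assert north == pytest.approx(exp_north, abs=1e-6)

    def test_heading_90_swaps_offset_axes(self):
        cx, cy = CAMERA.principal_point
        tel = TelemetryRow(0, 0.0, TEL.lat, TEL.lon, 60.0, 90.0)
        # pixel above center (forward) now points east
        lat, lon = pixel_to_ground((cx, cy - 50), tel, CAMERA)
        east, north = latlon_to_enu(lat, lon, TEL.lat, TEL.lon)
        assert east == pytest.approx(50 * 0.08, abs=1e-6)
        assert north == pytest.approx(0.0, abs=1e-6)

    def test_pixel_ground_round_trip(self):
        for heading in (0.0, 77.0, 191.5):
            tel = TelemetryRow(0, 0.0, TEL.lat, TEL.lon, 60.0, heading)
            for px in [(12.3, 456.7), (600.0, 8.0), (320.0, 256.0)]:
                back = ground_to_pixel(pixel_to_ground(px, tel, CAMERA), tel, CAMERA)
                assert back[0] == pytest.approx(px[0], abs=1e-6)
                assert back[1] == pytest.approx(px[1], abs=1e-6)

    def test_enu_round_trip(self):
        lat, lon = enu_to_latlon(321.5, -123.25, -27.26, 152.98)
        east, north = latlon_to_enu(lat, lon, -27.26, 152.98)
        assert east == pytest.approx(321.5, abs=1e-9)
        assert north == pytest.approx(-123.25, abs=1e-9)

    def test_gsd_from_optics(self):
        # 13 mm lens, 17 um pitch, 60 m altitude -> about 7.8 cm/px
        assert gsd_from_optics(13.0, 17.0, 60.0) == pytest.approx(0.0785, abs=1e-4)


def _terrain(open_everywhere):
    mask = np.full((50, 50), open_everywhere, dtype=bool)
    return TerrainMask(mask, origin_en=(-100.0, -100.0), cell_m=4.0,
                       origin_latlon=(TEL.lat, TEL.lon))


class TestClassification:
    def test_wide_fast_open_terrain_signature_is_kangaroo(self):
        ge = GroundEvent(_event(width=25, height=22, disp=6.0), TEL.lat, TEL.lon)
        assert classify_event(ge, _terrain(True)) == "kangaroo"

    def test_wide_slow_open_terrain_signature_is_still_kangaroo(self):
        # width over 20 px suffices on open ground, regardless of motion
        ge = GroundEvent(_event(width=25, height=22, disp=0.1), TEL.lat, TEL.lon)
        assert classify_event(ge, _terrain(True)) == "kangaroo"

    def test_small_still_canopy_signature_is_candidate(self):
        ge = GroundEvent(_event(width=8, height=8, disp=0.3), TEL.lat, TEL.lon)
        assert classify_event(ge, _terrain(False)) == "candidate"

    def test_small_fast_canopy_signature_falls_through_to_other(self):
        ge = GroundEvent(_event(width=8, height=8, disp=6.0), TEL.lat, TEL.lon)
        assert classify_event(ge, _terrain(False)) == "other"

    def test_car_sized_signature_is_car_anywhere(self):
        ge = GroundEvent(_event(width=45, height=40, disp=2.0), TEL.lat, TEL.lon)
        assert classify_event(ge, _terrain(False)) == "car"

    def test_missing_terrain_mask_skips_terrain_rules(self):
        ge = GroundEvent(_event(width=25, height=22, disp=6.0), TEL.lat, TEL.lon)
        # without a mask the kangaroo rule cannot fire; cascade ends at other
        assert classify_event(ge, None) == "other"


def _ge(lat, lon, label="candidate"):
    ge = GroundEvent(_event(), lat, lon)
    ge.label = label
    return ge


def _animal(aid, east, north):
    lat, lon = enu_to_latlon(east, north, TEL.lat, TEL.lon)
    return GroundTruthAnimal(aid, "s", lat, lon)


class TestMatching:
    def test_zero_events_leave_all_animals_undetected(self):
        animals = [_animal("a", 0, 0), _animal("b", 30, 0)]
        matched, events, undet = match_to_ground_truth([], animals, radius_m=15)
        assert matched == [] and len(undet) == 2

    def test_event_within_radius_matches(self):
        lat, lon = enu_to_latlon(5.0, 0.0, TEL.lat, TEL.lon)
        matched, _, undet = match_to_ground_truth(
            [_ge(lat, lon)], [_animal("a", 0, 0)], radius_m=15)
        assert len(matched) == 1
        assert matched[0][0].matched_animal_id == "a"
        assert undet == []

    def test_second_event_near_same_animal_relabelled_other(self):
        e1 = _ge(*enu_to_latlon(2.0, 0.0, TEL.lat, TEL.lon))
        e2 = _ge(*enu_to_latlon(4.0, 0.0, TEL.lat, TEL.lon))
        matched, events, _ = match_to_ground_truth([e1, e2], [_animal("a", 0, 0)], radius_m=15)
        assert len(matched) == 1
        assert matched[0][0] is e1  # closer event wins
        assert e2.label == "other"

    def test_non_candidate_events_are_ineligible(self):
        e = _ge(TEL.lat, TEL.lon, label="kangaroo")
        matched, _, undet = match_to_ground_truth([e], [_animal("a", 0, 0)], radius_m=15)
        assert matched == [] and len(undet) == 1
        assert e.label == "kangaroo"  # not relabelled: was never a candidate

    def test_matched_count_monotone_in_radius(self):
        rng = np.random.default_rng(4)
        events = [_ge(*enu_to_latlon(e, n, TEL.lat, TEL.lon))
                  for e, n in rng.uniform(-40, 40, size=(8, 2))]
        animals = [_animal(f"a{i}", e, n)
                   for i, (e, n) in enumerate(rng.uniform(-40, 40, size=(6, 2)))]
        prev = -1
        for radius in (2, 5, 10, 20, 40, 80):
            for ev in events:
                ev.label, ev.matched_animal_id = "candidate", None
            matched, _, _ = match_to_ground_truth(events, animals, radius_m=radius)
            assert len(matched) >= prev
            prev = len(matched)
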