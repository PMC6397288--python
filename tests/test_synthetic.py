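"""Synthetic survey generator: determinism, kinematics, phenomenology, I/O."""

import hashlib

import numpy as np
import pytest

from thermaltrack.model import HeatMap, warp_heatmap
from thermaltrack.synthetic import (
    DetectorNoiseModel,
    SceneConfig,
    generate_survey,
    read_fixture,
    run_mock_detector,
    write_fixture,
)

SMALL = dict(extent_m=(80.0, 60.0), frame_shape=(144, 192), gsd_m_per_px=0.3,
             n_frames=20, n_animals=4, n_kangaroos=1, seed=5)


def _checksum(bundle):
    h = hashlib.sha256()
    for f in bundle.frames:
        h.update(f.tobytes())
    return h.hexdigest()


class TestGeneration:
    def test_empty_scene_has_background_only(self):
        cfg = SceneConfig(**{**SMALL, "n_animals": 0, "n_kangaroos": 0})
        b = generate_survey(cfg)
        assert b.truth == []
        # all frames stay near the canopy/open temperature band: no warm blobs
        assert max(f.max() for f in b.frames) < cfg.canopy_mean + 5 * cfg.texture_std

    def test_same_seed_bit_identical(self):
        a = generate_survey(SceneConfig(**SMALL))
        b = generate_survey(SceneConfig(**SMALL))
        assert _checksum(a) == _checksum(b)
        for ra, rb in zip(a.telemetry, b.telemetry):
            assert ra == rb

    def test_different_seed_differs(self):
        a = generate_survey(SceneConfig(**SMALL))
        b = generate_survey(SceneConfig(**{**SMALL, "seed": 6}))
        assert _checksum(a) != _checksum(b)

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(**{**SMALL, "extent_m": (-10.0, 50.0)})

    def test_translation_magnitude_matches_kinematics(self):
        """Per-frame displacement equals (speed/fps)/gsd px, and matches the
        returned homographies."""
        cfg = SceneConfig(**{**SMALL, "heading_jitter_deg": 0.0})
        b = generate_survey(cfg)
        expected = cfg.px_per_frame
        center = np.array([[cfg.frame_shape[1] / 2, cfg.frame_shape[0] / 2]])
        for t in range(1, 10):
            d = b.homographies[t].apply(center) - center
            assert np.linalg.norm(d) == pytest.approx(expected, abs=1e-9)

    def test_homography_aligns_background_subpixel(self):
        """Warping frame t-1 by the true homography matches frame t almost
        exactly on noise-free texture (interior pixels)."""
        cfg = SceneConfig(**{**SMALL, "n_animals": 0, "n_kangaroos": 0,
                             "heading_jitter_deg": 0.0})
        b = generate_survey(cfg)
        t = 10
        hm = HeatMap(b.frame_refs[t - 1], b.frames[t - 1] / 65535.0, "combined")
        warped = warp_heatmap(hm, b.homographies[t], out_shape=cfg.frame_shape)
        ones = HeatMap(b.frame_refs[t - 1], np.ones(cfg.frame_shape), "combined")
        valid = warp_heatmap(ones, b.homographies[t], out_shape=cfg.frame_shape).values > 0.999
        residual = np.abs(warped.values * 65535.0 - b.frames[t].astype(float))[valid]
        misaligned = np.abs(b.frames[t - 1].astype(float) - b.frames[t].astype(float))[valid]
        assert residual.mean() < 1.0          # counts; texture std is 80
        assert residual.mean() < 0.05 * misaligned.mean()

    def test_visible_boxes_lie_within_frame(self):
        b = generate_survey(SceneConfig(**SMALL))
        h, w = b.config.frame_shape
        for rec in b.truth:
            for t, vis in rec.visible.items():
                if vis:
                    box = rec.boxes[t]
                    assert 0 <= box.x0 < box.x1 <= w
                    assert 0 <= box.y0 < box.y1 <= h

    def test_kangaroo_phenomenology(self):
        """Kangaroo-like distractors are wide (>20 px) and move faster across
        the scene than (static) animals."""
        cfg = SceneConfig(**{**SMALL, "n_kangaroos": 2, "n_frames": 30})
        b = generate_survey(cfg)
        kangaroos = [r for r in b.truth if r.cls == "kangaroo"]
        assert len(kangaroos) == 2
        for k in kangaroos:
            for t, box in k.boxes.items():
                assert box.width > 20
            step = np.linalg.norm(np.diff(k.path_en, axis=0), axis=1).max()
            animal_step = max(
                np.linalg.norm(np.diff(r.path_en, axis=0), axis=1).max()
                for r in b.truth if r.cls == "animal"
            )
            assert step > animal_step  # animals are static

    def test_occlusion_hides_animals_some_frames(self):
        cfg = SceneConfig(**{**SMALL, "occlusion_prob": 0.5, "n_frames": 30})
        b = generate_survey(cfg)
        animals = [r for r in b.truth if r.cls == "animal"]
        in_view = sum(1 for r in animals for t in r.boxes)
        visible = sum(1 for r in animals for t, v in r.visible.items() if v and t in r.boxes)
        assert 0 < visible < in_view


class TestMockDetector:
    def test_certain_miss_empties_output(self, noise_free_bundle):
        noise = DetectorNoiseModel(miss_rate=1.0, false_positive_rate=0.0, seed=1)
        assert run_mock_detector(noise_free_bundle, noise).all_detections() == []

    def test_perfect_detector_reproduces_truth_boxes(self, noise_free_bundle):
        noise = DetectorNoiseModel(miss_rate=0.0, false_positive_rate=0.0,
                                   box_jitter_px=0.0, seed=1)
        dets = run_mock_detector(noise_free_bundle, noise)
        truth_boxes = {
            (t, rec.boxes[t].x0, rec.boxes[t].y0)
            for rec in noise_free_bundle.truth
            for t, v in rec.visible.items() if v
        }
        got = {(d.frame.index, d.box.x0, d.box.y0) for d in dets.all_detections()}
        assert got == truth_boxes

    def test_miss_rate_count_within_binomial_bounds(self):
        cfg = SceneConfig(**{**SMALL, "extent_m": (100.0, 50.0), "n_frames": 70,
                             "n_animals": 10, "n_kangaroos": 0})
        b = generate_survey(cfg)
        n_visible = sum(1 for r in b.truth for t, v in r.visible.items() if v)
        assert n_visible > 200  # enough trials for a meaningful bound
        noise = DetectorNoiseModel(miss_rate=0.3, false_positive_rate=0.0, seed=9)
        n_det = len(run_mock_detector(b, noise).all_detections())
        mean = 0.7 * n_visible
        sd = (n_visible * 0.3 * 0.7) ** 0.5
        assert abs(n_det - mean) < 3 * sd

    def test_deterministic_given_seed(self, noise_free_bundle):
        noise = DetectorNoiseModel(miss_rate=0.4, false_positive_rate=1.0,
                                   box_jitter_px=1.0, seed=12)
        a = run_mock_detector(noise_free_bundle, noise).all_detections()
        b = run_mock_detector(noise_free_bundle, noise).all_detections()
        assert [(d.frame.index, d.box, d.confidence) for d in a] == [
            (d.frame.index, d.box, d.confidence) for d in b
        ]


class TestFixtureIO:
    def test_round_trip_reproduces_bundle(self, tmp_path):
        cfg = SceneConfig(**{**SMALL, "n_frames": 8})
        bundle = generate_survey(cfg)
        bundle.detections["m1"] = run_mock_detector(
            bundle, DetectorNoiseModel(detector_id="m1", miss_rate=0.2,
                                       false_positive_rate=0.3, box_jitter_px=0.5, seed=2))
        manifest = write_fixture(bundle, tmp_path / "fx")
        assert manifest["n_frames"] == 8
        back = read_fixture(tmp_path / "fx")
        assert back.config == cfg
        for fa, fb in zip(bundle.frames, back.frames):
            np.testing.assert_array_equal(fa, fb)
        assert back.telemetry == bundle.telemetry
        assert len(back.truth) == len(bundle.truth)
        for ra, rb in zip(bundle.truth, back.truth):
            assert (ra.object_id, ra.cls, ra.lat, ra.lon) == (rb.object_id, rb.cls, rb.lat, rb.lon)
            assert ra.visible == rb.visible
            assert ra.boxes == rb.boxes
            np.testing.assert_allclose(ra.path_en, rb.path_en, atol=1e-9)
        for ha, hb in zip(bundle.homographies, back.homographies):
            if ha is None:
                assert hb is None
            else:
                np.testing.assert_array_equal(ha.matrix, hb.matrix)
        a = bundle.detections["m1"].all_detections()
        b = back.detections["m1"].all_detections()
        assert [(d.frame.index, d.box, d.confidence) for d in a] == [
            (d.frame.index, d.box, d.confidence) for d in b
        ]
        np.testing.assert_array_equal(bundle.terrain.mask, back.terrain.mask)

    def test_empty_scene_manifest_has_zero_truth_rows(self, tmp_path):
        cfg = SceneConfig(**{**SMALL, "n_animals": 0, "n_kangaroos": 0, "n_frames": 3})
        bundle = generate_survey(cfg)
        write_fixture(bundle, tmp_path / "fx")
        back = read_fixture(tmp_path / "fx")
        assert back.truth == []

    def test_manifest_frame_count(self, tmp_path):
        cfg = SceneConfig(**{**SMALL, "n_frames": 10})
        manifest = write_fixture(generate_survey(cfg), tmp_path / "fx")
        assert len(manifest["frames"]) == 10
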