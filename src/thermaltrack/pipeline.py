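"""End-to-end pipeline: detections -> fused events -> ground labels -> counts.

Order of stages per frame: confidence-filter each detector, rasterize boxes
to binary heat maps, average across the ensemble, register against the
previous frame (or take known homographies), update the moving-average
accumulator, extract size-gated candidates, and step the greedy tracker.
After the last frame, tracks become events, events are georeferenced and
classified, and candidate events are matched one-to-one to ground-surveyed
animal positions to produce the survey's (K_obs, K_detected, K_false).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accumulation import DEFAULT_N, combine_heatmaps, update_accumulator
from .candidates import extract_candidates
from .detectors import DetectorOutputSet, filter_by_confidence
from .georeference import (
    CameraModel,
    ClassifierConfig,
    GroundEvent,
    GroundTruthAnimal,
    TelemetryRow,
    TerrainMask,
    classify_event,
    match_to_ground_truth,
    pixel_to_ground,
)
from .model import FrameRef, Homography, rasterize_boxes
from .registration import RegistrationResult, estimate_homography
from .tracking import GreedyTracker, TrackedEvent
from .evaluation import FalsePositiveBreakdown, SurveyCounts

__all__ = ["PipelineConfig", "FusionResult", "run_pipeline", "evaluate_events"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs in one place (defaults as used throughout)."""

    confidence_threshold: float = 0.05
    heatmap_threshold: float = 0.05
    accumulator_n: int = DEFAULT_N
    min_signature_px: int = 3
    max_signature_px: int = 30
    gate_px: float = 15.0
    max_missed: int = 5
    min_track_length: int = 2
    match_radius_m: float = 15.0
    gsd_m_per_px: float = 0.08
    registration_keypoints: int = 500
    registration_seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)


@dataclass
class FusionResult:
    """Output of one pipeline run over a survey."""

    events: list[TrackedEvent]
    ground_events: list[GroundEvent]
    registrations: list[RegistrationResult | None]
    reset_count: int
    matched: list = field(default_factory=list)
    undetected: list = field(default_factory=list)
    counts: SurveyCounts | None = None
    fp_breakdown: FalsePositiveBreakdown | None = None


def run_pipeline(
    frame_refs: list[FrameRef],
    detector_sets: list[DetectorOutputSet],
    telemetry: list[TelemetryRow] | None = None,
    config: PipelineConfig = PipelineConfig(),
    frames: list[np.ndarray] | None = None,
    known_homographies: list[Homography | None] | None = None,
    terrain: TerrainMask | None = None,
    animals: list[GroundTruthAnimal] | None = None,
) -> FusionResult:
    """Run detection fusion over one survey.

    Registration uses ``known_homographies`` when given, otherwise
    estimates homographies from ``frames``; with neither, every transition
    counts as a registration failure (accumulator resets each frame).
    When ``telemetry`` and ``animals`` are supplied, events are
    georeferenced, classified and matched, and per-survey counts computed.
    """
    filtered = [filter_by_confidence(ds, config.confidence_threshold) for ds in detector_sets]
    if not filtered:
        raise ValueError("need at least one detector output set")

    tracker = GreedyTracker(
        gate_px=config.gate_px,
        max_missed=config.max_missed,
        min_length=config.min_track_length,
    )
    registrations: list[RegistrationResult | None] = [None]
    state = None
    reset_count = 0
    for i, frame in enumerate(frame_refs):
        per_det = [
            rasterize_boxes([d.box for d in ds.detections(frame.index)], frame.shape, frame)
            for ds in filtered
        ]
        I_t = combine_heatmaps(per_det)
        if i == 0:
            reg = None
        elif known_homographies is not None:
            hmg = known_homographies[i]
            reg = RegistrationResult(hmg, num_matches=4 if hmg is not None else 0)
            registrations.append(reg)
        elif frames is not None:
            reg = estimate_homography(
                frames[i], frames[i - 1],
                n_keypoints=config.registration_keypoints,
                target=frame, source=frame_refs[i - 1],
                seed=config.registration_seed,
            )
            registrations.append(reg)
        else:
            reg = RegistrationResult(None, 0)
            registrations.append(reg)

        state = update_accumulator(state, I_t, reg if i > 0 else None, N=config.accumulator_n)
        reset_count = state.reset_count
        cands = extract_candidates(
            state.A,
            threshold=config.heatmap_threshold,
            min_size=config.min_signature_px,
            max_size=config.max_signature_px,
        )
        hmg = registrations[i].homography if (i > 0 and registrations[i] is not None) else None
        tracker.step(frame.index, cands, hmg)

    events = tracker.finish()

    ground_events: list[GroundEvent] = []
    matched: list = []
    undetected: list = []
    counts = None
    fp_breakdown = None
    if telemetry is not None:
        camera = CameraModel(config.gsd_m_per_px, frame_refs[0].shape if frame_refs else (512, 640))
        tel_by_frame = {row.frame: row for row in telemetry}
        for ev in events:
            row = tel_by_frame.get(ev.centroid_frame)
            if row is None:
                raise KeyError(f"no telemetry for frame {ev.centroid_frame}")
            lat, lon = pixel_to_ground(ev.centroid, row, camera)
            ge = GroundEvent(event=ev, lat=lat, lon=lon)
            ge.label = classify_event(ge, terrain, config.classifier)
            ground_events.append(ge)
        if animals is not None:
            matched, ground_events, undetected = match_to_ground_truth(
                ground_events, animals, radius_m=config.match_radius_m
            )
            counts, fp_breakdown = evaluate_events(
                ground_events, animals,
                survey_id=frame_refs[0].survey_id if frame_refs else "",
            )
    return FusionResult(
        events=events,
        ground_events=ground_events,
        registrations=registrations,
        reset_count=reset_count,
        matched=matched,
        undetected=undetected,
        counts=counts,
        fp_breakdown=fp_breakdown,
    )


def evaluate_events(
    ground_events: list[GroundEvent],
    animals: list[GroundTruthAnimal],
    survey_id: str = "",
) -> tuple[SurveyCounts, FalsePositiveBreakdown]:
    """Reduce labelled, matched events to survey counts.

    K_detected counts animals matched by a candidate event; K_false counts
    every event that is not a matched candidate — misclassified signatures
    (kangaroo/car/human) and unidentifiable "other" ones alike.
    """
    k_obs = len(animals)
    k_detected = sum(
        1 for e in ground_events if e.label == "candidate" and e.matched_animal_id
    )
    by_class = {"kangaroo": 0, "car": 0, "human": 0, "other": 0}
    for e in ground_events:
        if e.label == "candidate" and e.matched_animal_id:
            continue
        by_class[e.label if e.label in by_class else "other"] += 1
    counts = SurveyCounts(survey_id, k_obs=k_obs, k_detected=k_detected,
                          k_false=sum(by_class.values()))
    return counts, FalsePositiveBreakdown(**by_class)
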