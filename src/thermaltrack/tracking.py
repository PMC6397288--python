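"""Greedy frame-to-frame tracking of candidate signatures.

Each animal should yield one detection event rather than one per frame, so
candidates are associated across frames: at every frame, (track, candidate)
pairs are sorted by center distance and accepted greedily under a distance
gate, ties broken by lower track id then lower candidate index.  Track
positions are motion-compensated through the inter-frame homography before
gating — without this, camera motion alone (of order (speed/fps)/GSD pixels
per frame) would exceed any reasonable gate.  Tracks that go unmatched for
``max_missed`` consecutive frames close; closed tracks of sufficient length
become TrackedEvents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import CandidateSignature, Homography

__all__ = ["Track", "TrackedEvent", "GreedyTracker", "associate_step", "finalize_events"]

DEFAULT_GATE_PX = 15.0
DEFAULT_MAX_MISSED = 5
DEFAULT_MIN_LENGTH = 2


@dataclass
class Track:
    track_id: int
    members: list[tuple[int, CandidateSignature]] = field(default_factory=list)
    missed: int = 0
    state: str = "active"
    #: last centroid, warped into the current frame's coordinates
    compensated_pos: tuple[float, float] | None = None
    #: camera-compensated per-step centroid displacements (px/frame)
    displacements: list[float] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.members)

    @property
    def last_frame(self) -> int:
        return self.members[-1][0]


@dataclass
class TrackedEvent:
    """A deduplicated multi-frame detection of one signature."""

    track_id: int
    first_frame: int
    last_frame: int
    length: int
    #: centroid of the member at the median frame, in that frame's pixels
    centroid: tuple[float, float]
    #: frame index the centroid refers to
    centroid_frame: int
    mean_width: float
    mean_height: float
    #: mean camera-compensated centroid displacement, px/frame
    displacement_px_per_frame: float
    members: list[tuple[int, CandidateSignature]] = field(default_factory=list)


def associate_step(
    tracks: list[Track],
    candidates: list[CandidateSignature],
    frame_index: int,
    homography: Homography | None,
    gate_px: float = DEFAULT_GATE_PX,
    max_missed: int = DEFAULT_MAX_MISSED,
    next_track_id: int = 0,
) -> tuple[list[Track], int]:
    """Associate frame-t candidates with active tracks, greedily.

    ``homography`` maps previous-frame pixels onto frame t; when absent
    (registration failure) track positions are used as-is.  Returns the
    updated track list and the next unused track id.
    """
    active = [t for t in tracks if t.state == "active"]
    # carry last known positions into frame-t coordinates; tracks missed for
    # several frames keep being re-warped so the gate stays meaningful
    for t in active:
        base = t.compensated_pos if (t.missed > 0 and t.compensated_pos) else t.members[-1][1].centroid
        if homography is not None:
            t.compensated_pos = tuple(homography.apply([base])[0])
        else:
            t.compensated_pos = tuple(base)

    pairs = []
    for ti, t in enumerate(active):
        px, py = t.compensated_pos
        for ci, c in enumerate(candidates):
            d = math.hypot(c.centroid[0] - px, c.centroid[1] - py)
            if d <= gate_px:
                pairs.append((d, t.track_id, ci, ti))
    pairs.sort()

    used_tracks: set[int] = set()
    used_cands: set[int] = set()
    for d, tid, ci, ti in pairs:
        if ti in used_tracks or ci in used_cands:
            continue
        used_tracks.add(ti)
        used_cands.add(ci)
        t = active[ti]
        c = candidates[ci]
        px, py = t.compensated_pos
        t.displacements.append(math.hypot(c.centroid[0] - px, c.centroid[1] - py))
        t.members.append((frame_index, c))
        t.missed = 0

    for ti, t in enumerate(active):
        if ti not in used_tracks:
            t.missed += 1
            if t.missed > max_missed:
                t.state = "closed"

    for ci, c in enumerate(candidates):
        if ci not in used_cands:
            tracks.append(Track(next_track_id, members=[(frame_index, c)]))
            next_track_id += 1
    return tracks, next_track_id


def finalize_events(
    tracks: list[Track], min_length: int = DEFAULT_MIN_LENGTH
) -> list[TrackedEvent]:
    """Convert closed tracks of length >= ``min_length`` into events."""
    events: list[TrackedEvent] = []
    for t in sorted(tracks, key=lambda t: t.track_id):
        if t.length < min_length:
            continue
        frames = [f for f, _ in t.members]
        med = t.members[(t.length - 1) // 2]
        widths = [c.box.width for _, c in t.members]
        heights = [c.box.height for _, c in t.members]
        disp = float(np.mean(t.displacements)) if t.displacements else 0.0
        events.append(
            TrackedEvent(
                track_id=t.track_id,
                first_frame=frames[0],
                last_frame=frames[-1],
                length=t.length,
                centroid=med[1].centroid,
                centroid_frame=med[0],
                mean_width=float(np.mean(widths)),
                mean_height=float(np.mean(heights)),
                displacement_px_per_frame=disp,
                members=list(t.members),
            )
        )
    return events


class GreedyTracker:
    """Stateful wrapper driving :func:`associate_step` over a sequence."""

    def __init__(
        self,
        gate_px: float = DEFAULT_GATE_PX,
        max_missed: int = DEFAULT_MAX_MISSED,
        min_length: int = DEFAULT_MIN_LENGTH,
    ) -> None:
        self.gate_px = gate_px
        self.max_missed = max_missed
        self.min_length = min_length
        self.tracks: list[Track] = []
        self._next_id = 0

    def step(
        self,
        frame_index: int,
        candidates: list[CandidateSignature],
        homography: Homography | None,
    ) -> None:
        self.tracks, self._next_id = associate_step(
            self.tracks, candidates, frame_index, homography,
            gate_px=self.gate_px, max_missed=self.max_missed,
            next_track_id=self._next_id,
        )

    def finish(self) -> list[TrackedEvent]:
        for t in self.tracks:
            t.state = "closed"
        return finalize_events(self.tracks, self.min_length)
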