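"""Ensemble heat-map combination and the registered moving-average
accumulator.

The accumulator is the pipeline's temporal core: per-frame detection
evidence I(t) (the ensemble-averaged heat map) is blended into a running
map by

    A(t) = I(t)/N + ((N-1)/N) * A(t-1),

after warping A(t-1) into the pixel grid of frame t through the estimated
inter-frame homography.  N sets the effective memory: larger N weights
history more, so transient false detections decay while persistently
detected animals accumulate toward 1.  If registration fails, the history
cannot be aligned and the accumulator resets: A(t) = I(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import FrameRef, HeatMap, rasterize_boxes, warp_heatmap
from .registration import RegistrationResult

__all__ = [
    "AccumulatorState",
    "combine_heatmaps",
    "update_accumulator",
    "run_fusion",
    "write_accumulator_snapshot",
]

#: Default update constant: one second of history at the 9 Hz frame rate.
DEFAULT_N = 9


@dataclass
class AccumulatorState:
    """Accumulator A at one frame, with its update constant and the count
    of registration-failure resets seen so far."""

    A: HeatMap
    N: int
    last_frame_index: int
    reset_count: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"accumulator constant N must be >= 1, got {self.N}")


def combine_heatmaps(maps: Sequence[HeatMap]) -> HeatMap:
    """Pixel-wise arithmetic mean of per-detector binary heat maps.

    With two binary detectors the result takes values in {0, 0.5, 1}:
    0.5 where exactly one detector fired, 1 where both agree.
    """
    if not maps:
        raise ValueError("need at least one heat map to combine")
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"heat map shapes differ: {shapes}")
    mean = np.mean([m.values for m in maps], axis=0)
    return HeatMap(maps[0].frame, mean, "combined")


def update_accumulator(
    state: AccumulatorState | None,
    I_t: HeatMap,
    reg: RegistrationResult | None,
    N: int = DEFAULT_N,
) -> AccumulatorState:
    """Advance the accumulator by one frame.

    ``state`` None means start of sequence: A(0) = I(0).  A failed (or
    absent) registration resets: A(t) = I(t), and the reset counter
    increments.  Otherwise A(t-1) is warped into frame-t coordinates and
    blended per the moving-average recurrence.
    """
    if N < 1:
        raise ValueError(f"accumulator constant N must be >= 1, got {N}")
    if state is None:
        A = HeatMap(I_t.frame, I_t.values.copy(), "accumulated")
        return AccumulatorState(A, N, I_t.frame.index, reset_count=0)
    if reg is None or reg.failed:
        A = HeatMap(I_t.frame, I_t.values.copy(), "accumulated")
        return AccumulatorState(A, state.N, I_t.frame.index, state.reset_count + 1)
    warped_prev = warp_heatmap(
        state.A, reg.homography, out_shape=I_t.frame.shape, out_frame=I_t.frame
    )
    # algebraically A + (I - A)/N; exact at the fixed point I == A
    n = float(state.N)
    values = warped_prev.values + (I_t.values - warped_prev.values) / n
    np.clip(values, 0.0, 1.0, out=values)
    A = HeatMap(I_t.frame, values, "accumulated")
    return AccumulatorState(A, state.N, I_t.frame.index, state.reset_count)


def write_accumulator_snapshot(state: AccumulatorState, path) -> None:
    """Dump the accumulator as a 32-bit float TIFF for visual inspection."""
    import tifffile

    tifffile.imwrite(path, state.A.values.astype(np.float32))


def run_fusion(
    frames: Sequence[FrameRef],
    detections_per_detector: Iterable,
    N: int = DEFAULT_N,
    registrations: Sequence[RegistrationResult | None] | None = None,
    keep_history: bool = True,
):
    """Stream a frame sequence through rasterize -> combine -> accumulate.

    ``detections_per_detector`` is a sequence of DetectorOutputSet (already
    confidence-filtered); frames missing from a set contribute an empty
    (all-zero) binary map.  ``registrations[i]`` aligns frame i-1 onto
    frame i (entry 0 is ignored); None entries count as registration
    failures and reset the accumulator.

    Returns the list of per-frame AccumulatorState (or only the final state
    when ``keep_history`` is false, to bound memory on long sequences).
    """
    detector_sets = list(detections_per_detector)
    if not detector_sets:
        raise ValueError("need at least one detector output set")
    history: list[AccumulatorState] = []
    state: AccumulatorState | None = None
    for i, frame in enumerate(frames):
        per_detector = [
            rasterize_boxes([d.box for d in ds.detections(frame.index)], frame.shape, frame)
            for ds in detector_sets
        ]
        I_t = combine_heatmaps(per_detector)
        reg = None if (registrations is None or i == 0) else registrations[i]
        if i == 0:
            state = update_accumulator(None, I_t, None, N=N)
        else:
            state = update_accumulator(state, I_t, reg, N=N)
        if keep_history:
            history.append(state)
    if keep_history:
        return history
    return [state] if state is not None else []
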