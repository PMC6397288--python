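"""Candidate signature extraction from the accumulated heat map.

Pixels at or above the evidence threshold (default 0.05, the same level
used for the detector confidence filter) are foreground; 8-connected
components whose bounding box is between 3 and 30 pixels in both width and
height (inclusive) are accepted as candidate animal signatures.  The size
gate reflects the apparent size of an arboreal animal at the survey
altitude: smaller components are noise, larger ones are vehicles, people
or ground-dwelling macropods.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import BoundingBox, CandidateSignature, HeatMap

__all__ = ["extract_candidates"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def extract_candidates(
    A: HeatMap,
    threshold: float = 0.05,
    min_size: int = 3,
    max_size: int = 30,
) -> list[CandidateSignature]:
    """Threshold the accumulator and return size-gated connected components.

    Foreground is ``values >= threshold`` (boundary pixels retained).  The
    gate applies to the component's bounding-box extent, not its pixel
    count, and both bounds are inclusive.  Centroid is the unweighted mean
    of member pixel coordinates; ``mean_heat`` averages the accumulator over
    the component.
    """
    fg = A.values >= threshold
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    out: list[CandidateSignature] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = sl
        h, w = ys.stop - ys.start, xs.stop - xs.start
        if not (min_size <= w <= max_size and min_size <= h <= max_size):
            continue
        mask = np.zeros(A.values.shape, dtype=bool)
        local = labels[sl] == lab
        mask[sl] = local
        rows, cols = np.nonzero(local)
        cy = float(rows.mean()) + ys.start
        cx = float(cols.mean()) + xs.start
        out.append(
            CandidateSignature(
                frame=A.frame,
                pixel_mask=mask,
                box=BoundingBox(float(xs.start), float(ys.start), float(xs.stop), float(ys.stop)),
                centroid=(cx, cy),
                mean_heat=float(A.values[sl][local].mean()),
            )
        )
    return out
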