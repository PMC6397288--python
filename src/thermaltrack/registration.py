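"""Consecutive-frame registration via ORB keypoints and a robust
homography fit.

The camera translates (and slightly rotates) between consecutive video
frames, so detection evidence from frame t-1 must be re-expressed in the
pixel grid of frame t before temporal averaging.  Registration detects ORB
keypoints with binary descriptors on both frames, matches them, and fits a
planar homography with RANSAC.  When fewer than ``MIN_MATCHES`` point
matches survive, no homography is returned and the caller is expected to
reset its accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .model import FrameRef, Homography

__all__ = ["RegistrationResult", "MIN_MATCHES", "estimate_homography", "to_8bit"]

#: Minimum point matches required before a homography is attempted.
MIN_MATCHES = 4


@dataclass
class RegistrationResult:
    """Outcome of registering frame t-1 onto frame t.

    ``homography`` maps source-frame (t-1) pixels into target-frame (t)
    pixels and is absent when registration failed; ``num_matches`` counts
    descriptor matches; ``reproj_error_px`` is the mean reprojection error
    of RANSAC inliers.
    """

    homography: Homography | None
    num_matches: int
    reproj_error_px: float | None = None

    @property
    def failed(self) -> bool:
        return self.homography is None


def to_8bit(values: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Percentile contrast-stretch a 16-bit frame to uint8.

    Binary descriptors assume 8-bit input; thermal frames use only a narrow
    band of the 16-bit range, so a straight bit-shift would crush contrast.
    """
    v = np.asarray(values, dtype=np.float64)
    lo, hi = np.percentile(v, [p_low, p_high])
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.uint8)
    stretched = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return (stretched * 255.0 + 0.5).astype(np.uint8)


def estimate_homography(
    frame_t: np.ndarray,
    frame_t_minus_1: np.ndarray,
    n_keypoints: int = 500,
    residual_threshold: float = 3.0,
    target: FrameRef | None = None,
    source: FrameRef | None = None,
    seed: int = 0,
) -> RegistrationResult:
    """Estimate the homography carrying frame t-1 pixels onto frame t.

    Parameters
    ----------
    frame_t, frame_t_minus_1
        16-bit (or any-range) grayscale frames of identical shape.
    n_keypoints
        ORB keypoint budget per frame.
    residual_threshold
        RANSAC inlier reprojection threshold in pixels.
    seed
        Seed for the RANSAC sampler, making results reproducible.
    """
    if frame_t.shape != frame_t_minus_1.shape:
        raise ValueError(
            f"frame shapes differ: {frame_t.shape} vs {frame_t_minus_1.shape}"
        )
    img_t = to_8bit(frame_t).astype(np.float64) / 255.0
    img_s = to_8bit(frame_t_minus_1).astype(np.float64) / 255.0

    def _extract(img):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(img)
        except RuntimeError:  # no keypoints found (featureless frame)
            return None, None
        return orb.keypoints, orb.descriptors

    kp_s, desc_s = _extract(img_s)
    kp_t, desc_t = _extract(img_t)
    if desc_s is None or desc_t is None:
        return RegistrationResult(None, 0)

    matches = match_descriptors(desc_s, desc_t, cross_check=True)
    n_matches = len(matches)
    if n_matches < MIN_MATCHES:
        return RegistrationResult(None, n_matches)

    # ORB keypoints are (row, col); transforms operate on (x, y).
    src = kp_s[matches[:, 0]][:, ::-1]
    dst = kp_t[matches[:, 1]][:, ::-1]
    try:
        tform, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=MIN_MATCHES,
            residual_threshold=residual_threshold,
            max_trials=300,
            rng=seed,
        )
    except (ValueError, np.linalg.LinAlgError):
        return RegistrationResult(None, n_matches)
    if tform is None or inliers is None or inliers.sum() < MIN_MATCHES:
        return RegistrationResult(None, n_matches)
    matrix = np.asarray(tform.params)
    if not np.all(np.isfinite(matrix)) or abs(np.linalg.det(matrix)) < 1e-12:
        return RegistrationResult(None, n_matches)

    proj = tform(src[inliers])
    reproj = float(np.linalg.norm(proj - dst[inliers], axis=1).mean())
    return RegistrationResult(
        Homography(matrix, source_frame=source, target_frame=target),
        num_matches=n_matches,
        reproj_error_px=reproj,
    )
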