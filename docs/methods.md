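# Methods

## Problem and model

A drone flies parallel ("lawnmower") transects over forest at low altitude
with a nadir thermal camera. Warm-bodied animals appear as compact bright
blobs a few pixels wide; detectors looking at single frames miss animals
(occlusion by canopy, low contrast) and fire on clutter. The package's
premise is that a real animal is *persistent*: it is detected in roughly
the same ground position across many consecutive frames, while clutter is
transient. All stages serve that premise.

**Heat-map fusion.** Each detector's boxes on a frame become a binary
image (1 inside any box); the per-detector images are averaged, so with two
detectors a pixel holds 0, 0.5 or 1 according to ensemble agreement. The
average is used as-is rather than re-binarized (a union option exists in
`combine_heatmaps` callers by thresholding), so agreement information
propagates into the accumulator.

**Registration.** The camera moves ~(speed/fps)/GSD px between frames
(11 px at the default 8 m/s, 9 Hz, 0.08 m/px), so the previous accumulator
must be warped into the current frame before blending. ORB keypoints
(budget 500/frame) are detected on 8-bit percentile-stretched (1st–99th)
copies of the 16-bit frames, matched with cross-checked Hamming distance,
and a projective homography is fit by RANSAC (3 px inlier threshold, 300
trials, seeded). Fewer than 4 surviving matches, or a degenerate fit,
count as registration failure. Only consecutive frames are registered;
long-horizon drift is inherent and uncorrected, which is acceptable
because evidence older than a few multiples of N carries negligible
weight.

**Accumulation.** A(t) = I(t)/N + ((N−1)/N)·A(t−1), computed as
A + (I − A)/N so the fixed point I = A is exact in floating point. N
defaults to 9 — one second of history at the camera's 9 Hz — balancing
noise suppression against smear; it is fully configurable. A(0) = I(0)
(equivalent to a reset at t = 0), and any registration failure resets
A(t) = I(t), because unaligned history would smear evidence across the
scene. Warped-in border pixels read 0, slightly decaying evidence at frame
edges. Bilinear interpolation with clamping keeps A within [0, 1]; an
identity homography skips resampling entirely.

**Candidate extraction.** Foreground is A ≥ 0.05 — the same level as the
detector confidence filter, and the value a single half-confidence
detection contributes in one step (0.5/9 ≈ 0.056), so evidence appears
immediately and disappears ~N·ln(20) ≈ 27 frames after support stops.
Components use 8-connectivity (diagonal warm pixels of one animal must not
split). The size gate is applied to the component's bounding-box extent,
inclusively on both bounds [3, 30] px. Rasterization marks a pixel inside
a box iff the pixel *center* falls in the half-open box, so an integer-width
box covers exactly that many pixels at any subpixel position and gate
boundaries behave predictably.

**Tracking.** Greedy nearest-pair association: all (track, candidate)
pairs within the gate are sorted by center distance and accepted
first-come, ties broken by lower track id then lower candidate index —
a deterministic output contract. Track positions are warped through the
inter-frame homography before gating (and are re-warped while a track is
coasting), so the gate measures scene motion, not camera motion. Defaults:
gate 15 px (≈ half the maximum signature width), max 5 consecutive misses
(≈ half a second at 9 Hz), minimum event length 2 frames. Event
displacement is the mean camera-compensated centroid step, the feature the
classifier uses as "movement between frames".

**Georeferencing.** Nadir pinhole: ground offset = (pixel − principal
point) × GSD, rotated by heading, added to the aircraft position; the
principal point is the frame center. GSD is a required input (it can be
derived from focal length, pixel pitch and altitude via
`gsd_from_optics`). Geographic distances use a WGS84 local tangent-plane
(equirectangular) approximation, accurate to millimetres over the ~1 km
survey extents this targets; no DEM or gimbal-attitude correction is
attempted. The event's ground position uses the telemetry of its median
member frame.

**Classification and matching.** The rule cascade mirrors manual review:
car if both box sides exceed the animal gate (31–200 px template);
human if on open terrain, person-sized (5–15 px) and moving ≥ 1.5 px/frame;
kangaroo if on open terrain and (motion > 4 px/frame or width > 20 px);
candidate if 3–30 px in both dimensions and motion ≤ 1 px/frame; otherwise
"other". Motion thresholds ("rapid" > 4, "minimal" ≤ 1 px/frame) are
declared conventions for qualitative field criteria. Candidate events are
matched to surveyed animal positions greedily, closest first, one-to-one,
within 15 m (default; of the order of canopy positional error). Unmatched
candidates are relabelled "other" — signatures whose source could not be
identified — and every non-matched event contributes to K_false.

## Evaluation framework

P_d = K_detected/K_obs and PR = K_detected/(K_obs+K_false) are reported as
integer percentages, rounding half away from zero. K_detected ≤ K_obs is
enforced structurally (matching is one-to-one against collared animals).
RMSE and MAE operate on whatever survey series the caller passes.

The bundled reference dataset (`koala_study`) carries the per-survey counts
of an eleven-survey koala field campaign for both the automated pipeline
and independent manual review. Two caveats are recorded in its docstring:
per-survey K_false values are recovered from the reported precision rates
(unique integers exist for most rows; three rows admit only a best fit
within 1–2 rounded points), and the headline RMSE/MAE figures are defined
over a seven-survey set (North 3–6, South 3–5) rather than the six-survey
testing split. The false-positive composition uses the sum of the class
counts (73) as denominator.

## Synthetic scenes

The simulator emulates what the pipeline consumes, not thermal physics:

- background: smoothed Gaussian texture (std 80 counts around a 7000-count
  canopy mean) with a slightly cooler open-terrain strip along the southern
  quarter of the world; the terrain mask is exported for the classifier;
- animals: static warm elliptical blobs (+1500 counts, soft 1 px edge)
  placed in canopy with a minimum separation (default 8 m — one animal per
  tree crown) so distinct animals never merge into one component;
  per-frame Bernoulli occlusion optional;
- distractors: kangaroo-like blobs (> 20 px wide, 4 m/s) moving on open
  terrain, optional car- and human-like objects;
- camera: east-west lawnmower transects at 60 m, 8 m/s, 9 Hz, 640×512
  frames (all configurable), small per-frame heading jitter; frames are
  rendered by bilinearly sampling a world texture under the exact camera
  pose, so the returned frame-to-frame homographies are exact by
  construction (verified: warping by the true homography aligns noise-free
  background to < 1 count mean absolute error);
- mock detectors: per visible object, a detection with probability
  1 − miss_rate, corner jitter, Beta-distributed confidence (true boxes
  skewed high, spurious boxes low so some fall under the 0.05 filter);
  spurious boxes from a per-frame Poisson process. The detector cannot
  tell classes apart — every warm object yields a "koala" box, as with
  single-class trained detectors.

Everything is driven by one `numpy` Generator per artifact, so identical
config and seed give bit-identical frames, truth, telemetry and
detections; fixture CSVs are written with repr-precision floats and read
back with round-trip parsing.

What the scenes do *not* emulate: radiometric calibration, weather,
anisotropic canopy occlusion, motion blur, rolling shutter, terrain
relief, and detector confusion structure beyond the class-blind model.
Passing tests therefore demonstrate the correctness of the fusion,
registration, tracking and evaluation machinery under controlled
conditions — not field-level detection performance, which depends on the
trained detectors and habitat.

## Problem sizes in tests

Tests and the acceptance script run scaled-down scenes chosen as the
package's own working sizes: 144×192 px frames at 0.3 m/px (so camera
motion is ~3 px/frame), 40-frame surveys with 5 animals for end-to-end
checks, a 100-frame single-transect sequence for registration recovery,
and 12–20 replicate surveys for the pooled detection-probability study.
At these sizes the registration error against simulator truth is
~0.03–0.05 px (bound asserted: 0.5 px) and accumulating with estimated vs
true homographies differs by ~1e-4 mean absolute pixel value (bound:
0.02).

## Known limitations

- Greedy matching (both tracking and ground-truth matching) is optimal
  only when nearest-neighbour structure is unambiguous; dense aggregations
  of animals at the gate scale can mis-assign.
- A long registration outage resets the accumulator; animals visible only
  during the outage may fragment into multiple events.
- The classifier is a small rule cascade; its size/speed templates are
  configuration, not learned behaviour, and shape ("roundness") is
  deliberately not used.
- The equirectangular tangent plane degrades near the poles and over
  multi-kilometre extents; both are outside the intended regime.
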