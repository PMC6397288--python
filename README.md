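# thermaltrack

Automated detection of warm-bodied wildlife in low-altitude aerial thermal
video, built for drone-based surveys of cryptic arboreal species such as
koalas. Trained object detectors flown over a forest produce noisy,
flickering per-frame bounding boxes; this package turns them into a stable
per-survey animal count and evaluates that count against ground truth.

## Who it is for

Ecologists and remote-sensing engineers running RPAS (drone) thermal
surveys who already have per-frame detections — from one or several neural
detectors, or from the bundled classical blob detector — and need the
downstream machinery: ensemble fusion, temporal accumulation, duplicate
suppression, georeferencing, and survey-level accuracy metrics. A synthetic
survey simulator makes every stage testable with known ground truth, no
trained weights, and no field data.

## The method

Each detector's boxes on frame *t* (confidences < 0.05 discarded) are
rasterized to a binary heat map; the ensemble maps are averaged into
*I(t)*. Consecutive frames are registered with ORB keypoints and a
RANSAC-fit planar homography (at least 4 point matches required), and a
moving-average evidence accumulator is maintained in the pixel grid of the
current frame:

    A(t) = I(t)/N + (N-1)/N · A(t-1),      A(t) = I(t) on registration failure

where *N* (default 9, one second at 9 Hz) sets the temporal memory.
Pixels with A ≥ 0.05 are segmented into 8-connected components, and
components whose bounding box is 3–30 px in both width and height become
candidate signatures. A greedy tracker associates candidates across frames
(camera-motion-compensated, closest pair first) so each animal yields one
event. Events are projected to ground coordinates by a nadir pinhole model
(offset from the principal point × GSD, rotated by heading), classified
(candidate / kangaroo / car / human / other) by size, motion and terrain
rules, and matched one-to-one to surveyed animal positions within a radius.

Per-survey counts are scored as

    P_d = K_detected / K_obs          PR = K_detected / (K_obs + K_false)
    RMSE = sqrt(Σ(K_obs,i - K_detected,i)² / n)
    MAE  = Σ|K_obs,i - K_detected,i| / n

where K_obs is the number of collared animals known present, K_detected the
true positives and K_false the falsely identified or unidentifiable
signatures.

## Worked example

`python examples/evaluate_field_counts.py` scores the bundled eleven-survey
koala field campaign (two sites, automated pipeline vs manual frame
review):

```
pooled P_d testing  automated: 87%
pooled P_d testing  manual   : 63%
pooled P_d training automated: 85%
pooled P_d training manual   : 52%

automated RMSE 1.9272  MAE 1.4286  (n=7 surveys)
manual    RMSE 5.7321  MAE 5.4286  (n=7 surveys)

false positives by class: kangaroo 29%, car 12%, human 4%, other 55%
```

The pooled P_d lines say what fraction of the radio-collared animals known
to be on site each method found; RMSE/MAE measure how far per-survey counts
sit from the true number present. Fusion roughly triples the count accuracy
of manual review while detecting more animals.

`python examples/simulate_and_fuse.py` runs the full pipeline on a
synthetic survey (five animals, one kangaroo-like distractor, two mock
detectors each missing 30% of frames):

```
frames: 40, accumulator resets: 0
  track 0: candidate frames 0-23 size 17.1x14.7 px motion 0.44 px/frame matched=animal_002
  track 3: kangaroo  frames 1-11 size 26.5x18.5 px motion 1.19 px/frame matched=None
  ...
K_obs=5 K_detected=5 K_false=1 -> P_d 100%
```

Every animal is recovered as exactly one matched candidate event despite
the per-frame misses; the wide, fast signature on open terrain is labelled
a kangaroo and counted as a false positive, not an animal.

There is also a thin CLI for file-based workflows:

```
thermaltrack simulate --out fixture/ --seed 3 --n-frames 40
thermaltrack fuse --fixture fixture/ --out run/
thermaltrack evaluate --counts run/counts.csv --out report/
```

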