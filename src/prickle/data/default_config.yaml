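# Default annotation pipeline configuration.
#
# Detector parameters follow the partitioned simple-blob-detector scheme:
# one tight column for the coated root/center areas (suppresses cracks and
# petechiae) and one loose column shared by tip and margin (keeps faint
# genuine prickles).  Gray levels in [0, 255], areas in px^2.
#
# Reference colors are synthetic reddish prickle exemplars; replace them
# with colors picked from your own images (or a generator's exported
# ground-truth palette) for real use.

partition:
  f_root: 0.25
  f_tip: 0.20
  f_margin: 0.20
  root_at_top: true

detector:
  root_center:
    min_threshold: 60
    max_threshold: 100
    threshold_step: 2
    min_repeatability: 8
    min_area: 4
    max_area: 25
    min_circularity: 0.8
    min_convexity: 0.8
    min_inertia_ratio: 0.5
    max_aberration: 85
    min_dist_between_blobs: 10
    polarity: dark
  tip:
    min_threshold: 60
    max_threshold: 100
    threshold_step: 2
    min_repeatability: 4
    min_area: 2
    max_area: 40
    min_circularity: 0.4
    min_convexity: 0.4
    min_inertia_ratio: 0.4
    max_aberration: 100
    min_dist_between_blobs: 10
    polarity: dark
  margin:
    min_threshold: 60
    max_threshold: 100
    threshold_step: 2
    min_repeatability: 4
    min_area: 2
    max_area: 40
    min_circularity: 0.4
    min_convexity: 0.4
    min_inertia_ratio: 0.4
    max_aberration: 100
    min_dist_between_blobs: 10
    polarity: dark

reference_colors:  # synthetic defaults, not measured from any dataset
  root_center:
    - [138, 40, 50]
    - [155, 68, 74]
    - [170, 95, 98]
  tip:
    - [138, 40, 50]
    - [152, 60, 66]
    - [168, 85, 90]
  margin:
    - [138, 40, 50]
    - [152, 60, 66]
    - [168, 85, 90]

pipeline:
  box_pad: 1
  iou_threshold: 0.5
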