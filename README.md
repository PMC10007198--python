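# fluokernel

A machine-vision toolkit for fluorescently labelled seed imaging and sorting.
It covers the full classical pipeline around a fluorescent-kernel detector —
without requiring a camera, a dataset or a trained network:

- **`fluokernel.synth`** — synthetic dark-box scenes: elliptical kernels of
  three classes (bright red-magenta, dim red, non-fluorescent) with radial
  glow falloff, Gaussian noise and full per-kernel ground truth (mask, tight
  box, class, centroid). Deterministic per seed; rejection-sampled placement
  with a minimum-gap guarantee.
- **`fluokernel.segment`** — grayscale → median filter → Laplacian sharpening
  → Otsu + morphology → distance-transform-seeded watershed → per-kernel
  crops.
- **`fluokernel.features`** — 18 colour moments per kernel ({R,G,B,H,S,V} ×
  {mean, std, signed-cube-root third moment}) and a two-threshold H/V-mean
  fluorescence rule with a midpoint fitting helper.
- **`fluokernel.augment`** — gamma transform (`s = c·r^γ`), HSV jitter and
  four-image mosaic composition with box transformation.
- **`fluokernel.losses`** — bounding boxes, IoU/GIoU and the complete-IoU
  loss decomposition (centre-distance and aspect-ratio penalties), plus
  candidate ranking.
- **`fluokernel.metrics`** — greedy PASCAL-style detection matching,
  confusion counts, precision/recall/accuracy/F1, P–R curves and all-points
  average precision.
- **`fluokernel.cbam`** — forward pass of a convolutional block attention
  module (channel then spatial) on plain NumPy arrays.
- **`fluokernel.sorting`** — conveyor-belt sorting simulator: belt speed from
  seed spacing and drop interval, classifier error injection, and
  interval-dependent double-drop failures with a model/mechanical error
  breakdown.
- **`fluokernel.labels` / `fluokernel.cli`** — YOLO-txt and Pascal-VOC XML
  label I/O, PNG image I/O, bilinear resizing, and the umbrella CLI.

## CLI

```sh
fluokernel generate --out scene/ --seed 1 --n-kernels 12
fluokernel segment --in scene/scene.png --out labels.png --report segments.csv
fluokernel features --in scene/scene.png --labels labels.png --out moments.csv
fluokernel augment --in scene/scene.png --out bright.png --gamma 0.7
fluokernel evaluate --dets dets.txt --truths scene/scene.txt --iou 0.5
fluokernel simulate-sort --config run.yaml --reps 100 --out results.csv
```

Detections for `evaluate` are YOLO-txt lines with a sixth confidence column.
`simulate-sort` reads a YAML mapping with keys `spacing_mm`, `interval_s`,
`n_fluor`, `n_non`, `p_correct`, `seed`. CSV outputs begin with a provenance
comment (version, seed, config hash). Exit codes: 0 ok, 1 usage error,
2 data error.

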