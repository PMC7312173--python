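# nucmap

Large-scale single-cell image analysis for whole-slide fluorescence scans:
segment nuclei from the DAPI channel, correct acquisition artifacts,
extract per-nucleus features, classify every cell's cell-cycle phase from
DAPI alone, and map nuclear DNA damage (gamma-H2AX) as spatial
distributions around a treatment site.

## What it does

1. **Synthetic slides** (`nucmap.synthetic`) — ground-truthed two-channel
   slides: ellipse-like nuclei with per-phase DNA content (G2 = 2x G1,
   S uniform in between), five distinct mitotic morphologies, gamma-H2AX
   foci following a configurable radial damage field (plain decay or a
   ring), plus every artifact the pipeline must handle: foreground gain
   drift along the slow scan axis, additive background surfaces,
   multiplicative fast-axis stripes, locally blurred regions and
   Poisson-Gaussian noise. Fully seeded and bit-reproducible.
2. **Slide IO & QC** (`nucmap.io`) — TIFF channel/label-map round-trips,
   overlap tiling for large rasters, and per-tile quality control
   (cell-free and blurry tiles are discarded with reason codes).
3. **Segmentation** (`nucmap.segmentation`) — Gaussian blur (sigma 1 px),
   adaptive log-weighted Otsu threshold (per-window, bilinearly blended),
   and clump partitioning with a pluggable nucleus-center detector
   (default: distance-transform h-maxima with an intensity-weighted
   k-means fallback) feeding a geometric nearest-center split.
4. **Intensity correction** (`nucmap.correction`) — in fixed order:
   background-surface subtraction, per-scan-line stripe removal, DAPI
   foreground normalization (lowess band fits anchoring the G1 band at
   1 and the G2 band at 2 along the slow axis), and gamma-H2AX baseline
   flattening from the bottom 2–4% of G1-cell intensities per ~1 mm²
   block.
5. **Features** (`nucmap.features`) — per-nucleus shape, Fourier boundary
   descriptors, intensity statistics, radial shell intensities, 13
   Haralick texture statistics and a granularity spectrum.
6. **Cell-cycle classification** (`nucmap.cellcycle`) — a shallow neural
   network (hidden layers 30 and 10, softmax) separates interphase from
   four mitotic classes; interphase cells are assigned G1/S/G2 by a
   constrained mixture in (area, DAPI) space: seven Gaussians equally
   spaced on the G1→G2 segment, an eighth on the G1 peak, plus a uniform
   background component.
7. **Damage quantification** (`nucmap.damage`) — per-nucleus damage =
   gamma-H2AX/DAPI intensity ratio on a calibrated 0–150 scale, flow-
   control median subtraction, damage ratios (fraction above threshold
   75) and circular binned maps with missing-bin masking.
8. **Pipeline & CLI** (`nucmap.pipeline`, `nucmap.cli`) — one YAML config
   drives the whole run with per-stage outputs, config-hash resume and a
   single fan-out seed.

## CLI

```bash
nucmap simulate --n-nuclei 2000 --shape 2048 2048 --pixel-size 1.0 \
    --seed 1 --out-prefix runs/demo
nucmap segment runs/demo_dapi.tif --pixel-size 1.0 --out runs/labels.tif
nucmap features runs/labels.tif runs/demo_dapi.tif --gh2ax runs/demo_gh2ax.tif \
    --pixel-size 1.0 --out runs/nuclei.csv
nucmap correct runs/nuclei.csv --out runs/nuclei_corrected.csv
nucmap damage-map runs/nuclei_corrected.csv --center-x 1024 --center-y 1024 \
    --stat DR --out-prefix runs/map
nucmap run config.yaml --out-dir runs/full    # everything from one YAML
```

See `nucmap.pipeline.DEFAULTS` for every config key and its recorded
default.

## Conventions

Pixel coordinates are 0-based `(row, col)`; physical positions are
`pixel * pixel_size` micrometres. `fast_axis="rows"` means each scanner
line is an image row (stripes appear as whole rows; the slow axis is the
row index). Shell intensities are ordered outermost→innermost. All
randomness flows from one integer seed.
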