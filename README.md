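# seedlingvision

Machine-vision grading of potted seedlings in plug trays: find every
cell of a tray image, measure how much of it the seedling's leaves
cover, classify the cell as **healthy / sub-healthy / poor / empty**,
and report tray coordinates so a transplanting robot can act on the
result.

## What it does

The pipeline mirrors a classical color-index + entropy-threshold
segmentation stack:

1. **Color index** — each RGB pixel is mapped to the green-enhancing
   index `TG = (3G − R − B) / 3` (or `TR` for red, or plain luma), which
   makes leaves bright and tray/substrate dark.
2. **Gray-level rescale** — the index image is min–max rescaled to
   integer levels 0..255 and histogrammed.
3. **Maximum-entropy thresholding** — two thresholds `(T1, T2)` split
   the histogram into three classes (tray, substrate, leaf); the pair
   maximizing the sum of within-class Shannon entropies is found by a
   compact genetic algorithm (roulette selection with linear fitness
   scaling, single-point crossover, bit-flip mutation, elitism). An
   exhaustive search over all 32,640 pairs is included as an oracle.
4. **BM3D mask cleanup** — the binary mask is denoised by
   block-matching 3D-transform filtering (grouping similar 8×8 patches,
   hard-thresholding in a 3D DCT domain, weighted overlap aggregation,
   optional Wiener-weighted second pass) and re-binarized.
5. **Per-cell grading** — leaf pixels are counted per tray cell,
   converted to area via the pixel-to-mm² scale `K`, and the cover
   ratio `F = leaf pixels / cell pixels` is classified:
   healthy `F > 0.20`, sub-healthy `0.16 ≤ F ≤ 0.20`, empty
   `F < 0.015`, poor otherwise. Each cell gets an odd-lattice tray
   coordinate `(2·col − 1, 2·row − 1)`.

A synthetic tray generator with **exact** per-cell ground truth
(leaf-cover fractions rendered to the pixel) supports end-to-end
validation, and bundled calibration/grading tables reproduce the
published threshold statistics and accuracy figures.

## Worked example

Render a synthetic 3×7 tray with a known mix of cell states, then run
the full identification pipeline:

```sh
# per-cell target cover fractions (3 rows x 7 cols) in a YAML grid
seedlingvision synth --f-per-cell f.yaml --seed 11 --out tray.png --truth truth.json
seedlingvision identify --image tray.png --seed 1 --out cells.csv --summary summary.json
head -8 cells.csv
```

```
row,col,x,y,pixel_count,leaf_area_mm2,F,label
1,1,1,1,570,1526.79,0.25,healthy
1,2,3,1,412,1103.57,0.18,sub_healthy
1,3,5,1,0,0.0,0.0,empty
1,4,7,1,225,602.68,0.1,poor
1,5,9,1,571,1529.46,0.25,healthy
1,6,11,1,574,1537.5,0.25,healthy
1,7,13,1,14,37.5,0.01,empty
```

The JSON summary groups coordinates by label for downstream robotics:

```json
"counts_by_label": {"empty": 4, "healthy": 11, "poor": 3, "sub_healthy": 3},
"thresholds": {"t1": 60, "t2": 128}
```

On this tray all 21 cells are labeled correctly against the generator's
ground truth. Other subcommands: `segment` (threshold one image and
write the mask), `denoise` (BM3D-clean a mask), `calibrate` (pooled
F-threshold statistics), `eval` (grading accuracy from count tables).
Run any of them with `--help` for options; `identify --config` accepts
a YAML file overriding any pipeline setting (see `docs/methods.md`).

## Layout

- `src/seedlingvision/` — library (`preprocess`, `ga_threshold`,
  `bm3d`, `sihvs`, `synth`, `pipeline`, `config`, `cli`, `imgio`)
- `src/seedlingvision/data/` — bundled calibration and grading tables
- `tests/` — unit/property tests plus `test_acceptance.py`
- `docs/methods.md` — model details, parameters, and limitations
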