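# Methods

This document records the model implemented by `seedlingvision`, the
parameter choices and their rationale, the synthetic benchmark, and the
known limitations.

## 1. Preprocessing (`preprocess`)

- **Color indices.** `TG = (3G − R − B) / 3` enhances green (leaf)
  pixels; `TR = (3R − G − B) / 3` enhances red (tray) pixels. Values
  may be negative; they are kept as floats.
- **Grayscale.** Luma `Y = 0.2989 R + 0.5870 G + 0.1141 B`.
- **Rescaling.** Index images are min–max rescaled to integer levels
  0..255 with round-half-up (`floor(x + 0.5)`). A constant image maps
  to all zeros rather than dividing by zero.
- **Histogram.** `IntensityHistogram` stores the 256-bin probability
  vector and the pixel count; probabilities sum to 1 exactly up to
  float error.

## 2. Two-threshold maximum-entropy segmentation (`ga_threshold`)

The objective is Kapur-style three-class entropy: thresholds
`0 ≤ T1 < T2 ≤ 255` split the levels into `[0,T1]`, `(T1,T2]`,
`(T2,255]`, and the fitness is the sum of the three within-class
Shannon entropies (with `0·ln 0 := 0`; an empty class contributes 0).
Class entropies are computed in O(1) from cumulative `P` and `P·ln P`
tables, so the exhaustive oracle over all `C(256,2) = 32,640` pairs is
a vectorized 256×256 matrix evaluation (milliseconds per histogram).
Ties in the oracle resolve lexicographically.

**Genetic algorithm.** Each chromosome is 16 bits (8 per threshold,
MSB first). Decoding repairs infeasible pairs: if `t1 > t2` swap; if
equal, increment `t2` mod 256 and re-swap. Per generation: Goldberg
linear fitness scaling (mean preserved, max scaled to 2× mean, with a
min-floor fallback when scaling would go negative), roulette-wheel
selection, one elite copied unchanged, single-point crossover on
consecutive pairs with probability 0.6, bit-flip mutation at 0.03 per
bit. Population 21, at most 100 generations, early stop after 20
generations without improvement of the best-ever individual, which is
tracked across generations (elitist). A single seeded
`numpy.random.Generator` drives every stochastic step, so runs are
fully reproducible. On smooth multi-modal histograms the GA reaches
≥ 99% of the exhaustive optimum in ≥ 19/20 seeded runs.

**Binarization modes.** `upper_class` keeps levels `> T2` (the
brightest entropy class — under TG the leaf is the brightest material),
`geq_min` keeps levels `≥ min(T1,T2)`, `band` keeps `(T1, T2]`.

## 3. BM3D mask cleanup (`bm3d`)

A compact BM3D with separable orthonormal DCT-II as the 3D transform:

- **Block matching.** For each reference 8×8 block, candidates on a
  stride-4 lattice anchored at the reference within a ±16 search window
  are scored by `d = ‖X_ref − X_cand‖_F / h` (normalized by the step
  `h`, as the distance is defined here); candidates with `d` below the
  threshold 2.5 form the stack, sorted by `(d, scan order)` with the
  reference first and truncated to 16 blocks.
- **Hard-threshold pass.** 3D DCT, zero coefficients with
  `|X| ≤ λ·σ` (λ = 2.7), inverse transform; aggregation weight
  `1 / N_P` where `N_P` counts retained coefficients.
- **Optional Wiener pass.** The second pass shrinks coefficients by
  `E / (E + σ²)` using the first-pass energies and aggregates with the
  same form as weight.
- **Aggregation.** Overlapping estimates are averaged with their
  weights; the image is reflect-padded by `block − 1` so every pixel is
  covered. Zero-weight stacks fall back to a tiny positive weight to
  avoid 0/0.

**Parameter choice.** The standalone denoiser defaults to `σ = 0.25`
(appropriate for genuinely noisy grayscale input). The *pipeline's*
mask-cleanup stage defaults to `σ = 0.10`: after entropy thresholding
the residual error is sparse binary speckle (1–2% of pixels), and the
heavier setting over-smooths, eroding small leaf blobs and biasing the
cover ratio F low by about 0.007 — enough to flip labels near the
0.16/0.20 boundaries. At `σ = 0.10` the speckle is removed with
near-zero F bias. Either value can be set explicitly in the YAML
config (`bm3d: {sigma: ...}`).

## 4. Grading (`sihvs`)

- **Area scale.** `K = actual tray area (mm²) / tray pixels`; a cell's
  leaf area is `M = K · P` for `P` counted leaf pixels.
- **Cover ratio.** `F = leaf pixels / cell pixels`, classified with
  thresholds `f_avg = 0.20`, `f_min = 0.16`, `f_empty = 0.015`:
  healthy `F > f_avg`, sub-healthy `f_min ≤ F ≤ f_avg`, empty
  `F < f_empty`, poor otherwise. The band edges are closed on the
  sub-healthy side, matching the published rule.
- **Coordinates.** Cell `(row, col)` maps to `(x, y) = (2·col − 1,
  2·row − 1)` — the odd lattice used by the transplanting robot, with
  `x` along the 7-column axis and `y` along the 3-row axis.
- **Calibration.** Given groups of measured F values, per-group
  `(max, mean, min)` are pooled as mean-of-means / max-of-maxima /
  min-of-minima, rounded to 2 decimals. The bundled 20-group table
  yields pooled mean 0.20 and pooled max 0.25 (the pooled min, 0.15,
  comes from a single low group and the working `f_min` stays at 0.16).
- **Accuracy.** Per group, `100 · identified healthy / actual healthy`
  rounded to 2 decimals; the average is the mean of the rounded values.
  The bundled count tables give 96 / 92.55 / 94.44 (average 94.33) for
  the proposed method and 92 / 87.23 / 88.89 (average 89.37) for the
  comparison method.

## 5. Synthetic benchmark (`synth`)

Because no field imagery is deposited, validation uses a renderer with
exact ground truth. Each tray is a red tray surface, a brown-black
substrate ellipse per cell, and green leaf canopies drawn by
thresholding a random sum of Gaussian bumps at exactly the top-k pixels
of the cell, so every cell's true cover fraction is rendered to the
pixel. Realism terms: per-pixel Gaussian color jitter (σ = 8), a
corner-to-corner multiplicative illumination ramp (±10%), and additive
sensor noise (σ = 6). Ground truth (counts, F, labels, clean mask) is
recorded before the noise terms.

Default desk-scale geometry: 48-px cells, 3×7 grid, tray region
`(16, 16, 144, 336)` inside a 176×368 image — small enough that the
full pipeline runs in a few seconds per tray.

**What the benchmark shows.** On 20 trays whose true F values sit at
least 0.02 from every decision boundary the pipeline recovers 420/420
labels; on 20 trays with every cell within 0.005 of a boundary it
recovers ≈ 96–98%. This is a scaled-down stand-in for the published
94.33% field accuracy, not a reproduction of it: real pepper seedlings,
occlusions between neighboring plants, and greenhouse lighting are all
outside the generator's scope.

## 6. Problem sizes and runtimes (single CPU)

| Stage | Size | Time |
| --- | --- | --- |
| Exhaustive threshold oracle | 32,640 pairs | ~5 ms |
| GA (pop 21, ≤100 gens) | 16-bit chromosomes | ~25 ms |
| BM3D hard-threshold pass | 256×256 | ~2 s |
| Full pipeline | 176×368 tray | ~3 s |
| Acceptance script | all quantities | ~2 min |

## 7. Numerical choices

- All probability math in float64; `0·ln 0` handled by masking, never
  by adding epsilons to the data.
- Rounding of reported quantities (F, areas, accuracies) is
  round-half-even via Python's `round`, applied once at the reporting
  boundary; internal math is unrounded.
- Result files are written atomically and contain no timestamps, so
  reruns with the same seed are byte-identical.
- Seeds fan out from one global seed via a fixed affine map modulo
  `2^31 − 1`, keeping every stage independently reproducible.

## 8. Limitations

- The generator's blobs are convex-ish bump unions; real canopies have
  holes, specular highlights, and inter-cell occlusion the pipeline has
  never seen.
- The BM3D implementation is a faithful but compact variant (single
  fixed transform, no adaptive variance estimation); it is tuned for
  binary-mask cleanup, not photographic denoising benchmarks.
- Grading thresholds are global constants; no per-tray illumination
  normalization beyond what min–max rescaling provides.
- The maximum-entropy objective can place `T2` tight against the upper
  tail of the substrate mode on strongly bimodal index histograms; the
  BM3D cleanup absorbs the resulting speckle, but heavily blurred or
  low-contrast imagery may still need the `band` binarization mode or
  manual thresholds.
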