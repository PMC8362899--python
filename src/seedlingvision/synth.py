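"""Synthetic plug-tray image generator with exact ground truth.

Renders the three materials of a tray scene — red tray surface,
brown-black substrate plug in each cell, green leaf canopy — plus
per-pixel color jitter, a corner-to-corner multiplicative illumination
ramp, and additive Gaussian sensor noise.  Leaf canopies are drawn by
thresholding a random smooth bump field at exactly the top-k pixels of
the cell, so the ground-truth cover fraction of every cell matches its
target to within one pixel.

Ground truth (per-cell pixel count, cover ratio F, class label, and the
clean leaf mask) is recorded before noise and illumination are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError
from .sihvs import ClassThresholds, TrayLayout, classify

DEFAULT_TRAY_COLOR = (200, 30, 30)
DEFAULT_SUBSTRATE_COLOR = (60, 45, 35)
DEFAULT_LEAF_COLOR = (40, 160, 50)

#: true-F sampling ranges per class label used for validation sets;
#: disjoint and clear of the default decision boundaries
LABEL_F_RANGES = {
    "healthy": (0.22, 0.35),
    "sub_healthy": (0.165, 0.195),
    "poor": (0.02, 0.15),
    "empty": (0.0, 0.014),
}


@dataclass(frozen=True)
class SynthSpec:
    """Scene description for one synthetic tray image.

    ``per_cell_f`` is the target leaf-cover fraction of each cell
    (scalar, or an ``n_rows x n_cols`` array); fractions above 0.9 are
    rejected as unattainable with the blob renderer.
    """

    layout: TrayLayout = field(default_factory=TrayLayout)
    per_cell_f: float | np.ndarray = 0.0
    tray_color: tuple[int, int, int] = DEFAULT_TRAY_COLOR
    substrate_color: tuple[int, int, int] = DEFAULT_SUBSTRATE_COLOR
    leaf_color: tuple[int, int, int] = DEFAULT_LEAF_COLOR
    color_jitter: float = 8.0
    noise_sigma: float = 6.0
    illumination_gradient: float = 0.1
    rng_seed: int = 0

    def f_grid(self) -> np.ndarray:
        try:
            grid = np.broadcast_to(
                np.asarray(self.per_cell_f, dtype=np.float64),
                (self.layout.n_rows, self.layout.n_cols),
            ).copy()
        except ValueError as exc:
            raise InvalidInputError(
                f"per_cell_f must broadcast to "
                f"{self.layout.n_rows} x {self.layout.n_cols}: {exc}"
            ) from exc
        if np.any(grid < 0) or np.any(grid > 0.9):
            raise InvalidInputError("per_cell_f must lie in [0, 0.9]")
        return grid

    def __post_init__(self) -> None:
        self.f_grid()
        for c in (self.tray_color, self.substrate_color, self.leaf_color):
            if min(c) < 0 or max(c) > 255:
                raise InvalidInputError("colors must lie in [0, 255]")


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise truth for one rendered tray."""

    pixel_counts: np.ndarray  # (n_rows, n_cols) int
    f: np.ndarray  # (n_rows, n_cols) float
    labels: np.ndarray  # (n_rows, n_cols) str
    leaf_mask: np.ndarray  # (H, W) uint8


def _leaf_blob(
    rng: np.random.Generator, height: int, width: int, k: int
) -> np.ndarray:
    """Boolean mask with exactly k True pixels, shaped like a leaf canopy.

    A sum of random Gaussian bumps centered in the middle of the cell is
    thresholded at its k-th largest value, which gives organic blob
    shapes with an exact pixel count.
    """
    mask = np.zeros((height, width), dtype=bool)
    if k <= 0:
        return mask
    yy, xx = np.mgrid[0:height, 0:width]
    fld = np.zeros((height, width))
    n_bumps = int(rng.integers(3, 7))
    for _ in range(n_bumps):
        cy = rng.uniform(0.25 * height, 0.75 * height)
        cx = rng.uniform(0.25 * width, 0.75 * width)
        sy = rng.uniform(height / 8, height / 3)
        sx = rng.uniform(width / 8, width / 3)
        amp = rng.uniform(0.5, 1.0)
        fld += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    flat = np.argpartition(fld.ravel(), -k)[-k:]
    mask.ravel()[flat] = True
    return mask


def generate_tray(spec: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one tray image and its ground truth.

    Deterministic for a fixed ``spec.rng_seed``.  Returns an 8-bit RGB
    array and the :class:`GroundTruth` computed from the clean leaf mask.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lay = spec.layout
    top, left, height, width = lay.region
    img_h, img_w = top + height + top, left + width + left
    f_grid = spec.f_grid()
    thresholds = ClassThresholds()

    # scene: tray everywhere, substrate ellipse per cell, leaf blobs on top
    scene = np.zeros((img_h, img_w), dtype=np.uint8)  # 0 tray, 1 substrate, 2 leaf
    leaf_mask = np.zeros((img_h, img_w), dtype=np.uint8)
    counts = np.zeros((lay.n_rows, lay.n_cols), dtype=np.int64)
    f_true = np.zeros((lay.n_rows, lay.n_cols))
    labels = np.empty((lay.n_rows, lay.n_cols), dtype=object)

    for row, col in lay.cells():
        r0, r1, c0, c1 = lay.cell_bounds(row, col)
        ch, cw = r1 - r0, c1 - c0
        yy, xx = np.mgrid[0:ch, 0:cw]
        ellipse = (
            ((yy - (ch - 1) / 2) / (0.42 * ch)) ** 2
            + ((xx - (cw - 1) / 2) / (0.42 * cw)) ** 2
        ) <= 1.0
        scene[r0:r1, c0:c1][ellipse] = 1

        k = int(round(f_grid[row - 1, col - 1] * ch * cw))
        blob = _leaf_blob(rng, ch, cw, k)
        scene[r0:r1, c0:c1][blob] = 2
        leaf_mask[r0:r1, c0:c1][blob] = 1
        counts[row - 1, col - 1] = k
        f_true[row - 1, col - 1] = k / (ch * cw)
        labels[row - 1, col - 1] = classify(f_true[row - 1, col - 1], thresholds)

    palette = np.array(
        [spec.tray_color, spec.substrate_color, spec.leaf_color], dtype=np.float64
    )
    img = palette[scene]
    if spec.color_jitter > 0:
        img += rng.normal(0.0, spec.color_jitter, img.shape)
    if spec.illumination_gradient > 0:
        g = spec.illumination_gradient
        ramp = np.linspace(0, 1, img_h)[:, None] + np.linspace(0, 1, img_w)[None, :]
        img *= (1.0 - g + g * ramp)[..., None]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        pixel_counts=counts, f=f_true, labels=labels, leaf_mask=leaf_mask
    )
    return img, truth


def generate_validation_group(
    n_trays: int,
    label_mix: dict[str, float],
    seed: int = 0,
    layout: TrayLayout | None = None,
    base_spec: SynthSpec | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate a labeled set of trays with a requested class composition.

    Cells across the whole set are assigned labels by largest-remainder
    rounding of ``label_mix`` (proportions summing to 1); each cell's
    true F is then drawn uniformly from that label's range in
    :data:`LABEL_F_RANGES`, and trays are rendered cell by cell.
    """
    if n_trays < 1:
        raise InvalidInputError("n_trays must be >= 1")
    if abs(sum(label_mix.values()) - 1.0) > 1e-9:
        raise InvalidInputError("label_mix proportions must sum to 1")
    unknown = set(label_mix) - set(LABEL_F_RANGES)
    if unknown:
        raise InvalidInputError(f"unknown labels in mix: {sorted(unknown)}")

    lay = layout or (base_spec.layout if base_spec else TrayLayout())
    rng = np.random.default_rng(seed)
    cells_total = n_trays * lay.n_rows * lay.n_cols

    # largest-remainder apportionment of cells to labels
    labels_order = [lab for lab in LABEL_F_RANGES if lab in label_mix]
    quotas = np.array([label_mix[lab] * cells_total for lab in labels_order])
    counts = np.floor(quotas).astype(int)
    rem = cells_total - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1

    assignment = np.repeat(labels_order, counts)
    rng.shuffle(assignment)

    out = []
    for t in range(n_trays):
        cell_labels = assignment[
            t * lay.n_rows * lay.n_cols : (t + 1) * lay.n_rows * lay.n_cols
        ]
        f_cells = np.array(
            [rng.uniform(*LABEL_F_RANGES[lab]) for lab in cell_labels]
        ).reshape(lay.n_rows, lay.n_cols)
        spec = base_spec or SynthSpec(layout=lay)
        spec = replace(
            spec,
            layout=lay,
            per_cell_f=f_cells,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_tray(spec))
    return out
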