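"""End-to-end identification pipeline and result serialization.

Stage order: color index -> gray-level rescale -> histogram -> GA
maximum-entropy thresholding -> binarization -> BM3D cleanup of the mask
(re-binarized at 0.5) -> per-cell pixel counting -> leaf area, F ratio,
class label and tray coordinate per cell.  With ``denoise_first`` the
BM3D stage instead runs on the gray image before thresholding.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bm3d import bm3d_denoise
from .config import PipelineConfig
from .ga_threshold import binarize, ga_optimize
from .preprocess import (
    compute_color_index,
    intensity_histogram,
    rescale_to_levels,
    to_grayscale,
)
from .sihvs import (
    LABELS,
    SeedlingRecord,
    area_ratio,
    cell_coordinate,
    classify,
    leaf_area,
    partition_cells,
)

logger = logging.getLogger(__name__)


def segment_image(image: np.ndarray, cfg: PipelineConfig):
    """Index, threshold and binarize one tray image.

    Returns ``(mask, ga_result)`` where the mask is the cleaned binary
    image (1 = seedling) and ``ga_result`` carries the optimal threshold
    pair, its entropy fitness and the number of GA generations run.
    """
    t0 = time.perf_counter()
    if cfg.index == "gray":
        gray = to_grayscale(image)
    else:
        gray = compute_color_index(image, cfg.index)
    if cfg.denoise and cfg.denoise_first:
        gray = bm3d_denoise(gray, cfg.bm3d, two_pass=cfg.two_pass).estimate
    levels = rescale_to_levels(gray)
    hist = intensity_histogram(levels)
    result = ga_optimize(hist, cfg.ga)
    mask = binarize(levels, result.pair, cfg.binarize_mode)
    if cfg.denoise and not cfg.denoise_first:
        est = bm3d_denoise(mask.astype(np.float64), cfg.bm3d, two_pass=cfg.two_pass)
        mask = (est.estimate >= 0.5).astype(np.uint8)
    logger.info(
        "segment: thresholds (%d, %d), fitness %.4f, %d generations, %.2fs",
        result.t1, result.t2, result.fitness, result.generations,
        time.perf_counter() - t0,
    )
    return mask, result


def run_pipeline(
    image: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[list[SeedlingRecord], dict]:
    """Identify the growth state of every tray cell in one image.

    Deterministic given ``cfg.seed``.  Returns one
    :class:`~seedlingvision.sihvs.SeedlingRecord` per cell (row-major)
    and a summary dict with the segmentation thresholds and the cell
    coordinates grouped by label.
    """
    cfg = cfg or PipelineConfig()
    mask, ga_result = segment_image(image, cfg)

    records = []
    for row, col, count in partition_cells(mask, cfg.layout):
        f = area_ratio(count, cfg.layout, row, col)
        x, y = cell_coordinate(row, col, cfg.layout)
        records.append(
            SeedlingRecord(
                row=row,
                col=col,
                x=x,
                y=y,
                pixel_count=count,
                leaf_area_mm2=leaf_area(count, cfg.layout),
                ratio=f,
                label=classify(f, cfg.thresholds),
            )
        )

    coords = {lab: [] for lab in LABELS}
    counts = {lab: 0 for lab in LABELS}
    for rec in records:
        coords[rec.label].append([rec.x, rec.y])
        counts[rec.label] += 1
    summary = {
        "thresholds": {"t1": ga_result.t1, "t2": ga_result.t2},
        "fitness": ga_result.fitness,
        "generations": ga_result.generations,
        "counts_by_label": counts,
        "coordinates_by_label": coords,
        "seed": cfg.seed,
    }
    return records, summary


def records_to_frame(records: Sequence[SeedlingRecord]) -> pd.DataFrame:
    """Tabulate records with F and leaf area reported at 2 decimals."""
    return pd.DataFrame(
        {
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "pixel_count": [r.pixel_count for r in records],
            "leaf_area_mm2": [round(r.leaf_area_mm2, 2) for r in records],
            "F": [round(r.ratio, 2) for r in records],
            "label": [r.label for r in records],
        }
    )


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def emit_results(
    records: Sequence[SeedlingRecord],
    summary: dict,
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the per-cell CSV and optional JSON summary atomically.

    Output is byte-identical across reruns with the same inputs (no
    timestamps); timings and thresholds go to the log instead.
    """
    csv_path = Path(csv_path)
    frame = records_to_frame(records)
    if frame.empty:
        logger.warning("no records to emit; writing header-only CSV")
        frame = pd.DataFrame(
            columns=["row", "col", "x", "y", "pixel_count", "leaf_area_mm2", "F", "label"]
        )
    _atomic_write(csv_path, frame.to_csv(index=False))
    if json_path is not None:
        _atomic_write(Path(json_path), json.dumps(summary, indent=2, sort_keys=True) + "\n")
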