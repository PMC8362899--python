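"""Smart identification of healthy vegetable seedlings (SIHVS).

Given a segmented binary mask of a plug tray, this module counts leaf
pixels per tray cell, converts counts to physical leaf area
(``M = K * P`` with ``K`` = tray area / tray pixels), forms the grading
statistic ``F`` = leaf pixels / cell pixels, and classifies every cell:

    healthy      F >  f_avg            (default 0.20)
    sub-healthy  f_min <= F <= f_avg   (default 0.16 .. 0.20)
    poor         f_empty <= F < f_min
    empty        F <  f_empty          (default 0.015)

Cells are addressed both by 1-based (row, col) and by the odd-lattice
tray coordinate (x, y) = (2*col - 1, 2*row - 1) with the origin at the
tray's upper-left corner, x rightward and y downward — the convention a
transplanting gantry consumes.

Also provided: calibration statistics over measured F groups, and the
identification-accuracy summary over actual-vs-identified class counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidInputError

LABELS = ("healthy", "sub_healthy", "poor", "empty")


@dataclass(frozen=True)
class ClassThresholds:
    """Decision boundaries on the leaf-cover ratio F."""

    f_avg: float = 0.20
    f_min: float = 0.16
    f_empty: float = 0.015

    def __post_init__(self) -> None:
        if not (self.f_empty < self.f_min < self.f_avg):
            raise InvalidInputError(
                "thresholds must satisfy f_empty < f_min < f_avg, got "
                f"{self.f_empty} / {self.f_min} / {self.f_avg}"
            )


@dataclass(frozen=True)
class TrayLayout:
    """Grid geometry of a plug tray inside an image.

    ``region`` is (top, left, height, width) in pixels; the grid of
    ``n_rows x n_cols`` cells tiles it by integer division, with the
    bottom row / rightmost column absorbing any remainder pixels.
    ``actual_tray_area_mm2`` sets the pixel-to-area scale
    K = tray area / tray pixel count.
    """

    n_rows: int = 3
    n_cols: int = 7
    region: tuple[int, int, int, int] = (16, 16, 144, 336)
    actual_tray_area_mm2: float = 129600.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and column")
        top, left, height, width = self.region
        if height < self.n_rows or width < self.n_cols:
            raise GeometryError("tray region too small for the grid")
        if self.actual_tray_area_mm2 <= 0:
            raise GeometryError("tray area must be positive")

    @property
    def scale_k(self) -> float:
        """mm^2 per pixel: physical tray area over tray pixel count."""
        _, _, height, width = self.region
        return self.actual_tray_area_mm2 / (height * width)

    def cell_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) pixel bounds of a 1-based cell; r1/c1 exclusive."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise GeometryError(f"cell ({row}, {col}) outside the grid")
        top, left, height, width = self.region
        ch, cw = height // self.n_rows, width // self.n_cols
        r0 = top + (row - 1) * ch
        c0 = left + (col - 1) * cw
        r1 = top + height if row == self.n_rows else r0 + ch
        c1 = left + width if col == self.n_cols else c0 + cw
        return r0, r1, c0, c1

    def cell_pixel_area(self, row: int, col: int) -> int:
        r0, r1, c0, c1 = self.cell_bounds(row, col)
        return (r1 - r0) * (c1 - c0)

    def cells(self) -> Iterable[tuple[int, int]]:
        for row in range(1, self.n_rows + 1):
            for col in range(1, self.n_cols + 1):
                yield row, col


def partition_cells(
    mask: np.ndarray, layout: TrayLayout
) -> list[tuple[int, int, int]]:
    """Count foreground (1) pixels per tray cell.

    Returns one ``(row, col, pixel_count)`` triple per cell in row-major
    order.  Every 1-pixel inside the tray region is counted exactly once.
    """
    arr = np.asarray(mask)
    top, left, height, width = layout.region
    if top < 0 or left < 0 or top + height > arr.shape[0] or left + width > arr.shape[1]:
        raise GeometryError("tray region extends outside the mask")
    out = []
    for row, col in layout.cells():
        r0, r1, c0, c1 = layout.cell_bounds(row, col)
        out.append((row, col, int(np.count_nonzero(arr[r0:r1, c0:c1]))))
    return out


def leaf_area(pixel_count: int, layout: TrayLayout) -> float:
    """Physical leaf area M = K * P in mm^2."""
    if pixel_count < 0:
        raise InvalidInputError("pixel_count must be >= 0")
    return layout.scale_k * pixel_count


def area_ratio(
    pixel_count: int, layout: TrayLayout, row: int = 1, col: int = 1
) -> float:
    """Leaf-cover ratio F = leaf pixels / cell pixels for one cell.

    The physical scale cancels, so F is dimensionless.  F can exceed 1
    only if leaves from neighboring cells spill in; the raw value is
    reported either way.
    """
    if pixel_count < 0:
        raise InvalidInputError("pixel_count must be >= 0")
    area = layout.cell_pixel_area(row, col)
    if area <= 0:
        raise GeometryError("cell has zero pixel area")
    return pixel_count / area


def classify(f: float, thresholds: ClassThresholds | None = None) -> str:
    """Map a leaf-cover ratio to a growth-state label.

    Boundary ties: F == f_avg and F == f_min are sub-healthy (the
    "greater than" of the healthy rule is strict, the sub-healthy band is
    closed); F == f_empty is poor (the empty rule "below" is strict).
    """
    th = thresholds or ClassThresholds()
    if f < 0:
        raise InvalidInputError("F must be >= 0")
    if f < th.f_empty:
        return "empty"
    if f > th.f_avg:
        return "healthy"
    if f >= th.f_min:
        return "sub_healthy"
    return "poor"


def cell_coordinate(row: int, col: int, layout: TrayLayout | None = None) -> tuple[int, int]:
    """Odd-lattice tray coordinate (x, y) = (2*col - 1, 2*row - 1).

    Origin at the tray's upper-left corner, x along the top edge
    rightward, y down the left edge.  Cell centers land on the odd
    lattice: a 7 x 3 tray spans x in 1..13 and y in 1..5.
    """
    lay = layout or TrayLayout()
    if not (1 <= row <= lay.n_rows and 1 <= col <= lay.n_cols):
        raise GeometryError(f"cell ({row}, {col}) outside the grid")
    return 2 * col - 1, 2 * row - 1


@dataclass(frozen=True)
class SeedlingRecord:
    """Per-cell grading result."""

    row: int
    col: int
    x: int
    y: int
    pixel_count: int
    leaf_area_mm2: float
    ratio: float
    label: str


# ---------------------------------------------------------------------------
# threshold calibration and accuracy evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationSummary:
    per_group: list[tuple[float, float, float]]  # (max, mean, min) per group
    pooled_max: float
    pooled_mean: float
    pooled_min: float


def calibrate_thresholds(groups: Sequence[Sequence[float]]) -> CalibrationSummary:
    """Max / mean / min of F per measurement group, plus pooled summary.

    The pooled summary is the mean of group means, the max of group
    maxima, and the min of group minima; all values are reported rounded
    to 2 decimals (matching how field calibration tables are recorded).
    """
    if not groups:
        raise InvalidInputError("need at least one group")
    per_group = []
    for g in groups:
        vals = np.asarray(list(g), dtype=np.float64)
        if vals.size == 0:
            raise InvalidInputError("empty calibration group")
        per_group.append(
            (round(float(vals.max()), 2), round(float(vals.mean()), 2), round(float(vals.min()), 2))
        )
    maxima, means, minima = zip(*per_group)
    return CalibrationSummary(
        per_group=per_group,
        pooled_max=round(max(maxima), 2),
        pooled_mean=round(float(np.mean(means)), 2),
        pooled_min=round(min(minima), 2),
    )


@dataclass(frozen=True)
class GroupCounts:
    """Actual vs identified class counts for one validation group."""

    name: str
    actual: dict[str, int]
    identified: dict[str, int]

    def __post_init__(self) -> None:
        for d in (self.actual, self.identified):
            if any(v < 0 for v in d.values()):
                raise InvalidInputError("counts must be >= 0")


def evaluate_accuracy(groups: Sequence[GroupCounts]) -> tuple[list[float], float]:
    """Healthy-seedling identification accuracy per group and on average.

    Per group: 100 * identified_healthy / actual_healthy, rounded to 2
    decimals; the average is the arithmetic mean of the per-group
    accuracies, also rounded to 2 decimals.
    """
    per_group = []
    for g in groups:
        actual = g.actual.get("healthy", 0)
        if actual <= 0:
            raise InvalidInputError(f"group {g.name}: no actual healthy seedlings")
        per_group.append(round(100.0 * g.identified.get("healthy", 0) / actual, 2))
    average = round(float(np.mean(per_group)), 2)
    return per_group, average


# ---------------------------------------------------------------------------
# bundled field-measurement tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("seedlingvision.data").joinpath(name)


def load_calibration_table() -> pd.DataFrame:
    """Bundled per-group F statistics of 20 pepper-seedling groups.

    Columns: group, f_max, f_avg, f_min — the recorded max / mean / min
    leaf-cover ratio of each calibration group (2,100 seedlings total).
    """
    with importlib.resources.as_file(_data_path("calibration_thresholds.csv")) as p:
        return pd.read_csv(p)


def load_grading_counts() -> pd.DataFrame:
    """Bundled actual and identified class counts for validation groups A-C.

    ``method`` is ``actual`` (ground truth), ``proposed`` (this
    pipeline's published counts) or ``comparison`` (a leaf-area baseline
    consumed as given numbers).
    """
    with importlib.resources.as_file(_data_path("grading_counts.csv")) as p:
        return pd.read_csv(p)


def grading_counts_to_groups(df: pd.DataFrame, method: str) -> list[GroupCounts]:
    """Pair the ``actual`` rows with one identification method's rows."""
    groups = []
    for name, sub in df.groupby("group", sort=True):
        actual = sub[sub["method"] == "actual"]
        ident = sub[sub["method"] == method]
        if len(actual) != 1 or len(ident) != 1:
            raise InvalidInputError(f"group {name}: missing actual/{method} rows")
        to_dict = lambda r: {lab: int(r.iloc[0][lab]) for lab in LABELS}
        groups.append(GroupCounts(name=str(name), actual=to_dict(actual), identified=to_dict(ident)))
    return groups
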