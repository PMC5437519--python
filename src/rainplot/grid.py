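"""Discretization of a rainfall series onto a fixed pixel grid.

A printed or on-screen rainfall plot is a W x H raster: the x-domain
``[0, total_length)`` and y-domain ``[0, y_max]`` are divided into equal
half-open bins and every point is floored into exactly one pixel (values at
the domain edge are clamped into the last pixel, so the mapping is total).
The default grid is 1000 x 351 pixels, a typical journal-figure resolution;
the default y_max is the log of the longest chromosome, the largest
possible within-chromosome gap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .transform import RainfallSeries

logger = logging.getLogger(__name__)

__all__ = ["PixelGrid", "project_to_grid", "x_to_col", "y_to_row"]

DEFAULT_WIDTH = 1000
DEFAULT_HEIGHT = 351


def x_to_col(x, total_length: float, width: int) -> np.ndarray:
    """Column index: floor(x / total_length * W), clamped to [0, W-1]."""
    col = np.floor(np.asarray(x, dtype=float) / total_length * width).astype(np.int64)
    return np.clip(col, 0, width - 1)


def y_to_row(y, y_max: float, height: int) -> np.ndarray:
    """Row index: floor(y / y_max * H), clamped to [0, H-1]."""
    row = np.floor(np.asarray(y, dtype=float) / y_max * height).astype(np.int64)
    return np.clip(row, 0, height - 1)


@dataclass
class PixelGrid:
    """Per-pixel event counts and category multisets of a projected series.

    ``counts`` is indexed ``[col, row]`` with row 0 at the bottom (shortest
    distances).  ``categories`` holds a Counter per occupied pixel of a
    categorized series.
    """

    counts: np.ndarray
    width: int
    height: int
    total_length: int
    y_max: float
    log_base: float = 10.0
    categories: dict[tuple[int, int], Counter] | None = None

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int((self.counts > 0).sum())

    def multi_category_pixels(self) -> list[tuple[int, int]]:
        """Pixels whose multiset holds >= 2 distinct categories."""
        if self.categories is None:
            return []
        return sorted(px for px, ctr in self.categories.items() if len(ctr) >= 2)

    def to_frame(self) -> pd.DataFrame:
        """Occupied pixels as a table (x_pixel, y_pixel, count, categories)."""
        cols, rows = np.nonzero(self.counts)
        order = np.lexsort((rows, cols))
        cols, rows = cols[order], rows[order]
        records = []
        for c, r in zip(cols, rows):
            cats = ""
            if self.categories is not None:
                ctr = self.categories.get((int(c), int(r)), Counter())
                cats = ",".join(f"{k}:{v}" for k, v in sorted(ctr.items()))
            records.append((int(c), int(r), int(self.counts[c, r]), cats))
        return pd.DataFrame(records, columns=["x_pixel", "y_pixel", "count", "categories"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def project_to_grid(
    series: RainfallSeries,
    layout: GenomeLayout | None = None,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    y_max: float | None = None,
    total_length: int | None = None,
) -> PixelGrid:
    """Project a rainfall series onto a W x H pixel grid.

    Either ``layout`` or ``total_length`` must be given; ``y_max`` defaults
    to the layout's log longest-chromosome length (or the series maximum
    when only a total length is known).  Points with y above ``y_max`` are
    clamped into the top row with a logged warning; total point count is
    always conserved.
    """
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    if layout is not None:
        total_length = layout.total_length
        if y_max is None:
            y_max = layout.default_y_max(series.log_base)
    if total_length is None:
        raise ValueError("a layout or an explicit total_length is required")
    if y_max is None:
        y_max = float(series.y.max()) if len(series) else 1.0
        y_max = max(y_max, 1.0)
    if y_max <= 0:
        raise ValueError("y_max must be positive")

    counts = np.zeros((width, height), dtype=np.int64)
    categories: dict[tuple[int, int], Counter] | None = (
        {} if series.categories is not None else None
    )
    if len(series):
        n_clamped = int((series.y > y_max).sum())
        if n_clamped:
            logger.warning(
                "%d point(s) above y_max=%.3f clamped into the top row", n_clamped, y_max
            )
        cols = x_to_col(series.x, total_length, width)
        rows = y_to_row(series.y, y_max, height)
        np.add.at(counts, (cols, rows), 1)
        if categories is not None:
            for c, r, cat in zip(cols, rows, series.categories):
                categories.setdefault((int(c), int(r)), Counter())[str(cat)] += 1
    return PixelGrid(
        counts=counts,
        width=width,
        height=height,
        total_length=int(total_length),
        y_max=float(y_max),
        log_base=series.log_base,
        categories=categories,
    )
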