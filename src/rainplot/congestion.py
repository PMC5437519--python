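"""Quantifying plot congestion: how many events can or do share a pixel.

On a discretized rainfall plot every pixel stands for a range of genomic
positions (one x-bin of ``total_length / W`` bp) and a range of inter-event
distances (one y-row of ``y_max / H`` log units).  Low rows represent few
(sometimes zero) integer distances but can hide many events in one pixel;
high rows represent millions of distinct distances but, because those
distances exceed the x-bin width, at most one event per pixel.  This module
computes that theoretical capacity profile, measures realized congestion in
data, and audits how plotting order would recolor contested pixels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import PixelGrid, y_to_row

__all__ = [
    "CongestionProfile",
    "capacity_profile",
    "CongestionReport",
    "congestion_map",
    "OrderAudit",
    "order_sensitivity_audit",
    "row_occupancy_bands",
]

#: label used for pixels that mix categories under the neutral-color policy
NEUTRAL_LABEL = "neutral"


# ---------------------------------------------------------------------------
# theoretical capacity
# ---------------------------------------------------------------------------

@dataclass
class CongestionProfile:
    """Per-row capacity of a W x H grid.

    ``distinct_distances[j]`` is the number of integer bp distances
    ``d >= 1`` whose log maps into row ``j``; ``min_distance[j]`` the
    smallest of them (0 when the row represents none); ``max_overlap[j]``
    the largest number of events that could be packed into one x-bin with
    every consecutive gap mapping to row ``j`` — the worst-case congestion,
    ``floor(bin_width / min_distance) + 1``.
    """

    width: int
    height: int
    y_max: float
    total_length: int
    log_base: float
    distinct_distances: np.ndarray
    min_distance: np.ndarray
    max_overlap: np.ndarray

    @property
    def bin_width(self) -> float:
        """Width of one x-bin in bp."""
        return self.total_length / self.width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y_pixel": np.arange(self.height),
                "distinct_distances": self.distinct_distances,
                "min_distance": self.min_distance,
                "max_overlap": self.max_overlap,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _max_representable_distance(y_max: float, log_base: float) -> int:
    """Largest integer distance on the y-axis, ``floor(base ** y_max)``,
    tolerant of float error when y_max is the log of an integer length."""
    v = float(log_base) ** float(y_max)
    r = round(v)
    if abs(v - r) <= 1e-6 * max(1.0, abs(v)):
        return int(r)
    return int(np.floor(v))


def capacity_profile(
    width: int,
    height: int,
    y_max: float,
    total_length: int,
    log_base: float = 10.0,
) -> CongestionProfile:
    """Theoretical congestion capacity of a grid, row by row.

    Uses the same floor-and-clamp row mapping as :func:`~rainplot.grid.
    project_to_grid`, so the profile describes exactly the grid the data
    would land on.  Row boundaries in integer-distance space are located by
    binary search on the (monotone) mapping, which keeps the profile exact
    for genome-scale ``y_max`` without enumerating ~10^8 distances.
    """
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    if y_max <= 0 or total_length < 1:
        raise ValueError("y_max and total_length must be positive")

    d_max = _max_representable_distance(y_max, log_base)

    def row_of(d: int) -> int:
        if log_base == 10.0:
            y = np.log10(float(d))
        else:
            y = np.log(float(d)) / np.log(log_base)
        return int(y_to_row(y, y_max, height))

    def first_distance_at_or_above(j: int) -> int:
        """Smallest d in [1, d_max] with row_of(d) >= j, else d_max + 1."""
        if row_of(d_max) < j:
            return d_max + 1
        lo, hi = 1, d_max
        while lo < hi:
            mid = (lo + hi) // 2
            if row_of(mid) >= j:
                hi = mid
            else:
                lo = mid + 1
        return lo

    boundaries = [first_distance_at_or_above(j) for j in range(height)]
    boundaries.append(d_max + 1)

    distinct = np.zeros(height, dtype=np.int64)
    dmin = np.zeros(height, dtype=np.int64)
    overlap = np.zeros(height, dtype=np.int64)
    bin_width = total_length / width
    for j in range(height):
        n = boundaries[j + 1] - boundaries[j]
        if n > 0:
            distinct[j] = n
            dmin[j] = boundaries[j]
            overlap[j] = int(bin_width // boundaries[j]) + 1
    return CongestionProfile(
        width=width,
        height=height,
        y_max=float(y_max),
        total_length=int(total_length),
        log_base=float(log_base),
        distinct_distances=distinct,
        min_distance=dmin,
        max_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# realized congestion
# ---------------------------------------------------------------------------

@dataclass
class CongestionReport:
    """Realized per-pixel multiplicity of a populated grid."""

    width: int
    height: int
    n_points: int
    max_count: int
    n_occupied: int
    saturation: float                     # occupied pixels / (W * H)
    count_histogram: dict[int, int]       # per-pixel count -> number of pixels
    congested: pd.DataFrame               # pixels with count >= 2

    def to_tsv(self, path) -> None:
        self.congested.to_csv(path, sep="\t", index=False)


def congestion_map(grid: PixelGrid) -> CongestionReport:
    """Where, and how badly, events overlap in this grid.

    Congested pixels are those receiving >= 2 points; the histogram covers
    all occupied pixels and the saturation fraction is occupied / (W*H).
    """
    counts = grid.counts
    occupied = counts[counts > 0]
    hist = dict(sorted(Counter(occupied.tolist()).items()))
    cols, rows = np.nonzero(counts >= 2)
    order = np.lexsort((rows, cols))
    congested = pd.DataFrame(
        {
            "x_pixel": cols[order],
            "y_pixel": rows[order],
            "count": counts[cols[order], rows[order]],
        }
    )
    return CongestionReport(
        width=grid.width,
        height=grid.height,
        n_points=grid.n_points,
        max_count=int(counts.max()) if counts.size else 0,
        n_occupied=int((counts > 0).sum()),
        saturation=float((counts > 0).mean()),
        count_histogram=hist,
        congested=congested,
    )


# ---------------------------------------------------------------------------
# plotting-order sensitivity
# ---------------------------------------------------------------------------

@dataclass
class OrderAudit:
    """Which category 'wins' each contested pixel under each plotting order.

    Under naive last-drawn-wins rendering the color of a multi-category
    pixel depends on the (in principle arbitrary) order in which categories
    are plotted; under the neutral-color policy every such pixel is drawn
    in a neutral color and the rendering is order-invariant.
    """

    orders: dict[str, tuple[str, ...]]
    table: pd.DataFrame                # one row per multi-category pixel
    summary: pd.DataFrame              # per-category win/uncontested counts
    n_multi_category: int
    n_order_sensitive: int             # pixels whose winner differs across orders

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def order_sensitivity_audit(
    grid: PixelGrid,
    orders: Mapping[str, Sequence[str]] | None = None,
) -> OrderAudit:
    """Audit how plotting order would recolor the grid's contested pixels.

    Parameters
    ----------
    orders : mapping of name -> category plotting order, optional
        Defaults to the sorted category list ("by-category") and its
        reverse — the two orders that swap every contested pixel.
    """
    if grid.categories is None:
        raise ValueError("grid carries no categories")
    all_cats = sorted({c for ctr in grid.categories.values() for c in ctr})
    if orders is None:
        orders = {
            "by-category": tuple(all_cats),
            "reverse": tuple(reversed(all_cats)),
        }
    orders = {name: tuple(seq) for name, seq in orders.items()}
    for name, seq in orders.items():
        missing = set(all_cats) - set(seq)
        if missing:
            raise ValueError(f"order {name!r} omits categories {sorted(missing)}")

    def winner(order: tuple[str, ...], present: set[str]) -> str:
        # last-plotted category present at the pixel is drawn on top
        return max(present, key=order.index)

    records = []
    for (c, r), ctr in sorted(grid.categories.items()):
        present = set(ctr)
        if len(present) < 2:
            continue
        row: dict[str, object] = {
            "x_pixel": c,
            "y_pixel": r,
            "n_events": sum(ctr.values()),
            "categories": ",".join(sorted(present)),
            "neutral": NEUTRAL_LABEL,
        }
        for name, seq in orders.items():
            row[f"winner[{name}]"] = winner(seq, present)
        records.append(row)
    table = pd.DataFrame(records)

    n_multi = len(records)
    if n_multi:
        win_cols = [f"winner[{name}]" for name in orders]
        n_sensitive = int((table[win_cols].nunique(axis=1) > 1).sum())
    else:
        n_sensitive = 0

    uncontested = Counter()
    for ctr in grid.categories.values():
        if len(ctr) == 1:
            uncontested[next(iter(ctr))] += 1
    summary_rows = []
    for cat in all_cats:
        row = {"category": cat, "uncontested_pixels": uncontested.get(cat, 0)}
        for name in orders:
            if n_multi:
                row[f"wins[{name}]"] = int((table[f"winner[{name}]"] == cat).sum())
            else:
                row[f"wins[{name}]"] = 0
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    return OrderAudit(
        orders=orders,
        table=table,
        summary=summary,
        n_multi_category=n_multi,
        n_order_sensitive=n_sensitive,
    )


# ---------------------------------------------------------------------------
# band structure of row occupancy
# ---------------------------------------------------------------------------

def row_occupancy_bands(
    grid: PixelGrid,
    threshold_fraction: float = 0.1,
    smooth_rows: int | None = None,
) -> list[tuple[int, int]]:
    """Horizontal bands of a grid: maximal runs of well-occupied rows.

    Only *representable* rows — those whose distance range contains at
    least one integer (see :func:`capacity_profile`) — can ever hold a
    point, so band detection works on that subsequence: unrepresentable
    rows neither break nor extend a band.  Representable row totals are
    boxcar-smoothed (default window: 1/50 of the representable rows) and
    thresholded at ``threshold_fraction`` of the smoothed maximum; each
    maximal run above threshold is one band, returned as inclusive
    ``(first_row, last_row)`` pairs in grid coordinates.  Runs narrower
    than the smoothing window are below the resolution of the analysis and
    are discarded.  Recurrent
    distance enrichment at two scales (e.g. a two-state hidden Markov
    point process) shows up as two disjoint bands.
    """
    totals = grid.counts.sum(axis=0).astype(float)
    profile = capacity_profile(
        grid.width, grid.height, grid.y_max, grid.total_length, grid.log_base
    )
    idx = np.nonzero(profile.distinct_distances > 0)[0]
    if len(idx) == 0:
        return []
    vals = totals[idx]
    if smooth_rows is None:
        smooth_rows = max(1, len(idx) // 50)
    if smooth_rows > 1:
        kernel = np.ones(smooth_rows) / smooth_rows
        vals = np.convolve(vals, kernel, mode="same")
    if vals.max() <= 0:
        return []
    above = vals >= threshold_fraction * vals.max()
    runs: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(above):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return [
        (int(idx[a]), int(idx[b])) for a, b in runs if b - a + 1 >= smooth_rows
    ]
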