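"""Order-invariant rendering of rainfall and frequency figures.

The acceptance surface of a rendered rainfall plot is its *pixel-assignment
table* — one row per occupied pixel with the category (hence color) it
receives — not the encoded image bytes.  Two policies are implemented:

``neutral`` (default)
    A pixel receiving events of two or more categories is drawn in a
    neutral color.  The assignment is a pure function of the pixel's
    category multiset, so the rendering is invariant to plotting order.

``naive``
    Points are drawn in a configured order and the last one wins, which is
    how most plotting libraries behave; with congested data the resulting
    colors depend on that order and can misrepresent which category
    dominates.  Kept to reproduce the pitfall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib import colors as mcolors
from matplotlib.figure import Figure

from .congestion import NEUTRAL_LABEL, congestion_map
from .frequency import FrequencyTrack
from .genome import GenomeLayout
from .grid import DEFAULT_HEIGHT, DEFAULT_WIDTH, project_to_grid, x_to_col, y_to_row
from .transform import RainfallSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "RenderConfig",
    "pixel_assignments",
    "render_rainfall",
    "render_frequency",
]

#: label used for points of an uncategorized series
UNLABELED = "events"

_AUTO_PALETTE = [f"C{i}" for i in range(10)]


class ConfigError(ValueError):
    """Invalid rendering configuration."""


@dataclass
class RenderConfig:
    """Rendering parameters for rainfall / frequency figures.

    ``colors`` maps category label to a matplotlib color; when omitted, a
    palette is assigned to the sorted category labels.  ``point_order``
    only matters in naive mode: "genomic" (by position), "by-category"
    (categories plotted one after another, in ``colors``/sorted order),
    "reverse" (that order reversed), or "as-given" (input order).
    """

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    log_base: float = 10.0
    colors: Mapping[str, str] | None = None
    neutral_color: str = "black"
    mode: str = "neutral"              # "neutral" | "naive"
    point_order: str = "genomic"       # genomic | by-category | reverse | as-given
    show_chromosome_boundaries: bool = True
    highlight_congestion: bool = False
    y_max: float | None = None
    point_size: float = 1.0            # glyph size in pixels; >1 adds congestion

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "naive"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.point_order not in ("genomic", "by-category", "reverse", "as-given"):
            raise ConfigError(f"unknown point_order {self.point_order!r}")
        if self.colors is not None:
            neutral = mcolors.to_hex(self.neutral_color)
            for cat, color in self.colors.items():
                if mcolors.to_hex(color) == neutral:
                    raise ConfigError(
                        f"category {cat!r} uses the neutral color {self.neutral_color!r}"
                    )

    def color_table(self, categories: tuple[str, ...]) -> dict[str, str]:
        """Resolve a color for every category, erroring on unknown ones."""
        if self.colors is None:
            table = {
                cat: _AUTO_PALETTE[i % len(_AUTO_PALETTE)]
                for i, cat in enumerate(sorted(categories))
            }
        else:
            missing = [c for c in categories if c not in self.colors]
            if missing:
                raise ConfigError(f"no color configured for categories {missing}")
            table = dict(self.colors)
        table[NEUTRAL_LABEL] = self.neutral_color
        return table


def _series_categories(series: RainfallSeries) -> np.ndarray:
    if series.categories is not None:
        return series.categories.astype(object)
    return np.full(len(series), UNLABELED, dtype=object)


def pixel_assignments(
    series: RainfallSeries,
    layout: GenomeLayout | None,
    config: RenderConfig,
    total_length: int | None = None,
) -> pd.DataFrame:
    """Resolve the category drawn at each occupied pixel.

    Returns a DataFrame ``(x_pixel, y_pixel, category)`` sorted by pixel.
    Neutral mode depends only on each pixel's category multiset; naive mode
    replays last-drawn-wins under ``config.point_order``.
    """
    if layout is not None:
        total_length = layout.total_length
        y_max = config.y_max if config.y_max is not None else layout.default_y_max(config.log_base)
    else:
        if total_length is None:
            raise ValueError("a layout or total_length is required")
        y_max = config.y_max
        if y_max is None:
            y_max = max(float(series.y.max()), 1.0) if len(series) else 1.0

    if len(series) == 0:
        return pd.DataFrame(columns=["x_pixel", "y_pixel", "category"])

    cats = _series_categories(series)
    cols = x_to_col(series.x, total_length, config.width)
    rows = y_to_row(series.y, y_max, config.height)
    df = pd.DataFrame({"x_pixel": cols, "y_pixel": rows, "category": cats})

    if config.mode == "neutral":
        def resolve(group: pd.Series) -> str:
            distinct = set(group)
            return next(iter(distinct)) if len(distinct) == 1 else NEUTRAL_LABEL

        out = (
            df.groupby(["x_pixel", "y_pixel"], sort=True)["category"]
            .apply(resolve)
            .reset_index()
        )
    else:
        order = config.point_order
        if order == "genomic":
            df = df.sort_values("x_pixel", kind="stable")
        elif order in ("by-category", "reverse"):
            if config.colors is not None:
                rank = {c: i for i, c in enumerate(config.colors)}
            else:
                rank = {c: i for i, c in enumerate(sorted(set(cats)))}
            key = df["category"].map(rank)
            df = df.iloc[np.argsort(key.to_numpy(), kind="stable")]
            if order == "reverse":
                df = df.iloc[::-1]
        # "as-given": leave input order
        out = (
            df.drop_duplicates(["x_pixel", "y_pixel"], keep="last")
            .sort_values(["x_pixel", "y_pixel"], kind="stable")
            .reset_index(drop=True)
        )
    return out[["x_pixel", "y_pixel", "category"]].reset_index(drop=True)


def _raster(table: pd.DataFrame, config: RenderConfig, color_of: dict[str, str]) -> np.ndarray:
    img = np.ones((config.height, config.width, 3))
    for row in table.itertuples(index=False):
        try:
            rgb = mcolors.to_rgb(color_of[row.category])
        except KeyError as exc:
            raise ConfigError(f"no color for category {row.category!r}") from exc
        img[row.y_pixel, row.x_pixel] = rgb
    return img


def render_rainfall(
    series: RainfallSeries,
    layout: GenomeLayout,
    config: RenderConfig | None = None,
    path=None,
    pixel_table_path=None,
) -> tuple[Figure, pd.DataFrame]:
    """Render a rainfall figure and its pixel-assignment table.

    The figure shows the W x H raster on the global axis with light
    vertical rules at chromosome boundaries and a log-scaled y-axis
    annotated in bp.  An empty series yields a valid empty-axes figure.
    Returns ``(figure, pixel_table)``; writes the image and/or table when
    paths are given.
    """
    config = config or RenderConfig()
    y_max = config.y_max if config.y_max is not None else layout.default_y_max(config.log_base)

    table = pixel_assignments(series, layout, config)
    present = tuple(sorted(set(table["category"]) - {NEUTRAL_LABEL}))
    color_of = config.color_table(present)
    img = _raster(table, config, color_of)

    fig = Figure(figsize=(10.0, 10.0 * config.height / config.width * 1.6))
    ax = fig.add_subplot(111)
    ax.imshow(
        img,
        origin="lower",
        extent=(0, layout.total_length, 0, y_max),
        aspect="auto",
        interpolation="nearest",
    )
    if config.show_chromosome_boundaries:
        for off in layout.offsets[1:]:
            ax.axvline(off, color="0.85", linewidth=0.5, zorder=0)
    if config.highlight_congestion:
        grid = project_to_grid(
            series, layout, width=config.width, height=config.height, y_max=y_max
        )
        report = congestion_map(grid)
        if len(report.congested):
            cx = (report.congested["x_pixel"].to_numpy() + 0.5) / config.width * layout.total_length
            cy = (report.congested["y_pixel"].to_numpy() + 0.5) / config.height * y_max
            ax.scatter(cx, cy, s=30, facecolors="none", edgecolors="red",
                       linewidths=0.6, label="congested pixel")
    ticks = np.arange(0, int(np.floor(y_max)) + 1)
    ax.set_yticks(ticks)
    ax.set_yticklabels([f"$10^{{{int(t)}}}$" for t in ticks])
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel(f"inter-event distance (bp, log base {config.log_base:g})")
    ax.set_xlim(0, layout.total_length)
    ax.set_ylim(0, y_max)
    if path is not None:
        fig.savefig(path, dpi=100)
    if pixel_table_path is not None:
        table.to_csv(pixel_table_path, sep="\t", index=False)
    return fig, table


def render_frequency(
    freq: FrequencyTrack,
    config: RenderConfig | None = None,
    path=None,
) -> Figure:
    """Render a frequency line plot (counts per bin along the genome).

    The figure footer prints the total event count, which always equals
    the track size.
    """
    config = config or RenderConfig()
    fig = Figure(figsize=(10.0, 3.0))
    ax = fig.add_subplot(111)
    mids = (freq.starts + freq.ends) / 2.0
    ax.plot(mids, freq.counts, linewidth=0.8, color="steelblue")
    if config.show_chromosome_boundaries:
        for off in freq.layout.offsets[1:]:
            ax.axvline(off, color="0.85", linewidth=0.5, zorder=0)
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel(f"events per {freq.bin_size:,} bp bin")
    ax.set_xlim(0, freq.layout.total_length)
    fig.text(0.01, 0.01, f"total events: {freq.total}", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
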