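"""The rainfall transform.

For a strictly increasing position sequence ``p_1 < ... < p_N`` the rainfall
transform is the point set ``{(x_i, y_i)}`` with

    x_i = p_{i+1}
    y_i = log_b(p_{i+1} - p_i)          i = 1 .. N-1

i.e. each event is plotted at its own position against the log distance to
its predecessor.  N events yield exactly N-1 points.  The default base is
b = 10, so a band at y = 2 reads as a typical inter-event distance of
10^2 = 100 bp, the signature of a Poisson intensity of 0.01 events/bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import EventTrack, GenomeLayout

__all__ = ["RainfallSeries", "rainfall_transform", "genome_rainfall"]


def _log_base(values: np.ndarray, base: float) -> np.ndarray:
    # exact results for the common bases (log10(100) == 2.0 exactly)
    if base == 10.0:
        return np.log10(values)
    if base == 2.0:
        return np.log2(values)
    return np.log(values) / np.log(base)


@dataclass
class RainfallSeries:
    """The (x, y) point set of a rainfall transform.

    Attributes
    ----------
    x : ndarray of int64
        Plotted positions (global bp when produced by :func:`genome_rainfall`).
    y : ndarray of float
        Log inter-event distances, base ``log_base``; all >= 0 for integer
        positions, with y == 0 exactly for a 1 bp gap.
    categories : ndarray of object, optional
        Label carried by each point (see ``attach`` in the transforms).
    chroms : ndarray of object, optional
        Source chromosome of each point.
    """

    x: np.ndarray
    y: np.ndarray
    log_base: float = 10.0
    categories: np.ndarray | None = None
    chroms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y differ in length")
        for name in ("categories", "chroms"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.x):
                raise ValueError(f"{name} length does not match points")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def distances(self) -> np.ndarray:
        """Inter-event distances in bp (``log_base ** y``)."""
        return np.power(self.log_base, self.y)

    def mean_distance(self) -> float:
        """Arithmetic mean inter-event distance in bp."""
        if len(self) == 0:
            raise ValueError("empty series has no mean distance")
        return float(self.distances.mean())

    def implied_intensity(self) -> float:
        """Poisson intensity read off the plot: 1 / mean inter-event distance.

        For a homogeneous Poisson process the expected distance is 1/lambda,
        so a cloud of points with mean gap 100 bp reads as lambda = 0.01.
        """
        return 1.0 / self.mean_distance()

    def categorized(self) -> bool:
        return self.categories is not None


def rainfall_transform(
    positions,
    log_base: float = 10.0,
    categories=None,
    attach: str = "later",
) -> RainfallSeries:
    """Rainfall transform of a single chromosome's positions.

    Parameters
    ----------
    positions : strictly increasing sequence of int
    log_base : float > 1
    categories : sequence, optional
        One label per event.
    attach : {"later", "earlier"}
        Which event of each consecutive pair donates its label to the
        plotted point.  The point sits at the later event's position
        (x = p_{i+1}), so "later" is the default.

    Returns
    -------
    RainfallSeries with exactly ``len(positions) - 1`` points
    (empty for a single event).
    """
    if log_base <= 1.0:
        raise ValueError("log_base must be > 1")
    if attach not in ("later", "earlier"):
        raise ValueError("attach must be 'later' or 'earlier'")
    p = np.asarray(positions, dtype=np.int64)
    if p.ndim != 1:
        raise ValueError("positions must be one-dimensional")
    gaps = np.diff(p)
    if np.any(gaps <= 0):
        raise ValueError("positions must be strictly increasing")
    cats = None
    if categories is not None:
        cats = np.asarray(list(categories), dtype=object)
        if len(cats) != len(p):
            raise ValueError("one category per event required")
        cats = cats[1:] if attach == "later" else cats[:-1]
    y = _log_base(gaps.astype(float), log_base) if len(gaps) else np.empty(0)
    return RainfallSeries(x=p[1:], y=y, log_base=log_base, categories=cats)


def genome_rainfall(
    track: EventTrack,
    layout: GenomeLayout,
    log_base: float = 10.0,
    attach: str = "later",
) -> RainfallSeries:
    """Whole-genome rainfall transform on the concatenated axis.

    Each chromosome is transformed independently and shifted by its global
    offset; no distance ever spans a chromosome boundary (such a gap is
    biologically meaningless), so the first event of every chromosome is
    consumed without producing a point.  An empty track yields an empty
    series.
    """
    track.validate_against(layout)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    cat_parts: list[np.ndarray] = []
    chrom_parts: list[np.ndarray] = []
    for name in layout.names:
        pos = track.positions.get(name)
        if pos is None or len(pos) < 2:
            continue
        cats = track.categories[name] if track.categories is not None else None
        sub = rainfall_transform(pos, log_base=log_base, categories=cats, attach=attach)
        xs.append(sub.x + layout.offset_of(name))
        ys.append(sub.y)
        chrom_parts.append(np.full(len(sub), name, dtype=object))
        if sub.categories is not None:
            cat_parts.append(sub.categories)
    if not xs:
        return RainfallSeries(
            x=np.empty(0, dtype=np.int64),
            y=np.empty(0),
            log_base=log_base,
            categories=np.empty(0, dtype=object) if track.categorized else None,
            chroms=np.empty(0, dtype=object),
        )
    return RainfallSeries(
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        log_base=log_base,
        categories=np.concatenate(cat_parts) if track.categorized else None,
        chroms=np.concatenate(chrom_parts),
    )
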