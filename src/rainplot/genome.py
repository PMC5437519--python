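"""Genome coordinate system and event-track I/O.

The whole-genome x-axis of a rainfall or frequency plot is built by laying
the chromosomes end to end in a user-chosen order; every event position is
then shifted by the cumulative length of the preceding chromosomes.  All
coordinates are 0-based, half-open (BED native).  Any 1-based dialect must
be converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GenomeLayout",
    "EventTrack",
    "GlobalEvents",
    "read_chrom_sizes",
    "read_bed_events",
    "write_bed_events",
    "globalize",
    "HG19_CHROM_SIZES",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


#: GRCh37/hg19 chromosome lengths in karyotype order (autosomes, X, Y).
#: Bundled so that whole-genome examples need no external download.
HG19_CHROM_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 249250621), ("chr2", 243199373), ("chr3", 198022430),
    ("chr4", 191154276), ("chr5", 180915260), ("chr6", 171115067),
    ("chr7", 159138663), ("chr8", 146364022), ("chr9", 141213431),
    ("chr10", 135534747), ("chr11", 135006516), ("chr12", 133851895),
    ("chr13", 115169878), ("chr14", 107349540), ("chr15", 102531392),
    ("chr16", 90354753), ("chr17", 81195210), ("chr18", 78077248),
    ("chr19", 59128983), ("chr20", 63025520), ("chr21", 48129895),
    ("chr22", 51304566), ("chrX", 155270560), ("chrY", 59373566),
)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, defining the global plot axis.

    Chromosome order is taken verbatim from the input (no karyotype
    re-sorting): the user controls the x-axis layout.

    Parameters
    ----------
    names : tuple of str
        Chromosome names, in plotting order.
    lengths : tuple of int
        Chromosome lengths in bp; must be positive.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise FormatError("no chromosomes")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate chromosome name")
        for name, length in zip(self.names, self.lengths):
            if int(length) <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")

    # -- derived geometry ------------------------------------------------

    @property
    def offsets(self) -> np.ndarray:
        """Global start coordinate of each chromosome (bp)."""
        lengths = np.asarray(self.lengths, dtype=np.int64)
        return np.concatenate(([0], np.cumsum(lengths)[:-1]))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def max_length(self) -> int:
        """Length of the longest chromosome (bp)."""
        return int(max(self.lengths))

    def default_y_max(self, log_base: float = 10.0) -> float:
        """Default y-axis span: log of the longest chromosome length.

        No within-chromosome inter-event distance can exceed the longest
        chromosome, so this bounds every rainfall y-value.
        """
        return float(np.log(self.max_length) / np.log(log_base))

    # -- lookups ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)

    def length_of(self, name: str) -> int:
        return int(self.lengths[self.index(name)])

    def offset_of(self, name: str) -> int:
        return int(self.offsets[self.index(name)])

    # -- construction / I/O ----------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        names, lengths = zip(*pairs)
        return cls(tuple(names), tuple(int(x) for x in lengths))

    @classmethod
    def hg19(cls) -> "GenomeLayout":
        """The bundled GRCh37/hg19 layout (24 chromosomes, ~3.1 Gbp)."""
        return cls.from_pairs(HG19_CHROM_SIZES)

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeLayout":
        return read_chrom_sizes(path)

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a UCSC-style chrom.sizes file (two whitespace-separated columns).

    File order is preserved.  Malformed lines, non-positive lengths and
    duplicate names raise :class:`FormatError` naming the offending line.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 'name length'")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: length {parts[1]!r} is not an integer"
                ) from exc
            if length <= 0:
                raise FormatError(
                    f"{path}: line {lineno}: non-positive length for {name!r}"
                )
            if name in names:
                raise FormatError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(names), tuple(lengths))


@dataclass
class EventTrack:
    """Per-chromosome strictly increasing event positions, optionally labelled.

    ``positions`` maps chromosome name to a sorted ``int64`` array of 0-based
    positions.  ``categories`` (optional) maps chromosome name to an equal
    length object array of labels, e.g. the six pyrimidine-context
    substitution types C>A ... T>G.

    Duplicate positions on one chromosome violate the strictly-increasing
    premise of the rainfall transform (a zero distance has no logarithm) and
    are dropped at construction with a logged warning, keeping the first
    occurrence.
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, np.ndarray] | None = None

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dict(
        cls,
        events: Mapping[str, Sequence[int]],
        categories: Mapping[str, Sequence[str]] | None = None,
    ) -> "EventTrack":
        """Build a track from raw per-chromosome positions, sorting and
        deduplicating as declared."""
        pos_out: dict[str, np.ndarray] = {}
        cat_out: dict[str, np.ndarray] | None = {} if categories is not None else None
        n_dup = 0
        for chrom, raw in events.items():
            pos = np.asarray(raw, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            cats = None
            if categories is not None:
                cats = np.asarray(list(categories[chrom]), dtype=object)
                if len(cats) != len(pos):
                    raise ValueError(f"{chrom}: {len(cats)} categories for {len(pos)} events")
                cats = cats[order]
            if len(pos):
                keep = np.concatenate(([True], np.diff(pos) > 0))
                n_dup += int((~keep).sum())
                pos = pos[keep]
                if cats is not None:
                    cats = cats[keep]
            pos_out[chrom] = pos
            if cat_out is not None:
                cat_out[chrom] = cats if cats is not None else np.empty(0, dtype=object)
        if n_dup:
            logger.warning("dropped %d duplicate event position(s)", n_dup)
        return cls(pos_out, cat_out)

    # -- basic properties ------------------------------------------------

    @property
    def n_events(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.positions)

    @property
    def categorized(self) -> bool:
        return self.categories is not None

    def category_values(self) -> tuple[str, ...]:
        """Sorted distinct category labels present in the track."""
        if self.categories is None:
            return ()
        seen: set[str] = set()
        for arr in self.categories.values():
            seen.update(map(str, arr))
        return tuple(sorted(seen))

    # -- validation ------------------------------------------------------

    def validate_against(self, layout: GenomeLayout) -> None:
        """Check chromosome membership, bounds and strict monotonicity."""
        for chrom, pos in self.positions.items():
            if chrom not in layout:
                raise ValueError(f"chromosome {chrom!r} not in layout")
            if len(pos) == 0:
                continue
            if pos[0] < 0:
                raise ValueError(f"{chrom}: negative position {pos[0]}")
            if pos[-1] >= layout.length_of(chrom):
                raise ValueError(
                    f"{chrom}: position {int(pos[-1])} beyond chromosome length "
                    f"{layout.length_of(chrom)}"
                )
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")


class GlobalEvents(NamedTuple):
    """Events mapped onto the concatenated whole-genome axis."""

    positions: np.ndarray          # global bp, ascending
    categories: np.ndarray | None  # aligned labels, or None
    chroms: np.ndarray             # chromosome of origin per event


def globalize(track: EventTrack, layout: GenomeLayout) -> GlobalEvents:
    """Map per-chromosome positions onto the global axis: ``offset(c) + p``.

    Output is ascending because chromosomes are traversed in layout order
    and positions are sorted within each chromosome.  The chromosome of
    origin is retained so downstream code never computes a distance across
    a boundary.
    """
    track.validate_against(layout)
    pos_parts: list[np.ndarray] = []
    cat_parts: list[np.ndarray] = []
    chrom_parts: list[np.ndarray] = []
    for name in layout.names:
        pos = track.positions.get(name)
        if pos is None or len(pos) == 0:
            continue
        pos_parts.append(pos + layout.offset_of(name))
        chrom_parts.append(np.full(len(pos), name, dtype=object))
        if track.categories is not None:
            cat_parts.append(track.categories[name])
    if not pos_parts:
        return GlobalEvents(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object) if track.categorized else None,
            np.empty(0, dtype=object),
        )
    return GlobalEvents(
        np.concatenate(pos_parts),
        np.concatenate(cat_parts) if track.categorized else None,
        np.concatenate(chrom_parts),
    )


def read_bed_events(
    path,
    layout: GenomeLayout,
    category_column: int | None = None,
) -> EventTrack:
    """Read point events from a BED file (3+ columns, tab or space separated).

    The event position is the BED start (0-based, half-open).  Records on
    chromosomes absent from ``layout`` are skipped with a logged count.

    Parameters
    ----------
    category_column : int, optional
        0-based column index holding the per-event category label
        (e.g. column 3 for a ``chrom start end C>A`` file).
    """
    positions: dict[str, list[int]] = {}
    cats: dict[str, list[str]] = {}
    skipped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            if start < 0:
                raise FormatError(f"{path}: line {lineno}: negative start {start}")
            if chrom not in layout:
                skipped[chrom] = skipped.get(chrom, 0) + 1
                continue
            if start >= layout.length_of(chrom):
                raise FormatError(
                    f"{path}: line {lineno}: start {start} beyond {chrom!r} length "
                    f"{layout.length_of(chrom)}"
                )
            positions.setdefault(chrom, []).append(start)
            if category_column is not None:
                if category_column >= len(parts):
                    raise FormatError(
                        f"{path}: line {lineno}: no column {category_column}"
                    )
                cats.setdefault(chrom, []).append(parts[category_column])
    if skipped:
        logger.warning(
            "skipped %d record(s) on %d chromosome(s) absent from layout: %s",
            sum(skipped.values()), len(skipped), ", ".join(sorted(skipped)),
        )
    return EventTrack.from_dict(
        positions, cats if category_column is not None else None
    )


def write_bed_events(track: EventTrack, path, layout: GenomeLayout | None = None) -> None:
    """Write a track as BED (length-1 intervals, category in column 4 if any).

    Chromosomes follow ``layout`` order when a layout is given, otherwise
    the track's own insertion order.
    """
    names: Iterable[str]
    if layout is not None:
        names = [n for n in layout.names if n in track.positions]
    else:
        names = track.positions
    with open(path, "w") as fh:
        for chrom in names:
            pos = track.positions[chrom]
            cats = track.categories.get(chrom) if track.categories is not None else None
            for i, p in enumerate(pos):
                if cats is not None:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{cats[i]}\n")
                else:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")
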