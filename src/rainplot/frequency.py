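"""Binned mutation-frequency tracks, the conventional alternative to the
rainfall plot.

A frequency line plot counts events in fixed-size bins (3 Mbp by default
for a human genome) along the genome-wide axis.  It reads out the number of
events per bin directly but says nothing about their arrangement inside a
bin, and a short, intense hotspot loses prominence as bins grow.

By default bins restart at each chromosome start ("per-chromosome" mode),
so no bin mixes two chromosomes; the "global" mode lays bins on the
concatenated axis without restarting, in which case boundary-straddling
bins may mix chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import EventTrack, GenomeLayout, globalize

logger = logging.getLogger(__name__)

__all__ = ["FrequencyTrack", "bin_counts", "DEFAULT_BIN_SIZE"]

DEFAULT_BIN_SIZE = 3_000_000


@dataclass
class FrequencyTrack:
    """Per-bin event counts along the global axis.

    ``starts``/``ends`` are global coordinates of each bin (half-open);
    ``chroms`` names the bin's chromosome in per-chromosome mode and is
    None in global mode.
    """

    bin_size: int
    counts: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    mode: str                      # "per-chromosome" | "global"
    layout: GenomeLayout
    chroms: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def zscores(self) -> np.ndarray:
        """Per-bin z-score of the count against all bins (population SD).

        A planted hotspot's z-score shrinks as the bin size grows: the
        hotspot's fixed excess is diluted by the rising background mean and
        variance of larger bins.
        """
        mean = self.counts.mean()
        sd = self.counts.std()
        if sd == 0:
            return np.zeros_like(self.counts, dtype=float)
        return (self.counts - mean) / sd

    def bin_of(self, global_position: int) -> int:
        """Index of the bin containing a global position."""
        i = int(np.searchsorted(self.starts, global_position, side="right") - 1)
        if i < 0 or global_position >= self.ends[i]:
            raise ValueError(f"position {global_position} outside all bins")
        return i

    def to_frame(self) -> pd.DataFrame:
        data = {"start": self.starts, "end": self.ends, "count": self.counts}
        if self.chroms is not None:
            data = {"chrom": self.chroms, **data}
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        """Write a bedGraph (chromosome-local coordinates).

        Only available in per-chromosome mode: global-mode bins may
        straddle chromosome boundaries and have no faithful bedGraph form.
        """
        if self.mode != "per-chromosome" or self.chroms is None:
            raise ValueError("bedGraph export requires per-chromosome binning")
        with open(path, "w") as fh:
            for chrom, start, end, count in zip(
                self.chroms, self.starts, self.ends, self.counts
            ):
                off = self.layout.offset_of(str(chrom))
                fh.write(f"{chrom}\t{int(start) - off}\t{int(end) - off}\t{int(count)}\n")


def bin_counts(
    track: EventTrack,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    mode: str = "per-chromosome",
) -> FrequencyTrack:
    """Count events in fixed-size bins along the genome.

    An event at global position g falls in bin ``floor(g / bin_size)``
    (global mode) or in bin ``floor(p / bin_size)`` of its own chromosome
    (per-chromosome mode, the default).  Counts are conserved for any bin
    size, and 100 contiguous 30 kbp bins sum to the enclosing 3 Mbp bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("per-chromosome", "global"):
        raise ValueError("mode must be 'per-chromosome' or 'global'")

    if mode == "global":
        n_bins = -(-layout.total_length // bin_size)  # ceil
        counts = np.zeros(n_bins, dtype=np.int64)
        gpos = globalize(track, layout).positions
        if len(gpos):
            counts = np.bincount(gpos // bin_size, minlength=n_bins).astype(np.int64)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, layout.total_length)
        return FrequencyTrack(
            bin_size=bin_size, counts=counts, starts=starts, ends=ends,
            mode=mode, layout=layout,
        )

    track.validate_against(layout)
    all_counts, all_starts, all_ends, all_chroms = [], [], [], []
    for name in layout.names:
        length = layout.length_of(name)
        offset = layout.offset_of(name)
        n_bins = -(-length // bin_size)
        pos = track.positions.get(name)
        if pos is not None and len(pos):
            counts = np.bincount(pos // bin_size, minlength=n_bins).astype(np.int64)
        else:
            counts = np.zeros(n_bins, dtype=np.int64)
        starts = offset + np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, offset + length)
        all_counts.append(counts)
        all_starts.append(starts)
        all_ends.append(ends)
        all_chroms.append(np.full(n_bins, name, dtype=object))
    return FrequencyTrack(
        bin_size=bin_size,
        counts=np.concatenate(all_counts),
        starts=np.concatenate(all_starts),
        ends=np.concatenate(all_ends),
        mode=mode,
        layout=layout,
        chroms=np.concatenate(all_chroms),
    )
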