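"""Genome layout, BED/chrom.sizes I/O and globalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rainplot import (
    EventTrack,
    FormatError,
    GenomeLayout,
    globalize,
    read_bed_events,
    read_chrom_sizes,
    write_bed_events,
)


class TestReadChromSizes:
    def test_cumulative_offsets(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1 1000\nchr2 500\n")
        layout = read_chrom_sizes(p)
        assert layout.names == ("chr1", "chr2")
        assert layout.offset_of("chr1") == 0
        assert layout.offset_of("chr2") == 1000
        assert layout.total_length == 1500

    def test_file_order_is_preserved(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr2 500\nchr1 1000\n")
        assert read_chrom_sizes(p).names == ("chr2", "chr1")

    @pytest.mark.parametrize(
        "content, match",
        [
            ("", "no chromosomes"),
            ("chr1 0\n", "non-positive"),
            ("chr1 -5\n", "non-positive"),
            ("chr1\n", "expected"),
            ("chr1 abc\n", "not an integer"),
            ("chr1 10\nchr1 20\n", "duplicate"),
        ],
    )
    def test_malformed_files_raise_format_error(self, tmp_path, content, match):
        p = tmp_path / "bad.chrom.sizes"
        p.write_text(content)
        with pytest.raises(FormatError, match=match):
            read_chrom_sizes(p)


class TestLayoutInvariants:
    @given(
        lengths=st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=8)
    )
    @settings(derandomize=True, max_examples=50)
    def test_offsets_are_prefix_sums(self, lengths):
        names = tuple(f"c{i}" for i in range(len(lengths)))
        layout = GenomeLayout(names, tuple(lengths))
        offsets = layout.offsets
        assert offsets[0] == 0
        assert np.all(np.diff(offsets) > 0) or len(lengths) == 1
        for k in range(len(lengths)):
            assert offsets[k] == sum(lengths[:k])
        assert layout.total_length == sum(lengths)


class TestReadBedEvents:
    def test_records_are_sorted(self, tmp_path, two_chrom_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t11\nchr1\t5\t6\nchr1\t20\t21\n")
        track = read_bed_events(p, two_chrom_layout)
        assert track.positions["chr1"].tolist() == [5, 10, 20]

    def test_category_column(self, tmp_path, two_chrom_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t6\tC>A\n")
        track = read_bed_events(p, two_chrom_layout, category_column=3)
        assert track.positions["chr1"].tolist() == [5]
        assert track.categories["chr1"].tolist() == ["C>A"]

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path, two_chrom_layout, caplog):
        p = tmp_path / "a.bed"
        p.write_text("chrUn\t5\t6\nchr1\t5\t6\n")
        with caplog.at_level("WARNING", logger="rainplot.genome"):
            track = read_bed_events(p, two_chrom_layout)
        assert track.n_events == 1
        assert any("skipped 1" in r.message for r in caplog.records)

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t6\t5", "start 6 >= end 5"),
            ("chr1\t6\t6", ">= end"),
            ("chr1\t5000\t5001", "beyond"),
            ("chr1\t5", "fewer than 3"),
            ("chr1\tx\t6", "non-integer"),
        ],
    )
    def test_malformed_records_raise(self, tmp_path, two_chrom_layout, line, match):
        p = tmp_path / "bad.bed"
        p.write_text(line + "\n")
        with pytest.raises(FormatError, match=match):
            read_bed_events(p, two_chrom_layout)

    def test_duplicates_deduplicated_with_warning(self, tmp_path, two_chrom_layout, caplog):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t6\tC>A\nchr1\t5\t6\tT>G\n")
        with caplog.at_level("WARNING", logger="rainplot.genome"):
            track = read_bed_events(p, two_chrom_layout, category_column=3)
        assert track.positions["chr1"].tolist() == [5]
        # first occurrence kept
        assert track.categories["chr1"].tolist() == ["C>A"]
        assert any("duplicate" in r.message for r in caplog.records)


class TestGlobalize:
    def test_offset_arithmetic(self, two_chrom_layout):
        track = EventTrack.from_dict({"chr1": [100], "chr2": [50]})
        out = globalize(track, two_chrom_layout)
        assert out.positions.tolist() == [100, 1050]
        assert out.chroms.tolist() == ["chr1", "chr2"]

    def test_single_chromosome_is_identity(self):
        layout = GenomeLayout(("chrZ",), (500,))
        track = EventTrack.from_dict({"chrZ": [1, 7, 400]})
        assert globalize(track, layout).positions.tolist() == [1, 7, 400]

    @given(
        data=st.data(),
        lengths=st.lists(st.integers(min_value=50, max_value=5000), min_size=3, max_size=5),
    )
    @settings(derandomize=True, max_examples=40)
    def test_injective_and_order_preserving(self, data, lengths):
        names = tuple(f"c{i}" for i in range(len(lengths)))
        layout = GenomeLayout(names, tuple(lengths))
        events = {}
        for name, length in zip(names, lengths):
            pos = data.draw(
                st.lists(st.integers(min_value=0, max_value=length - 1),
                         unique=True, max_size=10),
                label=name,
            )
            events[name] = sorted(pos)
        track = EventTrack.from_dict(events)
        out = globalize(track, layout)
        # injective across the whole genome, sorted ascending
        assert len(np.unique(out.positions)) == len(out.positions)
        assert np.all(np.diff(out.positions) > 0) or len(out.positions) <= 1
        # events only on the last chromosome land at or above its offset
        for name in names:
            mask = out.chroms == name
            if mask.any():
                assert out.positions[mask].min() >= layout.offset_of(name)
                assert out.positions[mask].max() < (
                    layout.offset_of(name) + layout.length_of(name)
                )

    def test_rejects_out_of_bounds(self, two_chrom_layout):
        track = EventTrack.from_dict({"chr1": [1000]})
        with pytest.raises(ValueError, match="beyond"):
            globalize(track, two_chrom_layout)

    def test_rejects_unknown_chromosome(self, two_chrom_layout):
        track = EventTrack.from_dict({"chr9": [1]})
        with pytest.raises(ValueError, match="not in layout"):
            globalize(track, two_chrom_layout)


class TestBedRoundTrip:
    @given(data=st.data())
    @settings(derandomize=True, max_examples=25)
    def test_write_then_read_is_identity(self, data, tmp_path_factory):
        layout = GenomeLayout(("chr1", "chr2"), (10_000, 5_000))
        cats = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
        events, labels = {}, {}
        for name in layout.names:
            pos = sorted(
                data.draw(
                    st.lists(
                        st.integers(min_value=0, max_value=layout.length_of(name) - 1),
                        unique=True, max_size=20,
                    ),
                    label=name,
                )
            )
            events[name] = pos
            labels[name] = [cats[p % len(cats)] for p in pos]
        track = EventTrack.from_dict(events, labels)
        path = tmp_path_factory.mktemp("bed") / "t.bed"
        write_bed_events(track, path, layout)
        back = read_bed_events(path, layout, category_column=3)
        for name in layout.names:
            assert back.positions.get(name, np.empty(0)).tolist() == events[name]
            if events[name]:
                assert back.categories[name].tolist() == labels[name]
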