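import numpy as np
import pytest

from rainplot import EventTrack, GenomeLayout


@pytest.fixture
def two_chrom_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (1000, 2000))


@pytest.fixture
def small_track(two_chrom_layout) -> EventTrack:
    return EventTrack.from_dict({"chr1": [10, 110], "chr2": [5, 1005]})


@pytest.fixture(scope="session")
def hg19() -> GenomeLayout:
    return GenomeLayout.hg19()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170518)
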