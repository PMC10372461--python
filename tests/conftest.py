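import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from peakbench.genome import GenomeLayout, Interval, PeakSet


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout((("c1", 1000), ("c2", 500)))


@pytest.fixture
def big_layout() -> GenomeLayout:
    return GenomeLayout((("c1", 100_000), ("c2", 80_000), ("c3", 50_000)))


def make_peaks(triples, layout=None, label=""):
    return PeakSet.from_intervals(
        [Interval(c, s, e) for c, s, e in triples], label=label, layout=layout
    )
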