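import numpy as np
import pandas as pd
import pytest

from tadcore.genome_model import BinIndex, TADSet


@pytest.fixture
def index10():
    """One 100 kb chromosome in ten 10 kb bins."""
    return BinIndex({"chr1": 100_000}, 10_000)


@pytest.fixture
def tads10(index10):
    """Three disjoint TADs on chr1: bins 0-2, 3-5, 7-9 (bin 6 is a gap)."""
    return TADSet(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 30_000, 70_000],
                "end": [30_000, 60_000, 100_000],
                "tad_id": ["T1", "T2", "T3"],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
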