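import numpy as np
import pandas as pd
import pytest

from tadscape.layout import GenomeLayout
from tadscape import synthetic as syn


@pytest.fixture
def small_layout():
    """One 8-Mb chromosome at 40-kb bins (200 bins)."""
    return GenomeLayout(["chr1"], [8_000_000], 40_000)


@pytest.fixture
def two_chrom_layout():
    return GenomeLayout(["chr1", "chr2"], [8_000_000, 6_000_000], 40_000)


@pytest.fixture
def truth(small_layout):
    return syn.plant_truth(small_layout, seed=11, loops_per_chrom=6)


def make_truth(domains: pd.DataFrame, loops: pd.DataFrame | None = None,
               boundaries: pd.DataFrame | None = None) -> syn.SyntheticTruth:
    """Hand-built truth object for targeted generator tests."""
    if loops is None:
        loops = pd.DataFrame(columns=["chrom", "startA", "endA", "startB", "endB"])
    if boundaries is None:
        boundaries = pd.DataFrame(columns=["chrom", "start", "end"])
    return syn.SyntheticTruth(domains, boundaries, loops)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
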