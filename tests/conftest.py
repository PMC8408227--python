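import numpy as np
import pandas as pd
import pytest

from aneuscore import (BinnedProfile, SegmentProfile, build_genome, make_bins)


@pytest.fixture(scope="session")
def toy_genome():
    """Two chromosomes, 100 and 80 Mb, centromeres at 40%."""
    return build_genome({"lengths": [100e6, 80e6], "centromere": 0.4})


@pytest.fixture(scope="session")
def toy_grid(toy_genome):
    return make_bins(toy_genome, width=10_000_000)


@pytest.fixture(scope="session")
def small_genome():
    """Default-scale study genome: 1/10 hg38-like, autosomes + X."""
    return build_genome({"preset": "hg38-like", "scale": 0.1})


@pytest.fixture(scope="session")
def small_grid(small_genome):
    return make_bins(small_genome, width=1_000_000)


def make_binned(grid, values, sample_id="S"):
    return BinnedProfile(sample_id=sample_id, grid=grid,
                         values=np.asarray(values, dtype=float))


def make_seg(rows, sample_id="S", genome=None):
    """rows: iterable of (chrom, start, end, logr[, n_probes])."""
    recs = [(r + (10,))[:5] for r in rows]
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "logr", "n_probes"])
    return SegmentProfile(sample_id=sample_id, segments=df, genome=genome)
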