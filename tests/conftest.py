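import numpy as np
import pytest

from ervkit.core_io import (
    ChromSizes,
    GenomicInterval,
    MarkerPeakSet,
    ProvirusRecord,
)
from ervkit.simulate import SimulationConfig


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def element():
    return ProvirusRecord(
        element_id="e0", family="ERVF",
        interval=GenomicInterval("chr1", 1000, 2000, "+"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=42, n_focal=20, n_reads=5_000,
        background_families={"LINE": 10},
        chrom_sizes={"chr1": 20_000_000, "chr2": 10_000_000})


def make_peaks(positions, chrom="chr1", marker="H3K4me3", cell_type="ES"):
    return MarkerPeakSet(marker, cell_type, {chrom: positions})


def make_element(start, end, chrom="chr1", strand="+", eid="e", family="ERVF"):
    return ProvirusRecord(element_id=eid, family=family,
                          interval=GenomicInterval(chrom, start, end, strand))
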