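import numpy as np
import pytest

from sepredict.io_formats import GenomicRegion, Read, ReadSet


@pytest.fixture
def random_regions():
    """50 random valid regions (seed 7) across two chromosomes."""
    rng = np.random.default_rng(7)
    regions = []
    for i in range(50):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 100_000))
        length = int(rng.integers(1, 5_000))
        regions.append(GenomicRegion(chrom, start, start + length, f"r{i}"))
    return regions


@pytest.fixture
def small_readset():
    reads = [
        Read("chr1", 100, 150, "+"),
        Read("chr1", 300, 350, "-"),
        Read("chr1", 120, 170, "+"),
        Read("chr2", 50, 100, "+"),
    ]
    return ReadSet(reads=reads, total_mapped=4)


def brute_force_density(read_set, region, ext_len):
    """Per-base coverage sum oracle for region_density."""
    from sepredict.signal_quant import extend_read

    covered = 0
    for base in range(region.start, region.end):
        for read in read_set.reads:
            if read.chrom != region.chrom:
                continue
            r = extend_read(read, ext_len)
            if r.start <= base < r.end:
                covered += 1
    return covered / region.length * 1e6 / read_set.total_mapped
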