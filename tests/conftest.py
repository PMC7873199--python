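"""Shared fixtures: miniature BAM files with fully known record content."""

import numpy as np
import pytest

from amylocnv.regions import GenomicInterval, LocusRegionDef
from amylocnv.simulate import ReadSpec, write_bam

CONTIG = "chrT"
CONTIG_LEN = 100_000

# one 2-kb interval used by most counting tests
IV = GenomicInterval(CONTIG, 10_000, 12_000)

TOY = LocusRegionDef(
    locus_name="TOY",
    target_intervals=(
        GenomicInterval(CONTIG, 10_000, 12_000),
        GenomicInterval(CONTIG, 20_000, 22_000),
        GenomicInterval(CONTIG, 30_000, 32_000),
    ),
    unit_length=2_000,
    reference_intervals=(
        GenomicInterval(CONTIG, 50_000, 54_000),
        GenomicInterval(CONTIG, 60_000, 64_000),
    ),
    mapq_min=0,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210209)


@pytest.fixture(scope="session")
def bam_builder(tmp_path_factory):
    """Write a list of ReadSpec records to a fresh indexed BAM."""
    root = tmp_path_factory.mktemp("bams")
    counter = {"i": 0}

    def build(reads):
        counter["i"] += 1
        path = root / f"fixture{counter['i']}.bam"
        return write_bam(reads, path, CONTIG, CONTIG_LEN)

    return build


@pytest.fixture(scope="session")
def empty_bam(bam_builder):
    return bam_builder([])


@pytest.fixture(scope="session")
def mapq_mix_bam(bam_builder):
    """100 reads fully inside IV; 5 of them have MAPQ 10, the rest MAPQ 60."""
    reads = [ReadSpec(pos=10_100 + 10 * i, mapq=60) for i in range(95)]
    reads += [ReadSpec(pos=11_000 + 10 * i, mapq=10) for i in range(5)]
    return bam_builder(reads)


@pytest.fixture(scope="session")
def known_counts_bam(bam_builder):
    """Exact counts: 200 reads per target interval, 300 per reference interval."""
    reads = []
    for iv in TOY.target_intervals:
        reads += [ReadSpec(pos=iv.start + 2 * i) for i in range(200)]
    for iv in TOY.reference_intervals:
        reads += [ReadSpec(pos=iv.start + 2 * i) for i in range(300)]
    return bam_builder(reads)
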