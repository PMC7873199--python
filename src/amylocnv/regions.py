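"""Genomic interval sets and per-sample read counting / alignability QC.

The amylase genes (salivary *AMY1*, pancreatic *AMY2A*/*AMY2B*) sit in a
tandem paralogous cluster on chromosome 1 and are among the most
copy-number-variable genes in humans.  Coverage-based genotyping compares
the read density (reads/bp) over the paralogous target units of a locus
with the density over nearby copy-invariant reference intervals that every
individual carries at exactly two copies; the ratio calibrates out
library size and local depth.

This module defines the interval containers, counts alignment records over
intervals with samtools-compatible semantics (any >=1 bp overlap, optional
MAPQ floor, configurable flag filtering), and computes the alignability
diagnostics used to argue that coverage in the repeat is trustworthy:
the fraction of properly paired reads with a unique alignment (no ``XA``
secondary-hit tag, no ``SA`` split-read tag) and the fraction exceeding a
MAPQ threshold, whose Phred conversion bounds the mis-mapping probability.

All internal coordinates are 0-based half-open.  Printed/samtools-style
region strings ("chr1:104190000-104210000") are ingested as 1-based
inclusive and converted on parse; BED input is native 0-based half-open.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd
import pysam
import yaml

__all__ = [
    "GenomicInterval",
    "LocusRegionDef",
    "CountRecord",
    "AlignabilityReport",
    "FlagPolicy",
    "DEFAULT_FLAGS",
    "STRICT_FLAGS",
    "phred_to_prob",
    "count_reads",
    "locus_counts",
    "alignability_report",
    "read_bed",
    "load_regions",
    "default_regions",
    "counts_table",
    "qc_table",
]


# ---------------------------------------------------------------------------
# interval containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_region_string(cls, region: str) -> "GenomicInterval":
        """Parse a samtools-style ``chrom:start-end`` span (1-based inclusive)."""
        try:
            chrom, span = region.rsplit(":", 1)
            lo, hi = span.replace(",", "").replace("–", "-").split("-")
            start1, end1 = int(lo), int(hi)
        except ValueError as exc:
            raise ValueError(f"cannot parse region string {region!r}") from exc
        return cls(chrom, start1 - 1, end1)

    def to_region_string(self) -> str:
        """Render as a 1-based inclusive samtools region string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """>=1 bp overlap with another half-open span."""
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass(frozen=True)
class LocusRegionDef:
    """Interval set and counting policy for one multi-copy locus.

    ``unit_length`` is the normalization length of ONE paralogous repeat
    unit: target reads summed over all units divided by ``unit_length``
    gives a density whose ratio to the reference density scales directly
    to diploid copy number.
    """

    locus_name: str
    target_intervals: tuple[GenomicInterval, ...]
    unit_length: int
    reference_intervals: tuple[GenomicInterval, ...]
    mapq_min: int = 0

    def __post_init__(self) -> None:
        if not self.target_intervals or not self.reference_intervals:
            raise ValueError(f"{self.locus_name}: need >=1 target and >=1 reference interval")
        if self.unit_length <= 0:
            raise ValueError(f"{self.locus_name}: unit_length must be positive")
        if self.mapq_min < 0:
            raise ValueError(f"{self.locus_name}: mapq_min must be >= 0")
        object.__setattr__(self, "target_intervals", tuple(self.target_intervals))
        object.__setattr__(self, "reference_intervals", tuple(self.reference_intervals))

    @property
    def reference_length(self) -> int:
        return sum(iv.length for iv in self.reference_intervals)


@dataclass(frozen=True)
class CountRecord:
    """Per-sample read counts and densities over one locus."""

    sample_id: str
    locus_name: str
    target_count: int
    reference_count: int
    target_density: float
    reference_density: float


@dataclass(frozen=True)
class AlignabilityReport:
    """Alignability QC over the target intervals of one locus.

    When a sample has no properly paired reads in the target the fractions
    are NaN and ``defined`` is False (never silently zero).
    """

    sample_id: str
    locus_name: str
    frac_properly_paired_unique: float
    frac_mapq_gt_threshold: float
    mapping_error_prob_bound: float
    n_properly_paired: int

    @property
    def defined(self) -> bool:
        return self.n_properly_paired > 0


@dataclass(frozen=True)
class FlagPolicy:
    """Which alignment records participate in counting.

    The default mirrors plain ``samtools view -c`` region counting as used
    for coverage genotyping: unmapped, secondary and supplementary records
    are excluded, duplicates are kept.  ``STRICT_FLAGS`` additionally drops
    duplicates.
    """

    exclude_unmapped: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = False

    def keep(self, read: pysam.AlignedSegment) -> bool:
        if self.exclude_unmapped and read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        return True


DEFAULT_FLAGS = FlagPolicy()
STRICT_FLAGS = FlagPolicy(exclude_duplicates=True)


# ---------------------------------------------------------------------------
# Phred scale
# ---------------------------------------------------------------------------

def phred_to_prob(q: float) -> float:
    """Convert a Phred-scaled quality ``q`` to an error probability 10^(-q/10).

    A MAPQ floor of 20 therefore bounds the mis-mapping probability at 0.01.
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# alignment-file access
# ---------------------------------------------------------------------------

@contextmanager
def _open_alignment(alignment) -> Iterator[pysam.AlignmentFile]:
    if isinstance(alignment, pysam.AlignmentFile):
        yield alignment
    else:
        af = pysam.AlignmentFile(str(alignment))
        try:
            yield af
        finally:
            af.close()


def _check_fetchable(af: pysam.AlignmentFile, interval: GenomicInterval) -> None:
    try:
        af.check_index()
    except (AttributeError, ValueError) as exc:
        raise FileNotFoundError(
            f"alignment file {af.filename!r} has no index; run samtools index first"
        ) from exc
    if interval.chrom not in af.references:
        raise ValueError(
            f"chromosome {interval.chrom!r} absent from alignment header "
            f"(has {list(af.references)[:5]}...)"
        )
    ref_len = af.get_reference_length(interval.chrom)
    if interval.end > ref_len:
        raise ValueError(
            f"interval {interval.to_region_string()} extends past reference "
            f"length {ref_len} of {interval.chrom}"
        )


def count_reads(
    alignment,
    interval: GenomicInterval,
    mapq_min: int = 0,
    flag_policy: FlagPolicy = DEFAULT_FLAGS,
) -> int:
    """Count alignment records overlapping ``interval`` by >=1 bp.

    Records must have MAPQ >= ``mapq_min`` and satisfy ``flag_policy``.
    Semantics match ``samtools view -c -q <mapq_min> <region>`` with the
    default policy.
    """
    with _open_alignment(alignment) as af:
        _check_fetchable(af, interval)
        n = 0
        for read in af.fetch(interval.chrom, interval.start, interval.end):
            if read.mapping_quality < mapq_min:
                continue
            if flag_policy.keep(read):
                n += 1
        return n


def locus_counts(
    alignment,
    locus: LocusRegionDef,
    sample_id: str,
    flag_policy: FlagPolicy = DEFAULT_FLAGS,
) -> CountRecord:
    """Aggregate target/reference counts and densities for one locus.

    target_density divides the summed target count by ``unit_length`` (one
    repeat unit), reference_density divides by the total reference span;
    both are reads/bp.
    """
    with _open_alignment(alignment) as af:
        target = sum(
            count_reads(af, iv, locus.mapq_min, flag_policy) for iv in locus.target_intervals
        )
        reference = sum(
            count_reads(af, iv, locus.mapq_min, flag_policy)
            for iv in locus.reference_intervals
        )
    if reference == 0:
        raise ValueError(
            f"reference coverage absent for {sample_id}/{locus.locus_name}; "
            "cannot normalize target density"
        )
    return CountRecord(
        sample_id=sample_id,
        locus_name=locus.locus_name,
        target_count=target,
        reference_count=reference,
        target_density=target / locus.unit_length,
        reference_density=reference / locus.reference_length,
    )


def alignability_report(
    alignment,
    locus: LocusRegionDef,
    sample_id: str = "",
    mapq_threshold: int = 20,
) -> AlignabilityReport:
    """Alignability QC over a locus's target intervals.

    Among properly paired mapped records, reports the fraction with unique
    alignments (no ``XA:Z`` / ``SA:Z`` optional tags) and the fraction with
    MAPQ strictly above ``mapq_threshold``; the Phred conversion of the
    threshold bounds the residual mis-mapping probability.
    """
    n_pp = 0
    n_unique = 0
    n_hi_mapq = 0
    with _open_alignment(alignment) as af:
        for iv in locus.target_intervals:
            _check_fetchable(af, iv)
            for read in af.fetch(iv.chrom, iv.start, iv.end):
                if read.is_unmapped or not read.is_proper_pair:
                    continue
                n_pp += 1
                if not read.has_tag("XA") and not read.has_tag("SA"):
                    n_unique += 1
                if read.mapping_quality > mapq_threshold:
                    n_hi_mapq += 1
    if n_pp == 0:
        frac_unique = math.nan
        frac_mapq = math.nan
    else:
        frac_unique = n_unique / n_pp
        frac_mapq = n_hi_mapq / n_pp
    return AlignabilityReport(
        sample_id=sample_id,
        locus_name=locus.locus_name,
        frac_properly_paired_unique=frac_unique,
        frac_mapq_gt_threshold=frac_mapq,
        mapping_error_prob_bound=phred_to_prob(mapq_threshold),
        n_properly_paired=n_pp,
    )


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (native 0-based half-open)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return ivs


def _parse_locus(name: str, spec: Mapping) -> LocusRegionDef:
    targets = tuple(GenomicInterval.from_region_string(s) for s in spec["targets"])
    refs = tuple(GenomicInterval.from_region_string(s) for s in spec["references"])
    return LocusRegionDef(
        locus_name=name,
        target_intervals=targets,
        unit_length=int(spec["unit_length"]),
        reference_intervals=refs,
        mapq_min=int(spec.get("mapq_min", 0)),
    )


def load_regions(path) -> dict[str, LocusRegionDef]:
    """Load locus definitions from a YAML config (see packaged default)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {name: _parse_locus(name, spec) for name, spec in doc["loci"].items()}


def default_regions() -> dict[str, LocusRegionDef]:
    """The shipped GRCh37 amylase region definitions."""
    ref = resources.files("amylocnv.data").joinpath("amylase_grch37.yaml")
    with resources.as_file(ref) as path:
        return load_regions(path)


# ---------------------------------------------------------------------------
# tabular convenience layers (CLI backends)
# ---------------------------------------------------------------------------

def counts_table(
    alignments: Mapping[str, object],
    regions: Mapping[str, LocusRegionDef],
    flag_policy: FlagPolicy = DEFAULT_FLAGS,
) -> pd.DataFrame:
    """One CountRecord row per sample x locus."""
    rows = []
    for sample_id, bam in alignments.items():
        for locus in regions.values():
            rec = locus_counts(bam, locus, sample_id, flag_policy)
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def qc_table(
    alignments: Mapping[str, object],
    regions: Mapping[str, LocusRegionDef],
    mapq_threshold: int = 20,
) -> pd.DataFrame:
    """One AlignabilityReport row per sample x locus."""
    rows = []
    for sample_id, bam in alignments.items():
        for locus in regions.values():
            rep = alignability_report(bam, locus, sample_id, mapq_threshold)
            rows.append(rep.__dict__)
    return pd.DataFrame(rows)
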