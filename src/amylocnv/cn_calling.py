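"""Discrete amylase copy-number calling from coverage density ratios.

The continuous (raw) diploid copy number of a locus is

    raw_cn = scale * target_density / reference_density,

with ``scale = 2`` because the reference intervals are copy-invariant and
diploid, and with the target density normalized by the length of ONE
paralogous repeat unit, so a sample truly carrying C copies has
expectation C.

Integer calls exploit the structural haplotypes of the cluster: AMY1 and
AMY2A copies co-segregate such that their diploid counts share even/odd
parity.  AMY2A (and AMY2B) are rounded to the nearest integer first;
AMY1 is then rounded to the nearest integer of *matching parity* —
nearest even if AMY2A is even, nearest odd if odd.  Ties (a raw AMY1
value exactly midway between the two admissible integers) go to the
larger integer.

Association-ready filtering removes AMY1 = 0 samples and winsorizes rare
AMY1 calls above a cap (default 14 copies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import CountRecord

__all__ = [
    "RawCNEstimate",
    "CNGenotype",
    "FilterReport",
    "ConcordanceSummary",
    "round_half_up",
    "nearest_with_parity",
    "raw_cn",
    "conditional_round",
    "amy2b_concordance",
    "filter_for_association",
    "call_genotypes",
]


@dataclass(frozen=True)
class RawCNEstimate:
    sample_id: str
    locus_name: str
    raw_cn: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.raw_cn) or self.raw_cn < 0:
            raise ValueError(f"raw_cn must be finite and >= 0, got {self.raw_cn}")


@dataclass(frozen=True)
class CNGenotype:
    """Integer diploid copy-number calls for one sample."""

    sample_id: str
    amy1: int
    amy2a: int
    amy2b: int | None = None

    @property
    def parity_consistent(self) -> bool:
        return self.amy1 % 2 == self.amy2a % 2


@dataclass(frozen=True)
class FilterReport:
    removed: int
    capped: int


@dataclass(frozen=True)
class ConcordanceSummary:
    """AMY2A vs AMY2B agreement used to justify dropping AMY2B downstream."""

    frac_equal: float
    frac_discordant_amy2b_two: float  # NaN when no pair is discordant
    n: int


def round_half_up(x: float) -> int:
    """Round to nearest integer, exact halves upward (0.5 -> 1, 1.5 -> 2)."""
    return int(math.floor(x + 0.5))


def nearest_with_parity(x: float, parity: int) -> int:
    """Nearest non-negative integer to ``x`` with the given parity (0/1).

    Equidistant inputs resolve to the larger admissible integer.
    """
    if parity not in (0, 1):
        raise ValueError("parity must be 0 or 1")
    return 2 * int(math.floor((x - parity) / 2.0 + 0.5)) + parity


def raw_cn(count_record: CountRecord, scale: float = 2.0) -> RawCNEstimate:
    """Continuous diploid CN from a CountRecord's density ratio."""
    if count_record.reference_density <= 0:
        raise ValueError(
            f"reference density is zero for {count_record.sample_id}/"
            f"{count_record.locus_name}; cannot estimate copy number"
        )
    value = scale * count_record.target_density / count_record.reference_density
    return RawCNEstimate(count_record.sample_id, count_record.locus_name, value)


def conditional_round(
    raw_amy1: float,
    raw_amy2a: float,
    raw_amy2b: float | None = None,
    sample_id: str = "",
) -> CNGenotype:
    """Parity-conditional integer calling.

    AMY2A (and AMY2B, if given) round half-up to the nearest integer; AMY1
    rounds to the nearest integer sharing AMY2A's parity, so the output is
    parity-consistent by construction.
    """
    for name, v in (("raw_amy1", raw_amy1), ("raw_amy2a", raw_amy2a)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    amy2a = round_half_up(raw_amy2a)
    amy1 = nearest_with_parity(raw_amy1, amy2a % 2)
    amy2b = None
    if raw_amy2b is not None:
        if not math.isfinite(raw_amy2b) or raw_amy2b < 0:
            raise ValueError(f"raw_amy2b must be finite and >= 0, got {raw_amy2b}")
        amy2b = round_half_up(raw_amy2b)
    return CNGenotype(sample_id=sample_id, amy1=amy1, amy2a=amy2a, amy2b=amy2b)


def amy2b_concordance(genotypes: Sequence[CNGenotype]) -> ConcordanceSummary:
    """Fraction of samples with AMY2A == AMY2B, and among discordant pairs
    the fraction where AMY2B sits at the invariant two copies."""
    if not genotypes:
        raise ValueError("empty genotype list")
    if any(g.amy2b is None for g in genotypes):
        raise ValueError("amy2b calls missing; concordance undefined")
    equal = sum(g.amy2a == g.amy2b for g in genotypes)
    discordant = [g for g in genotypes if g.amy2a != g.amy2b]
    frac_b2 = (
        sum(g.amy2b == 2 for g in discordant) / len(discordant)
        if discordant
        else math.nan
    )
    return ConcordanceSummary(
        frac_equal=equal / len(genotypes),
        frac_discordant_amy2b_two=frac_b2,
        n=len(genotypes),
    )


def filter_for_association(
    genotypes: Sequence[CNGenotype], cap: int = 14
) -> tuple[list[CNGenotype], FilterReport]:
    """Drop AMY1 = 0 samples; winsorize AMY1 above ``cap`` down to ``cap``."""
    kept: list[CNGenotype] = []
    removed = 0
    capped = 0
    for g in genotypes:
        if g.amy1 == 0:
            removed += 1
            continue
        if g.amy1 > cap:
            capped += 1
            g = CNGenotype(g.sample_id, cap, g.amy2a, g.amy2b)
        kept.append(g)
    return kept, FilterReport(removed=removed, capped=capped)


def call_genotypes(counts: pd.DataFrame, scale: float = 2.0) -> pd.DataFrame:
    """Pipeline step: long counts table -> one genotype row per sample.

    Expects the columns written by :func:`amylocnv.regions.counts_table`
    with locus names AMY1/AMY2A and optionally AMY2B.  Returns raw and
    integer calls plus the parity flag.
    """
    required = {"sample_id", "locus_name", "target_density", "reference_density"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    ratio = scale * counts["target_density"] / counts["reference_density"]
    wide = (
        counts.assign(raw=ratio)
        .pivot(index="sample_id", columns="locus_name", values="raw")
        .rename(columns=str.upper)
    )
    for locus in ("AMY1", "AMY2A"):
        if locus not in wide.columns:
            raise ValueError(f"counts table lacks locus {locus}")
    rows = []
    for sample_id, row in wide.iterrows():
        b = row.get("AMY2B")
        g = conditional_round(
            row["AMY1"],
            row["AMY2A"],
            None if b is None or pd.isna(b) else float(b),
            sample_id=str(sample_id),
        )
        rows.append(
            {
                "sample_id": g.sample_id,
                "amy1_raw": row["AMY1"],
                "amy2a_raw": row["AMY2A"],
                "amy2b_raw": b,
                "amy1": g.amy1,
                "amy2a": g.amy2a,
                "amy2b": g.amy2b,
                "parity_consistent": g.parity_consistent,
            }
        )
    return pd.DataFrame(rows)
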