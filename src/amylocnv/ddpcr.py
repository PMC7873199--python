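"""Droplet digital PCR copy-number estimation and WGS reconciliation.

In ddPCR the reaction is partitioned into ~20,000 droplets; a FAM-labelled
probe marks the target amylase gene and a HEX-labelled probe a two-copy
control.  The plain estimator scales the FAM/HEX positive-droplet ratio by
the control ploidy (2).  Because a droplet is positive once it holds >= 1
molecule, occupancies saturate at high concentration; the Poisson-corrected
estimator uses lambda = -ln(1 - k/N) per channel and is preferred whenever
channel occupancy is not small.

Two independent AMY1 probes are reconciled against the AMY2A call through
the even/odd parity the two genes share: probe calls whose parity matches
AMY2A are "concordant".  Both concordant -> average; exactly one -> keep
it; none -> average, then parity-round against AMY2A so the final integer
always shares AMY2A parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cn_calling import nearest_with_parity, round_half_up

__all__ = [
    "DdPCRMeasurement",
    "ValidationCall",
    "ConcordanceReport",
    "ddpcr_cn",
    "average_replicates",
    "reconcile_amy1",
    "concordance",
]


@dataclass(frozen=True)
class DdPCRMeasurement:
    sample_id: str
    probe_id: str
    replicate: int
    fam_positive: int
    hex_positive: int
    total_droplets: int = 20000

    def __post_init__(self) -> None:
        for name in ("fam_positive", "hex_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.total_droplets:
                raise ValueError(
                    f"{name}={v} outside [0, total_droplets={self.total_droplets}]"
                )


@dataclass(frozen=True)
class ValidationCall:
    """Paired WGS and ddPCR integer calls for one sample."""

    sample_id: str
    amy1_wgs: int
    amy1_ddpcr: int
    amy2a_wgs: int
    amy2a_ddpcr: int

    @property
    def concordant_amy1(self) -> bool:
        return self.amy1_wgs == self.amy1_ddpcr

    @property
    def concordant_amy2a(self) -> bool:
        return self.amy2a_wgs == self.amy2a_ddpcr


@dataclass(frozen=True)
class ConcordanceReport:
    n_calls: int
    n_discordant: int
    percent_concordant: float


def ddpcr_cn(
    measurement: DdPCRMeasurement,
    control_copies: int = 2,
    poisson_correct: bool = False,
) -> float:
    """Continuous copy number from one droplet measurement.

    Without correction: control_copies * FAM/HEX positive-droplet ratio.
    With correction the ratio is taken between per-droplet concentrations
    lambda = -ln(1 - k/N), which removes the saturation bias.
    """
    m = measurement
    if m.hex_positive == 0:
        raise ValueError(f"{m.sample_id}/{m.probe_id}: no HEX-positive droplets")
    if not poisson_correct:
        return control_copies * m.fam_positive / m.hex_positive
    if m.fam_positive >= m.total_droplets or m.hex_positive >= m.total_droplets:
        raise ValueError(
            f"{m.sample_id}/{m.probe_id}: saturated channel; "
            "Poisson correction undefined"
        )
    lam_fam = -math.log1p(-m.fam_positive / m.total_droplets)
    lam_hex = -math.log1p(-m.hex_positive / m.total_droplets)
    return control_copies * lam_fam / lam_hex


def average_replicates(
    measurements: Sequence[DdPCRMeasurement],
    control_copies: int = 2,
    poisson_correct: bool = False,
) -> float:
    """Arithmetic mean of per-replicate copy-number estimates."""
    if not measurements:
        raise ValueError("no replicates supplied")
    vals = [ddpcr_cn(m, control_copies, poisson_correct) for m in measurements]
    return sum(vals) / len(vals)


def reconcile_amy1(
    call_probe1: float,
    call_probe2: float,
    amy2a_call: int,
    concordance_on_parity: bool = True,
) -> int:
    """Reconcile two AMY1 probe estimates using the AMY2A call.

    Each probe estimate is rounded half-up and checked for concordance with
    AMY2A — by shared even/odd parity (default) or, behind the flag, by
    integer equality with the parity-admissible value.  Both concordant:
    average the rounded calls; one concordant: keep it; none: average.
    Averaged paths re-apply parity rounding so the output always shares
    AMY2A parity.
    """
    if call_probe1 < 0 or call_probe2 < 0 or amy2a_call < 0:
        raise ValueError("calls must be >= 0")
    parity = amy2a_call % 2
    r1, r2 = round_half_up(call_probe1), round_half_up(call_probe2)
    if concordance_on_parity:
        ok1, ok2 = r1 % 2 == parity, r2 % 2 == parity
    else:
        ok1 = r1 == nearest_with_parity(call_probe1, parity)
        ok2 = r2 == nearest_with_parity(call_probe2, parity)
    if ok1 and not ok2:
        return r1
    if ok2 and not ok1:
        return r2
    return nearest_with_parity((r1 + r2) / 2.0, parity)


def concordance(validation_calls: Sequence[ValidationCall]) -> ConcordanceReport:
    """WGS vs ddPCR concordance over both loci (two calls per sample)."""
    if not validation_calls:
        raise ValueError("no validation calls supplied")
    n_calls = 2 * len(validation_calls)
    n_discordant = sum(
        (not c.concordant_amy1) + (not c.concordant_amy2a) for c in validation_calls
    )
    return ConcordanceReport(
        n_calls=n_calls,
        n_discordant=n_discordant,
        percent_concordant=100.0 * (n_calls - n_discordant) / n_calls,
    )
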