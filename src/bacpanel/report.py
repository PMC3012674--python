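"""Genome and validation summary reports with a fixed rounding rule.

All printed percentages use round-half-away-from-zero to the nearest
integer, applied uniformly and recorded in the output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .annotation_io import GenomeRecord

ROUNDING_RULE = "half-away-from-zero to nearest integer percent"


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percent(part: float, whole: float) -> int:
    if whole == 0:
        raise ZeroDivisionError("percent of a zero total")
    return round_half_away(100.0 * part / whole)


@dataclass
class GenomeSummary:
    """General genome statistics in the style of a genome-paper table."""

    genome_size_bp: int
    cds_count: int
    assigned_count: int
    hypothetical_count: int
    mean_cds_length: float
    percent_coding: int
    percent_assigned: int
    percent_hypothetical: int
    rrna_count: int = 0
    ncrna_count: int = 0
    trna_count: int = 0
    rounding_rule: str = ROUNDING_RULE

    def __post_init__(self) -> None:
        if self.assigned_count + self.hypothetical_count != self.cds_count:
            raise ValueError("assigned + hypothetical must equal CDS count")
        if not 0 <= self.percent_coding <= 100:
            raise ValueError("percent coding out of [0, 100]")

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_genome(
    record: GenomeRecord, assigned_gene_ids: set[str]
) -> GenomeSummary:
    """Summarize a GenomeRecord; ``assigned_gene_ids`` marks CDSs with a
    putative function, the rest count as hypothetical."""
    if record.size_bp <= 0:
        raise ValueError("genome size must be positive")
    cds = [g for g in record.genes if g.is_cds]
    coding_bp = sum(g.length for g in cds)
    assigned = sum(1 for g in cds if g.gene_id in assigned_gene_ids)
    n = len(cds)
    return GenomeSummary(
        genome_size_bp=record.size_bp,
        cds_count=n,
        assigned_count=assigned,
        hypothetical_count=n - assigned,
        mean_cds_length=coding_bp / n if n else 0.0,
        percent_coding=percent(coding_bp, record.size_bp),
        percent_assigned=percent(assigned, n) if n else 0,
        percent_hypothetical=percent(n - assigned, n) if n else 0,
        rrna_count=record.rrna_count,
        ncrna_count=record.ncrna_count,
        trna_count=record.trna_count,
    )


def summary_from_counts(
    genome_size_bp: int,
    cds_count: int,
    mean_cds_length: float,
    assigned_count: int,
    rrna_count: int = 0,
    ncrna_count: int = 0,
    trna_count: int = 0,
) -> GenomeSummary:
    """Summary when only the CDS count and mean CDS length are known:
    coding bp is taken as count x mean length."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    coding_bp = cds_count * mean_cds_length
    return GenomeSummary(
        genome_size_bp=genome_size_bp,
        cds_count=cds_count,
        assigned_count=assigned_count,
        hypothetical_count=cds_count - assigned_count,
        mean_cds_length=mean_cds_length,
        percent_coding=percent(coding_bp, genome_size_bp),
        percent_assigned=percent(assigned_count, cds_count),
        percent_hypothetical=percent(cds_count - assigned_count, cds_count),
        rrna_count=rrna_count,
        ncrna_count=ncrna_count,
        trna_count=trna_count,
    )


def validation_summary(confirmed: int, total: int) -> dict:
    """Microarray-style confirmation arithmetic.

    Returns confirmed / not-detected counts and their integer percentages.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= confirmed <= total:
        raise ValueError("need 0 <= confirmed <= total")
    not_detected = total - confirmed
    return {
        "confirmed": confirmed,
        "not_detected": not_detected,
        "percent_confirmed": percent(confirmed, total),
        "percent_not_detected": percent(not_detected, total),
        "rounding_rule": ROUNDING_RULE,
    }
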