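"""Gene-level copy-number categorization from segmented log2 ratios.

A segmented array-CGH profile reports, per genomic interval, the log2 of the
tumor/normal signal ratio (0 = balanced).  This module maps those ratios onto
an eight-level ordinal category ladder (gene loss ... amplification), projects
segment-level values onto genes, and summarizes chromosomal instability with
the genomic index A^2/C.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GeneAnnotation, SegmentRecord

__all__ = [
    "CnaCategory",
    "GeneCnaCall",
    "GenomicIndexInput",
    "GAIN_CATEGORIES",
    "LOSS_CATEGORIES",
    "categorize_log2",
    "call_genes",
    "count_alterations",
    "genomic_index",
]


class CnaCategory(enum.IntEnum):
    """Ordinal copy-number category, lowest (deepest loss) to highest.

    Interval assignment follows the half-open ladder used for the 180K
    aCGH analysis:

    ========================  =======================
    category                  log2 ratio interval
    ========================  =======================
    GENE_LOSS                 log2 <= -1
    DELETION                  -1 < log2 <= -0.5
    HET_DELETION              -0.5 < log2 <= -0.1
    NEUTRAL                   -0.1 < log2 < 0.1
    HET_GAIN                  0.1 <= log2 < 0.5
    GAIN                      0.5 <= log2 < 1
    STRONG_GAIN               1 <= log2 < 2
    AMPLIFICATION             log2 >= 2
    ========================  =======================
    """

    GENE_LOSS = 0
    DELETION = 1
    HET_DELETION = 2
    NEUTRAL = 3
    HET_GAIN = 4
    GAIN = 5
    STRONG_GAIN = 6
    AMPLIFICATION = 7


GAIN_CATEGORIES = frozenset(
    {
        CnaCategory.HET_GAIN,
        CnaCategory.GAIN,
        CnaCategory.STRONG_GAIN,
        CnaCategory.AMPLIFICATION,
    }
)
LOSS_CATEGORIES = frozenset(
    {
        CnaCategory.GENE_LOSS,
        CnaCategory.DELETION,
        CnaCategory.HET_DELETION,
    }
)


def categorize_log2(log2_ratio: float) -> CnaCategory:
    """Assign a finite log2 ratio to its unique copy-number category.

    Boundary values belong to the interval whose inequality includes them:
    0.1 -> HET_GAIN, -0.1 -> HET_DELETION, -0.5 -> HET_DELETION,
    -1 -> GENE_LOSS, 1 -> STRONG_GAIN, 2 -> AMPLIFICATION.

    Raises
    ------
    ValueError
        If ``log2_ratio`` is NaN or infinite.
    """
    x = float(log2_ratio)
    if not math.isfinite(x):
        raise ValueError(f"log2 ratio must be finite, got {log2_ratio!r}")
    if x >= 2.0:
        return CnaCategory.AMPLIFICATION
    if x >= 1.0:
        return CnaCategory.STRONG_GAIN
    if x >= 0.5:
        return CnaCategory.GAIN
    if x >= 0.1:
        return CnaCategory.HET_GAIN
    if x <= -1.0:
        return CnaCategory.GENE_LOSS
    if x <= -0.5:
        return CnaCategory.DELETION
    if x <= -0.1:
        return CnaCategory.HET_DELETION
    return CnaCategory.NEUTRAL


@dataclass(frozen=True)
class GeneCnaCall:
    """One gene's copy-number call within one sample."""

    sample_id: str
    gene_symbol: str
    category: CnaCategory
    log2_ratio: float

    @property
    def is_gain(self) -> bool:
        return self.category in GAIN_CATEGORIES

    @property
    def is_loss(self) -> bool:
        return self.category in LOSS_CATEGORIES


@dataclass(frozen=True)
class GenomicIndexInput:
    """Alteration count A and involved-chromosome count C for one profile."""

    alteration_count: int
    chromosome_count: int

    def __post_init__(self) -> None:
        if self.alteration_count < 0:
            raise ValueError("alteration_count must be non-negative")
        if self.alteration_count > 0 and self.chromosome_count < 1:
            raise ValueError(
                "chromosome_count must be >= 1 when alterations are present"
            )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def call_genes(
    segments: Sequence[SegmentRecord],
    genes: Iterable[GeneAnnotation],
) -> list[GeneCnaCall]:
    """Project a single sample's segmented profile onto genes.

    Each annotated gene receives exactly one call.  A gene overlapped by no
    segment is NEUTRAL with log2 = 0.  A gene overlapped by several segments
    takes the log2 of the segment with the largest overlap length; ties are
    broken toward the larger ``|log2|`` (then toward the leftmost segment so
    the result is deterministic).

    Raises
    ------
    ValueError
        If the segments belong to more than one sample.
    """
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) > 1:
        raise ValueError(
            f"segments must belong to one sample, got {sorted(sample_ids)}"
        )
    sample_id = sample_ids.pop() if sample_ids else ""

    by_chrom: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)

    calls: list[GeneCnaCall] = []
    for gene in genes:
        best: SegmentRecord | None = None
        best_key: tuple[int, float, int] | None = None
        for seg in by_chrom.get(gene.chromosome, ()):
            ov = _overlap(gene.start, gene.end, seg.start, seg.end)
            if ov <= 0:
                continue
            key = (ov, abs(seg.log2_ratio), -seg.start)
            if best_key is None or key > best_key:
                best, best_key = seg, key
        log2 = best.log2_ratio if best is not None else 0.0
        calls.append(
            GeneCnaCall(
                sample_id=sample_id,
                gene_symbol=gene.gene_symbol,
                category=categorize_log2(log2),
                log2_ratio=log2,
            )
        )
    return calls


def count_alterations(segments: Sequence[SegmentRecord]) -> GenomicIndexInput:
    """Count altered segments (non-NEUTRAL category) and their chromosomes."""
    altered = [s for s in segments if categorize_log2(s.log2_ratio) != CnaCategory.NEUTRAL]
    chroms = {s.chromosome for s in altered}
    return GenomicIndexInput(
        alteration_count=len(altered),
        chromosome_count=max(len(chroms), 1) if altered else 0,
    )


def genomic_index(gi_input: GenomicIndexInput) -> float:
    """Genomic index A^2 / C; defined as 0 for an alteration-free profile."""
    a, c = gi_input.alteration_count, gi_input.chromosome_count
    if a == 0:
        return 0.0
    if c <= 0:
        raise ValueError("chromosome_count must be positive when A > 0")
    return a * a / c
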