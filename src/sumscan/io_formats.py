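"""Readers and writers for the on-disk formats of the pipeline.

Formats handled: SEG-style segment tables, BED3+name gene annotations,
drug->target-gene panel TSVs, per-patient clinical CSVs, variant tables
(TSV or VCF), and TTC/TTL score reports.  All text is UTF-8 with LF line
endings; internal genomic coordinates are 0-based half-open and chromosome
names never carry a "chr" prefix.

The only analysis step housed here is the variant hard filter (minimum
total depth 100 and minimum 10 alternate reads).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .target_scoring import ClinicalRecord, SumscanResult, TargetPanel

__all__ = [
    "SegmentRecord",
    "GeneAnnotation",
    "VariantRecord",
    "FormatError",
    "read_segments",
    "write_segments",
    "segments_by_sample",
    "read_gene_bed",
    "write_gene_bed",
    "read_panel",
    "write_panel",
    "read_clinical",
    "write_clinical",
    "read_variants_tsv",
    "read_variants_vcf",
    "filter_variants",
    "write_scores",
    "read_scores",
]

SEG_DIALECTS = ("seg_1based_inclusive", "bed_like_0based_halfopen")


class FormatError(ValueError):
    """A malformed input file; the message names file, line, and field."""


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class SegmentRecord:
    """One segmented interval of a tumor/normal log2 ratio profile.

    Coordinates are 0-based half-open; ``log2_ratio`` = 0 means a balanced
    tumor/normal DNA ratio.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"segment start must precede end, got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValueError(f"log2 ratio must be finite, got {self.log2_ratio!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus (HGNC-style symbol), 0-based half-open coordinates."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_symbol}: start must precede end "
                f"({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One called sequence variant with its read support."""

    sample_id: str
    gene_symbol: str
    total_depth: int
    alt_depth: int
    variant_label: str = ""

    def __post_init__(self) -> None:
        if self.total_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt depth {self.alt_depth} exceeds total depth {self.total_depth}"
            )


# ---------------------------------------------------------------------------
# segments


def _looks_like_header(fields: Sequence[str]) -> bool:
    # A header row is any row whose numeric columns do not parse.
    try:
        float(fields[-1])
        int(float(fields[2]))
        return False
    except (ValueError, IndexError):
        return True


def read_segments(
    path: str | Path, dialect: str = "seg_1based_inclusive"
) -> list[SegmentRecord]:
    """Read a tab-delimited segment table into :class:`SegmentRecord` objects.

    Expected columns: sample, chromosome, start, end, ..., log2 (the log2
    ratio is taken from the last column, so the common 6-column SEG layout
    with a marker-count column is accepted).  A header row is optional.

    Parameters
    ----------
    dialect:
        ``"seg_1based_inclusive"`` (the common SEG convention; converted to
        the internal 0-based half-open convention by decrementing the start)
        or ``"bed_like_0based_halfopen"`` (taken as-is).
    """
    if dialect not in SEG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SEG_DIALECTS}")
    path = Path(path)
    records: list[SegmentRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 5 tab-separated columns, "
                    f"got {len(fields)}"
                )
            sample, chrom = fields[0], _strip_chr(fields[1])
            try:
                start = int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer start {fields[2]!r}"
                ) from None
            try:
                end = int(fields[3])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer end {fields[3]!r}"
                ) from None
            try:
                log2 = float(fields[-1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric log2 ratio {fields[-1]!r}"
                ) from None
            if dialect == "seg_1based_inclusive":
                start -= 1
            try:
                records.append(
                    SegmentRecord(sample, chrom, start, end, log2)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_segments(
    records: Iterable[SegmentRecord],
    path: str | Path,
    dialect: str = "seg_1based_inclusive",
) -> None:
    """Write segments as a 5-column SEG-style table (inverse of read)."""
    if dialect not in SEG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SEG_DIALECTS}")
    offset = 1 if dialect == "seg_1based_inclusive" else 0
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tchromosome\tstart\tend\tlog2_ratio\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chromosome}\t{r.start + offset}\t{r.end}\t"
                f"{r.log2_ratio:.6f}\n"
            )


def segments_by_sample(
    records: Iterable[SegmentRecord],
) -> dict[str, list[SegmentRecord]]:
    """Group segment records per sample, preserving input order."""
    grouped: dict[str, list[SegmentRecord]] = {}
    for r in records:
        grouped.setdefault(r.sample_id, []).append(r)
    return grouped


# ---------------------------------------------------------------------------
# gene annotations


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED3+name file (0-based half-open) of gene loci.

    Duplicate gene symbols are rejected: every downstream step assumes one
    locus per symbol.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected BED3+name (4 columns), "
                    f"got {len(fields)}"
                )
            chrom, symbol = _strip_chr(fields[0]), fields[3]
            if symbol in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate gene symbol {symbol!r}"
                )
            seen.add(symbol)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            try:
                genes.append(GeneAnnotation(symbol, chrom, start, end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_symbol}\n")


# ---------------------------------------------------------------------------
# drug panels


def read_panel(path: str | Path) -> "list[TargetPanel]":
    """Read a two-column TSV (drug, gene_symbol) into per-drug target panels.

    Gene symbols are normalized (case-insensitive, Greek-letter aliases) and
    de-duplicated within each panel; panel order follows first appearance of
    each drug.
    """
    from .target_scoring import TargetPanel, normalize_gene_symbol

    path = Path(path)
    panels: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected columns drug, gene_symbol"
                )
            drug, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and drug.lower() == "drug":
                continue
            if not drug:
                raise FormatError(f"{path}:{lineno}: empty drug field")
            if not gene:
                raise FormatError(f"{path}:{lineno}: empty gene_symbol field")
            symbol = normalize_gene_symbol(gene)
            bucket = panels.setdefault(drug, [])
            if symbol not in bucket:
                bucket.append(symbol)
    return [TargetPanel(drug=drug, genes=frozenset(genes)) for drug, genes in panels.items()]


def write_panel(panels: "Iterable[TargetPanel]", path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug\tgene_symbol\n")
        for panel in panels:
            for gene in sorted(panel.genes):
                fh.write(f"{panel.drug}\t{gene}\n")


# ---------------------------------------------------------------------------
# clinical tables

_CLINICAL_COLUMNS = [
    "sample_id",
    "drug",
    "line",
    "best_response",
    "response_duration_months",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "benefit",
]


def _opt_float(text: str) -> float | None:
    text = text.strip()
    return None if text in ("", "NA", "NaN") else float(text)


def _opt_bool(text: str) -> bool | None:
    text = text.strip()
    if text in ("", "NA"):
        return None
    if text in ("1", "True", "true", "TRUE"):
        return True
    if text in ("0", "False", "false", "FALSE"):
        return False
    raise ValueError(f"not a boolean flag: {text!r}")


def read_clinical(path: str | Path) -> "list[ClinicalRecord]":
    """Read the per-patient clinical CSV.

    Columns: sample_id, drug, line, best_response (CR/PR/SD/PD),
    response_duration_months, pfs_months, pfs_event, os_months, os_event,
    benefit (POSITIVE/NEGATIVE).  Missing optional values are empty or "NA".
    """
    from .target_scoring import Benefit, BestResponse, ClinicalRecord

    path = Path(path)
    records: list[ClinicalRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CLINICAL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                benefit_text = (row["benefit"] or "").strip()
                records.append(
                    ClinicalRecord(
                        sample_id=row["sample_id"].strip(),
                        drug=row["drug"].strip(),
                        line=int(row["line"]),
                        best_response=BestResponse[row["best_response"].strip()],
                        response_duration_months=_opt_float(
                            row["response_duration_months"]
                        ),
                        pfs_months=float(row["pfs_months"]),
                        pfs_event=bool(_opt_bool(row["pfs_event"])),
                        os_months=_opt_float(row["os_months"]),
                        os_event=_opt_bool(row["os_event"]),
                        benefit=Benefit[benefit_text] if benefit_text else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_clinical(records: "Iterable[ClinicalRecord]", path: str | Path) -> None:
    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, float):
            return f"{value:.4f}"
        if hasattr(value, "name"):
            return value.name
        return str(value)

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                ",".join(
                    fmt(getattr(r, col)) for col in _CLINICAL_COLUMNS
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# variants


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with columns sample_id, gene_symbol, total_depth,
    alt_depth[, variant_label]."""
    path = Path(path)
    records: list[VariantRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "sample_id":
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 columns "
                    "(sample_id, gene_symbol, total_depth, alt_depth)"
                )
            try:
                records.append(
                    VariantRecord(
                        sample_id=fields[0],
                        gene_symbol=fields[1],
                        total_depth=int(fields[2]),
                        alt_depth=int(fields[3]),
                        variant_label=fields[4] if len(fields) > 4 else "",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variants from a VCF v4.x file.

    Total depth comes from FORMAT/DP (or INFO/DP when no sample column);
    alt support from FORMAT/AD or INFO/AO.  The gene symbol is taken from an
    INFO ``GENE`` tag when present, else left empty.
    """
    import cyvcf2

    path = Path(path)
    records: list[VariantRecord] = []
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    for var in vcf:
        gene = var.INFO.get("GENE") or ""
        label = f"{var.CHROM}:{var.POS} {var.REF}>{','.join(var.ALT)}"
        if samples:
            depths = var.format("DP")
            ads = var.format("AD")
            for i, sample in enumerate(samples):
                total = int(depths[i][0]) if depths is not None else 0
                alt = int(ads[i][1]) if ads is not None and ads.shape[1] > 1 else 0
                records.append(
                    VariantRecord(sample, gene, max(total, alt), alt, label)
                )
        else:
            total = int(var.INFO.get("DP") or 0)
            alt = int(var.INFO.get("AO") or 0)
            records.append(VariantRecord("", gene, max(total, alt), alt, label))
    return records


def filter_variants(
    records: Iterable[VariantRecord],
    min_depth: int = 100,
    min_alt: int = 10,
) -> list[VariantRecord]:
    """Hard-filter variants on read support, preserving input order.

    Keeps exactly the records with ``total_depth >= min_depth`` and
    ``alt_depth >= min_alt`` (defaults: 100 total reads, 10 mutant reads).
    """
    return [
        r
        for r in records
        if r.total_depth >= min_depth and r.alt_depth >= min_alt
    ]


# ---------------------------------------------------------------------------
# score reports


def write_scores(results: "Iterable[SumscanResult]", path: str | Path) -> None:
    """Write TTC/TTL scores and classifications as a TSV report."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tdrug\tTTC\tTTL\tTTC_minus_TTL\tsumscan_class\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.drug}\t{r.ttc}\t{r.ttl}\t{r.delta}\t"
                f"{r.sumscan_class.name}\n"
            )


def read_scores(path: str | Path) -> "list[SumscanResult]":
    """Read a score TSV written by :func:`write_scores`."""
    from .target_scoring import SumscanClass, SumscanResult

    path = Path(path)
    results: list[SumscanResult] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "drug", "TTC", "TTL", "TTC_minus_TTL", "sumscan_class"]
        if header != expected:
            raise FormatError(f"{path}: unexpected score header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                results.append(
                    SumscanResult(
                        sample_id=fields[0],
                        drug=fields[1],
                        ttc=int(fields[2]),
                        ttl=int(fields[3]),
                        sumscan_class=SumscanClass[fields[5]],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return results
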