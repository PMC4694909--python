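"""Tumor Target Charge / Tumor Target Loss scoring and the SUMSCAN rule.

For a given multi-tyrosine-kinase inhibitor (MTKI), the Tumor Target Charge
(TTC) is the number of the drug's target genes carrying any copy-number gain
in a tumor, and the Tumor Target Loss (TTL) is the number carrying any loss.
Each gene contributes at most one event regardless of amplitude.  The SUMSCAN
rule converts (TTC, TTL) into a binary favorable/unfavorable prediction of
clinical benefit: by default a tumor is FAVORABLE when TTC >= 4 and TTC
exceeds TTL; both components are independently configurable.

Clinical benefit follows the RECIST-based definition: complete response,
partial response, or stable disease lasting at least 2 months is benefit
POSITIVE; progressive disease as best response at or before 8 weeks is
benefit NEGATIVE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cna_core import CnaCategory, GeneCnaCall

__all__ = [
    "REGORAFENIB_TARGETS",
    "Benefit",
    "BestResponse",
    "ClinicalRecord",
    "SumscanClass",
    "SumscanResult",
    "SumscanThresholds",
    "TargetPanel",
    "compute_ttc",
    "compute_ttl",
    "label_clinical_benefit",
    "normalize_gene_symbol",
    "score_cohort",
    "sumscan_classify",
]

#: The 18 kinase-coding regorafenib target genes.
REGORAFENIB_TARGETS = frozenset(
    {
        "RET", "FLT1", "KDR", "FLT4", "KIT", "PDGFRA", "PDGFRB",
        "FGFR1", "FGFR2", "TEK", "DDR2", "NTRK1", "EPHA2", "RAF1",
        "BRAF", "MAPK11", "FRK", "ABL1",
    }
)

# Aliases map mixed Greek/Latin and legacy spellings onto HGNC symbols.
_GENE_ALIASES = {
    "PDGFRα": "PDGFRA",   # lowercase alpha
    "PDGFRΑ": "PDGFRA",   # uppercase alpha (str.upper of the above)
    "PDGFRβ": "PDGFRB",
    "PDGFRΒ": "PDGFRB",
    "VEGFR1": "FLT1",
    "VEGFR2": "KDR",
    "VEGFR3": "FLT4",
}


def normalize_gene_symbol(symbol: str) -> str:
    """Canonical HGNC-style symbol: uppercased, Greek suffixes mapped."""
    s = symbol.strip().upper()
    return _GENE_ALIASES.get(s, s)


class SumscanClass(enum.Enum):
    FAVORABLE = "FAVORABLE"
    UNFAVORABLE = "UNFAVORABLE"


class Benefit(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class BestResponse(enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class TargetPanel:
    """A drug and the set of genes encoding its protein-kinase targets."""

    drug: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("panel drug name must be non-empty")
        if not self.genes:
            raise ValueError(f"panel for {self.drug!r} must contain genes")
        object.__setattr__(
            self, "genes", frozenset(normalize_gene_symbol(g) for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)


def regorafenib_panel() -> TargetPanel:
    return TargetPanel(drug="regorafenib", genes=REGORAFENIB_TARGETS)


@dataclass(frozen=True)
class SumscanThresholds:
    """Tunable components of the SUMSCAN rule.

    min_ttc:
        Minimum TTC for a FAVORABLE call (default 4).
    require_ttc_exceeds_ttl:
        When true (default), more or equally many target losses than gains
        forces UNFAVORABLE.
    large_delta:
        TTC - TTL at or above this is flagged as a "large difference"
        (default 5); reported only, never used in classification.
    count_strong_gain:
        Whether STRONG_GAIN events count toward TTC (default true).
    """

    min_ttc: int = 4
    require_ttc_exceeds_ttl: bool = True
    large_delta: int = 5
    count_strong_gain: bool = True

    def __post_init__(self) -> None:
        if self.min_ttc < 0:
            raise ValueError("min_ttc must be >= 0")

    def to_dict(self) -> dict:
        return {
            "min_ttc": self.min_ttc,
            "require_ttc_exceeds_ttl": self.require_ttc_exceeds_ttl,
            "large_delta": self.large_delta,
            "count_strong_gain": self.count_strong_gain,
        }


DEFAULT_THRESHOLDS = SumscanThresholds()


@dataclass(frozen=True)
class SumscanResult:
    """Per (sample, drug) TTC/TTL scores and the SUMSCAN call."""

    sample_id: str
    drug: str
    ttc: int
    ttl: int
    sumscan_class: SumscanClass
    large_delta: bool = False
    benefit: Benefit | None = None

    def __post_init__(self) -> None:
        if self.ttc < 0 or self.ttl < 0:
            raise ValueError("TTC and TTL must be non-negative")

    @property
    def delta(self) -> int:
        return self.ttc - self.ttl


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient-drug-line row of the clinical outcome table."""

    sample_id: str
    drug: str
    line: int
    best_response: BestResponse
    pfs_months: float
    pfs_event: bool
    response_duration_months: float | None = None
    os_months: float | None = None
    os_event: bool | None = None
    benefit: Benefit | None = None

    def __post_init__(self) -> None:
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be >= 0")
        if self.os_months is not None and self.os_months < self.pfs_months:
            raise ValueError("os_months must be >= pfs_months")


def _panel_calls(
    calls: Iterable[GeneCnaCall], panel: TargetPanel
) -> dict[str, GeneCnaCall]:
    """Index calls by normalized symbol, restricted to the panel.

    Panel genes without a call are treated as NEUTRAL (absent here,
    contributing to neither TTC nor TTL).
    """
    indexed: dict[str, GeneCnaCall] = {}
    for call in calls:
        symbol = normalize_gene_symbol(call.gene_symbol)
        if symbol in panel.genes and symbol not in indexed:
            indexed[symbol] = call
    return indexed


def compute_ttc(
    calls: Iterable[GeneCnaCall],
    panel: TargetPanel,
    count_strong_gain: bool = True,
) -> int:
    """Tumor Target Charge: panel genes carrying any copy-number gain.

    Amplification, strong gain, gain, and heterogeneous gain each count as
    one event; a gene contributes at most once.  Set
    ``count_strong_gain=False`` to restrict to the three named gain types.
    """
    ttc = 0
    for call in _panel_calls(calls, panel).values():
        if not call.is_gain:
            continue
        if not count_strong_gain and call.category is CnaCategory.STRONG_GAIN:
            continue
        ttc += 1
    return ttc


def compute_ttl(calls: Iterable[GeneCnaCall], panel: TargetPanel) -> int:
    """Tumor Target Loss: panel genes carrying any copy-number loss
    (gene loss, deletion, or heterogeneous deletion), one event per gene."""
    return sum(1 for call in _panel_calls(calls, panel).values() if call.is_loss)


def sumscan_classify(
    ttc: int,
    ttl: int,
    thresholds: SumscanThresholds = DEFAULT_THRESHOLDS,
) -> SumscanClass:
    """Apply the SUMSCAN rule to a (TTC, TTL) pair.

    FAVORABLE iff TTC >= ``thresholds.min_ttc`` and, when the TTL rule is
    active, TTC > TTL.  With ``min_ttc=0`` and the TTL rule on, this reduces
    to the pure sign test TTC > TTL (more target losses than gains predicts
    resistance).
    """
    if ttc < 0 or ttl < 0:
        raise ValueError("TTC and TTL must be non-negative")
    if ttc < thresholds.min_ttc:
        return SumscanClass.UNFAVORABLE
    if thresholds.require_ttc_exceeds_ttl and not ttc > ttl:
        return SumscanClass.UNFAVORABLE
    return SumscanClass.FAVORABLE


def label_clinical_benefit(
    best_response: BestResponse,
    response_duration_months: float | None = None,
    time_to_progression_weeks: float | None = None,
) -> Benefit:
    """Derive the MTKI clinical-benefit label from the RECIST best response.

    CR or PR is always POSITIVE; SD is POSITIVE when it lasted at least
    2 months and NEGATIVE otherwise; PD as best response (reached at or
    before the first 8-week evaluation) is NEGATIVE.

    Raises
    ------
    ValueError
        For SD without a recorded duration — the label cannot be derived.
    """
    if best_response in (BestResponse.CR, BestResponse.PR):
        return Benefit.POSITIVE
    if best_response is BestResponse.SD:
        if response_duration_months is None:
            raise ValueError(
                "stable disease requires a response duration to derive benefit"
            )
        return (
            Benefit.POSITIVE
            if response_duration_months >= 2.0
            else Benefit.NEGATIVE
        )
    # PD as best response: progression at/before the first evaluation window.
    return Benefit.NEGATIVE


def _derive_benefit(record: ClinicalRecord) -> Benefit | None:
    if record.benefit is not None:
        return record.benefit
    try:
        return label_clinical_benefit(
            record.best_response, record.response_duration_months
        )
    except ValueError:
        return None


def score_cohort(
    profiles: Mapping[str, Sequence[GeneCnaCall]],
    panels: Mapping[str, TargetPanel],
    clinical: Sequence[ClinicalRecord] = (),
    thresholds: SumscanThresholds = DEFAULT_THRESHOLDS,
) -> list[SumscanResult]:
    """Score every (sample, drug) pair and join benefit labels.

    Pairs come from the clinical table; samples with a profile but no
    clinical record are scored against every panel, unlabeled.

    Raises
    ------
    KeyError
        If a clinical record references a drug without a panel, or a sample
        without a profile.
    """
    pairs: list[tuple[str, str, ClinicalRecord | None]] = []
    clinical_samples = set()
    for rec in clinical:
        if rec.drug not in panels:
            raise KeyError(f"no target panel for drug {rec.drug!r}")
        if rec.sample_id not in profiles:
            raise KeyError(f"clinical record for unknown sample {rec.sample_id!r}")
        clinical_samples.add(rec.sample_id)
        pairs.append((rec.sample_id, rec.drug, rec))
    for sample_id in profiles:
        if sample_id not in clinical_samples:
            for drug in panels:
                pairs.append((sample_id, drug, None))

    results: list[SumscanResult] = []
    for sample_id, drug, rec in pairs:
        panel = panels[drug]
        calls = profiles[sample_id]
        ttc = compute_ttc(calls, panel, thresholds.count_strong_gain)
        ttl = compute_ttl(calls, panel)
        results.append(
            SumscanResult(
                sample_id=sample_id,
                drug=drug,
                ttc=ttc,
                ttl=ttl,
                sumscan_class=sumscan_classify(ttc, ttl, thresholds),
                large_delta=(ttc - ttl) >= thresholds.large_delta,
                benefit=_derive_benefit(rec) if rec is not None else None,
            )
        )
    return results
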