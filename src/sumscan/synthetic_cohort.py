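"""Synthetic MTKI cohort generator.

The real patient-level data behind the TTC/TTL analysis are not public, so
this module generates cohorts with the same statistical structure the
analysis assumes: class-conditional counts of gained and lost target genes
(truncated Poisson), genome-wide gain/loss burden over a 187-gene universe,
and progression-free survival whose median depends on the SUMSCAN class.
Output is ordinary segment/annotation/clinical data, so the entire pipeline
(gene calling, scoring, classification, evaluation, survival) runs on it
unchanged.

Default parameters are the cohort-level summaries of the pooled regorafenib
series: mean gained target genes 6.8 (benefit-positive) vs 2.1 (negative),
mean lost target genes 1.3 vs 2.4, genome-wide gains 49.5 vs 16.7 and losses
15.9 vs 18.9 over 187 genes, benefit prevalence 11/25, and median PFS 9.9
months (SUMSCAN favorable) vs 2.8 (unfavorable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cna_core import CnaCategory, GAIN_CATEGORIES, LOSS_CATEGORIES
from .io_formats import GeneAnnotation, SegmentRecord, VariantRecord
from .target_scoring import (
    Benefit,
    BestResponse,
    ClinicalRecord,
    REGORAFENIB_TARGETS,
    SumscanClass,
    SumscanThresholds,
    DEFAULT_THRESHOLDS,
    TargetPanel,
    sumscan_classify,
)

__all__ = [
    "CohortSimParams",
    "SimulatedCohort",
    "expected_operating_point",
    "generate_cohort",
    "make_gene_universe",
]

_GAIN_CLASSES = sorted(GAIN_CATEGORIES)
_LOSS_CLASSES = sorted(LOSS_CATEGORIES)

# Sampling intervals per category as (lo, hi) for |log2|; numpy's uniform is
# half-open [lo, hi), which keeps every draw strictly inside its category.
_CATEGORY_MAGNITUDE = {
    CnaCategory.HET_GAIN: (0.1, 0.5),
    CnaCategory.GAIN: (0.5, 1.0),
    CnaCategory.STRONG_GAIN: (1.0, 2.0),
    CnaCategory.AMPLIFICATION: (2.0, 3.0),  # amplitude capped at log2 = 3
    CnaCategory.HET_DELETION: (0.1, 0.5),
    CnaCategory.DELETION: (0.5, 1.0),
    CnaCategory.GENE_LOSS: (1.0, 3.0),
}


@dataclass(frozen=True)
class CohortSimParams:
    """Study-condition parameters of the simulated cohort.

    Counts of altered genes are Poisson, truncated at the panel/universe
    size; survival is exponential, parameterized by its median in months.
    """

    n_patients: int = 25
    benefit_fraction: float = 0.44  # 11 of 25 pooled regorafenib patients
    target_gain_mean_pos: float = 6.8
    target_gain_mean_neg: float = 2.1
    target_loss_mean_pos: float = 1.3
    target_loss_mean_neg: float = 2.4
    genome_gain_mean_pos: float = 49.5
    genome_gain_mean_neg: float = 16.7
    genome_loss_mean_pos: float = 15.9
    genome_loss_mean_neg: float = 18.9
    gene_universe_size: int = 187
    panel_size: int = 18
    median_pfs_favorable: float = 9.9
    median_pfs_unfavorable: float = 2.8
    median_os_extra: float = 6.0  # OS = PFS + exponential tail, months
    censoring_probability: float = 0.2
    drug: str = "regorafenib"
    multi_gene_segments: bool = False
    simulate_mutations: bool = False
    pik3ca_rate_low_ttc_negative: float = 0.6
    pik3ca_rate_other: float = 0.05

    def __post_init__(self) -> None:
        if self.panel_size > self.gene_universe_size:
            raise ValueError(
                f"panel_size {self.panel_size} exceeds gene_universe_size "
                f"{self.gene_universe_size}"
            )
        if not 0.0 <= self.benefit_fraction <= 1.0:
            raise ValueError("benefit_fraction must lie in [0, 1]")
        for name in (
            "target_gain_mean_pos", "target_gain_mean_neg",
            "target_loss_mean_pos", "target_loss_mean_neg",
            "genome_gain_mean_pos", "genome_gain_mean_neg",
            "genome_loss_mean_pos", "genome_loss_mean_neg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    segments: list[SegmentRecord]
    genes: list[GeneAnnotation]
    panel: TargetPanel
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame  # per sample: benefit, ttc, ttl, sumscan_class, pfs
    planted_categories: dict[tuple[str, str], CnaCategory]
    variants: list[VariantRecord] = field(default_factory=list)


def make_gene_universe(params: CohortSimParams) -> tuple[list[GeneAnnotation], TargetPanel]:
    """Synthetic gene universe: the drug's target genes plus filler genes.

    Loci are laid out deterministically over chromosomes 1..22 (round-robin,
    100 kb genes separated by 150 kb gaps) — downstream computation only
    needs consistent, non-overlapping coordinates.
    """
    target_names = sorted(REGORAFENIB_TARGETS)[: params.panel_size]
    if params.panel_size > len(target_names):
        target_names += [
            f"TGT{i:03d}" for i in range(len(target_names), params.panel_size)
        ]
    filler = [
        f"GENE{i:03d}" for i in range(params.gene_universe_size - params.panel_size)
    ]
    names = target_names + filler

    gene_len, gap = 100_000, 150_000
    genes: list[GeneAnnotation] = []
    per_chrom_slot: dict[str, int] = {}
    for i, name in enumerate(names):
        chrom = str(i % 22 + 1)
        slot = per_chrom_slot.get(chrom, 0)
        per_chrom_slot[chrom] = slot + 1
        start = 1_000_000 + slot * (gene_len + gap)
        genes.append(GeneAnnotation(name, chrom, start, start + gene_len))
    panel = TargetPanel(drug=params.drug, genes=frozenset(target_names))
    return genes, panel


def _truncated_poisson_pmf(mean: float, cap: int) -> np.ndarray:
    """Poisson(mean) pmf renormalized on {0..cap}.

    When the untruncated mass on the support underflows (a degenerate, very
    large mean), all mass is placed at the cap — the correct limit.
    """
    ks = np.arange(cap + 1)
    pmf = stats.poisson.pmf(ks, mean) if mean > 0 else np.where(ks == 0, 1.0, 0.0)
    total = pmf.sum()
    if total <= 0 or not np.isfinite(total):
        pmf = np.zeros(cap + 1)
        pmf[cap] = 1.0
        return pmf
    return pmf / total


def _draw_truncated_poisson(rng: np.random.Generator, mean: float, cap: int) -> int:
    if cap <= 0:
        return 0
    return int(rng.choice(cap + 1, p=_truncated_poisson_pmf(mean, cap)))


def _draw_log2(rng: np.random.Generator, category: CnaCategory) -> float:
    if category is CnaCategory.NEUTRAL:
        # strictly inside (-0.1, 0.1): magnitude in [0, 0.1), random sign
        return float(rng.uniform(0.0, 0.1) * rng.choice([-1.0, 1.0]))
    lo, hi = _CATEGORY_MAGNITUDE[category]
    magnitude = float(rng.uniform(lo, hi))
    return -magnitude if category in LOSS_CATEGORIES else magnitude


def generate_cohort(
    params: CohortSimParams = CohortSimParams(),
    seed: int = 0,
    thresholds: SumscanThresholds = DEFAULT_THRESHOLDS,
) -> SimulatedCohort:
    """Generate a reproducible synthetic cohort.

    Per patient: the benefit label is Bernoulli(benefit_fraction); counts of
    gained/lost target genes and of altered non-target genes are drawn from
    the class-conditional truncated Poissons; each altered gene receives a
    log2 value drawn uniformly within a uniformly chosen gain (or loss)
    category interval, all other genes a neutral value; one segment is
    emitted per gene.  PFS is exponential with the median of the tumor's
    SUMSCAN class (as computed from the planted TTC/TTL under
    ``thresholds``), censored with the stated probability; OS adds an
    exponential tail.  Identical seed and parameters give identical output.
    """
    rng = np.random.default_rng(seed)
    genes, panel = make_gene_universe(params)
    target_genes = [g for g in genes if g.gene_symbol in panel.genes]
    other_genes = [g for g in genes if g.gene_symbol not in panel.genes]
    gene_index = {g.gene_symbol: i for i, g in enumerate(genes)}
    next_on_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        next_on_chrom.setdefault(g.chromosome, []).append(g)

    segments: list[SegmentRecord] = []
    clinical: list[ClinicalRecord] = []
    truth_rows: list[dict] = []
    planted: dict[tuple[str, str], CnaCategory] = {}
    variants: list[VariantRecord] = []

    log2_ln = float(np.log(2.0))
    for i in range(params.n_patients):
        sample = f"SIM{i + 1:04d}"
        positive = bool(rng.random() < params.benefit_fraction)
        gain_mean = params.target_gain_mean_pos if positive else params.target_gain_mean_neg
        loss_mean = params.target_loss_mean_pos if positive else params.target_loss_mean_neg
        n_gain = _draw_truncated_poisson(rng, gain_mean, params.panel_size)
        n_loss = _draw_truncated_poisson(rng, loss_mean, params.panel_size - n_gain)

        order = rng.permutation(len(target_genes))
        gained = {target_genes[j].gene_symbol for j in order[:n_gain]}
        lost = {target_genes[j].gene_symbol for j in order[n_gain:n_gain + n_loss]}

        # Non-target burden: total genome-wide mean minus the target-gene
        # contribution, spread over the filler genes.
        g_extra_mean = max(
            0.0,
            (params.genome_gain_mean_pos if positive else params.genome_gain_mean_neg)
            - gain_mean,
        )
        l_extra_mean = max(
            0.0,
            (params.genome_loss_mean_pos if positive else params.genome_loss_mean_neg)
            - loss_mean,
        )
        n_other = len(other_genes)
        n_gain_other = _draw_truncated_poisson(rng, g_extra_mean, n_other)
        n_loss_other = _draw_truncated_poisson(
            rng, l_extra_mean, n_other - n_gain_other
        )
        order_other = rng.permutation(n_other)
        gained |= {other_genes[j].gene_symbol for j in order_other[:n_gain_other]}
        lost |= {
            other_genes[j].gene_symbol
            for j in order_other[n_gain_other:n_gain_other + n_loss_other]
        }

        for gene in genes:
            if gene.gene_symbol in gained:
                category = _GAIN_CLASSES[rng.integers(len(_GAIN_CLASSES))]
            elif gene.gene_symbol in lost:
                category = _LOSS_CLASSES[rng.integers(len(_LOSS_CLASSES))]
            else:
                category = CnaCategory.NEUTRAL
            planted[(sample, gene.gene_symbol)] = category
            log2 = _draw_log2(rng, category)
            end = gene.end
            if (
                params.multi_gene_segments
                and category is not CnaCategory.NEUTRAL
                and rng.random() < 0.25
            ):
                # Extend into 40% of the next gene on the chromosome; the
                # neighbor's own full-length segment still dominates, so the
                # overlap tie-break (not the call) is exercised.
                chrom_genes = next_on_chrom[gene.chromosome]
                pos = chrom_genes.index(gene)
                if pos + 1 < len(chrom_genes):
                    neighbor = chrom_genes[pos + 1]
                    end = neighbor.start + int(0.4 * (neighbor.end - neighbor.start))
            segments.append(
                SegmentRecord(sample, gene.chromosome, gene.start, end, log2)
            )

        ttc, ttl = n_gain, n_loss
        sclass = sumscan_classify(ttc, ttl, thresholds)
        median = (
            params.median_pfs_favorable
            if sclass is SumscanClass.FAVORABLE
            else params.median_pfs_unfavorable
        )
        pfs_true = float(rng.exponential(median / log2_ln))
        censored = bool(rng.random() < params.censoring_probability)
        pfs = float(rng.uniform(0.0, pfs_true)) if censored else pfs_true
        os_extra = float(rng.exponential(params.median_os_extra / log2_ln))
        os_time = pfs + os_extra
        os_event = not censored and bool(rng.random() < 0.8)

        if positive:
            best = BestResponse.PR if rng.random() < 0.3 else BestResponse.SD
            duration = (
                float(2.0 + rng.exponential(2.0)) if best is BestResponse.SD else None
            )
        else:
            best = BestResponse.PD
            duration = None
        clinical.append(
            ClinicalRecord(
                sample_id=sample,
                drug=params.drug,
                line=1,
                best_response=best,
                response_duration_months=duration,
                pfs_months=pfs,
                pfs_event=not censored,
                os_months=os_time,
                os_event=os_event,
                benefit=Benefit.POSITIVE if positive else Benefit.NEGATIVE,
            )
        )
        truth_rows.append(
            {
                "sample_id": sample,
                "benefit": "POSITIVE" if positive else "NEGATIVE",
                "ttc": ttc,
                "ttl": ttl,
                "sumscan_class": sclass.name,
                "pfs_true_months": pfs_true,
                "censored": censored,
            }
        )

        if params.simulate_mutations:
            low_ttc_negative = (not positive) and ttc <= 2
            rate = (
                params.pik3ca_rate_low_ttc_negative
                if low_ttc_negative
                else params.pik3ca_rate_other
            )
            if rng.random() < rate:
                depth = int(rng.integers(150, 1200))
                alt = int(rng.integers(15, max(16, depth // 3)))
                variants.append(
                    VariantRecord(sample, "PIK3CA", depth, alt, "PIK3CA E545K")
                )

    return SimulatedCohort(
        segments=segments,
        genes=genes,
        panel=panel,
        clinical=clinical,
        truth=pd.DataFrame(truth_rows),
        planted_categories=planted,
        variants=variants,
    )


def expected_operating_point(
    params: CohortSimParams,
    thresholds: SumscanThresholds = DEFAULT_THRESHOLDS,
) -> tuple[float, float]:
    """Analytic (sensitivity, specificity) of SUMSCAN under the generator.

    Sums the exact joint distribution of (TTC, TTL) per benefit class —
    TTC ~ truncated Poisson on {0..panel}, TTL | TTC ~ truncated Poisson on
    {0..panel-TTC} — to get the probability of a FAVORABLE call in each
    class.  Sensitivity is that probability in the positive class;
    specificity is its complement in the negative class.
    """
    def favorable_probability(gain_mean: float, loss_mean: float) -> float:
        cap = params.panel_size
        p_gain = _truncated_poisson_pmf(gain_mean, cap)
        prob = 0.0
        for ttc in range(cap + 1):
            if p_gain[ttc] == 0.0:
                continue
            if ttc < thresholds.min_ttc:
                continue
            if not thresholds.require_ttc_exceeds_ttl:
                prob += p_gain[ttc]
                continue
            p_loss = _truncated_poisson_pmf(loss_mean, cap - ttc)
            # favorable needs ttl < ttc (and ttl ranges over 0..cap-ttc)
            upper = min(ttc - 1, cap - ttc)
            if upper >= 0:
                prob += p_gain[ttc] * float(p_loss[: upper + 1].sum())
        return prob

    sensitivity = favorable_probability(
        params.target_gain_mean_pos, params.target_loss_mean_pos
    )
    specificity = 1.0 - favorable_probability(
        params.target_gain_mean_neg, params.target_loss_mean_neg
    )
    return sensitivity, specificity
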