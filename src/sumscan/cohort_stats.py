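"""Contingency and rank statistics plus classifier-performance evaluation.

Fisher's exact test is implemented by exact integer enumeration of the
hypergeometric distribution so that the two-sided rule is explicit: the
default point-probability ("Fisher-Irwin") rule sums all tables whose
probability does not exceed that of the observed table; the doubling rule
(twice the smaller tail, capped at 1) is available behind a flag.
Chi-square and Mann-Whitney delegate to scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cna_core import GeneCnaCall
from .target_scoring import Benefit, SumscanClass, SumscanResult, normalize_gene_symbol

__all__ = [
    "ClassifierMetrics",
    "ConfusionMatrix",
    "ContingencyTable2x2",
    "GeneFrequencyResult",
    "chi_square_2x2",
    "confusion_metrics",
    "evaluate_classifier",
    "fisher_exact_two_sided",
    "format_percent",
    "gene_frequency_table",
    "gene_gain_loss_frequencies",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d with rows = group (or classifier), columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one count")

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    return ContingencyTable2x2.from_rows(table)


def fisher_exact_two_sided(table, rule: str = "point_probability") -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    With the default ``rule="point_probability"`` the p-value sums, over all
    tables with the observed margins, the hypergeometric probabilities not
    exceeding that of the observed table (exact integer arithmetic, so ties
    at the observed probability are handled without rounding).  With
    ``rule="doubling"`` it is twice the smaller one-sided tail, capped at 1.

    A table with a zero margin carries no information about association; it
    yields p = 1 with a degenerate-table warning.
    """
    t = _as_table(table)
    if rule not in ("point_probability", "doubling"):
        raise ValueError(f"unknown two-sided rule {rule!r}")
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn(
            "degenerate 2x2 table (zero margin); Fisher p set to 1",
            stacklevel=2,
        )
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total_weight = comb(n, c1)
    w_obs = weights[t.a]
    if rule == "point_probability":
        numer = sum(w for w in weights.values() if w <= w_obs)
        return numer / total_weight
    left = sum(w for x, w in weights.items() if x <= t.a)
    right = sum(w for x, w in weights.items() if x >= t.a)
    return min(1.0, 2.0 * min(left, right) / total_weight)


def chi_square_2x2(table, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (df = 1) on a 2x2 table.

    Yates continuity correction is applied only when requested; the default
    is the uncorrected statistic.

    Raises
    ------
    ValueError
        If any expected cell count is zero (a zero margin); Fisher's exact
        test is the appropriate alternative there.
    """
    t = _as_table(table)
    observed = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    expected = stats.contingency.expected_freq(observed)
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell count; use fisher_exact_two_sided instead"
        )
    res = stats.chi2_contingency(observed, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact: bool | None = None,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    By default the exact permutation null is used when the pooled size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction.  Returns (U statistic of the first group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if exact is None:
        exact = (a.size + b.size <= 20) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# classifier evaluation


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = clinical benefit, predicted positive = FAVORABLE."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassifierMetrics:
    """Fractions in [0, 1]; a metric with a 0/0 denominator is None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(cm: ConfusionMatrix) -> ClassifierMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a confusion matrix."""
    return ClassifierMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def evaluate_classifier(
    results: Sequence[SumscanResult],
) -> tuple[ConfusionMatrix, ClassifierMetrics]:
    """Cross-tabulate SUMSCAN calls against clinical-benefit labels.

    FAVORABLE + benefit POSITIVE counts as a true positive.  Every result
    must carry a benefit label.
    """
    if not results:
        raise ValueError("no labeled results to evaluate")
    tp = fn = fp = tn = 0
    for r in results:
        if r.benefit is None:
            raise ValueError(f"unlabeled result for sample {r.sample_id!r}")
        favorable = r.sumscan_class is SumscanClass.FAVORABLE
        positive = r.benefit is Benefit.POSITIVE
        if favorable and positive:
            tp += 1
        elif favorable:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    return cm, confusion_metrics(cm)


# ---------------------------------------------------------------------------
# per-gene gain/loss frequencies


@dataclass(frozen=True)
class GeneFrequencyResult:
    """Class-conditional gain/loss frequencies for one gene."""

    gene_symbol: str
    n_positive: int
    n_negative: int
    gains_positive: int
    gains_negative: int
    losses_positive: int
    losses_negative: int
    freq_gain_pos: float
    freq_gain_neg: float
    freq_loss_pos: float
    freq_loss_neg: float
    fisher_p_gain: float
    fisher_p_loss: float


def _split_counts(
    calls_by_sample: Mapping[str, Sequence[GeneCnaCall]],
    labels: Mapping[str, Benefit],
    gene: str,
) -> tuple[int, int, int, int, int, int]:
    symbol = normalize_gene_symbol(gene)
    n_pos = n_neg = g_pos = g_neg = l_pos = l_neg = 0
    for sample_id, label in labels.items():
        calls = calls_by_sample.get(sample_id)
        if calls is None:
            raise KeyError(f"no call set for labeled sample {sample_id!r}")
        match = [c for c in calls if normalize_gene_symbol(c.gene_symbol) == symbol]
        if not match:
            raise KeyError(f"gene {gene!r} absent from call set of {sample_id!r}")
        call = match[0]
        if label is Benefit.POSITIVE:
            n_pos += 1
            g_pos += call.is_gain
            l_pos += call.is_loss
        else:
            n_neg += 1
            g_neg += call.is_gain
            l_neg += call.is_loss
    return n_pos, n_neg, g_pos, g_neg, l_pos, l_neg


def gene_gain_loss_frequencies(
    calls_by_sample: Mapping[str, Sequence[GeneCnaCall]],
    labels: Mapping[str, Benefit],
    gene: str,
) -> GeneFrequencyResult:
    """Gain and loss frequency of one gene in benefit-positive vs -negative
    tumors, with two-sided Fisher exact p-values on the 2x2 tables."""
    n_pos, n_neg, g_pos, g_neg, l_pos, l_neg = _split_counts(
        calls_by_sample, labels, gene
    )
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both benefit classes must be represented")

    def fisher(k_pos: int, k_neg: int) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fisher_exact_two_sided(
                ContingencyTable2x2(k_pos, n_pos - k_pos, k_neg, n_neg - k_neg)
            )

    return GeneFrequencyResult(
        gene_symbol=normalize_gene_symbol(gene),
        n_positive=n_pos,
        n_negative=n_neg,
        gains_positive=g_pos,
        gains_negative=g_neg,
        losses_positive=l_pos,
        losses_negative=l_neg,
        freq_gain_pos=g_pos / n_pos,
        freq_gain_neg=g_neg / n_neg,
        freq_loss_pos=l_pos / n_pos,
        freq_loss_neg=l_neg / n_neg,
        fisher_p_gain=fisher(g_pos, g_neg),
        fisher_p_loss=fisher(l_pos, l_neg),
    )


def gene_frequency_table(
    calls_by_sample: Mapping[str, Sequence[GeneCnaCall]],
    labels: Mapping[str, Benefit],
    genes: Iterable[str],
) -> pd.DataFrame:
    """Per-gene frequency table over several genes.

    Raw Fisher p-values are reported (no correction is applied to the
    headline results); Benjamini-Hochberg adjusted columns are emitted
    alongside for transparency.
    """
    from statsmodels.stats.multitest import multipletests

    rows = [gene_gain_loss_frequencies(calls_by_sample, labels, g) for g in genes]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        for col in ("fisher_p_gain", "fisher_p_loss"):
            df[col + "_bh"] = multipletests(df[col], method="fdr_bh")[1]
    return df


def format_percent(fraction: float | None, decimals: int = 1) -> str:
    """Render a fraction as a percentage with half-up rounding ('90.9')."""
    import decimal

    if fraction is None:
        return "NA"
    quantum = decimal.Decimal(1).scaleb(-decimals)
    value = (decimal.Decimal(repr(fraction)) * 100).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return str(value)
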