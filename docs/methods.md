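# Methods

## Problem and model

Multi-tyrosine-kinase inhibitors (MTKIs: regorafenib, sorafenib, sunitinib,
pazopanib, axitinib, vandetanib, cabozantinib) lack validated predictive
biomarkers. The hypothesis implemented here is that tumors which have gained
extra copies of the genes encoding a drug's kinase targets respond
preferentially to that drug, while tumors that have lost those genes do not.

The pipeline works at the gene level on segmented array-CGH profiles
(tumor/normal log2 ratios; segmentation is upstream and out of scope):

1. **Category calling.** Each log2 ratio maps to one of eight ordinal
   categories via a fixed half-open interval ladder:
   amplification (log2 ≥ 2), strong gain [1, 2), gain [0.5, 1),
   heterogeneous gain [0.1, 0.5), neutral (−0.1, 0.1), heterogeneous
   deletion (−0.5, −0.1], deletion (−1, −0.5], gene loss (≤ −1).
   Boundary values belong to the interval whose inequality includes them;
   the amplification boundary is read as ≥ 2, the only reading consistent
   with strong gain's upper bound. The ladder is a partition: every finite
   value gets exactly one category, monotone in log2.
2. **Gene projection.** A gene takes the log2 of the segment with the
   largest overlap; ties break toward larger |log2|, then toward the
   leftmost segment (deterministic). An uncovered gene is neutral. One gene
   therefore yields at most one gain or loss event, which is what bounds the
   panel scores below.
3. **TTC / TTL.** Against a drug's target panel (for regorafenib, the 18
   kinase genes RET, FLT1, KDR, FLT4, KIT, PDGFRA, PDGFRB, FGFR1, FGFR2,
   TEK, DDR2, NTRK1, EPHA2, RAF1, BRAF, MAPK11, FRK, ABL1), the Tumor Target
   Charge is the number of panel genes with any gain and the Tumor Target
   Loss the number with any loss. All events count equally; amplitude is
   deliberately ignored (a known limitation of the approach). Strong gains
   count toward TTC by default — the category ladder would be incoherent if
   the strongest sub-amplification gain class were excluded — with a flag to
   turn this off.
4. **SUMSCAN.** FAVORABLE ⇔ TTC ≥ `min_ttc` (default 4) AND TTC > TTL
   (default on). The published description of the rule is a sketch; both
   components are independently configurable and every run manifest records
   which variant ran. With `min_ttc = 0` the rule reduces exactly to the
   sign test TTC > TTL. TTC − TTL ≥ 5 is reported as a "large difference"
   flag but never used for classification.
5. **Clinical benefit.** CR or PR, or SD lasting ≥ 2 months, is benefit
   positive; PD as best response (at/before the first 8-week evaluation) is
   negative. SD without a recorded duration is an error rather than a silent
   guess.

## Statistics

* **Fisher's exact test** (two-sided) is computed by exact integer
  enumeration of the hypergeometric distribution with fixed margins. The
  default two-sided rule is the point-probability (Fisher–Irwin) rule — sum
  of all table probabilities ≤ the observed table's — because that is the
  rule that reproduces the published 2×2 p-values (e.g. 0.0011 for the
  second-line 10/2 vs 2/12 split). The doubling rule (2 × smaller tail,
  capped at 1) is available behind a flag. Exact integer arithmetic makes
  tie handling at the observed probability unambiguous. Zero-margin tables
  return p = 1 with a degenerate-table warning.
* **Chi-square** is uncorrected Pearson (df = 1) by default; the published
  p = 0.048 for the discovery-cohort TTC ≥ 4 split (5/6 vs 2/7) is matched
  only without the Yates correction, which remains available via a flag.
  Zero expected cells raise an error recommending Fisher.
* **Mann-Whitney U** uses the exact permutation null when the pooled sample
  is ≤ 20 without ties, otherwise the tie-corrected normal approximation
  (scipy).
* **Classifier evaluation** cross-tabulates SUMSCAN calls against benefit
  labels (favorable + benefit = true positive). Metrics with a 0/0
  denominator are reported as missing, never as 0. Note: the published
  pooled-cohort specificity of "66.7%" is inconsistent with its own counts
  (9/14 = 64.3%); this package reproduces the counts-derived value.
* **Per-gene frequencies** report raw two-sided Fisher p-values per gene
  (matching how the headline gene-level results were reported, without
  correction) plus Benjamini–Hochberg adjusted columns alongside for
  transparency.
* **Survival** uses the Kaplan-Meier product-limit estimator and the
  1-df log-rank test (lifelines). Conventions fixed here: events are
  processed before censorings tied at the same time; the median is the
  first time with S(t) ≤ 0.5 and is missing when the curve never reaches
  0.5; no confidence intervals by default.

## Synthetic cohorts

The patient-level data behind the published cohorts are not public, so the
`synthetic_cohort` module generates cohorts with the statistical structure
the analysis assumes. Defaults are the published cohort-level summaries and
are treated as study conditions, not tuning knobs:

| parameter | benefit+ | benefit− | unit |
|---|---|---|---|
| mean gained target genes (TTC) | 6.8 | 2.1 | genes, Poisson mean |
| mean lost target genes (TTL) | 1.3 | 2.4 | genes |
| genome-wide gains (187-gene universe) | 49.5 | 16.7 | genes |
| genome-wide losses | 15.9 | 18.9 | genes |
| benefit prevalence | 0.44 (11/25) | | |
| median PFS by SUMSCAN class | 9.9 (favorable) | 2.8 (unfavorable) | months |

Per patient: the benefit label is Bernoulli; gained/lost target-gene counts
are class-conditional Poisson draws truncated to the panel (gains first,
losses on the remaining genes, so TTC + TTL ≤ 18 holds by construction);
non-target burden makes up the difference between the genome-wide and
target-gene means. An altered gene's category is uniform over the gain (or
loss) classes and its log2 uniform within that category's interval
(amplification capped at log2 = 3, gene loss at −3) — amplitude
distributions are not published and nothing downstream depends on them.
Each gene becomes one whole-gene segment; a `multi_gene_segments` mode
occasionally extends segments into 40% of the neighboring gene to exercise
the dominant-overlap rule without changing any call. PFS is exponential
(single-parameter, median-parameterized, as only medians are published)
conditioned on the tumor's SUMSCAN class; censoring replaces the event time
with a uniform draw below it. RECIST responses are generated so that
re-deriving the benefit label from them reproduces the planted label.
An optional mutation co-simulation enriches PIK3CA variants in low-TTC
(TTC ≤ 2) benefit-negative tumors.

`expected_operating_point` computes the classifier's analytic
sensitivity/specificity by exact summation over the same truncated-Poisson
joint distribution of (TTC, TTL) — the Monte-Carlo pipeline is checked
against it to within 3 standard errors (at the defaults: sensitivity ≈ 0.90,
specificity ≈ 0.87).

What the generator does **not** emulate: real segment-length distributions,
wave/GC artifacts, intratumoral heterogeneity, correlated alterations among
neighboring genes, non-exponential survival, and informative censoring.
Passing tests therefore demonstrate the pipeline's correctness and internal
consistency, not clinical performance on real tumors.

## Problem sizes and numerical choices

Distributional-recovery and survival-recovery checks use cohorts of
n = 2,000 (≈ 0.06 standard errors on a Poisson mean of 6.8) — large enough
for 3-standard-error bands to be meaningful while keeping the default test
run fast. The exhaustive Fisher sweep covers all 135,750 tables with
N ≤ 40 against an independent implementation at 10⁻¹⁰ tolerance; the exact
Mann-Whitney check enumerates all label assignments for pooled sizes ≤ 10.
All randomness flows through `numpy.random.default_rng` seeded explicitly;
identical seed and parameters give byte-identical output files.

## Known limitations

* The exact published SUMSCAN decision tree is only sketched; the default
  rule here (TTC ≥ 4 AND TTC > TTL) follows the two published motivations
  but cannot be verified against unpublished per-patient data.
* Genomic-index comparisons and per-drug panels for the six non-regorafenib
  MTKIs are supported by the machinery but panels must be user-supplied.
* Gene-level calling assumes the supplied annotation set is the analysis
  universe; no genome build is assumed.
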