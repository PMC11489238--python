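# Methods

`toxconcord` implements a complete in vitro → in vivo concordance analysis
for organ toxicity: it quantifies targeted qPCR arrays and an 8-marker
protein panel measured in a liver cell model (HepaRG) and a kidney cell
model (RPTEC), grades the resulting evidence on a shared ordinal scale,
maps graded endpoints onto curated in vivo effect categories, and scores
how well the in vitro battery indicates the in vivo findings.

## Quantification of targeted qPCR arrays

Threshold cycles above the detection cutoff (default 35 cycles) and wells
with no amplification are censored to the cutoff: later cycles carry no
reliable quantity, and treating "undetermined" as the cutoff bounds the
expression estimate instead of dropping the well.  Each sample's target Cts
are normalized to the arithmetic mean of its housekeeping genes (ΔCt; five
housekeeping genes by default), treated and control samples are differenced
(ΔΔCt), and relative expression is 2^−ΔΔCt.  Fold regulation re-expresses a
fold change below 1 as its negative inverse so up- and down-regulation are
symmetric around ±1.

Significance is a one-sample, two-sided t-test of per-replicate ΔΔCt values
against 0, on the cycle (log2) scale, where replicate noise is approximately
symmetric.  Replicates are paired by position — biological replicate *i*
treated against biological replicate *i* control — because each independent
experiment carries its own control; the paired difference cancels the
shared housekeeping term of that experiment and keeps the test exactly
calibrated.  An unpaired construction (each treated ΔCt minus the control
*mean*) would inflate the t statistic by √2.  Unequal replicate counts fall
back to a Welch two-sample comparison of the ΔCt values.  Genes censored in
every treated and every control replicate are reported with fold change 1
and excluded from differential-expression calling: the ratio of two
censored values is uninformative.

A gene is differentially expressed when |fold regulation| ≥ 2 (inclusive)
and p < 0.05 (strict); the input filter for pathway analysis is the looser
|FR| ≥ 1.5 with p ≤ 0.05.  Cross-platform quality control passes when the
array and single-assay fold changes are within a configurable factor
(default 3-fold) of each other.

## Overrepresentation and transcript evidence

Pathway overrepresentation is the right tail of the hypergeometric
distribution: the probability that a uniformly random gene list of the same
size drawn from the panel background overlaps a gene set at least as much
as observed (Fisher's exact one-sided p, computed with
`scipy.stats.hypergeom`).  The package does not reproduce any commercial
knowledge base; it ingests annotation exports (category, annotation,
p-value of overlap) or builds synthetic equivalents from this statistic so
the whole chain is testable offline.

Annotation records are filtered to hepatic/renal relevance through a
packaged category whitelist (user-extensible), collapsed to one row per
category carrying the most significant annotation p-value, and graded:
very strong p ≤ 0.0005, strong p ≤ 0.005, medium p ≤ 0.05.  Reading the
category p as the *least* significant annotation instead is available as a
configuration switch (`collapse_rule: max_p`) for sensitivity analysis, but
the default follows the direction of the grading thresholds — a category
cannot be weaker than its own best-supported annotation.

## Protein evidence

Each analyte reads out one cellular function and is measured as percent of
the solvent control on a 2 concentrations × 2 timepoints grid, three
biological replicates per condition.  Grades use the condition **means**
only: very strong ≥ 2 conditions > 200%, strong = 1 condition > 200% or
≥ 2 conditions in (150, 200], medium = 1 condition in (150, 200].  The
mid band is half-open so the bands partition; "2 conditions" is read as "at
least 2".  Decreases below the control never contribute a grade — every
analyte in the panel is an induction readout.  Bootstrap significance
against the 100% null is reported per condition but does not gate the
grade; whether it should is genuinely open, and grading on magnitude alone
is the transparent default.

### Bootstrap significance at n = 3

Percent-of-control replicates are positive with multiplicative noise, so
the error model is lognormal (geometric mean at the true percent,
σ² = ln(1 + cv²)).  The default test is a **studentized parametric
bootstrap on the log scale**: the studentized mean of log-values is pivotal
under this null, so its null distribution is simulated directly and the
two-sided p is the fraction of simulated statistics at least as extreme as
the observed one (with the +1 correction).  This keeps type-I error at the
nominal level even with three replicates.  A plain percentile bootstrap of
the mean (`bootstrap_method: percentile`) is provided for comparison; with
three replicates the resample distribution has ~10 support points, the
smallest achievable two-sided p is far from 0.05, and the "all replicates
on one side" event alone fires in roughly a quarter of null samples — the
percentile variant is strongly anti-conservative at this sample size and
should not be used for inference at n = 3.  Defaults: 10 000 resamples,
deterministic per seed, order-invariant.

## Viability screen

WST-1 absorbance readings are related to the 620 nm reference wavelength,
blank-corrected, and expressed relative to the solvent-control net value;
neutral-red fluorescence uses a single blank term.  The exposure
concentration for all downstream assays is the largest tested concentration
with viability strictly above 80% in **every** provided assay (conjunction;
the assays are run sequentially on the same wells and a concentration must
survive both), plus a second exposure at 0.33× that value.  Exactly 80.0%
fails — the rule is "greater than 80%".  When even the highest tested
concentration passes, the selection is flagged top-of-range.

## Mapping and concordance

Graded endpoints are projected through two ontologies: cellular function →
in vivo effect categories (protein side; two endpoints, protein degradation
and hypoxia, intentionally have no accepted in vivo counterpart and can
never predict), and pathway-analysis category → effect categories
(transcript side).  Mapping rows keyed by a *combination* of categories
fire only when every member reaches the active grade threshold, and
contribute at the weakest member's grade.

Scoring evaluates (substance, organ, effect) triples.  The universe of a
scope is restricted to effects reachable by at least one mapping row of
that scope — the battery is not scored on endpoints it cannot express
(`include_unmapped_effects: true` turns such effects into automatic misses
for sensitivity analysis).  Absence of an effect from a substance's in vivo
profile is treated as observed-negative; an explicit "unknown" marker is
supported but unused by the packaged registry.  Indicative concordance is
the percentage of observed-positive triples predicted positive; negative
agreement is the percentage of observed-negative triples with no
prediction.  The sweep produces one report per scope × threshold — seven
scopes (protein/mRNA/combined × HepaRG/RPTEC/combined) × three thresholds
(≥ medium, ≥ strong, very strong only) — with raw ratios in machine output
and integer display rounding.  Single-cell-line scopes are organ-matched
(HepaRG → liver, RPTEC → kidney); combined scopes cover both organs.

Two structural properties hold by construction and are tested: stricter
thresholds never increase indicative concordance and never decrease
negative agreement within a scope (the universe is conserved across
thresholds), and an OR-combination of prediction sets can only add hits on
any shared universe.  Note that *percentages* of differently-scoped reports
are not directly comparable: the combined scope's denominator includes
effects only one data type can express, so its percentage can fall below a
constituent's even though its prediction set is a superset.  The dominance
property is therefore stated — and verified — on the constituent's own
universe.

## Synthetic data

The generator mirrors the study design: two cell lines, ~370-target arrays
with five shared housekeeping genes, six substances, 8 markers ×
2 concentrations × 2 timepoints × 3 replicates.  Ct noise is Gaussian on
the cycle scale; a planted log2 fold change shifts the treated expectation
down by that many cycles.  Protein replicates are lognormal around the
planted condition truth.  Planted protein grades use condition-mean
templates placed well inside the grading bands; planted transcript activity
marks a random fraction (25/50/100%) of a category's gene set as
differentially expressed so overlap p-values span the grade bands.

`simulate_study` draws the in vivo registry conditional on the noise-free
predictions implied by the planted truth: a predicted-positive triple is
observed positive with probability 0.7, and the rate for unpredicted
triples is set so the expected indicative concordance at the ≥ medium
threshold equals the scenario's target.  The bundle is pipeline-ready and
carries its ground truth (expected evidence, prediction set and report) for
recovery tests.

Calibration scenarios differ in one structural point: genes quantified in
the same sample share that sample's housekeeping-mean noise, which
correlates their tests, so a single large null table has a rejection
fraction with much more than binomial variance.  The null scenario
therefore measures each null gene in its own independent exposure slice,
making the rejection fraction binomial; the study-shaped generator keeps
the realistic shared-housekeeping structure.

What the generator does **not** emulate: plate effects, bead-level
immunoassay signals, primer-efficiency differences, correlated biological
pathway co-regulation beyond the planted gene sets, and the idiosyncrasies
of real knowledge-base annotations.  Passing recovery tests shows the
analysis chain is self-consistent and calibrated under its own error model,
not that real assays meet that model.

## Problem sizes and defaults

| Parameter | Default | Rationale |
|---|---|---|
| Ct cutoff | 35 cycles | detection limit of the array protocol |
| DEG gate | FR ≥ 2, p < 0.05 | standard profiler-array convention |
| Pathway-input gate | FR ≥ 1.5, p ≤ 0.05 | looser input filter for enrichment |
| Protein bands | 150% / 200% | grading matrix bands |
| Transcript grades | 0.0005 / 0.005 / 0.05 | grading matrix p thresholds |
| Viability | > 80%, 0.33× second dose | exposure-selection rule |
| Bootstrap | 10 000 resamples, studentized log-scale | calibrated at n = 3 |
| Ct noise | σ = 0.25 cycles (calibration), 0.15 (recovery) | typical replicate scatter |
| Protein cv | 0.3 (calibration), 0.1 (recovery) | recovery isolates mapping calibration from assay power, which is characterized separately |
| Recovery runs | 100 × 6 substances, full panels | ≈ 45–55 evaluable positives per run |

The acceptance script (`scripts/acceptance.py`) recomputes, from scratch at
a given seed: the t-test and bootstrap type-I error under the synthetic
null (1000 genes / 1000 panels), exactness of the overlap statistic against
full enumeration (backgrounds ≤ 12), the grading-matrix truth tables,
sweep invariants over random studies, and recovery of a planted 75%
concordance (coverage of the binomial 95% interval over 50 runs).

## Known limitations

* The packaged panel manifests and pathway catalogs are synthetic (the
  vendor's array gene lists and pathway assignments are proprietary);
  users supply their own for real data.
* The concordance engine takes the in vivo categorization as given; it does
  not re-derive effect categories from regulatory dossiers.
* The percentile bootstrap is retained only for comparison; see above.
* Primer efficiency, instrument baseline correction and acquisition
  thresholds are upstream of the package: Ct values are taken as exported.
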