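# Methods

This note documents the models and procedures implemented in `panffpe`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## TIC loading calibration

The per-sample loading signal is the total ion current summed over all
MS1 scans of a short LC-MS run (MS2 scans, where present, are excluded;
a run with no MS1 scans is an error, never a zero). The calibration model
is ordinary least squares of ΣTIC on amount over a dilution series of a
standard digest, **with intercept retained**: a constant background TIC
(solvent, column bleed) shifts every run equally, and absorbing it in the
intercept keeps the inverse estimates unbiased; forcing the line through
the origin was the alternative and was rejected for that reason. The
curve is gated on R² > 0.97 (`r2_threshold`); a failing curve raises
rather than propagating — an unreliable calibration must be remeasured.
Unknowns are estimated by inverse regression, m̂ = (ΣTIC − b)/a.

Triage: estimates below the bottom calibration point (16 ng by default,
or a configurable `min_yield_ng`) are `low_yield`; TIC sums above the
top point are `above_range` — extrapolated and flagged but not refused,
since over-loading is recoverable by dilution while under-loading is not.
Loading volume is target/concentration (default target 600 ng); samples
needing more than `max_volume_ul` (default 20 µl) become `low_yield` and
are excluded from analytical runs. Excluded-sample accounting is carried
through the pipeline manifest with a reason code per sample.

CoV conventions: loading-sum CoVs (`tic_normalization.cov_percent`,
`normalization_benefit`) use the population SD (n denominator) — they
describe the dispersion of the cohort actually measured. Matrix-level
`cov_metrics` uses the sample SD (n−1), the estimator convention for
quantitative-precision reporting. Both are computed on natural-scale
summed intensities, not log scale.

## Protein-level FDR

PEP = 1 − protein probability. Records are sorted ascending by PEP and
the q-value of row i is the cumulative mean of the first i PEPs — the
expected fraction of false identifications in the list accepted at that
threshold. **Ties share the q of the last tied row**, the conservative
choice (any record with the same PEP is statistically indistinguishable,
so all of them carry the worst-case q of the group). The filter retains
q ≤ α (default 0.01) and drops any group intersecting the contaminant
accession set. Correctness is checked against an O(n²) literal
re-implementation of the definition at sizes up to 1000, and calibration
against synthetic scores whose false labels are Bernoulli draws in each
record's own PEP — under that construction the realized false fraction
among retained records must match the q-value up to binomial error.

Group-ID harmonization keeps, for each multi-accession group, the member
occurring most frequently across the *other* searches; ties break
lexicographically (deterministic, and unbiased with respect to abundance).

## Completeness cutoff

For integer cutoffs c = 1..100%, count the proteins whose completeness is
≥ c. Two scopes exist: `global` (completeness over all samples; used for
cutoff *selection*) and `per_cohort_max` (a protein's best per-cohort
completeness; used for *filtering*, so a protein reliably seen in one
cohort survives even if absent elsewhere). The first derivative at x is
the OLS slope of counts over the 5-point window x−2..x+2; the second
derivative applies the same windowed slope to the first-derivative
series. The selected cutoff is the smallest x with |d2(x)| ≤ 1% of
max |d2| (`zero_tol`, relative — hence invariant under vertical scaling
of the counts). An exactly linear curve has d2 ≡ 0 everywhere and
selects the first evaluable cutoff (x = 5, the first position with a
complete double window); if no position satisfies the tolerance the
selector raises with diagnostics rather than guessing. The windowed
estimator discretizes the knee to about ±2 percentage points; recovery
tests use piecewise constructions with a quartic ramp joining the linear
section (value and first three derivatives vanish at the join), the
smoothest construction for which the knee location is well defined.

The 13% default used by the pipeline when no curve is supplied is the
study-scale value of this procedure.

## Imputation

Missing values are filled **only** for embedding input (dimensionality
reduction needs complete data), after completeness filtering, never for
testing: per protein, draws from Normal(median_valid − 1.8·SD_valid,
0.3·SD_valid) in log2 space — a downshifted, narrowed distribution
representing "present but below detection". Valid cells are never
altered; proteins with fewer than two valid values have no defined
spread and are returned unimputed and flagged. A fixed seed makes the
fill bitwise reproducible.

## Fold-change null and differential expression

The effect-size threshold is calibrated from the data: samples of every
cohort are split half/half at random (the extra sample of odd cohorts
alternates sides across splits), and per protein with at least one
detected value per side the null log2 FC is the difference of group
median log2 intensities; the cutoff is the maximum absolute value over
proteins and splits. Default one split mirrors the study-scale
procedure; ≥ 20 splits are recommended for a stable cutoff and exposed
via `n_splits`. The study-scale default when no matrix is supplied is
0.73 log2 (1.66-fold).

One-vs-rest testing compares each cohort's detected intensities for a
protein against the pooled rest ("mixed") with a two-sided Wilcoxon
rank-sum test — exact for small tie-free groups, tie-corrected normal
approximation otherwise (scipy's `mannwhitneyu`, `method="auto"`,
verified against exhaustive permutation enumeration on small groups).
Both groups must meet the completeness requirement (default 13%);
untestable rows are emitted flagged rather than dropped, but excluded
from the BH family, whose scope is all tested (protein, cohort) pairs
jointly. log2 FC is the difference of group medians over detected values.
Significance: adj. p < 0.01 **and** |log2 FC| > cutoff; a `directional`
flag restricts to positive fold changes for enrichment-style lists.

## Fingerprint classes

Per (protein, cohort), using medians over detected values only:

* **Class I** — detected (≥ 1 sample, configurable) in exactly one cohort;
* **Class II** — median ≥ cutoff above the median of *each individual*
  other cohort in which the protein is detected (cohorts where it is
  undetected contribute no median and are skipped);
* **Class III** — median ≥ cutoff above the pooled median of all other
  cohorts' samples, and not already Class II.

Two readings of Class II exist in the field (per-cohort vs averaged);
the stricter per-cohort reading is primary, and `class_ii_mode="average"`
(median ≥ cutoff above the mean of other cohorts' medians) is available.
Classes are mutually exclusive per (protein, cohort) by construction.
Origin attribution intersects each cohort's fingerprint with a
user-supplied tissue-specific gene set; cohorts without a set fall back
to entity-specific with a warning. Overrepresentation uses Pearson's χ²
without continuity correction on the 2×2 membership table (hypergeometric
upper tail as alternative); tables with an expected cell < 1 are tested
but flagged. When several cohorts are tested, all (cohort, term) p-values
form one global BH family.

## QC monitoring

Retention-time drift is modelled linearly, observed = slope·reference +
offset, per run over the matched standard peptides (≥ 3 required) —
the minimal model covering both offset (dead-volume/column change) and
stretch (gradient deformation); runs are flagged at |offset| > 1 min or
RMSE > 0.5 min (configurable). Control-run series flagging uses
median ± 4·MAD per metric (identifications, peptides, mass error), with
a fixed 1 ppm bound on |median mass error| regardless of the series,
since modern recalibration keeps well-behaved systems below that.

## Synthetic data: what it emulates

All generators are pure functions of a single-seed config; named
sub-streams (via `SeedSequence.spawn`) keep the generators independent
of each other. Defaults encode the study conditions: six tumor cohorts
at case counts 246/168/265/204/145/192 (1220 total), an 8-point 16–1000 ng
dilution grid, 40 RT standards across an 88-min gradient, base log2
abundances uniform over 20 log2 units (≈ 6 orders of magnitude).

Choices the underlying data do not pin down, set once as realistic for
FFPE LFQ data and not revisited:

* within-cohort spread σ = 0.8 log2 (typical protein-level LFQ CoV);
* cohort-level mean shifts σ = 0.25 log2 for shared proteins (mild
  tissue structure);
* detection is Bernoulli in a logistic function of the cell's log2 value
  (midpoint 14, slope 0.7), producing abundance-dependent missingness
  and a bimodal completeness distribution; an infinite-slope sentinel
  gives a step detection model for limit tests. The logistic form is an
  assumption — the real censoring mechanism of LFQ data is unknown;
* planted exclusive/enriched proteins draw their base abundance from the
  reliably detectable upper range (fingerprint proteins in tissue data
  are characteristically abundant); enrichment effect default 2.0 log2;
* mean peptide load 300 ng with log-normal CoV 0.5 between samples, TIC
  response 2×10⁸ units/ng with 5% multiplicative noise;
* identification scores: true-protein PEPs ~ Beta(1, 400), a 10% false
  tail with PEPs ~ Beta(2, 2), and every record's false label drawn
  Bernoulli in its own PEP, making q-values calibrated by construction.

Not emulated: raw spectra, chromatographic peak shapes, ion-mobility
physics, search-engine behavior, batch/temporal effects, and correlated
(protein-complex) abundance structure. Passing recovery tests therefore
demonstrates the correctness and calibration of the procedures under the
stated statistical structure, not robustness to every artifact of real
acquisitions.

## Problem sizes in the test and acceptance runs

Unit and recovery tests run at 2 cohorts × 20 samples × 300 proteins up
to 6 × 40 × 800; the realized-FDR check uses ~5000 score records; the
fold-change-null oracle uses 10⁴ Monte-Carlo replicates at 200 proteins ×
120 samples; the acceptance script's null-FC section runs the full
1220-sample cohort geometry with 2000 proteins. These sizes give stable
statistics for every planted-truth comparison while keeping any single
run in seconds.

## Known limitations

* The inverse-regression amount estimate ignores calibration-parameter
  uncertainty; at 8 dilution points and R² > 0.97 that error is
  negligible against the 5% TIC noise floor.
* The knee selector reports integer cutoffs and inherits the ±2-point
  window discretization.
* `n_splits=1` makes the fold-change cutoff itself a random variable
  with substantial spread at small cohort sizes (visible in the demo);
  use more splits for stable thresholds.
* Imputation is a visualization device; any inferential use of imputed
  values is out of scope by design.
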