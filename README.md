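# panffpe

A Python toolkit for the computational backbone of large-scale clinical
FFPE (formalin-fixed paraffin-embedded) proteomics: normalizing peptide
loading across hundreds of LC-MS runs, controlling protein-level false
discoveries, deriving data-driven analysis cutoffs, calling differential
protein expression between tumor cohorts, classifying cohort-specific
proteome fingerprints, and monitoring instrument performance over years of
data acquisition. It is aimed at proteomics core facilities and
computational biologists running multi-cohort label-free quantification
(LFQ) studies.

## What it computes

**TIC loading normalization.** The total ion current summed over all MS1
scans of a short LC-MS run is linear in the peptide amount on column.
Fitting ΣTIC = a·m + b on a dilution series of a standard digest
(16–1000 ng) gives an external calibration, gated on R² > 0.97; inverting
it for each patient sample yields the injected amount, the digest
concentration, and the volume needed to load a common target (default
600 ng). Samples below the calibrated range or needing more volume than
can be injected are triaged out before the expensive analytical runs.

**Protein FDR.** From per-group identification probabilities,
PEP = 1 − p; sorting by PEP, the q-value of a row is the mean PEP of all
rows with smaller or equal PEP (the expected false-discovery rate of the
accepted list). Groups with q ≤ 0.01 are retained, contaminants removed,
and multi-accession groups harmonized across searches by majority
membership.

**Data-driven cutoffs.** Plotting the number of proteins quantified in at
least c% of samples against c gives a curve whose initial steep drop marks
unreliably observed proteins; the completeness filter is placed where the
second derivative (sliding-window regression slopes, 5-point windows)
first approaches zero. The fold-change threshold is the maximum |log2 FC|
observed between random cohort-balanced halves of the data — variation
achievable by chance alone (0.73 log2 ≈ 1.66-fold at study scale).

**Differential expression and fingerprints.** One-vs-rest two-sided
Wilcoxon rank-sum tests per (protein, cohort) with Benjamini–Hochberg
correction; significance requires adj. p < 0.01 and |log2 FC| above the
null cutoff. Cohort fingerprints follow Human-Protein-Atlas-style classes:
Class I (detected in one cohort only), Class II (≥ cutoff above each other
cohort's median), Class III (≥ cutoff above the pooled rest, not already
Class II), then split into tissue-of-origin vs entity-specific fractions
and tested for annotation-term overrepresentation (χ², one global BH
family).

**QC monitoring.** Linear retention-time drift fits against 40 spiked
standard peptides per run, and k·MAD outlier flagging over interspersed
control-digest runs (mass-error bound 1 ppm).

A first-class synthetic-data module generates all of the above inputs with
planted ground truth (loads, effects, false identifications, drift), so
every stage is testable end to end.

## Worked example

```bash
panffpe run --demo --seed 42 --outdir demo_out
```

runs the full pipeline on synthetic data (6 cohorts × 20 samples, 1500
proteins) and prints:

```
completed 6 stages; manifest at demo_out/manifest.json
```

`demo_out/manifest.json` records, per stage, the counts in/out and key
results. With seed 42 the calibration fit gives R² = 0.9975 (gate 0.97
passed), 119 of 120 samples pass loading triage (one `low_yield`
exclusion, listed with its reason), FDR filtering retains 1547 of 1650
score records at q ≤ 0.01, the completeness knee lands at 30% at this
small demo scale and keeps 1423 of 1500 proteins, the random-split null
yields a fold-change cutoff of 1.03 log2 (small per-side counts under
missingness make chance medians volatile; at the full study scale the
same procedure gives ≈ 0.7), 510 of 8170 tested (protein, cohort) pairs
come out significant, 524 fingerprint assignments are made, and 10 of 10
QC runs fit with drift offsets growing linearly.
Artifacts per stage: `loadings.tsv`, `calibration.json`,
`completeness.json`, `matrix.tsv`, `de_table.tsv`, `fingerprints.tsv`,
`enrichment.tsv`, `rt_drift.tsv`.

Library use mirrors the CLI:

```python
from panffpe import fit_calibration, estimate_amounts

curve = fit_calibration([(16, 3.1e9), (125, 2.5e10), (1000, 2.0e11)])
loadings = estimate_amounts(curve, [("patient_01", 8.0e10, 1.0)])
print(loadings[0].est_amount_ng)   # ≈ 400 ng injected
```

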