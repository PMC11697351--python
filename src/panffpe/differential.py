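"""Fold-change null calibration and one-vs-rest differential expression.

The effect-size threshold for calling differential expression is taken
from the data itself: samples of every cohort are randomly assigned to two
balanced halves, the per-protein log2 fold change between the halves is
computed, and the maximum absolute value observed — variation achievable
by chance alone — becomes the cutoff.  The study-scale default is 0.73
log2 (1.66-fold).

Differential testing is one-vs-rest: for each (protein, cohort) pair the
cohort's intensities are compared to the pooled intensities of all other
cohorts ("mixed") by a two-sided Wilcoxon rank-sum test, provided both
groups meet the completeness requirement.  Benjamini–Hochberg correction
is applied across all tested pairs jointly, and significance requires both
adjusted p < 0.01 and |log2FC| above the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StratificationError, ValidationError
from .quant_matrix import QuantMatrix
from .study_design import DEFAULT_FC_CUTOFF_LOG2

DEFAULT_DE_ALPHA = 0.01
DEFAULT_MIN_COMPLETENESS = 0.13


# ---------------------------------------------------------------------------


@dataclass
class NullSplitResult:
    """Null log2 fold changes from cohort-balanced random splits."""

    n_splits: int
    seed: int
    null_fcs: pd.DataFrame  # proteins × splits, NaN where a side had no data
    fc_cutoff: float

    def __post_init__(self):
        if self.fc_cutoff < 0:
            raise ValidationError("fc_cutoff cannot be negative")


def random_split_null(
    matrix: QuantMatrix, n_splits: int = 1, seed: int = 0
) -> NullSplitResult:
    """Maximum |log2FC| between random cohort-balanced halves.

    Each split assigns the samples of every cohort half/half to two groups
    (for odd cohorts the extra sample alternates sides across splits).  Per
    protein with at least one valid value on each side, the null fold
    change is the difference of the group median log2 intensities; the
    cutoff is the maximum absolute value over proteins and splits.
    """
    rng = np.random.default_rng(seed)
    cohorts = matrix.cohort_names()
    for cohort in cohorts:
        if len(matrix.cohort_columns(cohort)) < 2:
            raise StratificationError(f"cohort {cohort!r} has fewer than 2 samples")

    log2 = matrix.log2()
    per_split = {}
    for split in range(n_splits):
        left: list[str] = []
        right: list[str] = []
        for cohort in cohorts:
            cols = list(matrix.cohort_columns(cohort))
            perm = rng.permutation(len(cols))
            half = len(cols) // 2
            extra = len(cols) % 2
            n_left = half + (extra if split % 2 == 0 else 0)
            left.extend(cols[i] for i in perm[:n_left])
            right.extend(cols[i] for i in perm[n_left:])
        med_left = log2[left].median(axis=1, skipna=True)
        med_right = log2[right].median(axis=1, skipna=True)
        per_split[split] = med_left - med_right
    null_fcs = pd.DataFrame(per_split)
    fc_cutoff = float(np.nanmax(np.abs(null_fcs.to_numpy()))) if null_fcs.size else 0.0
    return NullSplitResult(
        n_splits=n_splits, seed=seed, null_fcs=null_fcs, fc_cutoff=fc_cutoff
    )


# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_vs_rest_tests(
    matrix: QuantMatrix,
    fc_cutoff: float = DEFAULT_FC_CUTOFF_LOG2,
    alpha: float = DEFAULT_DE_ALPHA,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    directional: bool = False,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum tests per (protein, cohort).

    A pair is tested only when the protein is quantified in at least
    ``min_completeness`` of the cohort's samples and of the rest; untested
    pairs are emitted with ``tested=False`` rather than silently dropped,
    but are excluded from the BH family.  p-values use the exact rank-sum
    distribution for small tie-free groups and the tie-corrected normal
    approximation otherwise.  log2FC is the difference of group medians
    over detected values.  ``significant`` requires adj_p < alpha and
    |log2FC| > fc_cutoff (log2FC > fc_cutoff when ``directional``).
    """
    log2 = matrix.log2()
    cohorts = matrix.cohort_names()
    rows = []
    for cohort in cohorts:
        in_cols = matrix.cohort_columns(cohort)
        rest_cols = matrix.samples.difference(in_cols, sort=False)
        a = log2[in_cols].to_numpy()
        b = log2[rest_cols].to_numpy()
        n_in, n_rest = a.shape[1], b.shape[1]
        for i, protein in enumerate(matrix.proteins):
            av = a[i][~np.isnan(a[i])]
            bv = b[i][~np.isnan(b[i])]
            testable = (
                av.size >= min_completeness * n_in
                and bv.size >= min_completeness * n_rest
                and av.size >= 1
                and bv.size >= 1
            )
            log2fc = (
                float(np.median(av) - np.median(bv))
                if av.size and bv.size
                else np.nan
            )
            p = np.nan
            if testable:
                p = float(
                    stats.mannwhitneyu(av, bv, alternative="two-sided", method="auto").pvalue
                )
            rows.append(
                {
                    "protein": str(protein),
                    "cohort": cohort,
                    "log2fc": log2fc,
                    "p_value": p,
                    "n_cohort": int(av.size),
                    "n_rest": int(bv.size),
                    "tested": bool(testable),
                }
            )
    table = pd.DataFrame(rows)
    table["adj_p"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        table.loc[tested, "adj_p"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    effect = table["log2fc"] if directional else table["log2fc"].abs()
    table["significant"] = tested & (table["adj_p"] < alpha) & (effect > fc_cutoff)
    return table
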