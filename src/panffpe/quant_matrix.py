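"""Protein × sample intensity matrix and matrix-level operations.

The matrix stores natural-scale label-free quantification (LFQ) intensities
with missing values for non-detections, sample→cohort labels and an
optional iBAQ layer (abundance proxy used for top-N selection).  Medians,
fold changes and imputation all operate in log2 space.

The module implements the data-driven completeness cutoff: counting, for
every integer completeness cutoff 1–100%, the proteins meeting it yields a
curve with an initial steep drop (proteins seen in very few samples), a
near-linear middle, and a final drop.  Sliding-window regression slopes
approximate the first and second derivatives; the smallest cutoff at which
the second derivative first approaches zero marks the start of the linear
section and is taken as the completeness filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoKneeError, ValidationError

DERIVATIVE_WINDOW = 5  # sliding window of 5 neighbors, x-2 .. x+2


# ---------------------------------------------------------------------------


class QuantMatrix:
    """Protein × sample intensity matrix with cohort labels.

    Parameters
    ----------
    lfq : DataFrame
        Natural-scale intensities, proteins as index, sample ids as
        columns; NaN marks a missing (not-detected) value.  All present
        values must be positive.
    cohorts : Series or mapping
        sample id → cohort name, covering every column of ``lfq``.
    ibaq : DataFrame, optional
        Parallel iBAQ layer with identical shape and labels.
    """

    def __init__(
        self,
        lfq: pd.DataFrame,
        cohorts: pd.Series | Mapping[str, str],
        ibaq: pd.DataFrame | None = None,
    ):
        cohorts = pd.Series(dict(cohorts)) if not isinstance(cohorts, pd.Series) else cohorts
        missing = [s for s in lfq.columns if s not in cohorts.index]
        if missing:
            raise ValidationError(f"samples without cohort label: {missing[:5]}")
        vals = lfq.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValidationError("present intensities must be positive")
        if ibaq is not None and (
            not ibaq.index.equals(lfq.index) or not ibaq.columns.equals(lfq.columns)
        ):
            raise ValidationError("iBAQ layer must share the LFQ matrix labels")
        self.lfq = lfq
        self.cohorts = cohorts.loc[lfq.columns]
        self.ibaq = ibaq

    # -- basic views ------------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.lfq.index

    @property
    def samples(self) -> pd.Index:
        return self.lfq.columns

    @property
    def n_proteins(self) -> int:
        return len(self.lfq.index)

    @property
    def n_samples(self) -> int:
        return len(self.lfq.columns)

    def detected(self) -> pd.DataFrame:
        return self.lfq.notna()

    def log2(self) -> pd.DataFrame:
        return np.log2(self.lfq)

    def cohort_names(self) -> list[str]:
        # insertion order of first appearance, deterministic
        return list(dict.fromkeys(self.cohorts))

    def cohort_columns(self, cohort: str) -> pd.Index:
        return self.cohorts.index[self.cohorts == cohort]

    def subset(self, proteins: Sequence[str]) -> "QuantMatrix":
        ibaq = self.ibaq.loc[proteins] if self.ibaq is not None else None
        return QuantMatrix(self.lfq.loc[proteins], self.cohorts, ibaq)

    # -- completeness -----------------------------------------------------

    def completeness_global(self) -> pd.Series:
        """Per protein: percent of all samples with a quantified value."""
        return 100.0 * self.detected().sum(axis=1) / self.n_samples

    def completeness_per_cohort(self) -> pd.DataFrame:
        det = self.detected()
        cols = {}
        for cohort in self.cohort_names():
            cc = self.cohort_columns(cohort)
            cols[cohort] = 100.0 * det[cc].sum(axis=1) / len(cc)
        return pd.DataFrame(cols)

    def completeness_per_cohort_max(self) -> pd.Series:
        """Per protein: maximum completeness over the cohorts."""
        return self.completeness_per_cohort().max(axis=1)

    # -- IO ---------------------------------------------------------------

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        self.lfq.to_csv(matrix_path, sep="\t", index_label="protein", float_format="%.17g")
        pd.DataFrame(
            {"sample_id": self.samples, "cohort": self.cohorts.values}
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path: str | Path, samples_path: str | Path) -> "QuantMatrix":
        lfq = pd.read_csv(matrix_path, sep="\t", index_col="protein")
        samples = pd.read_csv(samples_path, sep="\t")
        cohorts = pd.Series(samples.cohort.values, index=samples.sample_id.astype(str))
        lfq.columns = lfq.columns.astype(str)
        return cls(lfq, cohorts)


# ---------------------------------------------------------------------------
# completeness curve and knee selection
# ---------------------------------------------------------------------------


@dataclass
class CompletenessCurve:
    """Protein counts over integer completeness cutoffs with derivatives."""

    cutoffs: np.ndarray  # 1..100
    counts: np.ndarray
    d1: np.ndarray | None = None  # NaN where the window is incomplete
    d2: np.ndarray | None = None
    selected_cutoff: int | None = None

    def to_dict(self) -> dict:
        def ser(a):
            return None if a is None else [None if np.isnan(v) else float(v) for v in a]

        return {
            "cutoffs": self.cutoffs.tolist(),
            "counts": self.counts.tolist(),
            "d1": ser(self.d1),
            "d2": ser(self.d2),
            "selected_cutoff": self.selected_cutoff,
        }


def completeness_curve(matrix: QuantMatrix, scope: str = "global") -> CompletenessCurve:
    """Protein counts meeting each integer completeness cutoff 1–100%.

    ``scope='global'`` uses completeness across all samples;
    ``scope='per_cohort_max'`` uses each protein's best per-cohort
    completeness (a protein present in ≥c% of at least one cohort counts).
    """
    if matrix.n_proteins == 0:
        raise ValidationError("empty matrix")
    if scope == "global":
        completeness = matrix.completeness_global().to_numpy()
    elif scope == "per_cohort_max":
        completeness = matrix.completeness_per_cohort_max().to_numpy()
    else:
        raise ValidationError(f"unknown completeness scope {scope!r}")
    cutoffs = np.arange(1, 101)
    counts = (completeness[None, :] >= cutoffs[:, None] - 1e-9).sum(axis=1)
    return CompletenessCurve(cutoffs=cutoffs, counts=counts.astype(float))


def _sliding_ols_slope(y: np.ndarray, half: int) -> np.ndarray:
    """OLS slope of y over x in centered windows x−half..x+half.

    Positions whose window leaves the array (or touches a NaN) get NaN.
    """
    n = y.size
    out = np.full(n, np.nan)
    x = np.arange(-half, half + 1, dtype=float)
    sxx = float(np.sum(x**2))
    for i in range(half, n - half):
        w = y[i - half : i + half + 1]
        if np.any(np.isnan(w)):
            continue
        out[i] = float(np.sum(x * (w - w.mean()))) / sxx
    return out


def select_completeness_cutoff(
    curve: CompletenessCurve,
    window: int = DERIVATIVE_WINDOW,
    zero_tol: float | None = None,
) -> CompletenessCurve:
    """Pick the cutoff where the second derivative first approaches zero.

    The first derivative at x is the OLS slope of counts over cutoffs
    x−2..x+2; the second derivative is the same windowed slope applied to
    the first-derivative series.  The selected cutoff is the smallest x
    with |d2(x)| ≤ zero_tol, where zero_tol defaults to 1% of max|d2|
    (relative, hence invariant under vertical scaling of the counts).  An
    exactly linear curve has d2 ≡ 0 and selects the first evaluable cutoff.
    """
    half = window // 2
    if curve.counts.size < 2 * window:
        raise ValidationError("curve too short for the sliding windows")
    d1 = _sliding_ols_slope(curve.counts, half)
    d2 = _sliding_ols_slope(d1, half)
    finite = np.abs(d2[~np.isnan(d2)])
    max_d2 = finite.max() if finite.size else 0.0
    tol = zero_tol if zero_tol is not None else 0.01 * max_d2
    candidates = np.where(~np.isnan(d2) & (np.abs(d2) <= tol))[0]
    if candidates.size == 0:
        raise NoKneeError(
            f"no cutoff with |d2| <= {tol:.4g} (max |d2| = {max_d2:.4g})"
        )
    selected = int(curve.cutoffs[candidates[0]])
    return CompletenessCurve(
        cutoffs=curve.cutoffs,
        counts=curve.counts,
        d1=d1,
        d2=d2,
        selected_cutoff=selected,
    )


def filter_by_completeness(matrix: QuantMatrix, cutoff_percent: float) -> QuantMatrix:
    """Keep proteins detected in at least ``cutoff_percent`` of the patients
    of at least one cohort (boundary inclusive)."""
    if not (0 < cutoff_percent <= 100):
        raise ValidationError("cutoff must lie in (0, 100]")
    best = matrix.completeness_per_cohort_max()
    keep = best.index[best >= cutoff_percent - 1e-9]
    return matrix.subset(keep)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_downshifted(
    matrix: QuantMatrix,
    shift_sd: float = 1.8,
    width_factor: float = 0.3,
    seed: int = 0,
) -> tuple[QuantMatrix, list[str]]:
    """Fill missing values from a per-protein downshifted normal (log2 space).

    For each protein, missing cells are drawn from
    Normal(median_valid − shift_sd·sd_valid, width_factor·sd_valid)
    computed on the protein's valid log2 intensities; valid cells are never
    altered.  Proteins with fewer than two valid values cannot supply a
    spread and are returned unimputed in the flagged list.  Intended for
    embedding input only (after completeness filtering), not for testing.

    Returns the completed matrix and the list of unimputable proteins.
    """
    rng = np.random.default_rng(seed)
    log2 = matrix.log2().to_numpy()
    out = log2.copy()
    unimputable: list[str] = []
    for i, protein in enumerate(matrix.proteins):
        row = log2[i]
        valid = row[~np.isnan(row)]
        n_missing = int(np.isnan(row).sum())
        if n_missing == 0:
            continue
        if valid.size < 2:
            unimputable.append(str(protein))
            continue
        center = np.median(valid) - shift_sd * valid.std(ddof=1)
        width = width_factor * valid.std(ddof=1)
        draws = rng.normal(center, width, size=n_missing)
        out[i, np.isnan(row)] = draws
    # unimputable proteins keep their missing cells (2**NaN is NaN)
    lfq = pd.DataFrame(2.0**out, index=matrix.proteins, columns=matrix.samples)
    return QuantMatrix(lfq, matrix.cohorts, matrix.ibaq), unimputable


# ---------------------------------------------------------------------------
# top-N abundance and CoV
# ---------------------------------------------------------------------------

TOP_N_PRESETS = (10, 50, 100, 1000)


def top_n_by_abundance(matrix: QuantMatrix, n: int) -> list[str]:
    """Union over cohorts of the n most abundant proteins by median iBAQ.

    Per cohort, proteins are ranked by their median iBAQ across that
    cohort's samples (missing values ignored; undetected proteins rank
    last); ties break by accession for determinism.
    """
    if matrix.ibaq is None:
        raise ValidationError("matrix has no iBAQ layer")
    if n <= 0:
        raise ValidationError("n must be positive")
    selected: set[str] = set()
    for cohort in matrix.cohort_names():
        cc = matrix.cohort_columns(cohort)
        med = matrix.ibaq[cc].median(axis=1, skipna=True)
        order = sorted(
            med.index,
            key=lambda p: (-(med[p]) if not np.isnan(med[p]) else np.inf, str(p)),
        )
        selected.update(map(str, order[:n]))
    return sorted(selected)


def cov_metrics(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Per-group coefficient of variation, percent (sample SD, n−1)."""
    out = {}
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValidationError(f"group {group!r} has fewer than 2 values")
        mean = values.mean()
        if mean == 0:
            raise ValidationError(f"group {group!r} has zero mean")
        out[group] = 100.0 * values.std(ddof=1) / mean
    return out
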