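"""Sample-loading normalization from MS1 total-ion-chromatogram sums.

The total ion current summed over all MS1 scans of a short LC-MS run is, to
good approximation, linear in the peptide amount on column.  A dilution
series of a standard digest of known amounts therefore yields an external
calibration curve (ordinary least squares of ΣTIC on amount, intercept
retained to absorb constant background); the curve is gated on R² and, when
it passes, inverted to estimate each unknown sample's injected amount, its
digest concentration, and the volume needed to load a common target amount.
Samples whose estimate falls below the calibrated range, or whose required
volume exceeds what can be injected, are triaged out before the much more
expensive analytical runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    CalibrationRejectedError,
    DegenerateDesignError,
    NoDataError,
    ValidationError,
)
from .io_formats import SpectrumTICRecord

DEFAULT_R2_THRESHOLD = 0.97
DEFAULT_TARGET_NG = 600.0


# ---------------------------------------------------------------------------


def sum_ms1_tic(records: Iterable[SpectrumTICRecord], run_id: str) -> float:
    """Sum the TIC over all MS1 scans of one run (MS2 scans are ignored).

    Equivalent to the area under the MS1 TIC chromatogram for uniform scan
    spacing.  Raises :class:`NoDataError` if the run has no MS1 scans — a
    run without MS1 data carries no loading information and must not be
    silently treated as zero.
    """
    total = 0.0
    seen = False
    for r in records:
        if r.run_id == run_id and r.ms_level == 1:
            total += r.tic
            seen = True
    if not seen:
        raise NoDataError(f"no MS1 scans found for run {run_id!r}")
    return total


def sum_ms1_tic_by_run(records: Iterable[SpectrumTICRecord]) -> dict[str, float]:
    """ΣMS1-TIC for every run present in ``records``."""
    sums: dict[str, float] = {}
    for r in records:
        if r.ms_level == 1:
            sums[r.run_id] = sums.get(r.run_id, 0.0) + r.tic
    return sums


# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Fitted linear calibration ΣTIC = slope·amount + intercept."""

    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]
    r2_threshold: float = DEFAULT_R2_THRESHOLD

    @property
    def qc_pass(self) -> bool:
        return self.r_squared > self.r2_threshold

    @property
    def min_amount_ng(self) -> float:
        return min(a for a, _ in self.points)

    @property
    def max_amount_ng(self) -> float:
        return max(a for a, _ in self.points)

    def predict(self, amount_ng: float) -> float:
        """Forward prediction: expected ΣTIC for a given amount."""
        return self.slope * amount_ng + self.intercept

    def invert(self, tic_sum: float) -> float:
        """Inverse regression: estimated amount for an observed ΣTIC."""
        return (tic_sum - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "r2_threshold": self.r2_threshold,
            "qc_pass": self.qc_pass,
            "points": [list(p) for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationCurve":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            points=[tuple(p) for p in d["points"]],
            r2_threshold=d.get("r2_threshold", DEFAULT_R2_THRESHOLD),
        )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> CalibrationCurve:
    """Ordinary least squares of ΣTIC on amount over the dilution series.

    R² = 1 − SSres/SStot.  At least two distinct amounts are required; an
    all-identical design is degenerate.  A perfect fit (SStot → interpolation
    through identical responses) yields R² = 1.
    """
    if len(points) < 2:
        raise DegenerateDesignError("calibration needs at least 2 points")
    amounts = np.asarray([p[0] for p in points], dtype=float)
    tics = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(amounts).size < 2:
        raise DegenerateDesignError("all calibration amounts are identical")

    # closed-form normal equations for the two-parameter line
    x_mean, y_mean = amounts.mean(), tics.mean()
    sxx = float(np.sum((amounts - x_mean) ** 2))
    sxy = float(np.sum((amounts - x_mean) * (tics - y_mean)))
    slope = sxy / sxx
    intercept = y_mean - slope * x_mean

    residuals = tics - (slope * amounts + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((tics - y_mean) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        points=[tuple(map(float, p)) for p in points],
        r2_threshold=r2_threshold,
    )


# ---------------------------------------------------------------------------


@dataclass
class SampleLoading:
    """Per-sample amount estimate, concentration, loading volume and triage."""

    sample_id: str
    tic_sum: float
    est_amount_ng: float
    injected_fraction: float
    est_concentration_ng_per_ul: float
    volume_for_target_ul: float | None = None
    triage: str = "ok"  # ok | low_yield | above_range | failed_run


def estimate_amounts(
    curve: CalibrationCurve,
    samples: Sequence[tuple[str, float, float]],
    min_yield_ng: float | None = None,
) -> list[SampleLoading]:
    """Estimate injected amounts and digest concentrations for unknowns.

    ``samples`` are ``(sample_id, tic_sum, injected_volume_ul)`` tuples; the
    injected volume is the digest volume loaded for the normalization run,
    so concentration = estimated amount / injected volume.

    Refuses a curve that failed its R² gate — an unreliable calibration must
    be remeasured, not used.  Triage: estimates below the bottom calibration
    point (or below ``min_yield_ng``) are ``low_yield``; TIC sums above the
    top calibration point's fitted value are ``above_range`` (extrapolated,
    flagged but not refused).
    """
    if not curve.qc_pass:
        raise CalibrationRejectedError(
            f"calibration R²={curve.r_squared:.4f} is not above the "
            f"{curve.r2_threshold} threshold; repeat the dilution series"
        )
    floor_ng = curve.min_amount_ng if min_yield_ng is None else max(
        curve.min_amount_ng, min_yield_ng
    )
    top_tic = curve.predict(curve.max_amount_ng)
    out = []
    for sample_id, tic_sum, injected_ul in samples:
        est = curve.invert(tic_sum)
        conc = est / injected_ul if injected_ul > 0 else float("nan")
        if est < floor_ng:
            triage = "low_yield"
        elif tic_sum > top_tic:
            triage = "above_range"
        else:
            triage = "ok"
        out.append(
            SampleLoading(
                sample_id=sample_id,
                tic_sum=float(tic_sum),
                est_amount_ng=float(est),
                injected_fraction=float(injected_ul),
                est_concentration_ng_per_ul=float(conc),
                triage=triage,
            )
        )
    return out


def compute_loading_volumes(
    loadings: Sequence[SampleLoading],
    target_ng: float = DEFAULT_TARGET_NG,
    max_volume_ul: float = 20.0,
) -> list[SampleLoading]:
    """Volume of digest to load ``target_ng`` for each sample.

    volume = target / concentration.  Samples whose required volume exceeds
    ``max_volume_ul`` (or with non-positive concentration) are triaged
    ``low_yield`` and excluded from analytical runs; a negative volume is
    never emitted.
    """
    if target_ng <= 0:
        raise ValidationError(f"target amount must be positive, got {target_ng}")
    out = []
    for ld in loadings:
        volume: float | None
        triage = ld.triage
        if ld.est_concentration_ng_per_ul <= 0 or not np.isfinite(
            ld.est_concentration_ng_per_ul
        ):
            volume = None
            triage = "low_yield"
        else:
            volume = target_ng / ld.est_concentration_ng_per_ul
            if volume > max_volume_ul:
                triage = "low_yield"
        out.append(
            SampleLoading(
                sample_id=ld.sample_id,
                tic_sum=ld.tic_sum,
                est_amount_ng=ld.est_amount_ng,
                injected_fraction=ld.injected_fraction,
                est_concentration_ng_per_ul=ld.est_concentration_ng_per_ul,
                volume_for_target_ul=volume,
                triage=triage,
            )
        )
    return out


# ---------------------------------------------------------------------------


def cov_percent(values: np.ndarray | Sequence[float]) -> float:
    """Coefficient of variation, percent: 100·SD/mean with population SD.

    Loading-sum CoVs describe the dispersion of the cohort actually
    measured, not an estimate for a larger population, hence the n
    denominator here (the matrix-level ``cov_metrics`` uses sample SD).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("CoV is undefined for groups of size < 2")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("CoV is undefined for zero-mean values")
    return 100.0 * values.std(ddof=0) / mean


def normalization_benefit(
    sums_before: Mapping[str, Sequence[float]],
    sums_after: Mapping[str, Sequence[float]],
) -> dict[str, dict[str, float]]:
    """Per-group CoV of per-sample summed intensity before vs after
    normalization, plus their ratio.

    Groups must match between the two mappings.  CoV is computed on
    natural-scale sums.
    """
    if set(sums_before) != set(sums_after):
        raise ValidationError("group sets differ between before and after")
    report = {}
    for group in sums_before:
        before = cov_percent(sums_before[group])
        after = cov_percent(sums_after[group])
        report[group] = {
            "cov_before_percent": before,
            "cov_after_percent": after,
            "cov_ratio": before / after if after > 0 else float("inf"),
        }
    return report
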