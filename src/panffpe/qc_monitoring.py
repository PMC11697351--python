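"""Longitudinal LC-MS quality control.

Two monitors: (1) retention-time drift of spiked synthetic standard
peptides — a linear model (stretch + offset) of observed on reference RT
per run, flagged when the offset or residual RMSE exceeds configured
bounds; (2) a trend summary over interspersed standard-digest control
runs, flagging runs whose identification counts or mass error deviate
beyond k·MAD from the series median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientStandardsError, ValidationError

DEFAULT_MAX_OFFSET_MIN = 1.0
DEFAULT_MAX_RMSE_MIN = 0.5
DEFAULT_MAD_K = 4.0
DEFAULT_MASS_ERROR_PPM = 1.0


@dataclass
class RTDriftReport:
    """Linear RT drift fit for one run: observed = slope·reference + offset."""

    run_id: str
    n_standards_found: int
    slope: float
    offset: float
    rmse: float
    flagged: bool


def rt_drift_fit(
    observed: Sequence[tuple[str, float, float]],
    run_id: str = "",
    max_offset_min: float = DEFAULT_MAX_OFFSET_MIN,
    max_rmse_min: float = DEFAULT_MAX_RMSE_MIN,
) -> RTDriftReport:
    """Fit observed retention times of matched standards on their references.

    ``observed`` holds ``(standard_id, reference_rt, observed_rt)`` tuples;
    at least three matched standards are required for a meaningful
    two-parameter fit.  The run is flagged when |offset| or the residual
    RMSE exceeds its bound.
    """
    if len(observed) < 3:
        raise InsufficientStandardsError(
            f"run {run_id!r}: {len(observed)} matched standards, need >= 3"
        )
    ref = np.asarray([o[1] for o in observed], dtype=float)
    obs = np.asarray([o[2] for o in observed], dtype=float)
    x_mean, y_mean = ref.mean(), obs.mean()
    sxx = float(np.sum((ref - x_mean) ** 2))
    if sxx == 0:
        raise ValidationError("all reference retention times identical")
    slope = float(np.sum((ref - x_mean) * (obs - y_mean))) / sxx
    offset = y_mean - slope * x_mean
    residuals = obs - (slope * ref + offset)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    flagged = abs(offset) > max_offset_min or rmse > max_rmse_min
    return RTDriftReport(
        run_id=run_id,
        n_standards_found=len(observed),
        slope=slope,
        offset=float(offset),
        rmse=rmse,
        flagged=flagged,
    )


QC_METRICS = ("n_proteins", "n_peptides", "median_mass_error_ppm")


def qc_series_summary(
    control_runs: pd.DataFrame,
    k: float = DEFAULT_MAD_K,
    mass_error_limit_ppm: float = DEFAULT_MASS_ERROR_PPM,
) -> pd.DataFrame:
    """Flag control runs that deviate from the series.

    ``control_runs`` needs columns run_id, date and the metrics in
    :data:`QC_METRICS`.  For each metric the series median and MAD (median
    absolute deviation) are computed; runs beyond median ± k·MAD are
    flagged for that metric.  |median mass error| above the ppm limit is
    flagged regardless (modern search software recalibrates to well below
    1 ppm, so larger values indicate an instrument problem).
    """
    if len(control_runs) < 1:
        raise ValidationError("need at least one control run")
    for col in ("run_id", *QC_METRICS):
        if col not in control_runs.columns:
            raise ValidationError(f"control-run table missing column {col!r}")
    out = control_runs.copy()
    flag_cols = []
    for metric in QC_METRICS:
        values = out[metric].to_numpy(dtype=float)
        center = np.median(values)
        mad = np.median(np.abs(values - center))
        col = f"{metric}_flag"
        if mad == 0:
            out[col] = values != center
        else:
            out[col] = np.abs(values - center) > k * mad
        flag_cols.append(col)
    out["mass_error_flag"] = (
        out["median_mass_error_ppm"].abs().to_numpy(dtype=float) > mass_error_limit_ppm
    )
    out["flagged"] = out[flag_cols + ["mass_error_flag"]].any(axis=1)
    return out
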