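"""Printed design constants of the 1220-case pan-cancer FFPE study.

These are input data (cohort sizes, run scheme, search-engine overlap
counts) from which simple summary quantities of the study design are
recomputed — total case and run counts, the sample-triage exclusion rate,
the instrument-time overhead of the TIC normalization run, and the
linear-scale equivalent of the log2 fold-change cutoff.
"""

from __future__ import annotations

#: Tumor cohorts and their case counts (the two DLBCL batches are merged).
COHORT_SIZES = {
    "GBM": 246,
    "OSCC": 168,
    "DLBCL": 265,
    "PDAC": 204,
    "CRC": 145,
    "MEL": 192,
}

#: Samples entering TIC-normalization triage, and those excluded by it.
INITIAL_SAMPLES = 1424
EXCLUDED_SAMPLES = 165

#: Each sample is measured twice on the analytical gradient,
#: with five FAIMS compensation voltages per run.
ANALYTICAL_RUNS_PER_SAMPLE = 2
CVS_PER_ANALYTICAL_RUN = 5

#: Gradient lengths (minutes): short MS1-only normalization run vs the
#: analytical runs.
NORMALIZATION_GRADIENT_MIN = 11.5
ANALYTICAL_GRADIENT_MIN = 88.0

#: Protein-group overlap across the five search strategies: total distinct
#: quantified groups and those called by all five methods.
TOTAL_PROTEINS_ALL_SEARCHES = 11395
PROTEINS_SHARED_BY_ALL_SEARCHES = 8560

#: Data-driven analysis thresholds.
DEFAULT_COMPLETENESS_CUTOFF_PERCENT = 13.0
DEFAULT_FC_CUTOFF_LOG2 = 0.73


def total_cases() -> int:
    """Number of tumor cases profiled (sum of cohort sizes)."""
    return sum(COHORT_SIZES.values())


def total_analytical_runs() -> int:
    """Number of analytical LC-FAIMS-MS/MS runs (two per case)."""
    return total_cases() * ANALYTICAL_RUNS_PER_SAMPLE


def cvs_per_sample() -> int:
    """FAIMS compensation voltages applied per tissue sample."""
    return ANALYTICAL_RUNS_PER_SAMPLE * CVS_PER_ANALYTICAL_RUN


def exclusion_rate_percent() -> float:
    """Percent of initial samples triaged out for insufficient peptide yield."""
    return 100.0 * EXCLUDED_SAMPLES / INITIAL_SAMPLES


def tic_overhead_percent() -> float:
    """Instrument-time overhead of the normalization run, percent of the
    analytical time per sample."""
    return 100.0 * NORMALIZATION_GRADIENT_MIN / (
        ANALYTICAL_RUNS_PER_SAMPLE * ANALYTICAL_GRADIENT_MIN
    )


def all_search_overlap_percent() -> float:
    """Percent of quantified protein groups called by all five search methods."""
    return 100.0 * PROTEINS_SHARED_BY_ALL_SEARCHES / TOTAL_PROTEINS_ALL_SEARCHES


def fc_cutoff_linear(fc_cutoff_log2: float = DEFAULT_FC_CUTOFF_LOG2) -> float:
    """Linear-scale fold change corresponding to a log2 cutoff."""
    return float(2.0 ** fc_cutoff_log2)
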