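"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of a :class:`SyntheticConfig`; a single
integer seed drives named, independent sub-streams so that runs are
reproducible and adding one generator never perturbs another.  Each
generator also returns the planted ground truth needed for recovery tests.

What is emulated (and the defaults that define the study conditions):

* an 8-point dilution series of a standard digest, 16–1000 ng, with ΣMS1
  TIC linear in amount plus multiplicative noise, and per-sample peptide
  loads with high between-sample variability (log-normal, CoV ≈ 0.5);
* a multi-cohort protein × sample intensity matrix: six tumor cohorts at
  the study's case counts, log2-normal abundances spanning ~6 orders of
  magnitude, planted cohort-exclusive and cohort-enriched proteins, and
  abundance-dependent missingness (logistic detection probability);
* protein identification probabilities with a planted false-positive
  tail, calibrated so that a record's planted false label is Bernoulli in
  its own PEP;
* 40 retention-time standard peptides per run with linear drift across
  runs.

Not emulated: raw spectra, peak shapes, ion-mobility physics, or search
engine behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import SpectrumTICRecord
from .protein_fdr import ProteinScoreRecord
from .quant_matrix import QuantMatrix

#: Tumor cohorts at the study's case counts.
DEFAULT_COHORTS = (
    ("GBM", 246),
    ("OSCC", 168),
    ("DLBCL", 265),
    ("PDAC", 204),
    ("CRC", 145),
    ("MEL", 192),
)

#: Doubling-like dilution grid within the printed 16–1000 ng range.
DEFAULT_DILUTION_NG = (16.0, 31.0, 63.0, 125.0, 250.0, 500.0, 750.0, 1000.0)

#: Sentinel for a step-function missingness model.
STEP_SLOPE = math.inf


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of all synthetic generators.

    Abundance scale: log2 intensities; the base-abundance range of 20 log2
    units corresponds to ~6 orders of magnitude on the linear scale.
    """

    seed: int = 0
    cohorts: tuple[tuple[str, int], ...] = DEFAULT_COHORTS
    n_proteins: int = 2000
    frac_shared: float = 0.67
    frac_exclusive: float = 0.032
    dynamic_range_log10: float = 6.0
    base_log2_min: float = 10.0
    enriched_effect_log2: float = 2.0
    sample_sd_log2: float = 0.8
    cohort_shift_sd_log2: float = 0.25
    missingness_midpoint_log2: float = 14.0
    missingness_slope: float = 0.7
    load_cov: float = 0.5
    load_mean_ng: float = 300.0
    tic_noise_cv: float = 0.05
    tic_per_ng: float = 2.0e8
    dilution_points_ng: tuple[float, ...] = DEFAULT_DILUTION_NG
    n_ms1_scans_per_run: int = 60
    n_ms2_scans_per_run: int = 20
    gradient_min: float = 11.5
    n_rt_standards: int = 40
    rt_gradient_min: float = 88.0
    rt_drift_per_run: float = 0.1
    rt_noise_sd_min: float = 0.0
    n_qc_runs: int = 10

    def __post_init__(self):
        if not (0 <= self.frac_shared <= 1 and 0 <= self.frac_exclusive <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if self.frac_shared + self.frac_exclusive > 1:
            raise ValidationError("frac_shared + frac_exclusive must be <= 1")
        if self.n_proteins <= 0 or any(n <= 0 for _, n in self.cohorts):
            raise ValidationError("all counts must be positive")

    @property
    def base_log2_max(self) -> float:
        return self.base_log2_min + self.dynamic_range_log10 * math.log2(10.0)

    def n_samples(self) -> int:
        return sum(n for _, n in self.cohorts)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    protein_class: pd.Series | None = None  # "shared" | "exclusive:<cohort>" | "enriched:<cohort>"
    true_mean_log2: pd.DataFrame | None = None  # protein × cohort
    sample_load_ng: pd.Series | None = None
    tic_slope_per_ng: float | None = None
    false_protein: pd.Series | None = None  # bool per score record id


def _streams(config: SyntheticConfig, *names: str) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from the single config seed."""
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# TIC / dilution series
# ---------------------------------------------------------------------------


def _make_run_records(
    run_id: str,
    ms1_total: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[SpectrumTICRecord]:
    """Spread a total MS1 TIC over a run's scans, interleaving MS2 scans.

    The per-scan profile is a noisy bell over the gradient — downstream
    code must sum scans, so only the total is calibrated.
    """
    n1, n2 = config.n_ms1_scans_per_run, config.n_ms2_scans_per_run
    rts = np.linspace(0.0, config.gradient_min, n1 + n2, endpoint=False)
    # bell-shaped chromatogram with random roughness, normalized to ms1_total
    centers = np.linspace(0, 1, n1)
    profile = np.exp(-(((centers - 0.5) / 0.25) ** 2)) + 0.05
    profile *= rng.uniform(0.5, 1.5, size=n1)
    profile = profile / profile.sum() * ms1_total
    ms2_positions = set(
        rng.choice(n1 + n2, size=n2, replace=False).tolist()
    )
    records = []
    i1 = 0
    for idx in range(n1 + n2):
        if idx in ms2_positions and i1 < n1:
            level, tic = 2, float(rng.uniform(0.001, 0.01) * ms1_total / n1)
        elif i1 < n1:
            level, tic = 1, float(profile[i1])
            i1 += 1
        else:
            level, tic = 2, float(rng.uniform(0.001, 0.01) * ms1_total / n1)
        records.append(
            SpectrumTICRecord(
                run_id=run_id,
                scan_index=idx,
                ms_level=level,
                rt_min=float(rts[idx]),
                tic=tic,
            )
        )
    return records


def generate_tic_dataset(
    config: SyntheticConfig,
) -> tuple[list[SpectrumTICRecord], list[SpectrumTICRecord], PlantedTruth]:
    """Dilution-series runs and patient normalization runs.

    Each dilution run's ΣMS1 TIC is ``tic_per_ng · ng · (1 + ε)`` with
    ε ~ Normal(0, tic_noise_cv); patient loads are log-normal with mean
    ``load_mean_ng`` and CoV ``load_cov``.  MS2 scans are interleaved and
    must be ignored by downstream TIC summation.
    """
    rngs = _streams(config, "dilution", "loads", "scans")
    dilution_records: list[SpectrumTICRecord] = []
    for ng in config.dilution_points_ng:
        eps = rngs["dilution"].normal(0.0, config.tic_noise_cv) if config.tic_noise_cv > 0 else 0.0
        total = config.tic_per_ng * ng * (1.0 + eps)
        dilution_records.extend(
            _make_run_records(f"dilution_{ng:g}ng", max(total, 0.0), config, rngs["scans"])
        )

    n = config.n_samples()
    # log-normal parameterized by mean and CoV
    sigma2 = math.log(1.0 + config.load_cov**2)
    mu = math.log(config.load_mean_ng) - sigma2 / 2.0
    loads = (
        np.exp(rngs["loads"].normal(mu, math.sqrt(sigma2), size=n))
        if config.load_cov > 0
        else np.full(n, config.load_mean_ng)
    )
    sample_records: list[SpectrumTICRecord] = []
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    for sid, load in zip(sample_ids, loads):
        eps = rngs["loads"].normal(0.0, config.tic_noise_cv) if config.tic_noise_cv > 0 else 0.0
        total = config.tic_per_ng * load * (1.0 + eps)
        sample_records.extend(
            _make_run_records(sid, max(total, 0.0), config, rngs["scans"])
        )
    truth = PlantedTruth(
        sample_load_ng=pd.Series(loads, index=sample_ids),
        tic_slope_per_ng=config.tic_per_ng,
    )
    return dilution_records, sample_records, truth


# ---------------------------------------------------------------------------
# quantitative matrix
# ---------------------------------------------------------------------------


def _assign_classes(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    """Round-robin class labels: shared, exclusive:<cohort>, enriched:<cohort>."""
    n = config.n_proteins
    n_shared = int(round(config.frac_shared * n))
    n_exclusive = int(round(config.frac_exclusive * n))
    n_enriched = n - n_shared - n_exclusive
    cohort_names = [c for c, _ in config.cohorts]
    labels = ["shared"] * n_shared
    labels += [
        f"exclusive:{cohort_names[i % len(cohort_names)]}" for i in range(n_exclusive)
    ]
    labels += [
        f"enriched:{cohort_names[i % len(cohort_names)]}" for i in range(n_enriched)
    ]
    rng.shuffle(labels)
    return labels


def _detection_probability(log2_abundance: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Logistic detection probability in log2 abundance; ∞ slope = step."""
    delta = log2_abundance - config.missingness_midpoint_log2
    if math.isinf(config.missingness_slope):
        return (delta > 0).astype(float)
    return 1.0 / (1.0 + np.exp(-config.missingness_slope * delta))


def generate_quant_matrix(
    config: SyntheticConfig,
) -> tuple[QuantMatrix, list[ProteinScoreRecord], PlantedTruth]:
    """Protein × sample matrix with planted cohort structure, plus scores.

    Base abundances are uniform in log2 over the configured dynamic range;
    planted exclusive/enriched proteins are drawn from the upper, reliably
    detectable part of the range (fingerprint-class proteins in tissue data
    are characteristically abundant).  Values per sample add a cohort-level
    shift (tissue structure), the enrichment effect where planted, and
    within-cohort noise.  Detection is Bernoulli in a logistic function of
    the cell's log2 value; exclusive proteins are structurally absent
    outside their cohort.  The iBAQ layer divides intensity by a per-protein
    theoretical peptide count.

    Identification scores: true proteins get PEPs near 0, a planted tail
    gets diffuse PEPs; every record's false label is Bernoulli in its own
    PEP, so q-values are calibrated by construction.
    """
    rngs = _streams(config, "classes", "abundance", "values", "detect", "scores", "ibaq")
    cohort_names = [c for c, _ in config.cohorts]
    labels = _assign_classes(config, rngs["classes"])
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]

    lo, hi = config.base_log2_min, config.base_log2_max
    base = rngs["abundance"].uniform(lo, hi, size=config.n_proteins)
    special = np.array([lab != "shared" for lab in labels])
    detectable_lo = min(config.missingness_midpoint_log2 + 4.0, hi - 1.0)
    base[special] = rngs["abundance"].uniform(detectable_lo, hi, size=int(special.sum()))

    cohort_shift = (
        rngs["values"].normal(0.0, config.cohort_shift_sd_log2, size=(config.n_proteins, len(cohort_names)))
        if config.cohort_shift_sd_log2 > 0
        else np.zeros((config.n_proteins, len(cohort_names)))
    )

    true_mean = np.tile(base[:, None], (1, len(cohort_names))) + cohort_shift
    for i, lab in enumerate(labels):
        if lab.startswith("enriched:"):
            k = cohort_names.index(lab.split(":", 1)[1])
            true_mean[i, k] += config.enriched_effect_log2
        elif lab.startswith("exclusive:"):
            k = cohort_names.index(lab.split(":", 1)[1])
            mask = np.ones(len(cohort_names), bool)
            mask[k] = False
            true_mean[i, mask] = np.nan  # structurally absent

    sample_ids = []
    sample_cohorts = []
    blocks = []
    det_blocks = []
    for k, (cohort, n_k) in enumerate(config.cohorts):
        ids = [f"{cohort}_{i + 1:03d}" for i in range(n_k)]
        sample_ids.extend(ids)
        sample_cohorts.extend([cohort] * n_k)
        mean_k = true_mean[:, k][:, None]
        vals = mean_k + rngs["values"].normal(
            0.0, config.sample_sd_log2, size=(config.n_proteins, n_k)
        )
        p_det = _detection_probability(vals, config)
        detected = rngs["detect"].random(size=vals.shape) < p_det
        detected &= ~np.isnan(mean_k)  # exclusive proteins absent elsewhere
        blocks.append(vals)
        det_blocks.append(detected)

    log2_vals = np.concatenate(blocks, axis=1)
    detected = np.concatenate(det_blocks, axis=1)
    lfq = np.where(detected, 2.0**log2_vals, np.nan)
    lfq_df = pd.DataFrame(lfq, index=proteins, columns=sample_ids)
    n_theoretical = rngs["ibaq"].integers(5, 100, size=config.n_proteins)
    ibaq_df = lfq_df.div(n_theoretical, axis=0)
    cohorts = pd.Series(sample_cohorts, index=sample_ids)
    matrix = QuantMatrix(lfq_df, cohorts, ibaq=ibaq_df)

    # identification scores with a planted false tail
    n_true = config.n_proteins
    n_false = max(1, int(round(0.1 * n_true)))
    pep_true = rngs["scores"].beta(1.0, 400.0, size=n_true)
    pep_false = rngs["scores"].beta(2.0, 2.0, size=n_false)
    peps = np.concatenate([pep_true, pep_false])
    is_false = rngs["scores"].random(size=peps.size) < peps
    score_ids = proteins + [f"FALSE{i + 1:05d}" for i in range(n_false)]
    scores = [
        ProteinScoreRecord(group_ids=(sid,), probability=float(1.0 - pep))
        for sid, pep in zip(score_ids, peps)
    ]

    truth = PlantedTruth(
        protein_class=pd.Series(labels, index=proteins),
        true_mean_log2=pd.DataFrame(true_mean, index=proteins, columns=cohort_names),
        false_protein=pd.Series(is_false, index=score_ids),
    )
    return matrix, scores, truth


def simulate_analytical_sums(
    true_loads_ng: np.ndarray,
    est_amounts_ng: np.ndarray,
    target_ng: float,
    config: SyntheticConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Per-sample summed MS1 intensity of volume-adjusted analytical runs.

    After normalization the volume loaded aims at ``target_ng`` using the
    estimated concentration, so the amount actually on column is
    ``target · true/estimate``; the analytical measurement adds fresh
    multiplicative TIC noise.  The returned sums carry only the residual
    estimation error plus measurement noise — the quantity whose CoV is
    compared against the unnormalized loading sums.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    loaded = target_ng * np.asarray(true_loads_ng) / np.asarray(est_amounts_ng)
    eps = (
        rng.normal(0.0, config.tic_noise_cv, size=loaded.size)
        if config.tic_noise_cv > 0
        else np.zeros(loaded.size)
    )
    return config.tic_per_ng * loaded * (1.0 + eps)


# ---------------------------------------------------------------------------
# retention-time standards
# ---------------------------------------------------------------------------


def generate_rt_runs(
    config: SyntheticConfig, n_runs: int | None = None
) -> tuple[dict[str, list[tuple[str, float, float]]], PlantedTruth]:
    """Per-run observed retention times of the standard peptides.

    Reference RTs are equally spaced across the analytical gradient;
    observed RTs add an offset growing by ``rt_drift_per_run`` per run
    index plus Gaussian noise.
    """
    rngs = _streams(config, "rt")
    n_runs = config.n_qc_runs if n_runs is None else n_runs
    refs = np.linspace(
        0.05 * config.rt_gradient_min,
        0.95 * config.rt_gradient_min,
        config.n_rt_standards,
    )
    standard_ids = [f"RT{i + 1:02d}" for i in range(config.n_rt_standards)]
    runs: dict[str, list[tuple[str, float, float]]] = {}
    for r in range(n_runs):
        offset = config.rt_drift_per_run * (r + 1)  # run r has drifted r steps
        noise = (
            rngs["rt"].normal(0.0, config.rt_noise_sd_min, size=refs.size)
            if config.rt_noise_sd_min > 0
            else np.zeros_like(refs)
        )
        observed = refs + offset + noise
        runs[f"run_{r + 1:03d}"] = [
            (sid, float(ref), float(obs))
            for sid, ref, obs in zip(standard_ids, refs, observed)
        ]
    return runs, PlantedTruth()


# ---------------------------------------------------------------------------
# minimal mzML writer (for exercising the mzML reader on generator output)
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="0">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000285" name="total ion current" value="{tic:.8g}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(records: Sequence[SpectrumTICRecord], path: str | Path) -> None:
    """Write scans of a single run as a minimal mzML file.

    Only the fields the TIC reader needs are emitted (ms level, total ion
    current, scan start time); peak arrays are empty.
    """
    run_ids = {r.run_id for r in records}
    if len(run_ids) != 1:
        raise ValidationError("write_mzml expects records from exactly one run")
    records = sorted(records, key=lambda r: r.scan_index)
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(run_id=records[0].run_id, count=len(records)))
        for r in records:
            fh.write(
                _MZML_SPECTRUM.format(
                    index=r.scan_index, ms_level=r.ms_level, tic=r.tic, rt=r.rt_min
                )
            )
        fh.write(_MZML_FOOTER)
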