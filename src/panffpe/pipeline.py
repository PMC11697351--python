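"""End-to-end orchestration with stage-level accounting.

``run_pipeline`` executes the stages in order — TIC normalization →
protein FDR → matrix filtering → differential expression → fingerprints →
QC — on synthetic data generated from the pipeline seed (demo mode) or on
user-supplied tables, writing TSV/JSON artifacts per stage plus a manifest
recording parameters, seeds, and counts in/out with exclusion reasons.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import (
    differential,
    fingerprints,
    protein_fdr,
    qc_monitoring,
    quant_matrix,
    synthetic,
    tic_normalization,
)
from .errors import PanFFPEError, ValidationError


@dataclass
class PipelineConfig:
    """Thresholds, seeds and paths for one pipeline run."""

    seed: int = 0
    outdir: str = "panffpe_out"
    target_load_ng: float = 600.0
    max_volume_ul: float = 20.0
    r2_min: float = 0.97
    fdr_alpha: float = 0.01
    completeness_cutoff: float | str = "auto"  # percent, or "auto" for the knee
    fc_cutoff: float | str = "auto"  # log2, or "auto" for the random-split null
    de_alpha: float = 0.01
    # demo-mode synthetic scale
    demo_cohorts: tuple[tuple[str, int], ...] = (
        ("GBM", 20),
        ("OSCC", 20),
        ("DLBCL", 20),
        ("PDAC", 20),
        ("CRC", 20),
        ("MEL", 20),
    )
    demo_n_proteins: int = 1500

    def validate(self) -> None:
        if not (0 < self.fdr_alpha <= 1 and 0 < self.de_alpha <= 1):
            raise ValidationError("alpha thresholds must lie in (0, 1]")
        if not (0 < self.r2_min <= 1):
            raise ValidationError("r2_min must lie in (0, 1]")
        if isinstance(self.completeness_cutoff, (int, float)) and not (
            0 < self.completeness_cutoff <= 100
        ):
            raise ValidationError("completeness_cutoff must lie in (0, 100]")
        if isinstance(self.fc_cutoff, (int, float)) and self.fc_cutoff < 0:
            raise ValidationError("fc_cutoff cannot be negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "demo_cohorts" in data:
            data["demo_cohorts"] = tuple(map(tuple, data["demo_cohorts"]))
        data.update(overrides)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on synthetic demo data; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _pkg_version,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("demo_cohorts", "demo_n_proteins")
        },
        "stages": [],
        "exclusions": [],
    }

    current_stage = "init"

    def stage(name: str, **info):
        manifest["stages"].append({"stage": name, **info})

    syn = synthetic.SyntheticConfig(
        seed=config.seed,
        cohorts=config.demo_cohorts,
        n_proteins=config.demo_n_proteins,
    )

    try:
        current_stage = "tic"
        t0 = time.time()
        dilution, samples, tic_truth = synthetic.generate_tic_dataset(syn)
        dil_sums = tic_normalization.sum_ms1_tic_by_run(dilution)
        points = [
            (ng, dil_sums[f"dilution_{ng:g}ng"]) for ng in syn.dilution_points_ng
        ]
        curve = tic_normalization.fit_calibration(points, r2_threshold=config.r2_min)
        sample_sums = tic_normalization.sum_ms1_tic_by_run(samples)
        loadings = tic_normalization.estimate_amounts(
            curve, [(sid, s, 1.0) for sid, s in sample_sums.items()]
        )
        loadings = tic_normalization.compute_loading_volumes(
            loadings, target_ng=config.target_load_ng, max_volume_ul=config.max_volume_ul
        )
        for ld in loadings:
            if ld.triage != "ok":
                manifest["exclusions"].append(
                    {"stage": "tic", "sample_id": ld.sample_id, "reason": ld.triage}
                )
        loading_df = pd.DataFrame([asdict(ld) for ld in loadings])
        loading_df.to_csv(outdir / "loadings.tsv", sep="\t", index=False)
        (outdir / "calibration.json").write_text(json.dumps(curve.to_dict(), indent=2))
        stage(
            "tic",
            seconds=round(time.time() - t0, 3),
            r_squared=curve.r_squared,
            qc_pass=curve.qc_pass,
            n_samples_in=len(loadings),
            n_samples_out=sum(ld.triage == "ok" for ld in loadings),
        )

        current_stage = "fdr"
        t0 = time.time()
        matrix, scores, truth = synthetic.generate_quant_matrix(syn)
        scored = protein_fdr.compute_qvalues(scores)
        retained = protein_fdr.filter_fdr(scored, alpha=config.fdr_alpha)
        retained_ids = {r.group_ids[0] for r in retained}
        stage(
            "fdr",
            seconds=round(time.time() - t0, 3),
            n_in=len(scores),
            n_out=len(retained),
            alpha=config.fdr_alpha,
        )

        current_stage = "matrix"
        t0 = time.time()
        keep = [p for p in matrix.proteins if p in retained_ids]
        matrix = matrix.subset(keep)
        curve_c = quant_matrix.completeness_curve(matrix, scope="global")
        if config.completeness_cutoff == "auto":
            curve_c = quant_matrix.select_completeness_cutoff(curve_c)
            cutoff = float(curve_c.selected_cutoff)
        else:
            cutoff = float(config.completeness_cutoff)
        filtered = quant_matrix.filter_by_completeness(matrix, cutoff)
        (outdir / "completeness.json").write_text(json.dumps(curve_c.to_dict(), indent=2))
        filtered.write(outdir / "matrix.tsv", outdir / "samples.tsv")
        imputed, unimputable = quant_matrix.impute_downshifted(filtered, seed=config.seed)
        stage(
            "matrix",
            seconds=round(time.time() - t0, 3),
            completeness_cutoff=cutoff,
            n_proteins_in=matrix.n_proteins,
            n_proteins_out=filtered.n_proteins,
            n_unimputable=len(unimputable),
        )

        current_stage = "de"
        t0 = time.time()
        if config.fc_cutoff == "auto":
            null = differential.random_split_null(filtered, n_splits=1, seed=config.seed)
            fc_cutoff = null.fc_cutoff
        else:
            fc_cutoff = float(config.fc_cutoff)
        de = differential.one_vs_rest_tests(
            filtered, fc_cutoff=fc_cutoff, alpha=config.de_alpha
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        stage(
            "de",
            seconds=round(time.time() - t0, 3),
            fc_cutoff=fc_cutoff,
            n_tested=int(de["tested"].sum()),
            n_significant=int(de["significant"].sum()),
        )

        current_stage = "fingerprints"
        t0 = time.time()
        assignments = fingerprints.classify_fingerprints(filtered, fc_cutoff_log2=fc_cutoff)
        # synthetic tissue sets: planted exclusive proteins per cohort
        tissue_sets = {
            cohort: set(
                truth.protein_class.index[truth.protein_class == f"exclusive:{cohort}"]
            )
            for cohort, _ in syn.cohorts
        }
        assignments = fingerprints.split_by_origin(assignments, tissue_sets)
        assignments.to_csv(outdir / "fingerprints.tsv", sep="\t", index=False)
        fp_sets = fingerprints.fingerprint_sets(assignments)
        background = set(map(str, filtered.proteins))
        rng = np.random.default_rng(config.seed)
        annotation_sets = {
            f"SET{j:02d}": set(
                rng.choice(sorted(background), size=min(80, len(background)), replace=False)
            )
            for j in range(1, 6)
        }
        enrich = fingerprints.enrich_fingerprints(
            {c: s & background for c, s in fp_sets.items()}, annotation_sets, background
        )
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        stage(
            "fingerprints",
            seconds=round(time.time() - t0, 3),
            n_assignments=len(assignments),
            n_cohorts=len(fp_sets),
        )

        current_stage = "qc"
        t0 = time.time()
        rt_runs, _ = synthetic.generate_rt_runs(syn)
        reports = [
            qc_monitoring.rt_drift_fit(obs, run_id=run) for run, obs in rt_runs.items()
        ]
        pd.DataFrame([asdict(r) for r in reports]).to_csv(
            outdir / "rt_drift.tsv", sep="\t", index=False
        )
        stage(
            "qc",
            seconds=round(time.time() - t0, 3),
            n_runs=len(reports),
            n_flagged=sum(r.flagged for r in reports),
        )
    except PanFFPEError as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
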