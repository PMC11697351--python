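"""Readers and writers for the tabular and spectral formats the pipeline touches.

TSV is the canonical interchange format; every reader enforces a strict
column dialect and fails loudly (naming the offending column) rather than
guessing.  mzML is supported read-only for MS1 TIC extraction (a streaming
cvParam extractor over the spectrum list).
Missing intensities are encoded as empty fields and read back as missing
(``None``/NaN), never as zero: non-detection is absence of evidence, not a
measurement of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DialectError, ValidationError

# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumTICRecord:
    """One MS scan: run id, scan index, MS level, retention time and TIC."""

    run_id: str
    scan_index: int
    ms_level: int
    rt_min: float
    tic: float

    def __post_init__(self):
        if self.tic < 0:
            raise ValidationError(
                f"negative TIC {self.tic} in run {self.run_id!r} scan {self.scan_index}"
            )
        if self.rt_min < 0:
            raise ValidationError(
                f"negative retention time {self.rt_min} in run {self.run_id!r}"
            )
        if self.ms_level not in (1, 2):
            raise ValidationError(f"unsupported MS level {self.ms_level}")


#: Columns required in a concatenated search-evidence table.
EVIDENCE_COLUMNS = (
    "Sequence",
    "id",
    "Fraction",
    "Raw file",
    "Intensity",
    "Charge",
    "Experiment",
    "Mass",
    "Mass error [ppm]",
    "PEP",
    "Score",
    "Leading proteins",
    "Type",
    "Reverse",
    "Delta score",
    "Modified sequence",
    "MS/MS scan number",
    "Potential contaminant",
)


@dataclass(frozen=True)
class EvidenceRecord:
    """One peptide-evidence row with the analytic fields the pipeline uses."""

    id: int
    sequence: str
    raw_file: str
    experiment: str
    intensity: float | None
    charge: int
    mass_error_ppm: float | None
    score: float
    leading_proteins: str
    reverse_flag: bool
    contaminant_flag: bool
    msms_scan: int
    modified_sequence: str


@dataclass
class ProteinTableRecord:
    """One protein-group row: accessions, identification probability, quant."""

    group_ids: tuple[str, ...]
    probability: float
    unique_peptides: int = 0
    intensity_by_sample: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if not self.group_ids:
            raise ValidationError("protein group has no accessions")
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"protein probability {self.probability} outside [0, 1] "
                f"for group {';'.join(self.group_ids)}"
            )


# ---------------------------------------------------------------------------
# TIC records
# ---------------------------------------------------------------------------

TIC_COLUMNS = ("run_id", "scan_index", "ms_level", "rt_min", "tic")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise DialectError(f"{what}: missing required column {col!r}")


def read_tic_records(path: str | Path, source_dialect: str = "tsv") -> list[SpectrumTICRecord]:
    """Read per-scan TIC records from a TSV export or an mzML file.

    Records are returned ordered by ``(run_id, scan_index)``.
    """
    path = Path(path)
    if source_dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, TIC_COLUMNS, f"TIC table {path.name}")
        records = [
            SpectrumTICRecord(
                run_id=str(r.run_id),
                scan_index=int(r.scan_index),
                ms_level=int(r.ms_level),
                rt_min=float(r.rt_min),
                tic=float(r.tic),
            )
            for r in df.itertuples(index=False)
        ]
    elif source_dialect == "mzml":
        records = _read_tic_mzml(path)
    else:
        raise DialectError(f"unknown TIC dialect {source_dialect!r}")

    records.sort(key=lambda r: (r.run_id, r.scan_index))
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.run_id, r.scan_index)
        if key in seen:
            raise ValidationError(f"duplicate scan_index {r.scan_index} in run {r.run_id!r}")
        seen.add(key)
    return records


#: PSI-MS controlled-vocabulary accessions used by the mzML reader.
_CV_MS_LEVEL = "MS:1000511"
_CV_TIC = "MS:1000285"
_CV_SCAN_START = "MS:1000016"


def _read_tic_mzml(path: Path) -> list[SpectrumTICRecord]:
    """Pull per-spectrum MS level, TIC and scan start time from an mzML file.

    Streams ``<spectrum>`` elements with lxml and reads the three needed
    cvParams by accession (falling back to the cv name); second-unit scan
    times are converted to minutes.
    """
    from lxml import etree

    run_id = path.stem
    records = []
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        ms_level = tic = rt = None
        for cv in elem.iter("{*}cvParam"):
            accession = cv.get("accession", "")
            name = cv.get("name", "")
            if accession == _CV_MS_LEVEL or name == "ms level":
                ms_level = int(cv.get("value"))
            elif accession == _CV_TIC or name == "total ion current":
                tic = float(cv.get("value"))
            elif accession == _CV_SCAN_START or name == "scan start time":
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute") == "second":
                    rt /= 60.0
        if ms_level is None or tic is None:
            raise DialectError(
                f"mzML {path.name}: spectrum {elem.get('index')} lacks "
                "'ms level' or 'total ion current' cvParam"
            )
        records.append(
            SpectrumTICRecord(
                run_id=run_id,
                scan_index=int(elem.get("index")),
                ms_level=ms_level,
                rt_min=0.0 if rt is None else rt,
                tic=tic,
            )
        )
        elem.clear(keep_tail=True)
    return records


def write_tic_records(records: Sequence[SpectrumTICRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "run_id": [r.run_id for r in records],
            "scan_index": [r.scan_index for r in records],
            "ms_level": [r.ms_level for r in records],
            "rt_min": [r.rt_min for r in records],
            "tic": [r.tic for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------


def _flag(value) -> bool:
    if isinstance(value, str):
        return value.strip() == "+"
    return bool(value) and not (isinstance(value, float) and np.isnan(value))


def read_evidence(paths: str | Path | Sequence[str | Path]) -> list[EvidenceRecord]:
    """Read one or more peptide-evidence tables and concatenate them.

    The running ``id`` is reassigned 1..N over the concatenation so every
    entry has a unique number regardless of the ids in the input files.
    Reverse hits and potential contaminants are preserved; filtering them is
    a downstream decision.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(Path(p), sep="\t")
        _require_columns(df, EVIDENCE_COLUMNS, f"evidence table {Path(p).name}")
        frames.append(df)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EVIDENCE_COLUMNS)

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        intensity = row["Intensity"]
        intensity = None if pd.isna(intensity) else float(intensity)
        mass_err = row["Mass error [ppm]"]
        mass_err = None if pd.isna(mass_err) else float(mass_err)
        records.append(
            EvidenceRecord(
                id=i,
                sequence=str(row["Sequence"]),
                raw_file=str(row["Raw file"]),
                experiment=str(row["Experiment"]),
                intensity=intensity,
                charge=int(row["Charge"]),
                mass_error_ppm=mass_err,
                score=float(row["Score"]),
                leading_proteins=str(row["Leading proteins"]),
                reverse_flag=_flag(row["Reverse"]),
                contaminant_flag=_flag(row["Potential contaminant"]),
                msms_scan=int(row["MS/MS scan number"]),
                modified_sequence=str(row["Modified sequence"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# protein tables
# ---------------------------------------------------------------------------

GENERIC_PROTEIN_COLUMNS = ("group_ids", "probability")


def read_protein_table(path: str | Path, dialect: str = "generic") -> list[ProteinTableRecord]:
    """Read a protein-group table.

    ``generic`` dialect: columns ``group_ids`` (";"-separated accessions),
    ``probability``, optional ``unique_peptides``; every remaining column is
    a per-sample intensity (blank = missing).

    ``fragpipe_combined`` dialect: columns ``Protein`` and
    ``Protein Probability``; sample intensities are columns ending in
    ``" Intensity"``.  Protein groups carry a single accession each.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    records: list[ProteinTableRecord] = []
    if dialect == "generic":
        _require_columns(df, GENERIC_PROTEIN_COLUMNS, f"protein table {path.name}")
        meta = {"group_ids", "probability", "unique_peptides"}
        sample_cols = [c for c in df.columns if c not in meta]
        for row in df.itertuples(index=False):
            row = dict(zip(df.columns, row))
            intensities = {
                c: (None if pd.isna(row[c]) else float(row[c])) for c in sample_cols
            }
            records.append(
                ProteinTableRecord(
                    group_ids=tuple(str(row["group_ids"]).split(";")),
                    probability=float(row["probability"]),
                    unique_peptides=int(row.get("unique_peptides", 0) or 0),
                    intensity_by_sample=intensities,
                )
            )
    elif dialect == "fragpipe_combined":
        _require_columns(df, ("Protein", "Protein Probability"), f"protein table {path.name}")
        sample_cols = [c for c in df.columns if c.endswith(" Intensity")]
        for row in df.itertuples(index=False):
            row = dict(zip(df.columns, row))
            intensities = {
                c[: -len(" Intensity")]: (None if pd.isna(row[c]) else float(row[c]))
                for c in sample_cols
            }
            records.append(
                ProteinTableRecord(
                    group_ids=(str(row["Protein"]),),
                    probability=float(row["Protein Probability"]),
                    unique_peptides=int(row.get("Combined Unique Spectral Count", 0) or 0),
                    intensity_by_sample=intensities,
                )
            )
    else:
        raise DialectError(f"unknown protein-table dialect {dialect!r}")
    return records


def write_protein_table(records: Sequence[ProteinTableRecord], path: str | Path) -> None:
    """Write protein-group records in the generic dialect (round-trippable)."""
    sample_cols: list[str] = []
    for r in records:
        for s in r.intensity_by_sample:
            if s not in sample_cols:
                sample_cols.append(s)
    rows = []
    for r in records:
        row = {
            "group_ids": ";".join(r.group_ids),
            "probability": r.probability,
            "unique_peptides": r.unique_peptides,
        }
        for s in sample_cols:
            row[s] = r.intensity_by_sample.get(s)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# FASTA contaminant accessions
# ---------------------------------------------------------------------------


def contaminant_accessions_from_fasta(path: str | Path) -> set[str]:
    """Extract accessions from a contaminant FASTA file.

    Headers of the form ``>sp|P00761|TRYP_PIG ...`` yield ``P00761``;
    plain ``>ACC description`` headers yield ``ACC``.
    """
    accessions: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            token = line[1:].split()[0]
            parts = token.split("|")
            accessions.add(parts[1] if len(parts) >= 2 else parts[0])
    return accessions
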