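"""Validated readers/writers for the tabular schemas and the run manifest.

Tables are UTF-8, tab-separated with one header row ('.' decimal); CSV is
accepted via ``sep=","``. Header names are normalized case-insensitively
through a documented synonym table, so ``Protein``/``accession`` or
``M0``/``m0`` both resolve. Rows violating the measurement invariants are
dropped — never silently: every dropped record is counted per reason in the
read report, and the manifest's bookkeeping requires in = kept + dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

log = logging.getLogger("midaflux")

#: canonical name -> accepted synonyms (matched after lowercasing)
HEADER_SYNONYMS = {
    "sequence": {"sequence", "peptide", "peptide_sequence", "seq"},
    "accession": {"accession", "protein", "protein_accession", "uniprot"},
    "sample": {"sample", "sample_id", "animal", "subject"},
    "group": {"group", "condition", "treatment"},
    "time_h": {"time_h", "time", "timepoint", "time_hours"},
    "charge": {"charge", "z"},
    "analyte": {"analyte"},
    "fraction": {"fraction", "lipid_fraction", "depot"},
    **{f"m{i}": {f"m{i}"} for i in range(4)},
    **{f"std_m{i}": {f"std_m{i}", f"standard_m{i}", f"baseline_m{i}"} for i in range(3)},
}

PEPTIDE_REQUIRED = ("sequence", "accession", "sample", "group", "time_h",
                    "m0", "m1", "m2", "m3")
LIPID_REQUIRED = ("analyte", "fraction", "sample", "group", "time_h",
                  "m0", "m1", "m2", "std_m0", "std_m1", "std_m2")

SUM_RANGE = (0.98, 1.02)


@dataclass
class ReadReport:
    """Row bookkeeping for one table read: in = kept + sum(dropped)."""

    path: str
    n_in: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)
            log.warning("%s: dropped %d rows (%s)", self.path, count, reason)

    @property
    def consistent(self) -> bool:
        return self.n_in == self.n_kept + sum(self.dropped.values())


def _normalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    lookup = {}
    for canonical, synonyms in HEADER_SYNONYMS.items():
        for s in synonyms:
            lookup[s] = canonical
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in lookup:
            renames[col] = lookup[key]
    return df.rename(columns=renames)


def _read(path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValidationError(f"no data rows in {path}")
    return _normalize_headers(df)


def _validate_channels(df: pd.DataFrame, channels: list[str], report: ReadReport,
                       label: str) -> pd.DataFrame:
    vals = df[channels].apply(pd.to_numeric, errors="coerce")
    bad_numeric = vals.isna().any(axis=1)
    report.drop(f"{label}: non-numeric abundance", bad_numeric.sum())
    df, vals = df[~bad_numeric], vals[~bad_numeric]
    neg = (vals < 0).any(axis=1) | (vals > 1).any(axis=1)
    report.drop(f"{label}: abundance outside [0, 1]", neg.sum())
    df, vals = df[~neg], vals[~neg]
    sums = vals.sum(axis=1)
    bad_sum = (sums < SUM_RANGE[0]) | (sums > SUM_RANGE[1])
    report.drop(f"{label}: abundance sum outside {SUM_RANGE}", bad_sum.sum())
    return df[~bad_sum]


def read_peptide_table(path, sep: str | None = None
                       ) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a peptide isotopomer table.

    Required columns (after synonym normalization): sequence, accession,
    sample, group, time_h, m0..m3. Invalid rows are dropped with logged
    reasons; a missing required column rejects the whole file.
    """
    df = _read(path, sep)
    missing = [c for c in PEPTIDE_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"peptide table {path} missing columns: {missing}")
    report = ReadReport(path=str(path), n_in=len(df))
    df = _validate_channels(df, ["m0", "m1", "m2", "m3"], report, "peptide")
    bad_time = pd.to_numeric(df["time_h"], errors="coerce").fillna(-1) <= 0
    report.drop("peptide: non-positive time", bad_time.sum())
    df = df[~bad_time].reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def read_lipid_table(path, sep: str | None = None
                     ) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a GC-MS lipid table (standards columns required)."""
    df = _read(path, sep)
    missing = [c for c in LIPID_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"lipid table {path} missing columns: {missing}")
    report = ReadReport(path=str(path), n_in=len(df))
    df = _validate_channels(df, ["m0", "m1", "m2"], report, "lipid")
    df = _validate_channels(df, ["std_m0", "std_m1", "std_m2"], report, "standard")
    df = df.reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a TSV with a stable float format (bitwise-reproducible runs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted for every pipeline/CLI run."""

    inputs: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    package_version: str = ""
    seed: int | None = None
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record_stage(self, name: str, n_in: int, n_kept: int,
                     dropped: dict[str, int] | None = None) -> None:
        dropped = dropped or {}
        if n_in != n_kept + sum(dropped.values()):
            raise ValidationError(
                f"stage {name}: row bookkeeping does not sum "
                f"({n_in} != {n_kept} + {sum(dropped.values())})"
            )
        self.stages[name] = {"rows_in": int(n_in), "rows_kept": int(n_kept),
                             "dropped": {k: int(v) for k, v in dropped.items()}}

    def to_json(self, path=None) -> str:
        payload = {
            "inputs": self.inputs,
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text + "\n")
        return text
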