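"""Domain types, delimited-text IO and cohort validation.

All stages of the pipeline exchange a small set of record types: per-cell
tables from segmented multiplexed-immunofluorescence slides, per-patient
outcome records, per-patient mutation profiles, and the two-stage trial
design. Files are comma-separated UTF-8 with a header row; exporter column
dialects are absorbed through an alias map in the configuration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._constants import PANEL_MARKERS

__all__ = [
    "SchemaError",
    "ParseError",
    "CellTable",
    "PhenotypeDef",
    "PatientRecord",
    "MutationProfile",
    "TwoStageDesign",
    "ValidationFinding",
    "read_cell_table",
    "write_cell_table",
    "read_manifest",
    "read_outcomes",
    "write_outcomes",
    "read_mutation_profiles",
    "write_mutation_profiles",
    "validate_cohort",
    "load_config",
    "DEFAULT_CONFIG",
]

BOR_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
PFS24_CATEGORIES = ("benefit", "no_benefit", "not_evaluable")
COMPARTMENTS = ("tumor", "stroma")

_CELL_COLUMNS = ["cell_id", "x", "y", "compartment"] + [m.lower() for m in PANEL_MARKERS]

_TRUTHY = {"1", "true", "t", "yes", "pos", "+"}
_FALSY = {"0", "false", "f", "no", "neg", "-", ""}


class SchemaError(ValueError):
    """A required column or field is missing or structurally wrong."""


class ParseError(ValueError):
    """A cell value could not be interpreted; the message names the row."""


@dataclass
class CellTable:
    """Segmented cells of one specimen.

    ``cells`` has columns ``cell_id, x, y, compartment`` plus one boolean
    column per panel marker (lower-case). Coordinates are micrometres in an
    arbitrary per-specimen frame; geometry is never compared across
    specimens.
    """

    specimen_id: str
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SchemaError(
                f"specimen {self.specimen_id!r}: missing columns {missing}"
            )
        df = self.cells
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ParseError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        if (xy < 0).any():
            raise ParseError(f"specimen {self.specimen_id!r}: negative coordinates")
        bad = set(df["compartment"].unique()) - set(COMPARTMENTS)
        if bad:
            raise ParseError(
                f"specimen {self.specimen_id!r}: unknown compartment labels {sorted(bad)}"
            )
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise SchemaError(
                f"specimen {self.specimen_id!r}: duplicate cell_id {dup!r}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def in_compartment(self, compartment: str) -> pd.DataFrame:
        """Rows of ``cells`` in one compartment, or all rows for 'both'."""
        if compartment == "both":
            return self.cells
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return self.cells[self.cells["compartment"] == compartment]


@dataclass(frozen=True)
class PhenotypeDef:
    """A marker gate: a cell matches iff every required-positive marker is
    present and every required-negative marker is absent."""

    name: str
    required_positive: frozenset[str] = frozenset()
    required_negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_positive", frozenset(self.required_positive))
        object.__setattr__(self, "required_negative", frozenset(self.required_negative))
        overlap = self.required_positive & self.required_negative
        if overlap:
            raise ValueError(
                f"phenotype {self.name!r}: markers {sorted(overlap)} both required "
                "positive and negative"
            )
        unknown = (self.required_positive | self.required_negative) - set(PANEL_MARKERS)
        if unknown:
            raise SchemaError(
                f"phenotype {self.name!r}: unknown markers {sorted(unknown)}"
            )


@dataclass
class PatientRecord:
    """Clinical outcomes for one patient."""

    patient_id: str
    specimens: list[str] = field(default_factory=list)
    bor: str = "NE"
    pfs_months: float = 0.0
    pfs_event: bool = False
    os_months: float = 0.0
    os_event: bool = False
    pfs24: str = "not_evaluable"

    def __post_init__(self) -> None:
        if self.bor not in BOR_CATEGORIES:
            raise ValueError(f"patient {self.patient_id!r}: bad BOR {self.bor!r}")
        if self.pfs24 not in PFS24_CATEGORIES:
            raise ValueError(f"patient {self.patient_id!r}: bad pfs24 {self.pfs24!r}")
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError(f"patient {self.patient_id!r}: negative survival time")
        if self.pfs_event and self.os_event and self.pfs_months > self.os_months + 1e-9:
            raise ValueError(
                f"patient {self.patient_id!r}: PFS exceeds OS with both events observed"
            )

    @property
    def evaluable(self) -> bool:
        """Efficacy-evaluable: has a best overall response other than NE."""
        return self.bor != "NE"


@dataclass
class MutationProfile:
    """Per-patient genomic summary consumed from upstream pipelines."""

    patient_id: str
    gene_flags: dict[str, bool]
    n_nonsyn: int
    capture_mb: float
    msisensor: float
    exposures: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nonsyn < 0:
            raise ValueError(f"{self.patient_id}: negative mutation count")
        if not self.capture_mb > 0:
            raise ValueError(f"{self.patient_id}: capture size must be positive")
        total = sum(self.exposures.values())
        if total > 1 + 1e-6:
            raise ValueError(f"{self.patient_id}: signature exposures sum to {total} > 1")
        if any(v < 0 for v in self.exposures.values()):
            raise ValueError(f"{self.patient_id}: negative signature exposure")


@dataclass(frozen=True)
class TwoStageDesign:
    """Simon two-stage rule.

    Stage 1 enrolls ``n1`` evaluable patients and continues iff successes
    ≥ ``r1`` + 1; the regimen is promising iff total successes among ``n``
    are ≥ ``r`` + 1.
    """

    n1: int
    r1: int
    n: int
    r: int
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 <= self.n):
            raise ValueError("require 0 <= r1 < n1 <= n")
        if not (self.r1 <= self.r < self.n):
            raise ValueError("require r1 <= r < n")
        if not (0 < self.p0 < self.p1 < 1):
            raise ValueError("require 0 < p0 < p1 < 1")


# ---------------------------------------------------------------------------
# Delimited-text IO


def _parse_bool(value, row: int, column: str):
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ParseError(f"row {row}: cannot parse {column}={value!r} as a marker call")


def read_cell_table(
    path: str | Path,
    specimen_id: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> CellTable:
    """Read one specimen's cell table from CSV.

    ``aliases`` maps exporter column names to canonical names (for example
    ``{"Cell X Position": "x"}``). The specimen id defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if aliases:
        df = df.rename(columns=dict(aliases))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    out = pd.DataFrame()
    out["cell_id"] = df["cell_id"].astype(str)
    for coord in ("x", "y"):
        vals = pd.to_numeric(df[coord], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # 1-based incl. header
            raise ParseError(f"{path.name}: row {row}: non-numeric {coord} coordinate")
        out[coord] = vals.astype(float)
    out["compartment"] = df["compartment"].str.strip().str.lower()
    for marker in PANEL_MARKERS:
        col = marker.lower()
        out[col] = [
            _parse_bool(v, i + 2, col) for i, v in enumerate(df[col].fillna(""))
        ]
    return CellTable(specimen_id or path.stem, out.reset_index(drop=True))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    df = table.cells.copy()
    for marker in PANEL_MARKERS:
        df[marker.lower()] = df[marker.lower()].astype(int)
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the specimen-to-patient manifest (columns specimen_id, patient_id)."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("specimen_id", "patient_id"):
        if col not in df.columns:
            raise SchemaError(f"manifest: missing column {col!r}")
    return df[["specimen_id", "patient_id"]]


def read_outcomes(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["patient_id", "bor", "pfs_months", "pfs_event", "os_months", "os_event", "pfs24"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"outcomes: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                bor=str(row["bor"]),
                pfs_months=float(row["pfs_months"]),
                pfs_event=bool(int(row["pfs_event"])),
                os_months=float(row["os_months"]),
                os_event=bool(int(row["os_event"])),
                pfs24=str(row["pfs24"]),
            )
        )
    return records


def write_outcomes(records: Sequence[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "bor": [r.bor for r in records],
            "pfs_months": [r.pfs_months for r in records],
            "pfs_event": [int(r.pfs_event) for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [int(r.os_event) for r in records],
            "pfs24": [r.pfs24 for r in records],
        }
    ).to_csv(path, index=False)


def read_mutation_profiles(
    mutations_path: str | Path, exposures_path: str | Path | None = None
) -> list[MutationProfile]:
    """Read mutation flags plus TMB inputs, optionally joining exposures.

    ``mutations.csv`` holds patient_id, n_nonsyn, capture_mb, msisensor and
    one 0/1 column per gene; ``exposures.csv`` holds patient_id plus one
    column per signature id.
    """
    df = pd.read_csv(mutations_path, dtype={"patient_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    fixed = {"patient_id", "n_nonsyn", "capture_mb", "msisensor"}
    missing = fixed - set(df.columns)
    if missing:
        raise SchemaError(f"mutations: missing columns {sorted(missing)}")
    gene_cols = [c for c in df.columns if c not in fixed]
    expo: dict[str, dict[str, float]] = {}
    if exposures_path is not None:
        edf = pd.read_csv(exposures_path, dtype={"patient_id": str})
        edf.columns = [c.strip().lower() for c in edf.columns]
        sig_cols = [c for c in edf.columns if c != "patient_id"]
        for _, row in edf.iterrows():
            expo[str(row["patient_id"])] = {
                s.upper(): float(row[s]) for s in sig_cols
            }
    profiles = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        profiles.append(
            MutationProfile(
                patient_id=pid,
                gene_flags={g.upper(): bool(int(row[g])) for g in gene_cols},
                n_nonsyn=int(row["n_nonsyn"]),
                capture_mb=float(row["capture_mb"]),
                msisensor=float(row["msisensor"]),
                exposures=expo.get(pid, {}),
            )
        )
    return profiles


def write_mutation_profiles(
    profiles: Sequence[MutationProfile],
    mutations_path: str | Path,
    exposures_path: str | Path | None = None,
) -> None:
    genes = sorted({g for p in profiles for g in p.gene_flags})
    rows = []
    for p in profiles:
        row = {
            "patient_id": p.patient_id,
            "n_nonsyn": p.n_nonsyn,
            "capture_mb": p.capture_mb,
            "msisensor": p.msisensor,
        }
        row.update({g: int(p.gene_flags.get(g, False)) for g in genes})
        rows.append(row)
    pd.DataFrame(rows).to_csv(mutations_path, index=False)
    if exposures_path is not None:
        sigs = sorted({s for p in profiles for s in p.exposures})
        erows = [
            {"patient_id": p.patient_id, **{s: p.exposures.get(s, 0.0) for s in sigs}}
            for p in profiles
        ]
        pd.DataFrame(erows).to_csv(exposures_path, index=False)


# ---------------------------------------------------------------------------
# Cohort validation


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "warning" | "fatal"
    message: str


def validate_cohort(
    cells: Iterable[CellTable], patients: Iterable[PatientRecord]
) -> list[ValidationFinding]:
    """Cross-check specimens against patients; order-independent report.

    Fatal findings (duplicate ids, a patient's specimen that has no cell
    table) should stop a pipeline run; orphan specimens are warnings.
    """
    findings: list[ValidationFinding] = []
    cells = list(cells)
    patients = list(patients)

    specimen_ids = [t.specimen_id for t in cells]
    for sid in sorted({s for s in specimen_ids if specimen_ids.count(s) > 1}):
        findings.append(ValidationFinding("fatal", f"duplicate specimen_id {sid!r}"))
    patient_ids = [p.patient_id for p in patients]
    for pid in sorted({p for p in patient_ids if patient_ids.count(p) > 1}):
        findings.append(ValidationFinding("fatal", f"duplicate patient_id {pid!r}"))

    referenced = {s for p in patients for s in p.specimens}
    for sid in sorted(set(specimen_ids) - referenced):
        findings.append(
            ValidationFinding("warning", f"specimen {sid!r} referenced by no patient")
        )
    available = set(specimen_ids)
    for p in sorted(patients, key=lambda p: p.patient_id):
        if p.specimens and not set(p.specimens) <= available:
            missing = sorted(set(p.specimens) - available)
            findings.append(
                ValidationFinding(
                    "fatal",
                    f"patient {p.patient_id!r} references missing specimens {missing}",
                )
            )
        if not p.specimens:
            findings.append(
                ValidationFinding("warning", f"patient {p.patient_id!r} has no specimens")
            )
    return findings


def has_fatal(findings: Iterable[ValidationFinding]) -> bool:
    return any(f.severity == "fatal" for f in findings)


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict = {
    "radius_um": 50.0,
    "msi_threshold": 3.5,
    "cutoff_rule": "tertile",
    "two_by_two_test": "chisq",
    "compartment": "tumor",
    "column_aliases": {},
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, filling unspecified keys with defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError("config must be a YAML mapping")
        cfg.update(user)
    return cfg
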