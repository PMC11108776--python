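"""Phenotype gating and population-fraction parameters.

Cells are gated with boolean marker combinations into (possibly nested)
phenotypes — e.g. dysfunctional T cells are CD8+PD-1+ and terminally
dysfunctional T cells CD8+PD-1+TOX+, so the latter is a subset of the
former. Fractions are reported as percentages of total nucleated cells,
of the CD8+ compartment, or of a custom denominator, within the tumor
compartment by default (stroma analysis is available behind the
``compartment`` argument). Per-patient values are unweighted means across
that patient's specimens.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CellTable, PhenotypeDef, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_PHENOTYPES",
    "classify",
    "phenotype_mask",
    "population_fraction",
    "cd8_foxp3_ratio",
    "pdl1_positivity",
    "patient_average",
    "biomarker_matrix",
]

#: Gates used throughout the analysis. CD8 and FoxP3 lineages are mutually
#: exclusive in the generator, but the gates do not assume it.
STANDARD_PHENOTYPES: dict[str, PhenotypeDef] = {
    d.name: d
    for d in [
        PhenotypeDef("CD8", {"CD8"}),
        PhenotypeDef("CD8_PD1", {"CD8", "PD1"}),
        PhenotypeDef("CD8_PD1_TOX", {"CD8", "PD1", "TOX"}),
        PhenotypeDef("FOXP3", {"FOXP3"}),
        PhenotypeDef("PDL1", {"PDL1"}),
        PhenotypeDef("PDL1_TUMOR", {"PDL1", "PAX8"}),
        PhenotypeDef("TUMOR_CELL", {"PAX8"}),
    ]
}


def phenotype_mask(cells: pd.DataFrame, definition: PhenotypeDef) -> np.ndarray:
    """Boolean membership of each row of a cell frame in one phenotype."""
    mask = np.ones(len(cells), dtype=bool)
    for marker in definition.required_positive:
        mask &= cells[marker.lower()].to_numpy(dtype=bool)
    for marker in definition.required_negative:
        mask &= ~cells[marker.lower()].to_numpy(dtype=bool)
    return mask


def classify(table: CellTable, defs: Sequence[PhenotypeDef]) -> pd.DataFrame:
    """Per-cell membership matrix (cells x phenotypes), indexed by cell_id.

    Membership is not exclusive: a CD8+PD-1+TOX+ cell matches all three
    nested T-cell gates.
    """
    out = pd.DataFrame(index=table.cells["cell_id"])
    for d in defs:
        out[d.name] = phenotype_mask(table.cells, d)
    return out


def _resolve_denominator(
    cells: pd.DataFrame, denominator: str | PhenotypeDef
) -> np.ndarray:
    if isinstance(denominator, PhenotypeDef):
        return phenotype_mask(cells, denominator)
    if denominator == "total_nucleated":
        return np.ones(len(cells), dtype=bool)
    if denominator in STANDARD_PHENOTYPES:
        return phenotype_mask(cells, STANDARD_PHENOTYPES[denominator])
    raise SchemaError(f"unknown denominator {denominator!r}")


def population_fraction(
    table: CellTable,
    phenotype: PhenotypeDef | str,
    denominator: str | PhenotypeDef = "total_nucleated",
    compartment: str = "tumor",
) -> float:
    """Percentage of denominator cells matching ``phenotype`` in a compartment.

    Returns NaN (with a logged warning) when the denominator is empty.
    """
    cells = table.in_compartment(compartment)
    if isinstance(phenotype, str):
        phenotype = STANDARD_PHENOTYPES[phenotype]
    denom_mask = _resolve_denominator(cells, denominator)
    n_denom = int(denom_mask.sum())
    if n_denom == 0:
        logger.warning(
            "specimen %s: empty denominator for %s in %s compartment",
            table.specimen_id, phenotype.name, compartment,
        )
        return math.nan
    num = int((phenotype_mask(cells, phenotype) & denom_mask).sum())
    return 100.0 * num / n_denom


def cd8_foxp3_ratio(table: CellTable, compartment: str = "tumor") -> float:
    """CD8+ to FoxP3+ cell-count ratio; NaN when there are no FoxP3+ cells."""
    cells = table.in_compartment(compartment)
    n_cd8 = int(phenotype_mask(cells, STANDARD_PHENOTYPES["CD8"]).sum())
    n_treg = int(phenotype_mask(cells, STANDARD_PHENOTYPES["FOXP3"]).sum())
    if n_treg == 0:
        return math.nan
    return n_cd8 / n_treg


def pdl1_positivity(table: CellTable, scope: str = "tumor_cells") -> float:
    """PD-L1 positivity in the tumor compartment.

    ``tumor_cells``: PD-L1+ share of Pax8+ tumor cells; ``combined``:
    PD-L1+ share of all cells (tumor and immune).
    """
    cells = table.in_compartment("tumor")
    pdl1 = phenotype_mask(cells, STANDARD_PHENOTYPES["PDL1"])
    if scope == "tumor_cells":
        pax8 = phenotype_mask(cells, STANDARD_PHENOTYPES["TUMOR_CELL"])
        if pax8.sum() == 0:
            return math.nan
        return 100.0 * int((pdl1 & pax8).sum()) / int(pax8.sum())
    if scope == "combined":
        if len(cells) == 0:
            return math.nan
        return 100.0 * int(pdl1.sum()) / len(cells)
    raise ValueError(f"unknown scope {scope!r}")


def patient_average(values: Iterable[float]) -> float:
    """Unweighted mean over non-missing per-specimen values; NaN if none."""
    vals = [v for v in values if not (v is None or (isinstance(v, float) and math.isnan(v)))]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def biomarker_matrix(
    tables: Sequence[CellTable],
    manifest: Mapping[str, str] | pd.DataFrame,
    compartment: str = "tumor",
    radius_um: float = 50.0,
) -> pd.DataFrame:
    """Patient-level biomarker matrix combining fraction and spatial metrics.

    ``manifest`` maps specimen_id to patient_id. Specimen values are
    averaged per patient; missing values are dropped from the average and
    propagate as NaN when no specimen yields a value.
    """
    from .spatial import interaction_panel  # deferred to avoid import cycle

    if isinstance(manifest, pd.DataFrame):
        manifest = dict(zip(manifest["specimen_id"], manifest["patient_id"]))

    rows = []
    for table in tables:
        row: dict[str, float] = {"specimen_id": table.specimen_id}
        row["pct_CD8"] = population_fraction(table, "CD8", compartment=compartment)
        row["pct_CD8_PD1"] = population_fraction(table, "CD8_PD1", compartment=compartment)
        row["pct_CD8_PD1_TOX"] = population_fraction(
            table, "CD8_PD1_TOX", compartment=compartment
        )
        row["pct_CD8_PD1_of_CD8"] = population_fraction(
            table, "CD8_PD1", denominator="CD8", compartment=compartment
        )
        row["pct_CD8_PD1_TOX_of_CD8"] = population_fraction(
            table, "CD8_PD1_TOX", denominator="CD8", compartment=compartment
        )
        row["pct_FOXP3"] = population_fraction(table, "FOXP3", compartment=compartment)
        row["cd8_foxp3_ratio"] = cd8_foxp3_ratio(table, compartment=compartment)
        row["pct_PDL1_tumor"] = pdl1_positivity(table, scope="tumor_cells")
        row["pct_PDL1_all"] = pdl1_positivity(table, scope="combined")
        row.update(interaction_panel(table, compartment=compartment, radius_um=radius_um))
        rows.append(row)

    per_specimen = pd.DataFrame(rows).set_index("specimen_id")
    per_specimen["patient_id"] = [manifest.get(s, None) for s in per_specimen.index]
    matrix = per_specimen.groupby("patient_id").agg(
        lambda col: patient_average(col.tolist())
    )
    matrix.index.name = "patient_id"
    return matrix
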