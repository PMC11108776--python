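"""Nearest-neighbor distances and within-radius interaction fractions.

Distances are Euclidean in micrometres within a single specimen. The
interaction fraction follows the plain slide-level estimator: the share of
target-phenotype cells with at least one anchor-phenotype cell within the
radius (inclusive boundary), with no edge correction. A cell is never its
own neighbor: when target and anchor classes overlap, self-pairs are
excluded but coincident *other* cells at distance zero still count.

Neighbor queries use a k-d tree; a brute-force O(|A|·|B|) scan gives the
identical result and serves as the oracle in the test-suite.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._constants import DEFAULT_RADIUS_UM
from .data_model import CellTable, PhenotypeDef
from .phenotyping import STANDARD_PHENOTYPES, phenotype_mask

logger = logging.getLogger(__name__)

__all__ = [
    "nn_distances",
    "median_nn_distance",
    "interaction_fraction",
    "interaction_panel",
]


def _masks(
    cells: pd.DataFrame, from_phenotype: PhenotypeDef | str, to_phenotype: PhenotypeDef | str
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(from_phenotype, str):
        from_phenotype = STANDARD_PHENOTYPES[from_phenotype]
    if isinstance(to_phenotype, str):
        to_phenotype = STANDARD_PHENOTYPES[to_phenotype]
    return phenotype_mask(cells, from_phenotype), phenotype_mask(cells, to_phenotype)


def nn_distances(
    table: CellTable,
    from_phenotype: PhenotypeDef | str,
    to_phenotype: PhenotypeDef | str,
    compartment: str = "tumor",
) -> np.ndarray:
    """Distance from each from-phenotype cell to its nearest to-phenotype cell.

    Returns one value per from-cell (NaN when no eligible neighbor exists,
    e.g. the to-class is empty, or consists solely of the from-cell itself).
    """
    cells = table.in_compartment(compartment)
    a_mask, b_mask = _masks(cells, from_phenotype, to_phenotype)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    a_idx = np.flatnonzero(a_mask)
    b_idx = np.flatnonzero(b_mask)
    if a_idx.size == 0:
        return np.empty(0)
    if b_idx.size == 0:
        return np.full(a_idx.size, np.nan)

    tree = cKDTree(xy[b_idx])
    k = min(2, b_idx.size)
    dist, nbr = tree.query(xy[a_idx], k=k)
    dist = np.atleast_2d(dist.T).T  # (n_a, k)
    nbr = np.atleast_2d(nbr.T).T
    out = np.empty(a_idx.size)
    b_of = b_idx[nbr]  # original row indices of neighbors
    for i, a in enumerate(a_idx):
        if b_of[i, 0] != a:
            out[i] = dist[i, 0]
        elif k > 1:
            out[i] = dist[i, 1]
        else:  # the only to-cell is the from-cell itself
            out[i] = np.nan
    return out


def median_nn_distance(
    table: CellTable,
    from_phenotype: PhenotypeDef | str,
    to_phenotype: PhenotypeDef | str,
    compartment: str = "tumor",
) -> float:
    """Median nearest-neighbor distance in µm; NaN when no distance exists."""
    d = nn_distances(table, from_phenotype, to_phenotype, compartment=compartment)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return math.nan
    return float(np.median(d))


def interaction_fraction(
    table: CellTable,
    target_phenotype: PhenotypeDef | str,
    anchor_phenotype: PhenotypeDef | str,
    radius_um: float = DEFAULT_RADIUS_UM,
    compartment: str = "tumor",
) -> float:
    """Percent of target cells within ``radius_um`` of any anchor cell.

    Boundary inclusive; empty anchor class yields 0% with a warning; empty
    target class yields NaN.
    """
    if not radius_um > 0:
        raise ValueError("radius must be positive")
    cells = table.in_compartment(compartment)
    t_mask, a_mask = _masks(cells, target_phenotype, anchor_phenotype)
    t_idx = np.flatnonzero(t_mask)
    a_idx = np.flatnonzero(a_mask)
    if t_idx.size == 0:
        return math.nan
    if a_idx.size == 0:
        logger.warning(
            "specimen %s: no anchor cells; interaction fraction set to 0",
            table.specimen_id,
        )
        return 0.0

    xy = cells[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy[a_idx])
    balls = tree.query_ball_point(xy[t_idx], r=radius_um)
    n_hit = 0
    for t, members in zip(t_idx, balls):
        for m in members:
            if a_idx[m] != t:  # exclude the self-pair
                n_hit += 1
                break
    return 100.0 * n_hit / t_idx.size


def interaction_panel(
    table: CellTable,
    compartment: str = "tumor",
    radius_um: float = DEFAULT_RADIUS_UM,
) -> Mapping[str, float]:
    """The slide-level spatial parameter set.

    PD-L1+ (tumor-cell and any-cell) interaction fractions anchored on CD8+
    and on dysfunctional CD8+PD-1+ cells, Treg interaction fractions on the
    same anchors, and the median distance from CD8+PD-1+ cells to the
    nearest PD-L1+ cell.
    """
    out: dict[str, float] = {}
    for target, label in [("PDL1_TUMOR", "PDL1tumor"), ("PDL1", "PDL1"), ("FOXP3", "FoxP3")]:
        for anchor, alabel in [("CD8", "CD8"), ("CD8_PD1", "CD8PD1")]:
            key = f"frac_{label}_within{radius_um:g}_of_{alabel}"
            out[key] = interaction_fraction(
                table, target, anchor, radius_um=radius_um, compartment=compartment
            )
    out["median_nn_CD8PD1_to_PDL1"] = median_nn_distance(
        table, "CD8_PD1", "PDL1", compartment=compartment
    )
    return out
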