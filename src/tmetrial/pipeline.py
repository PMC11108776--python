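"""End-to-end orchestration: simulate/load -> biomarkers -> statistics -> report.

Each stage writes plain CSV/JSON artifacts into the output directory and
logs the seed it ran under, so a run is reproducible from its bundle.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._constants import ONE_YEAR_MONTHS, WEEKS24_MONTHS
from .biomarker_stats import (
    TwoByTwo,
    TmeLogisticModel,
    bottom_tertile_cutoff,
    chi_square,
    correlation_cluster,
    diagnostics,
    dichotomize,
    fisher_exact,
    mann_whitney,
    roc_auc,
)
from .data_model import (
    CellTable,
    PatientRecord,
    TwoStageDesign,
    has_fatal,
    load_config,
    read_cell_table,
    read_manifest,
    read_mutation_profiles,
    read_outcomes,
    validate_cohort,
    write_cell_table,
    write_mutation_profiles,
    write_outcomes,
)
from .genomics import gene_benefit_scan, group_compare_tmb, msi_classify, signature_labels
from .phenotyping import biomarker_matrix
from .synthetic import SimulationParams, simulate_cohort
from .trial_endpoints import clopper_pearson, km_estimate, pfs24_classify, response_rates, simon_oc

logger = logging.getLogger(__name__)

__all__ = [
    "ORR_DESIGN",
    "PFS24_DESIGN",
    "MODEL_PARAMETERS",
    "benefit_groups",
    "association_table",
    "fit_benefit_model",
    "endpoint_report",
    "run_pipeline",
]

#: The ORR co-primary rule: stage 1 enrolls 23 and continues iff >=2
#: responses; promising iff >=6 responses among 40 total; H0 5% vs H1 25%.
ORR_DESIGN = TwoStageDesign(n1=23, r1=1, n=40, r=5, p0=0.05, p1=0.25)

#: The PFS24 co-primary rule: >=5 of the initial 17 evaluable progression
#: free at 24 weeks to continue; promising iff >=16 of 40; 25% vs 50%.
PFS24_DESIGN = TwoStageDesign(n1=17, r1=4, n=40, r=15, p0=0.25, p1=0.50)

#: The two-covariate benefit model: terminally dysfunctional share of CD8+
#: cells, and PD-L1+ cells within the radius of dysfunctional T cells.
MODEL_PARAMETERS = ("pct_CD8_PD1_TOX_of_CD8", "frac_PDL1_within50_of_CD8PD1")


def benefit_groups(patients: Sequence[PatientRecord]) -> dict[str, str]:
    """patient_id -> 24-week benefit label, excluding not-evaluable."""
    return {
        p.patient_id: p.pfs24
        for p in patients
        if p.pfs24 in ("benefit", "no_benefit")
    }


def association_table(
    matrix: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-parameter benefit association: group medians + Mann–Whitney p.

    Missing values are dropped pairwise per parameter, with a logged count.
    """
    rows = []
    for col in matrix.columns:
        vals = matrix[col]
        x = vals[[pid for pid in vals.index if groups.get(pid) == "benefit"]].dropna()
        y = vals[[pid for pid in vals.index if groups.get(pid) == "no_benefit"]].dropna()
        n_missing = vals.isna().sum()
        if n_missing:
            logger.info("parameter %s: %d missing values dropped", col, n_missing)
        if len(x) == 0 or len(y) == 0:
            rows.append({"parameter": col, "n_benefit": len(x), "n_no_benefit": len(y),
                         "median_benefit": math.nan, "median_no_benefit": math.nan,
                         "mw_p": math.nan})
            continue
        res = mann_whitney(x.to_numpy(), y.to_numpy())
        rows.append(
            {
                "parameter": col,
                "n_benefit": len(x),
                "n_no_benefit": len(y),
                "median_benefit": float(np.median(x)),
                "median_no_benefit": float(np.median(y)),
                "mw_p": res.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def fit_benefit_model(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    parameters: Sequence[str] = MODEL_PARAMETERS,
    two_by_two_test: str = "chisq",
) -> dict:
    """Dichotomize the two model parameters at their bottom-tertile cutoffs,
    cross-tabulate against benefit, fit the logistic model and compute the
    ROC AUC of its fitted probabilities."""
    pids = [p for p in matrix.index if p in groups and
            not matrix.loc[p, list(parameters)].isna().any()]
    X = matrix.loc[pids, list(parameters)].to_numpy(dtype=float)
    y = np.array([groups[p] == "benefit" for p in pids])
    out: dict = {"n": len(pids), "parameters": list(parameters)}

    out["cutoffs"] = {}
    out["two_by_two"] = {}
    for j, param in enumerate(parameters):
        cutoff = bottom_tertile_cutoff(X[:, j])
        high = dichotomize(X[:, j], cutoff)
        t = TwoByTwo(
            int((high & y).sum()), int((high & ~y).sum()),
            int((~high & y).sum()), int((~high & ~y).sum()),
        )
        if two_by_two_test == "fisher":
            test_p = fisher_exact(t)
            stat = math.nan
        else:
            stat, test_p = chi_square(t)
        out["cutoffs"][param] = cutoff
        out["two_by_two"][param] = {
            "table": [t.a, t.b, t.c, t.d],
            "test": two_by_two_test,
            "statistic": stat,
            "p": test_p,
            **diagnostics(t),
        }

    model = TmeLogisticModel().fit(X, y)
    scores = model.predict_proba(X)[:, 1]
    roc = roc_auc(scores, y)
    out["coefficients"] = {
        "intercept": float(model.intercept_[0]),
        **{p: float(c) for p, c in zip(parameters, model.coef_[0])},
    }
    out["converged"] = model.converged_
    out["separated"] = model.separated_
    out["auc"] = roc.auc
    return out


def endpoint_report(patients: Sequence[PatientRecord]) -> dict:
    """Trial endpoint summary: ORR/DCR/PFS24 with exact CIs, KM PFS/OS,
    and exact operating characteristics of both two-stage designs."""
    bors = [p.bor for p in patients]
    rates = response_rates(bors)
    n_eval = rates["n_evaluable"]
    n_resp = rates["counts"]["CR"] + rates["counts"]["PR"]
    n_ctrl = n_resp + rates["counts"]["SD"]
    orr_ci = clopper_pearson(n_resp, n_eval, level=0.975, sided="lower_one")
    dcr_ci = clopper_pearson(n_ctrl, n_eval, level=0.95, sided="two")
    pfs24 = pfs24_classify(patients)
    n24 = pfs24["benefit"] + pfs24["no_benefit"]
    pfs24_ci = clopper_pearson(pfs24["benefit"], n24, level=0.975, sided="lower_one")

    km_pfs = km_estimate(
        [p.pfs_months for p in patients], [p.pfs_event for p in patients],
        landmark=WEEKS24_MONTHS,
    )
    km_os = km_estimate(
        [p.os_months for p in patients], [p.os_event for p in patients],
        landmark=ONE_YEAR_MONTHS,
    )

    def _oc(design: TwoStageDesign) -> dict:
        null = simon_oc(design, design.p0)
        alt = simon_oc(design, design.p1)
        return {
            "design": asdict(design),
            "attained_alpha": null.prob_promising,
            "attained_beta": 1.0 - alt.prob_promising,
            "prob_early_stop_null": null.prob_early_stop,
            "expected_n_null": null.expected_n,
        }

    return {
        "n_patients": len(patients),
        "n_evaluable": n_eval,
        "bor_counts": rates["counts"],
        "orr_pct": rates["orr"],
        "orr_lower_97_5_one_sided_pct": 100 * orr_ci[0],
        "dcr_pct": rates["dcr"],
        "dcr_ci_95_pct": [100 * dcr_ci[0], 100 * dcr_ci[1]],
        "pfs24_counts": pfs24,
        "pfs24_rate_pct": 100.0 * pfs24["benefit"] / n24,
        "pfs24_lower_97_5_one_sided_pct": 100 * pfs24_ci[0],
        "median_pfs_months": km_pfs.median,
        "pfs24_km_rate": km_pfs.landmark_rate,
        "median_os_months": km_os.median,
        "os_1yr_km_rate": km_os.landmark_rate,
        "simon_orr": _oc(ORR_DESIGN),
        "simon_pfs24": _oc(PFS24_DESIGN),
    }


def _genomics_report(profiles, groups) -> dict:
    scan = gene_benefit_scan(profiles, groups)
    tmb_cmp = group_compare_tmb(profiles, groups)
    msi = {p.patient_id: msi_classify(p.msisensor) for p in profiles}
    sigs = {
        p.patient_id: signature_labels(p.exposures)
        for p in profiles
        if p.exposures and any(v > 0 for v in p.exposures.values())
    }
    n_msih = sum(1 for v in msi.values() if v == "MSI-H")
    n_dmmr_dom = sum(1 for s in sigs.values() if s["dominant_class"] == "dMMR")
    return {
        "gene_scan": scan,
        "tmb": tmb_cmp,
        "msi_h_fraction": n_msih / len(msi) if msi else math.nan,
        "dominant_dmmr_fraction": n_dmmr_dom / len(sigs) if sigs else math.nan,
    }


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle.

    With ``simulate: true`` in the config the cohort is generated (and its
    file set written out); otherwise ``cells_dir``, ``manifest``,
    ``outcomes``, ``mutations`` and ``exposures`` paths are read. Returns
    the report dict that is also written as JSON.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.get("simulate", True):
        params = SimulationParams(seed=int(cfg.get("seed", 0)),
                                  **cfg.get("simulation", {}))
        logger.info("simulating cohort under master seed %d", params.seed)
        cohort = simulate_cohort(params)
        tables, patients, profiles = cohort.tables, cohort.patients, cohort.profiles
        manifest = cohort.manifest
        cells_dir = out / "cells"
        cells_dir.mkdir(exist_ok=True)
        for t in tables:
            write_cell_table(t, cells_dir / f"{t.specimen_id}.csv")
        manifest.to_csv(out / "manifest.csv", index=False)
        write_outcomes(patients, out / "outcomes.csv")
        write_mutation_profiles(profiles, out / "mutations.csv", out / "exposures.csv")
    else:
        for key in ("cells_dir", "manifest", "outcomes", "mutations"):
            if key not in cfg:
                raise FileNotFoundError(f"config lacks required input path {key!r}")
        aliases = cfg.get("column_aliases") or {}
        cells_dir = Path(cfg["cells_dir"])
        tables = [read_cell_table(p, aliases=aliases)
                  for p in sorted(cells_dir.glob("*.csv"))]
        manifest = read_manifest(cfg["manifest"])
        patients = read_outcomes(cfg["outcomes"])
        by_patient: dict[str, list[str]] = {}
        for _, row in manifest.iterrows():
            by_patient.setdefault(row["patient_id"], []).append(row["specimen_id"])
        for p in patients:
            p.specimens = by_patient.get(p.patient_id, [])
        profiles = read_mutation_profiles(cfg["mutations"], cfg.get("exposures"))

    findings = validate_cohort(tables, patients)
    for f in findings:
        logger.log(logging.ERROR if f.severity == "fatal" else logging.WARNING, f.message)
    if has_fatal(findings):
        raise ValueError("cohort validation failed: "
                         + "; ".join(f.message for f in findings if f.severity == "fatal"))

    radius = float(cfg.get("radius_um", 50.0))
    compartment = cfg.get("compartment", "tumor")
    matrix = biomarker_matrix(tables, manifest, compartment=compartment, radius_um=radius)
    matrix.to_csv(out / "biomarkers.csv")

    groups = benefit_groups(patients)
    assoc = association_table(matrix, groups)
    assoc.to_csv(out / "associations.csv")
    corr, leaf_order = correlation_cluster(matrix.drop(columns=["cd8_foxp3_ratio"],
                                                       errors="ignore"))
    corr.to_csv(out / "correlation.csv")

    model = fit_benefit_model(matrix, groups,
                              two_by_two_test=cfg.get("two_by_two_test", "chisq"))
    endpoints = endpoint_report(patients)
    gen = _genomics_report(profiles, groups)
    gen["gene_scan"].to_csv(out / "gene_associations.csv")

    report = {
        "seed": cfg.get("seed"),
        "radius_um": radius,
        "n_specimens": len(tables),
        "validation_warnings": [f.message for f in findings],
        "correlation_leaf_order": leaf_order,
        "benefit_model": model,
        "endpoints": endpoints,
        "genomics": {k: v for k, v in gen.items() if k != "gene_scan"},
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_text_report(report, assoc, out / "report.txt")
    return report


def _write_text_report(report: dict, assoc: pd.DataFrame, path: Path) -> None:
    ep = report["endpoints"]
    lines = [
        "tmetrial run summary",
        "====================",
        f"seed: {report['seed']}   specimens: {report['n_specimens']}   "
        f"radius: {report['radius_um']:g} um",
        "",
        f"ORR  {ep['orr_pct']:.1f}%  (97.5% one-sided lower bound "
        f"{ep['orr_lower_97_5_one_sided_pct']:.1f}%)",
        f"DCR  {ep['dcr_pct']:.1f}%  (95% CI {ep['dcr_ci_95_pct'][0]:.1f}–"
        f"{ep['dcr_ci_95_pct'][1]:.1f}%)",
        f"PFS24 rate  {ep['pfs24_rate_pct']:.1f}%  (lower bound "
        f"{ep['pfs24_lower_97_5_one_sided_pct']:.1f}%)",
        f"median PFS  {ep['median_pfs_months']:.1f} mo" if not math.isnan(
            ep["median_pfs_months"]) else "median PFS  not reached",
        f"median OS   {ep['median_os_months']:.1f} mo" if not math.isnan(
            ep["median_os_months"]) else "median OS   not reached",
        "",
        f"Simon ORR design attained alpha {ep['simon_orr']['attained_alpha']:.4f}, "
        f"beta {ep['simon_orr']['attained_beta']:.4f}",
        "",
        f"benefit model (n={report['benefit_model']['n']}): AUC "
        f"{report['benefit_model']['auc']:.3f}",
        "",
        "parameter associations (Mann–Whitney, two-sided, unadjusted):",
        assoc.round(4).to_string(),
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
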