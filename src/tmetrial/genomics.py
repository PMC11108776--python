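"""Downstream genomic summaries and benefit-group comparisons.

Consumes precomputed per-patient profiles (mutation calls, nonsynonymous
counts, MSIsensor scores, signature exposure vectors) — variant calling,
signature inference and MSI scoring happen upstream. Provides tumor
mutational burden, MSI classification, dominant/secondary signature
labels, a per-gene benefit association scan (Fisher) and group TMB
comparison (Mann–Whitney).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import MSI_H_THRESHOLD
from .biomarker_stats import TwoByTwo, fisher_exact, mann_whitney
from .data_model import MutationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "tmb",
    "msi_classify",
    "signature_labels",
    "DEFAULT_SIGNATURE_CLASSES",
    "gene_benefit_scan",
    "group_compare_tmb",
]

#: Signature-id to biological-class map. dMMR signatures are 6/15/20;
#: 1 and 5 are taken as the aging-related set; 10 is POLE.
DEFAULT_SIGNATURE_CLASSES: dict[str, str] = {
    "6": "dMMR", "15": "dMMR", "20": "dMMR",
    "1": "aging", "5": "aging",
    "10": "POLE",
}


def tmb(n_nonsyn: int, capture_mb: float) -> float:
    """Tumor mutational burden: nonsynonymous mutations per captured Mb."""
    if not capture_mb > 0:
        raise ValueError("capture size must be positive")
    if n_nonsyn < 0:
        raise ValueError("mutation count must be non-negative")
    return n_nonsyn / capture_mb


def msi_classify(score: float, threshold: float = MSI_H_THRESHOLD) -> str:
    """MSI-H iff the MSIsensor score is at or above the threshold."""
    if not math.isfinite(score):
        raise ValueError("MSIsensor score must be finite")
    return "MSI-H" if score >= threshold else "MSS"


def _sig_key(sig: str) -> str:
    """Normalize a signature id ('SBS6', 'Signature.6', 6) to its number."""
    s = str(sig).upper()
    for prefix in ("SBS", "SIGNATURE.", "SIGNATURE "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    return s.lstrip("0") or "0"


def _sig_sort_key(sig: str):
    key = _sig_key(sig)
    return (0, int(key)) if key.isdigit() else (1, key)


def signature_labels(
    exposures: Mapping[str, float],
    classes: Mapping[str, str] | None = None,
) -> dict:
    """Dominant and secondary mutational signatures plus the dominant class.

    Ties are broken toward the smaller signature id (flagged in the
    result); the output is independent of mapping insertion order.
    """
    if not exposures or all(v <= 0 for v in exposures.values()):
        raise ValueError("need at least one positive signature exposure")
    classes = DEFAULT_SIGNATURE_CLASSES if classes is None else classes
    items = sorted(exposures.items(), key=lambda kv: (-kv[1], _sig_sort_key(kv[0])))
    dominant, top = items[0]
    secondary = items[1][0] if len(items) > 1 and items[1][1] > 0 else None
    tie = len(items) > 1 and items[1][1] == top
    return {
        "dominant": dominant,
        "secondary": secondary,
        "dominant_class": classes.get(_sig_key(dominant), "other"),
        "tie": tie,
    }


@dataclass(frozen=True)
class GeneAssociation:
    gene: str
    n_benefit: int
    n_no_benefit: int
    freq_benefit: float      # percent
    freq_no_benefit: float   # percent
    fisher_p: float


def gene_benefit_scan(
    profiles: Sequence[MutationProfile],
    groups: Mapping[str, str] | Sequence[str],
) -> pd.DataFrame:
    """Per-gene mutation frequencies by benefit group with Fisher p-values.

    ``groups`` maps patient_id to "benefit"/"no_benefit" (or is a parallel
    sequence). Profiles lacking a gene are excluded pairwise for that gene
    with a logged count. No multiplicity adjustment is applied.
    """
    if not isinstance(groups, Mapping):
        groups = {p.patient_id: g for p, g in zip(profiles, groups)}
    labels = [groups[p.patient_id] for p in profiles]
    if "benefit" not in labels or "no_benefit" not in labels:
        raise ValueError("both benefit groups must be non-empty")
    genes = sorted({g for p in profiles for g in p.gene_flags})
    rows = []
    for gene in genes:
        a = b = c = d = 0
        n_missing = 0
        for p, lab in zip(profiles, labels):
            if gene not in p.gene_flags:
                n_missing += 1
                continue
            mutated = p.gene_flags[gene]
            if lab == "benefit":
                a, c = (a + 1, c) if mutated else (a, c + 1)
            else:
                b, d = (b + 1, d) if mutated else (b, d + 1)
        if n_missing:
            logger.info("gene %s: %d profiles without a call (excluded)", gene, n_missing)
        nb, nn = a + c, b + d
        rows.append(
            GeneAssociation(
                gene=gene,
                n_benefit=nb,
                n_no_benefit=nn,
                freq_benefit=100.0 * a / nb if nb else math.nan,
                freq_no_benefit=100.0 * b / nn if nn else math.nan,
                fisher_p=fisher_exact(TwoByTwo(a, b, c, d)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("gene")


def group_compare_tmb(
    profiles: Sequence[MutationProfile],
    groups: Mapping[str, str] | Sequence[str],
) -> dict:
    """Group TMB medians and the two-sided Mann–Whitney p-value."""
    if not isinstance(groups, Mapping):
        groups = {p.patient_id: g for p, g in zip(profiles, groups)}
    tmbs = {
        "benefit": [tmb(p.n_nonsyn, p.capture_mb) for p in profiles
                    if groups[p.patient_id] == "benefit"],
        "no_benefit": [tmb(p.n_nonsyn, p.capture_mb) for p in profiles
                       if groups[p.patient_id] == "no_benefit"],
    }
    if not tmbs["benefit"] or not tmbs["no_benefit"]:
        raise ValueError("both benefit groups must be non-empty")
    result = mann_whitney(tmbs["benefit"], tmbs["no_benefit"])
    return {
        "median_benefit": float(np.median(tmbs["benefit"])),
        "median_no_benefit": float(np.median(tmbs["no_benefit"])),
        "mann_whitney_p": result.pvalue,
        "u": result.u,
    }
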