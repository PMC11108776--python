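"""Trial endpoints and design statistics.

Best overall response from target-lesion sums (simplified RECIST 1.1
rules for target lesions only), response rates with exact Clopper–Pearson
binomial intervals, the 24-week progression-free classification,
Kaplan–Meier summaries, and exact operating characteristics of the Simon
two-stage design by binomial enumeration (no normal approximation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from ._constants import WEEKS24_MONTHS
from .data_model import PatientRecord, TwoStageDesign

__all__ = [
    "classify_bor",
    "response_rates",
    "clopper_pearson",
    "pfs24_classify",
    "KmSummary",
    "km_estimate",
    "SimonOC",
    "simon_oc",
    "apply_two_stage_rule",
]


def classify_bor(baseline_sum: float, followup_sums: Sequence[float]) -> str:
    """Best overall response from target-lesion diameter sums (mm).

    Simplified target-lesion rules: CR when a follow-up sum reaches 0; PR
    at a >=30% decrease from baseline; PD at a >=20% increase from the
    nadir that is also >=5 mm absolute. Assessment stops at the first
    qualifying progression; CR and PR achieved before progression take
    precedence (CR > PR), otherwise progression is the best response, and
    stable disease only when no progression occurred. No post-baseline
    assessment yields NE.
    """
    if baseline_sum < 0 or any(s < 0 for s in followup_sums):
        raise ValueError("lesion sums must be non-negative")
    if len(followup_sums) == 0:
        return "NE"
    if baseline_sum == 0:
        raise ValueError("baseline target-lesion sum must be positive")
    cr = pr = pd_seen = False
    nadir = baseline_sum
    for s in followup_sums:
        if s >= nadir * 1.2 and s - nadir >= 5.0:
            pd_seen = True
            break
        if s == 0:
            cr = True
        if baseline_sum - s >= 0.30 * baseline_sum:
            pr = True
        nadir = min(nadir, s)
    if cr:
        return "CR"
    if pr:
        return "PR"
    if pd_seen:
        return "PD"
    return "SD"


def response_rates(bors: Sequence[str]) -> dict:
    """ORR and DCR (percent) over efficacy-evaluable (non-NE) patients."""
    counts = {c: sum(1 for b in bors if b == c) for c in ("CR", "PR", "SD", "PD", "NE")}
    n_eval = len(bors) - counts["NE"]
    if n_eval == 0:
        raise ValueError("no evaluable patients")
    responders = counts["CR"] + counts["PR"]
    controlled = responders + counts["SD"]
    return {
        "n_evaluable": n_eval,
        "counts": counts,
        "orr": 100.0 * responders / n_eval,
        "dcr": 100.0 * controlled / n_eval,
    }


def clopper_pearson(
    x: int, n: int, level: float = 0.95, sided: str = "two"
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles, on [0, 1].

    ``sided``: "two" gives the equal-tailed two-sided interval;
    "lower_one" an interval (L, 1] whose lower bound holds with the full
    ``level``; "upper_one" the mirror image. The one-sided 97.5% lower
    bound coincides with the two-sided 95% lower bound.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if not (0 <= x <= n and n >= 1):
        raise ValueError("require 0 <= x <= n, n >= 1")
    if sided == "two":
        alpha = 1.0 - level
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lo, hi
    if sided == "lower_one":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(1 - level, x, n - x + 1))
        return lo, 1.0
    if sided == "upper_one":
        hi = 1.0 if x == n else float(stats.beta.ppf(level, x + 1, n - x))
        return 0.0, hi
    raise ValueError(f"unknown sided {sided!r}")


def pfs24_classify(patients: Sequence[PatientRecord]) -> dict:
    """Count 24-week clinical benefit.

    Benefit iff progression-free and alive at 24 weeks. Patients lost to
    follow-up or dying before the landmark count as events (no benefit) —
    including response-NE patients, who are excluded from ORR but not
    from this classification.
    """
    benefit = no_benefit = 0
    for p in patients:
        if p.pfs_months >= WEEKS24_MONTHS:
            benefit += 1
        else:
            # event before the landmark, or early loss to follow-up
            no_benefit += 1
    return {"benefit": benefit, "no_benefit": no_benefit}


@dataclass
class KmSummary:
    times: np.ndarray          # event/censor grid of the step function
    survival: np.ndarray       # S(t) on that grid
    median: float              # NaN when not reached
    median_ci: tuple[float, float]
    landmark_time: float | None = None
    landmark_rate: float | None = None
    landmark_ci: tuple[float, float] | None = None


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    landmark: float | None = None,
    level: float = 0.95,
) -> KmSummary:
    """Kaplan–Meier product-limit summary.

    Greenwood variance with log(-log) (exponential-Greenwood) confidence
    bands; the median is the smallest time where the estimate drops to
    0.5 or below, NaN ("not reached") when it never does.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter(alpha=1 - level)
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    if math.isinf(med):
        med = math.nan
        med_ci = (math.nan, math.nan)
    else:
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        med_ci = (lo if not math.isinf(lo) else math.nan,
                  hi if not math.isinf(hi) else math.nan)
    summary = KmSummary(grid, surv, med, med_ci)
    if landmark is not None:
        summary.landmark_time = landmark
        summary.landmark_rate = float(kmf.predict(landmark))
        ci_df = kmf.confidence_interval_
        at = ci_df.index.searchsorted(landmark, side="right") - 1
        at = max(at, 0)
        summary.landmark_ci = (
            float(ci_df.iloc[at, 0]),
            float(ci_df.iloc[at, 1]),
        )
    return summary


@dataclass(frozen=True)
class SimonOC:
    prob_promising: float
    prob_early_stop: float
    expected_n: float


def simon_oc(design: TwoStageDesign, p: float) -> SimonOC:
    """Exact operating characteristics of a Simon two-stage rule at a true
    response rate ``p``, by binomial enumeration over stage-1 outcomes."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    n1, r1, n, r = design.n1, design.r1, design.n, design.r
    n2 = n - n1
    prob_early = float(stats.binom.cdf(r1, n1, p))
    prob_promising = 0.0
    for s1 in range(r1 + 1, n1 + 1):
        need = r + 1 - s1
        tail = 1.0 if need <= 0 else float(stats.binom.sf(need - 1, n2, p))
        prob_promising += float(stats.binom.pmf(s1, n1, p)) * tail
    expected_n = n1 + (1.0 - prob_early) * n2
    return SimonOC(prob_promising, prob_early, expected_n)


def apply_two_stage_rule(design: TwoStageDesign, successes_stage1: int, successes_total: int) -> dict:
    """Apply the decision rule to observed counts."""
    cont = successes_stage1 >= design.r1 + 1
    promising = cont and successes_total >= design.r + 1
    return {"continue_to_stage2": cont, "promising": promising}
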