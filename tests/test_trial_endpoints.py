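import math

import numpy as np
import pytest

from tmetrial._constants import WEEKS24_MONTHS
from tmetrial.data_model import PatientRecord, TwoStageDesign
from tmetrial.pipeline import ORR_DESIGN
from tmetrial.synthetic import SimulationParams, simulate_outcomes
from tmetrial.trial_endpoints import (
    apply_two_stage_rule,
    classify_bor,
    clopper_pearson,
    km_estimate,
    pfs24_classify,
    response_rates,
    simon_oc,
)


class TestClassifyBor:
    @pytest.mark.parametrize(
        "baseline,followups,expected",
        [
            (100.0, [70.0], "PR"),            # -30% boundary is inclusive
            (100.0, [80.0, 97.0], "PD"),      # nadir 80: +21.25% and +17 mm
            (100.0, [], "NE"),                # no post-baseline assessment
            (100.0, [0.0], "CR"),
            (100.0, [85.0], "SD"),
            (100.0, [60.0, 95.0], "PR"),      # response before progression
            (100.0, [115.0], "SD"),           # +15% < 20%: not progression
            (20.0, [23.0], "SD"),             # +15%: below both PD thresholds
        ],
    )
    def test_target_lesion_rules(self, baseline, followups, expected):
        assert classify_bor(baseline, followups) == expected

    def test_negative_sum_rejected(self):
        with pytest.raises(ValueError):
            classify_bor(100.0, [-1.0])


class TestResponseRates:
    def test_printed_trial_counts(self):
        """7 CR + 13 PR + 5 SD + 9 PD among 34 evaluable (plus 1 NE)."""
        bors = ["CR"] * 7 + ["PR"] * 13 + ["SD"] * 5 + ["PD"] * 9 + ["NE"]
        rates = response_rates(bors)
        assert rates["n_evaluable"] == 34
        assert rates["orr"] == pytest.approx(58.8, abs=0.05)
        assert rates["dcr"] == pytest.approx(73.5, abs=0.05)

    def test_all_progressors(self):
        rates = response_rates(["PD"] * 5)
        assert rates["orr"] == 0.0 and rates["dcr"] == 0.0

    def test_all_ne_rejected(self):
        with pytest.raises(ValueError):
            response_rates(["NE", "NE"])


class TestClopperPearson:
    def test_orr_one_sided_lower_bound(self):
        lo, hi = clopper_pearson(20, 34, level=0.975, sided="lower_one")
        assert 100 * lo == pytest.approx(40.7, abs=0.05)
        assert hi == 1.0

    def test_dcr_two_sided_interval(self):
        lo, hi = clopper_pearson(25, 34, level=0.95, sided="two")
        assert 100 * lo == pytest.approx(55.6, abs=0.05)
        assert 100 * hi == pytest.approx(87.1, abs=0.05)

    def test_one_sided_975_equals_two_sided_95_lower(self):
        lo1, _ = clopper_pearson(12, 30, level=0.975, sided="lower_one")
        lo2, _ = clopper_pearson(12, 30, level=0.95, sided="two")
        assert lo1 == pytest.approx(lo2, abs=1e-12)

    def test_boundary_cases(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, level=1.5)


class TestPfs24Classify:
    def _patient(self, pfs, event, pfs24="not_evaluable"):
        return PatientRecord("p", bor="SD", pfs_months=pfs, pfs_event=event,
                             os_months=pfs + 1, os_event=False, pfs24=pfs24)

    def test_event_before_landmark_is_no_benefit(self):
        counts = pfs24_classify([self._patient(10 * 7 / 30.4375, True)])
        assert counts == {"benefit": 0, "no_benefit": 1}

    def test_censored_after_landmark_is_benefit(self):
        counts = pfs24_classify([self._patient(30 * 7 / 30.4375, False)])
        assert counts == {"benefit": 1, "no_benefit": 0}

    def test_early_loss_to_followup_counts_as_event(self):
        counts = pfs24_classify([self._patient(12 * 7 / 30.4375, False)])
        assert counts == {"benefit": 0, "no_benefit": 1}


class TestKmEstimate:
    def test_no_censoring_reduces_to_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(2)
        km = km_estimate(times, np.ones(40, dtype=bool))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([3.0, 5.0, 9.0], [False, False, False])
        assert np.all(km.survival == 1.0)
        assert math.isnan(km.median)

    def test_hand_product_limit_oracle(self):
        """Ten-subject worked example: the product-limit estimate computed
        by hand must match at every event time."""
        times = [1, 2, 2, 4, 5, 6, 7, 9, 11, 12]
        events = [1, 1, 1, 0, 1, 0, 1, 1, 0, 1]
        km = km_estimate(times, [bool(e) for e in events])
        # hand computation: S(t) = prod (1 - d_i / n_i) over event times <= t
        # t=1: n=10 d=1 -> 0.9 ; t=2: n=9 d=2 -> 0.9*7/9 = 0.7
        # t=5: n=6 d=1 -> 0.7*5/6 ; t=7: n=4 d=1 -> *3/4
        # t=9: n=3 d=1 -> *2/3 ; t=12: n=1 d=1 -> 0
        expected = {
            1.0: 0.9,
            2.0: 0.7,
            5.0: 0.7 * 5 / 6,
            7.0: 0.7 * 5 / 6 * 3 / 4,
            9.0: 0.7 * 5 / 6 * 3 / 4 * 2 / 3,
            12.0: 0.0,
        }
        lookup = dict(zip(km.times, km.survival))
        for t, s in expected.items():
            assert lookup[t] == pytest.approx(s, abs=1e-12)
        # S(5) = 0.583 > 0.5 but S(7) = 0.4375: the median is 7
        assert km.median == pytest.approx(7.0)

    def test_restricted_mean_identity_without_censoring(self):
        """With every subject evented at distinct times, the area under the
        step function up to the last event equals the sample mean."""
        times = np.array([1.0, 3.0, 4.0, 7.0, 10.0])
        km = km_estimate(times, np.ones(5, dtype=bool))
        grid = np.r_[0.0, np.sort(times)]
        surv = np.r_[1.0, [km.survival[km.times == t][0] for t in np.sort(times)]]
        area = float(np.sum(np.diff(grid) * surv[:-1]))
        assert area == pytest.approx(times.mean())
        assert km.survival[-1] == 0.0

    def test_landmark_rate_and_ci(self):
        times = [2.0, 8.0, 9.0, 12.0, 20.0, 30.0]
        km = km_estimate(times, [True] * 6, landmark=10.0)
        assert km.landmark_rate == pytest.approx(0.5)
        lo, hi = km.landmark_ci
        assert 0 <= lo < 0.5 < hi <= 1

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [True])


class TestSimonOc:
    def test_null_rate_limits(self):
        oc = simon_oc(ORR_DESIGN, 0.0)
        assert oc.prob_promising == 0.0
        assert oc.prob_early_stop == 1.0
        assert oc.expected_n == ORR_DESIGN.n1

    def test_certain_response_limit(self):
        oc = simon_oc(ORR_DESIGN, 1.0)
        assert oc.prob_promising == pytest.approx(1.0)
        assert oc.prob_early_stop == 0.0
        assert oc.expected_n == ORR_DESIGN.n

    def test_printed_error_rates_are_bounds(self):
        """The ORR rule's attained alpha and beta sit within the stated
        0.025 / 0.05 error rates."""
        assert simon_oc(ORR_DESIGN, ORR_DESIGN.p0).prob_promising <= 0.025
        assert 1 - simon_oc(ORR_DESIGN, ORR_DESIGN.p1).prob_promising <= 0.05

    def test_promising_probability_monotone_in_p(self):
        probs = [simon_oc(ORR_DESIGN, p).prob_promising for p in np.linspace(0, 1, 21)]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            TwoStageDesign(n1=10, r1=10, n=20, r=12, p0=0.1, p1=0.3)

    def test_decision_rule_application(self):
        assert apply_two_stage_rule(ORR_DESIGN, 1, 1) == {
            "continue_to_stage2": False, "promising": False}
        assert apply_two_stage_rule(ORR_DESIGN, 2, 6)["promising"]

    def test_monte_carlo_trial_agrees_with_enumeration(self, rng):
        """Simulated trials applying the decision rule declare 'promising'
        at the exactly enumerated frequency (within Monte-Carlo error)."""
        params = SimulationParams(seed=77)
        mix = ["benefit"] * 26 + ["no_benefit"] * 14  # 65% benefit archetype
        p_resp = sum(
            (params.bor_probs[a]["CR"] + params.bor_probs[a]["PR"]) for a in mix
        ) / len(mix)
        n_rep = 600
        promising = 0
        for rep in range(n_rep):
            records = simulate_outcomes(params, mix, seed=1000 + rep)
            responses = [r.bor in ("CR", "PR") for r in records]
            s1 = sum(responses[: ORR_DESIGN.n1])
            total = sum(responses)
            if apply_two_stage_rule(ORR_DESIGN, s1, total)["promising"]:
                promising += 1
        expected = simon_oc(ORR_DESIGN, p_resp).prob_promising
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert promising / n_rep == pytest.approx(expected, abs=4 * se + 1e-9)


class TestCoverage:
    def test_clopper_pearson_achieves_nominal_coverage(self, rng):
        """10,000 binomial replicates at n=34, p=0.6: the exact interval
        must cover at or above the nominal 95%."""
        n, p, level = 34, 0.6, 0.95
        draws = rng.binomial(n, p, size=10_000)
        intervals = {x: clopper_pearson(x, n, level=level) for x in range(n + 1)}
        covered = sum(
            1 for x in draws if intervals[x][0] <= p <= intervals[x][1]
        )
        assert covered / 10_000 >= level
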