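"""Performance statistics: Wilson CIs, exact incidence CIs, sweeps, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, gamma

from trecscreen.performance import (
    ConfusionTable,
    confusion_metrics,
    cutoff_sweep,
    exact_poisson_ci,
    percentile_equivalence,
    referral_rates,
    summarise_distribution,
    wilson_ci,
)
from trecscreen.published import referred_children


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,lower,upper",
        [
            (3, 73, 0.0141, 0.1140),
            (21, 73, 0.1965, 0.4001),
            (3, 3, 0.4385, 1.0000),
            (18, 53, 0.2269, 0.4741),
        ],
    )
    def test_reference_intervals(self, k, n, lower, upper):
        ci = wilson_ci(k, n)
        assert ci.estimate == pytest.approx(k / n)
        assert ci.lower == pytest.approx(lower, abs=5e-5)
        assert ci.upper == pytest.approx(upper, abs=5e-5)

    def test_no_successes_has_zero_lower_bound(self):
        ci = wilson_ci(0, 10)
        assert ci.lower == 0.0
        assert 0 < ci.upper < 1

    def test_symmetric_in_complement(self):
        a = wilson_ci(5, 20)
        b = wilson_ci(15, 20)
        assert a.lower == pytest.approx(1 - b.upper)
        assert a.upper == pytest.approx(1 - b.lower)

    @pytest.mark.parametrize("k,n", [(1, 0), (-1, 5), (6, 5)])
    def test_invalid_inputs(self, k, n):
        with pytest.raises(ValueError):
            wilson_ci(k, n)

    def test_exact_coverage_over_all_small_n(self):
        """Exact binomial coverage of the 95% Wilson interval at p = k/n over
        all (k, n <= 30): the known worst dip is at n = 4, p = 1/2, where
        only the two extreme outcomes miss p, giving 1 - 2*(1/2)^4 = 0.875
        exactly; average coverage sits near the nominal level."""
        covers = []
        worst = (1.0, None)
        for n in range(1, 31):
            intervals = [wilson_ci(j, n) for j in range(n + 1)]
            for k in range(n + 1):
                p = k / n
                cover = sum(
                    binom.pmf(j, n, p)
                    for j in range(n + 1)
                    if intervals[j].lower <= p <= intervals[j].upper
                )
                covers.append(cover)
                if cover < worst[0]:
                    worst = (cover, (k, n))
        assert worst[0] == pytest.approx(1 - 2 * 0.5**4, abs=1e-12)
        assert worst[1] == (2, 4)
        assert np.mean(covers) > 0.94


class TestExactPoisson:
    def test_reference_incidence(self):
        est = exact_poisson_ci(3, 115_216)
        assert est.one_in == pytest.approx(38_405.33, abs=0.01)
        # independent oracle: gamma-distribution quantiles for a Poisson count
        lo = gamma.ppf(0.025, a=3)
        hi = gamma.ppf(0.975, a=4)
        assert est.rate_lower == pytest.approx(lo / 115_216, rel=1e-9)
        assert est.rate_upper == pytest.approx(hi / 115_216, rel=1e-9)
        assert est.one_in_lower == pytest.approx(186_231, abs=1.0)
        assert est.one_in_upper == pytest.approx(13_141.6, abs=0.1)

    def test_zero_cases(self):
        est = exact_poisson_ci(0, 1000)
        assert est.rate == 0.0
        assert est.rate_lower == 0.0
        assert est.rate_upper > 0

    def test_identity_denominator(self):
        est = exact_poisson_ci(1, 1)
        assert est.rate == 1.0
        assert est.rate_lower < 1.0 < est.rate_upper

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_poisson_ci(-1, 10)
        with pytest.raises(ValueError):
            exact_poisson_ci(1, 0)


class TestConfusionMetrics:
    def test_scid_outcome_table(self):
        t = ConfusionTable("SCID", tp=3, fp=70, tn=115_704, fn=0)
        m = confusion_metrics(t)
        assert m["ppv"].estimate == pytest.approx(0.0411, abs=5e-5)
        assert m["sensitivity"].estimate == 1.0
        assert m["npv"].estimate == 1.0
        assert m["specificity"].estimate == pytest.approx(115_704 / 115_774)

    def test_lymphopenia_outcome_table(self):
        t = ConfusionTable("T_cell_lymphopenia", tp=21, fp=52, tn=115_704, fn=0)
        assert confusion_metrics(t)["ppv"].estimate == pytest.approx(0.2877, abs=5e-5)

    def test_perfect_test(self):
        m = confusion_metrics(ConfusionTable("x", tp=5, fp=0, tn=5, fn=0))
        assert all(m[k].estimate == 1.0 for k in m)

    def test_zero_denominator_is_undefined_not_error(self):
        m = confusion_metrics(ConfusionTable("x", tp=0, fp=0, tn=5, fn=0))
        assert m["ppv"] is None
        assert m["specificity"].estimate == 1.0


class TestReferralRates:
    def test_stratified_rates(self):
        children = pd.DataFrame(
            {
                "child_id": ["a", "b", "c", "d"],
                "ga_weeks": [40.0, 30.0, 39.0, np.nan],
                "is_newborn": [True, True, True, False],
            }
        )
        outcomes = pd.DataFrame(
            {
                "child_id": ["a", "b", "c", "d"],
                "status": ["positive_referral", "positive_referral", "negative", "negative"],
                "mean_trec": [0.5, 3.0, 80.0, 90.0],
            }
        )
        rates = referral_rates(outcomes, children).set_index("stratum")
        assert rates.loc["overall", "rate"] == 0.5
        assert rates.loc["term", "rate"] == 0.5
        assert rates.loc["preterm", "rate"] == 1.0
        assert rates.loc["non_newborn", "rate"] == 0.0
        assert rates.loc["undetectable_trec", "referred"] == 1

    def test_empty_stratum_rate_is_nan(self):
        children = pd.DataFrame(
            {"child_id": ["a"], "ga_weeks": [40.0], "is_newborn": [True]}
        )
        outcomes = pd.DataFrame(
            {"child_id": ["a"], "status": ["negative"], "mean_trec": [50.0]}
        )
        rates = referral_rates(outcomes, children).set_index("stratum")
        assert math.isnan(rates.loc["non_newborn", "rate"])


class TestCutoffSweep:
    def test_monotone_in_cutoff(self):
        table = referred_children()
        cutoffs = [0, 1, 2, 3, 4, 5, 6]
        sweep = cutoff_sweep(table, cutoffs)
        assert sweep["referred_total"].is_monotonic_increasing
        fp = sweep["referred_total"] - sweep["tp_lymphopenia"]
        assert fp.is_monotonic_increasing
        assert sweep["sensitivity_scid"].is_monotonic_increasing

    def test_zero_cutoff_keeps_scid_when_all_scid_trec_is_zero(self):
        """With every SCID case at 0 copies/well, even a cut-off of 0
        (inclusive) retains full SCID sensitivity."""
        table = pd.DataFrame(
            {
                "mean_trec": [0.0, 0.0, 0.0, 2.5, 5.0],
                "stratum": ["term", "term", "preterm", "term", "preterm"],
                "scid": [True, True, True, False, False],
                "lymphopenia": [True, True, True, True, False],
            }
        )
        sweep = cutoff_sweep(table, [0.0])
        assert sweep.loc[0, "sensitivity_scid"] == 1.0
        assert sweep.loc[0, "referred_total"] == 3


class TestPercentileEquivalence:
    def test_identical_distributions_return_cutoff(self, rng):
        x = rng.lognormal(np.log(10), 1.0, 50_000)  # ~18% mass below 4
        got = percentile_equivalence(x, x, 4.0)
        assert got == pytest.approx(4.0, rel=0.02)

    def test_equivariant_under_scaling(self, rng):
        term = rng.lognormal(np.log(10), 1.0, 100_000)
        preterm = 0.5 * rng.lognormal(np.log(10), 1.0, 100_000)
        got = percentile_equivalence(term, preterm, 4.0)
        assert got == pytest.approx(2.0, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percentile_equivalence([], [1.0], 4.0)


class TestSummarise:
    def test_constant_vector(self):
        s = summarise_distribution([5.0] * 10)
        assert s["median"] == s["q1"] == s["q3"] == 5.0
        assert s["share_above_cap"] == 0.0

    def test_share_above_display_cap(self):
        s = summarise_distribution([10.0, 500.0, 20.0, 30.0])
        assert s["share_above_cap"] == 0.25
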