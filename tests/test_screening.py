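"""Screening decision algorithm: triage, consensus, verdicts, programme run."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trecscreen.cohort import CohortConfig, Condition, simulate_cohort
from trecscreen.screening import (
    Action,
    ScreeningPolicy,
    SpotResult,
    Status,
    classify_initial,
    replicate_consensus,
    run_programme,
    screen_child,
)

POLICY = ScreeningPolicy()
EPOCH1 = date(2020, 3, 1)
EPOCH2 = date(2020, 5, 1)


class TestClassifyInitial:
    @pytest.mark.parametrize(
        "trec,actb,ok,when,expected",
        [
            (79, 5000, True, EPOCH1, Action.NEGATIVE),
            (12, 5000, True, EPOCH1, Action.REANALYSE_DUPLICATE),
            (12, 5000, True, EPOCH2, Action.NEGATIVE),  # cut-off lowered 15 -> 10
            (8, 5000, True, EPOCH2, Action.REANALYSE_DUPLICATE),
            (6, 5000, True, EPOCH1, Action.REANALYSE_QUADRUPLICATE),  # inclusive
            (0, 5000, True, EPOCH1, Action.REANALYSE_QUADRUPLICATE),
            (0, 500, True, EPOCH1, Action.QUALITY_FAIL),
            (0, 500, True, EPOCH2, Action.QUALITY_FAIL),
            (79, 5000, False, EPOCH1, Action.QUALITY_FAIL),
        ],
    )
    def test_triage(self, trec, actb, ok, when, expected):
        assert classify_initial(trec, actb, ok, POLICY, when) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_initial(-1, 5000, True, POLICY, EPOCH1)

    def test_policy_invariant_referral_below_reanalysis(self):
        with pytest.raises(ValueError):
            ScreeningPolicy(referral_cutoff=12, reanalysis_cutoff_epoch2=10)


class TestReplicateConsensus:
    @pytest.mark.parametrize(
        "trecs,mean,excluded",
        [
            ([0, 0, 0, 0], 0.0, []),        # uniform low: rule never fires
            ([8, 9, 10, 0.4], 9.0, [3]),    # one aberrant low replicate dropped
            ([5, 5, 5, 5], 5.0, []),
            ([4.0], 4.0, []),
        ],
    )
    def test_examples(self, trecs, mean, excluded):
        got_mean, got_excluded = replicate_consensus(trecs, POLICY)
        assert got_mean == pytest.approx(mean)
        assert got_excluded == excluded

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus([], POLICY)

    @given(
        st.lists(st.floats(min_value=0, max_value=50, allow_nan=False), min_size=1, max_size=6)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_chain(self, trecs):
        """Independent oracle: drop the k smallest values for the largest k
        whose every removal step satisfies the stated rule."""
        v = np.asarray(trecs, float)
        order = np.argsort(v, kind="stable")
        best_removed: list[int] = []
        removed: list[int] = []
        for step in range(len(v) - 1):
            kept = [i for i in range(len(v)) if i not in removed]
            sub = v[kept]
            lo, hi = sub.min(), sub.max()
            variable = lo < hi and hi > lo * POLICY.outlier_ratio
            i_min = order[step]
            rest_mean = v[[i for i in kept if i != i_min]].mean()
            if variable and rest_mean > POLICY.referral_cutoff:
                removed = removed + [int(i_min)]
                best_removed = removed
            else:
                break
        mean, excluded = replicate_consensus(trecs, POLICY)
        assert sorted(excluded) == sorted(best_removed)
        kept = [i for i in range(len(v)) if i not in best_removed]
        assert mean == pytest.approx(v[kept].mean())

    @given(
        st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=6)
    )
    @settings(max_examples=200, derandomize=True)
    def test_consensus_mean_dominates_plain_mean(self, trecs):
        mean, _ = replicate_consensus(trecs, POLICY)
        assert mean >= np.mean(trecs) - 1e-12


def _spots(trecs, actb=5000.0, krec=50.0, ok=True):
    return [SpotResult(t, krec, actb, ok) for t in trecs]


class TestScreenChild:
    def test_uniform_zero_trec_with_good_actb_is_referred(self):
        out = screen_child("c", _spots([0, 0, 0, 0]), POLICY, EPOCH1)
        assert out.status is Status.POSITIVE_REFERRAL
        assert out.mean_trec == 0.0

    def test_low_trec_with_failed_actb_is_inconclusive(self):
        out = screen_child("c", _spots([2, 3, 1, 2], actb=400.0), POLICY, EPOCH1)
        assert out.status is Status.INCONCLUSIVE_NEW_CARD

    def test_initial_above_reanalysis_cutoff_is_directly_negative(self):
        out = screen_child("c", _spots([20, 20, 20, 20]), POLICY, EPOCH1)
        assert out.status is Status.NEGATIVE
        assert out.replicates_used == 1

    def test_duplicate_band_uses_three_pcrs(self):
        out = screen_child("c", _spots([12, 11, 13, 10]), POLICY, EPOCH1)
        assert out.status is Status.NEGATIVE_AFTER_REANALYSIS
        assert out.replicates_used == 3

    def test_no_spots_is_inconclusive(self):
        out = screen_child("c", [], POLICY, EPOCH1)
        assert out.status is Status.INCONCLUSIVE_NEW_CARD

    @given(
        trecs=st.lists(
            st.floats(min_value=0, max_value=0.999, allow_nan=False),
            min_size=1, max_size=4,
        ),
        ratio=st.floats(min_value=1.5, max_value=100),
        epoch2=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_no_scid_escape(self, trecs, ratio, epoch2):
        """All-replicate TREC < 1 with ACTB >= 1000 is always referred,
        whatever the outlier-rule ratio and at both epoch cut-offs."""
        policy = ScreeningPolicy(outlier_ratio=ratio)
        when = EPOCH2 if epoch2 else EPOCH1
        out = screen_child("c", _spots(trecs), policy, when)
        assert out.status is Status.POSITIVE_REFERRAL

    def test_epoch_change_affects_workload_never_verdicts(self):
        """Sweeping initial TREC over 0..20: lowering the reanalysis cut-off
        changes only who gets reanalysed, never who is referred."""
        for trec in np.arange(0, 20.05, 0.1):
            spots = _spots([trec] * 4)
            out1 = screen_child("c", spots, POLICY, EPOCH1)
            out2 = screen_child("c", spots, POLICY, EPOCH2)
            assert (out1.status is Status.POSITIVE_REFERRAL) == (
                out2.status is Status.POSITIVE_REFERRAL
            ), trec


class TestRunProgramme:
    def test_healthy_term_cohort_rarely_referred(self, healthy_term_config):
        cohort = simulate_cohort(healthy_term_config)
        outcomes, log = run_programme(cohort, POLICY, seed=0)
        assert log["n_referred"] / log["n_children"] <= 0.005

    def test_every_child_gets_exactly_one_terminal_status(self, mixed_config):
        cohort = simulate_cohort(mixed_config)
        outcomes, _ = run_programme(cohort, POLICY, seed=0)
        assert len(outcomes) == cohort["child_id"].nunique()
        valid = {s.value for s in Status}
        assert set(outcomes["status"]) <= valid
        assert outcomes["child_id"].is_unique

    def test_scid_children_all_referred(self):
        cfg = CohortConfig(
            n_newborns=3, n_non_newborns=0,
            case_rates={Condition.SCID: 1.0}, tech_failure_rate=0.0, seed=4,
        )
        outcomes, log = run_programme(simulate_cohort(cfg), POLICY, seed=0)
        assert (outcomes["status"] == Status.POSITIVE_REFERRAL.value).all()
        assert log["n_referred"] == 3

    def test_programme_is_deterministic(self, mixed_config):
        cohort = simulate_cohort(mixed_config)
        out1, log1 = run_programme(cohort, POLICY, seed=9)
        out2, log2 = run_programme(cohort, POLICY, seed=9)
        pd.testing.assert_frame_equal(out1, out2)
        assert log1 == log2

    def test_referral_outcomes_respect_cutoff(self, mixed_config):
        cohort = simulate_cohort(mixed_config)
        outcomes, _ = run_programme(cohort, POLICY, seed=0)
        referred = outcomes[outcomes["status"] == Status.POSITIVE_REFERRAL.value]
        assert (referred["mean_trec"] <= POLICY.referral_cutoff + 1e-12).all()

    def test_inconclusive_children_resolve_to_negative_or_lost(self, mixed_config):
        cohort = simulate_cohort(mixed_config)
        outcomes, log = run_programme(cohort, POLICY, seed=0)
        assert log["n_inconclusive"] > 0
        n_lost = (outcomes["status"] == Status.LOST_TO_FOLLOWUP.value).sum()
        assert n_lost == log["n_lost_to_followup"] <= log["n_inconclusive"]
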