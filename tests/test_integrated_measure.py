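"""The rank-based integrated speed-accuracy score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from startrack.integrated_measure import (
    arm_summaries,
    integrated_measures,
    rank_with_midranks,
)
from startrack.trial_model import TrialRecord

from conftest import make_validity_trials


def brute_force_midranks(values):
    """Midranks by explicit enumeration: count of strictly smaller values
    plus half the tied group (including self)."""
    return [
        sum(1 for w in values if w < v) + (1 + sum(1 for w in values if w == v)) / 2
        for v in values
    ]


def brute_force_im(trials):
    n = len(trials)
    mr = (n + 1) / 2
    rt = brute_force_midranks([t.completion_time_s for t in trials])
    re = brute_force_midranks([t.error_count for t in trials])
    return [(a - mr) / mr + (b - mr) / mr for a, b in zip(rt, re)]


def vtrial(subject, cond, t, e):
    return TrialRecord(subject, "validity", cond, t, e)


class TestMidranks:
    def test_tie_example(self):
        assert list(rank_with_midranks([10, 20, 20, 30])) == [1, 2.5, 2.5, 4]

    def test_singleton(self):
        assert list(rank_with_midranks([5])) == [1]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank_with_midranks([])

    def test_rank_sum_80(self):
        values = np.random.default_rng(0).normal(size=80)
        assert rank_with_midranks(values).sum() == pytest.approx(3240)

    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=40)
    )
    def test_rank_sum_invariant_under_heavy_ties(self, values):
        n = len(values)
        ranks = rank_with_midranks(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranks.min() >= 1 and ranks.max() <= n
        assert list(ranks) == pytest.approx(brute_force_midranks(values))


class TestIntegratedMeasure:
    def test_two_trial_hand_example(self):
        scored = integrated_measures(
            [vtrial("a", "baseline", 100, 5), vtrial("b", "fatigue", 120, 9)]
        )
        assert (scored[0].rank_time, scored[0].rank_error) == (1, 1)
        assert (scored[1].rank_time, scored[1].rank_error) == (2, 2)
        assert scored[0].im == pytest.approx(-0.667, abs=5e-4)
        assert scored[1].im == pytest.approx(+0.667, abs=5e-4)

    def test_identical_trials_score_zero(self):
        scored = integrated_measures(
            [vtrial(f"s{i}", "baseline", 100, 5) for i in range(6)]
        )
        assert all(s.im == pytest.approx(0, abs=1e-12) for s in scored)

    def test_pooled_study_of_80(self):
        scored = integrated_measures(make_validity_trials(seed=1))
        assert len(scored) == 80
        assert np.mean([s.rank_time for s in scored]) == pytest.approx(40.5)
        assert np.mean([s.rank_error for s in scored]) == pytest.approx(40.5)

    def test_rejects_tiny_or_mixed_studies(self):
        with pytest.raises(ValueError):
            integrated_measures([vtrial("a", "baseline", 100, 5)])
        with pytest.raises(ValueError, match="phases"):
            integrated_measures(
                [
                    vtrial("a", "baseline", 100, 5),
                    TrialRecord("b", "retest", "day1", 120, 9),
                ]
            )

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_zero_sum_including_ties(self, data):
        n = data.draw(st.integers(min_value=2, max_value=30))
        times = data.draw(
            st.lists(
                st.sampled_from([50.0, 100.0, 100.0, 150.0, 200.0, 250.0]),
                min_size=n,
                max_size=n,
            )
        )
        errors = data.draw(
            st.lists(st.integers(min_value=0, max_value=3), min_size=n, max_size=n)
        )
        trials = [
            vtrial(f"s{i}", "baseline", t, e) for i, (t, e) in enumerate(zip(times, errors))
        ]
        scored = integrated_measures(trials)
        assert abs(sum(s.im for s in scored)) <= 1e-9
        assert [s.im for s in scored] == pytest.approx(brute_force_im(trials))

    def test_monotone_transform_invariance(self):
        trials = make_validity_trials(seed=2)
        base = [s.im for s in integrated_measures(trials)]
        # the transform must expand spacing so ms-rounded times stay distinct
        warped_times = [
            TrialRecord(t.subject_id, t.phase, t.condition,
                        t.completion_time_s ** 2, t.error_count)
            for t in trials
        ]
        assert [s.im for s in integrated_measures(warped_times)] == pytest.approx(base)
        warped_errors = [
            TrialRecord(t.subject_id, t.phase, t.condition,
                        t.completion_time_s, t.error_count ** 2 + 3 * t.error_count)
            for t in trials
        ]
        assert [s.im for s in integrated_measures(warped_errors)] == pytest.approx(base)

    def test_antisymmetry_of_reversed_performance(self):
        # tie-free study; reversing both channels negates every score
        times = [100.0, 111.0, 125.0, 140.0, 160.0]
        errors = [0, 2, 5, 9, 14]
        fwd = [vtrial(f"s{i}", "baseline", t, e) for i, (t, e) in enumerate(zip(times, errors))]
        rev = [
            vtrial(f"s{i}", "baseline", t, e)
            for i, (t, e) in enumerate(zip(sorted(times, reverse=True), sorted(errors, reverse=True)))
        ]
        fwd_im = [s.im for s in integrated_measures(fwd)]
        rev_im = [s.im for s in integrated_measures(rev)]
        assert rev_im == pytest.approx([-x for x in fwd_im])

    def test_brute_force_oracle_small_studies(self):
        rng = np.random.default_rng(11)
        for n in range(2, 7):
            for _ in range(20):
                trials = [
                    vtrial(
                        f"s{i}",
                        "baseline",
                        float(rng.choice([90, 100, 100, 110, 120])),
                        int(rng.integers(0, 3)),
                    )
                    for i in range(n)
                ]
                got = [s.im for s in integrated_measures(trials)]
                assert got == pytest.approx(brute_force_im(trials))

    def test_im_bounds(self):
        trials = make_validity_trials(seed=5)
        n = len(trials)
        bound = 2 * (n - 1) / (n + 1)
        for s in integrated_measures(trials):
            assert -bound - 1e-12 <= s.im <= bound + 1e-12


class TestArmSummaries:
    def test_single_trial_arms_have_undefined_sd(self):
        scored = integrated_measures(
            [vtrial("a", "baseline", 100, 5), vtrial("b", "fatigue", 120, 9)]
        )
        summaries = {a.condition: a for a in arm_summaries(scored)}
        assert summaries["baseline"].mean_im == pytest.approx(-0.667, abs=5e-4)
        assert summaries["fatigue"].mean_im == pytest.approx(+0.667, abs=5e-4)
        assert math.isnan(summaries["baseline"].sd_im)

    def test_identical_arm_scores(self):
        scored = integrated_measures(
            [vtrial(f"s{i}", "baseline", 100, 5) for i in range(5)]
        )
        (summary,) = arm_summaries(scored)
        assert summary.n == 5
        assert summary.mean_im == pytest.approx(0, abs=1e-12)
        assert summary.sd_im == pytest.approx(0, abs=1e-12)

    def test_null_generator_arm_means_center_on_zero(self):
        # under exchangeable conditions each arm's mean im averages to ~0
        rng = np.random.default_rng(0)
        grand = []
        for rep in range(200):
            trials = make_validity_trials(
                seed=int(rng.integers(2**31)),
                effect_fatigue=0.0,
                effect_stress=0.0,
                effect_combined=0.0,
            )
            grand.append([a.mean_im for a in arm_summaries(integrated_measures(trials))])
        assert np.abs(np.mean(grand, axis=0)).max() < 0.05
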