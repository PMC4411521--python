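"""Crossover construct-validity pipeline: matrix, Mauchly, RM-ANOVA, post-hocs."""

import numpy as np
import pandas as pd
import pytest

from startrack.integrated_measure import arm_summaries, integrated_measures
from startrack.trial_model import TrialRecord
from startrack.validity import (
    WithinSubjectMatrix,
    analyze_validity,
    bonferroni_posthoc,
    build_matrix,
    mauchly_test,
    rm_anova,
)

from conftest import make_validity_trials


def random_matrix(rng, n=20, k=4):
    return WithinSubjectMatrix(
        rng.normal(size=(n, k)),
        tuple(f"s{i:02d}" for i in range(n)),
        tuple("abcd"[:k]),
    )


def pingouin_long(m):
    df = pd.DataFrame(m.values, columns=list(m.conditions))
    df["subject"] = list(m.subjects)
    return df.melt(id_vars="subject", var_name="cond", value_name="y")


class TestBuildMatrix:
    def test_full_crossover(self):
        scored = integrated_measures(make_validity_trials(seed=1))
        m = build_matrix(scored)
        assert m.values.shape == (20, 4)
        assert m.conditions == ("baseline", "fatigue", "stress", "fatigue_stress")

    def test_missing_arm_names_subject_and_arm(self):
        scored = integrated_measures(make_validity_trials(seed=1))
        dropped = [
            s for s in scored
            if not (s.trial.subject_id == "S03" and s.trial.condition == "stress")
        ]
        with pytest.raises(ValueError) as exc:
            build_matrix(dropped)
        assert "S03" in str(exc.value) and "stress" in str(exc.value)

    def test_row_order_invariance(self):
        scored = integrated_measures(make_validity_trials(seed=2))
        m1 = build_matrix(scored)
        m2 = build_matrix(list(reversed(scored)))
        assert np.array_equal(m1.values, m2.values)
        assert m1.subjects == m2.subjects


class TestMauchly:
    def test_two_conditions_trivially_spherical(self):
        m = random_matrix(np.random.default_rng(0), n=10, k=2)
        W, chi2, df, p = mauchly_test(m)
        assert (W, df, p) == (1.0, 0, 1.0)

    def test_four_conditions_have_df_5(self):
        m = random_matrix(np.random.default_rng(1))
        _, _, df, _ = mauchly_test(m)
        assert df == 5

    def test_needs_more_subjects_than_conditions(self):
        with pytest.raises(ValueError, match="n > k"):
            mauchly_test(random_matrix(np.random.default_rng(2), n=4, k=4))

    def test_reference_implementation_oracle(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_matrix(rng)
            W, chi2, df, _ = mauchly_test(m)
            ref = pg.sphericity(pingouin_long(m), dv="y", within="cond", subject="subject")
            assert W == pytest.approx(ref.W, abs=1e-9)
            assert chi2 == pytest.approx(ref.chi2, abs=1e-9)
            assert df == ref.dof


class TestRmAnova:
    def test_subject_effect_absorption(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng)
        shifted = WithinSubjectMatrix(
            m.values + rng.normal(size=(20, 1)), m.subjects, m.conditions
        )
        F1, *_ = rm_anova(m)
        F2, *_ = rm_anova(shifted)
        assert F2 == pytest.approx(F1, abs=1e-9)

    def test_equal_condition_means_give_zero_f(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(12, 4))
        v = v - v.mean(axis=0, keepdims=True)  # force SS_conditions = 0
        m = WithinSubjectMatrix(v, tuple(f"s{i}" for i in range(12)), tuple("abcd"))
        F, df1, df2, p = rm_anova(m)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (3, 33)
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_error_variance(self):
        v = np.outer(np.arange(5.0), np.ones(4)) + np.arange(4.0)
        m = WithinSubjectMatrix(v, tuple("vwxyz"), tuple("abcd"))
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova(m)

    def test_reference_implementation_oracle(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        for _ in range(20):
            m = random_matrix(rng)
            F, df1, df2, p = rm_anova(m)
            aov = pg.rm_anova(
                pingouin_long(m), dv="y", within="cond", subject="subject", detailed=True
            )
            assert F == pytest.approx(float(aov.loc[0, "F"]), abs=1e-9)
            assert p == pytest.approx(float(aov.loc[0, "p_unc"]), abs=1e-9)
            assert (df1, df2) == (int(aov.loc[0, "DF"]), int(aov.loc[1, "DF"]))


class TestPosthoc:
    def test_six_comparisons_for_four_arms(self):
        m = random_matrix(np.random.default_rng(7))
        posthoc = bonferroni_posthoc(m)
        assert len(posthoc) == 6
        assert {frozenset(c.pair) for c in posthoc} == {
            frozenset(p) for p in
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        }

    def test_bonferroni_caps_at_one(self):
        m = random_matrix(np.random.default_rng(8))
        for c in bonferroni_posthoc(m):
            assert 0 <= c.p_bonferroni <= 1
            assert c.p_bonferroni == pytest.approx(min(1.0, c.p_uncorrected * 6))
        # similar columns => LSD p near 1 => corrected p exactly 1
        v = np.random.default_rng(9).normal(size=(15, 1)) + np.random.default_rng(10).normal(
            scale=0.01, size=(15, 4)
        )
        m2 = WithinSubjectMatrix(v, tuple(f"s{i}" for i in range(15)), tuple("abcd"))
        assert any(c.p_bonferroni == 1.0 for c in bonferroni_posthoc(m2))

    def test_ci_brackets_the_difference_and_adjustment_widens(self):
        m = random_matrix(np.random.default_rng(11))
        adjusted = bonferroni_posthoc(m, adjust_ci=True)
        plain = bonferroni_posthoc(m, adjust_ci=False)
        for a, u in zip(adjusted, plain):
            assert a.ci_low <= a.mean_difference <= a.ci_high
            assert a.ci_high - a.ci_low > u.ci_high - u.ci_low

    def test_differences_match_column_means_exactly(self):
        m = random_matrix(np.random.default_rng(12))
        means = m.values.mean(axis=0)
        for c in bonferroni_posthoc(m):
            i, j = m.conditions.index(c.pair[0]), m.conditions.index(c.pair[1])
            assert c.mean_difference == pytest.approx(means[i] - means[j], abs=1e-12)


class TestAnalyzeValidity:
    def test_full_pipeline_shapes(self):
        result = analyze_validity(make_validity_trials(seed=13))
        assert len(result.arms) == 4
        assert all(a.n == 20 for a in result.arms)
        assert len(result.posthoc) == 6
        assert result.mauchly_df == 5
        assert result.anova_df == (3, 57)
        assert set(result.shapiro_p) == {
            "baseline", "fatigue", "stress", "fatigue_stress"
        }

    def test_posthoc_consistent_with_arm_summaries(self):
        result = analyze_validity(make_validity_trials(seed=14))
        means = {a.condition: a.mean_im for a in result.arms}
        for c in result.posthoc:
            assert c.mean_difference == pytest.approx(
                means[c.pair[0]] - means[c.pair[1]], abs=1e-12
            )

    def test_baseline_minus_intervention_is_negative(self):
        result = analyze_validity(make_validity_trials(seed=15))
        for c in result.posthoc:
            if c.pair[0] == "baseline":
                assert c.mean_difference < 0

    def test_degenerate_identical_data_raise(self):
        trials = [
            TrialRecord(f"s{i}", "validity", cond, 100.0, 5)
            for i in range(8)
            for cond in ("baseline", "fatigue", "stress", "fatigue_stress")
        ]
        with pytest.raises(ValueError):
            analyze_validity(trials)

    def test_baseline_arm_lowest_in_effect_simulations(self):
        # positive intervention effects push every other arm above baseline
        lowest = 0
        for seed in range(100):
            result = analyze_validity(make_validity_trials(seed=seed))
            means = {a.condition: a.mean_im for a in result.arms}
            lowest += means["baseline"] == min(means.values())
        assert lowest >= 95

    def test_effect_recovery_majority_rejects(self):
        from startrack.validity import build_matrix, rm_anova

        rejections = 0
        for seed in range(50):
            scored = integrated_measures(make_validity_trials(seed=200 + seed))
            _, _, _, p = rm_anova(build_matrix(scored))
            rejections += p < 0.05
        assert rejections > 25
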