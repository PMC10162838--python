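"""Reliability and group-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srmkit.relstats import (
    GroupSummary,
    PairedSessions,
    bland_altman,
    fisher_z_compare,
    hhia_score,
    holm_adjust,
    jzs_bf10,
    outlier_reject_3sd,
    pearson_r,
    summary_ttest,
)


def hand_fisher_z(r1, n1, r2, n2):
    """Independent closed-form evaluation used as the oracle."""
    num = 0.5 * np.log((1 + r1) / (1 - r1)) - 0.5 * np.log((1 + r2) / (1 - r2))
    return num / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))


def hand_pooled_t(n1, m1, s1, n2, m2, s2):
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestPearson:
    def test_perfect_line_gives_r_one(self):
        pairs = PairedSessions([1, 2, 3, 4], [2, 4, 6, 8])
        r, p = pearson_r(pairs)
        assert r == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self, rng):
        pairs = PairedSessions(rng.standard_normal(2000), rng.standard_normal(2000))
        r, _ = pearson_r(pairs)
        assert abs(r) < 0.08

    def test_small_example_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        r, _ = pearson_r(PairedSessions(x, y))
        direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(PairedSessions([1, 1, 1, 1], [1, 2, 3, 4]))


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.6, 50, 0.6, 80)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_known_value(self):
        z, _ = fisher_z_compare(0.8, 100, 0.5, 100)
        assert z == pytest.approx(3.825, abs=0.005)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.8, 60, 0.5, 90)
        z2, p2 = fisher_z_compare(0.5, 90, 0.8, 60)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.5, 50)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(-0.99, 0.99), st.integers(5, 500),
        st.floats(-0.99, 0.99), st.integers(5, 500),
    )
    def test_agrees_with_hand_oracle(self, r1, n1, r2, n2):
        z, _ = fisher_z_compare(r1, n1, r2, n2)
        assert z == pytest.approx(hand_fisher_z(r1, n1, r2, n2), rel=1e-10, abs=1e-12)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_two_p_worked_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_adjusted_never_smaller_and_order_preserved(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBlandAltman:
    def test_identical_sessions_zero_bias_zero_cor(self):
        res = bland_altman(PairedSessions([1, 2, 3], [1, 2, 3]))
        assert res.bias == 0.0 and res.cor == 0.0

    def test_two_point_example(self):
        res = bland_altman(PairedSessions([0.0, 0.0], [1.0, -1.0]))
        assert res.bias == 0.0
        assert res.cor == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.limits == pytest.approx((-res.cor, res.cor))

    def test_constant_shift_moves_bias_only(self, rng):
        s1 = rng.standard_normal(50)
        s2 = s1 + rng.standard_normal(50) * 0.3
        base = bland_altman(PairedSessions(s1, s2))
        shifted = bland_altman(PairedSessions(s1, s2 + 1.7))
        assert shifted.bias == pytest.approx(base.bias + 1.7)
        assert shifted.cor == pytest.approx(base.cor)

    def test_doubling_differences_doubles_cor(self, rng):
        s1 = rng.standard_normal(40)
        d = rng.standard_normal(40)
        a = bland_altman(PairedSessions(s1, s1 + d))
        b = bland_altman(PairedSessions(s1, s1 + 2 * d))
        assert b.cor == pytest.approx(2 * a.cor)


class TestOutlierRejection:
    def test_mean_kept_boundary_rejected(self):
        kept, rejected = outlier_reject_3sd([0.0, 3.01], 0.0, 1.0)
        assert list(kept) == [0.0] and list(rejected) == [3.01]

    def test_normal_tail_fraction(self, rng):
        v = rng.standard_normal(100_000)
        _, rejected = outlier_reject_3sd(v, 0.0, 1.0)
        assert len(rejected) / len(v) == pytest.approx(0.0027, abs=0.001)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            outlier_reject_3sd([1.0], 0.0, 0.0)


class TestSummaryTTest:
    def test_colocated_group_comparison(self):
        t, df, p, diff, d = summary_ttest(
            GroupSummary(274, 2.28, 1.42), GroupSummary(96, 1.29, 1.16)
        )
        assert df == 368
        assert t == pytest.approx(6.14, abs=0.01)
        assert d == pytest.approx(0.72, abs=0.01)
        assert diff == pytest.approx(0.99, abs=1e-9)
        assert p < 0.001

    def test_separated_group_comparison(self):
        t, df, p, diff, _ = summary_ttest(
            GroupSummary(278, -3.86, 3.23), GroupSummary(96, -5.67, 2.68)
        )
        assert df == 372
        assert t == pytest.approx(4.94, abs=0.01)
        assert diff == pytest.approx(1.81, abs=1e-9)

    def test_identical_groups_zero(self):
        t, df, p, diff, d = summary_ttest(
            GroupSummary(20, 1.0, 0.5), GroupSummary(30, 1.0, 0.5)
        )
        assert t == 0.0 and d == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(2, 400), st.floats(-10, 10), st.floats(0.1, 5),
        st.integers(2, 400), st.floats(-10, 10), st.floats(0.1, 5),
    )
    def test_agrees_with_hand_oracle(self, n1, m1, s1, n2, m2, s2):
        t, df, _, _, _ = summary_ttest(GroupSummary(n1, m1, s1),
                                       GroupSummary(n2, m2, s2))
        assert t == pytest.approx(hand_pooled_t(n1, m1, s1, n2, m2, s2),
                                  rel=1e-10, abs=1e-12)
        assert df == n1 + n2 - 2


class TestBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert jzs_bf10(0.0, 50, 50) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf10(t, 60, 60) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))

    def test_order_of_magnitude_for_large_effect(self):
        bf = jzs_bf10(6.14, 274, 96)
        assert bf > 1e5  # decisive evidence, millions-scale


class TestHHIA:
    def test_all_no_is_zero(self):
        assert hhia_score(["no"] * 25) == 0

    def test_all_si_is_hundred(self):
        assert hhia_score(["sí"] * 25) == 100

    def test_five_sometimes_is_ten(self):
        assert hhia_score(["a veces"] * 5 + ["no"] * 20) == 10

    def test_numeric_answers_accepted(self):
        assert hhia_score([4, 2, 0] + [0] * 22) == 6

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            hhia_score(["no"] * 24)

    def test_unknown_answer_rejected(self):
        with pytest.raises(ValueError):
            hhia_score(["maybe"] + ["no"] * 24)


class TestEndToEndReliability:
    def test_cohort_reproduces_variance_ratio_prediction(self):
        """A simulated cohort's test-retest r matches the variance-ratio
        prediction r = between / (between + within + procedural)."""
        from srmkit.battery import BatteryConfig
        from srmkit.observers import CohortSpec, simulate_cohort

        config = BatteryConfig(tasks=("gap",), familiarization=())
        between, within = 0.6, 0.25

        # estimate procedural (track-estimation) variance with fixed observers
        null = CohortSpec(task_midpoints={"gap": np.log(2.0)}, between_sd=1e-9,
                          within_sd=0.0, spread=0.5)
        tab0 = simulate_cohort(config, null, 100, seed=21)
        proc_var = np.var(np.log(tab0.threshold), ddof=1)

        cohort = CohortSpec(task_midpoints={"gap": np.log(2.0)},
                            between_sd=between, within_sd=within, spread=0.5)
        tab = simulate_cohort(config, cohort, 300, seed=22)
        wide = tab[tab.task == "gap"].pivot(index="participant", columns="session",
                                            values="threshold")
        r = np.corrcoef(np.log(wide[1]), np.log(wide[2]))[0, 1]
        predicted = between**2 / (between**2 + within**2 + proc_var)
        # tolerance = sampling error of r at n=300 plus variance-estimate error
        assert r == pytest.approx(predicted, abs=0.15)
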