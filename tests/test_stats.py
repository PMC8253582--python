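"""Trajectory AUC, Kruskal-Wallis/Dunn and the power calculation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from qorscore.stats import (
    InsufficientTrajectoryError,
    Trajectory,
    dunn_posthoc,
    dunnett_posthoc,
    exact_kw_pvalue,
    group_trajectory_summary,
    kruskal_wallis,
    repeated_measures_anova,
    required_sample_size,
    trajectories_from_composites,
    trajectory_auc,
)


def traj(days, totals, animal="a1", group="naive"):
    return Trajectory(animal_id=animal, group=group, days=days, totals=totals)


class TestTrajectoryAUC:
    def test_constant_17_over_study_window_is_102(self):
        assert trajectory_auc(traj((0, 1, 2, 3, 6), (17,) * 5)) == pytest.approx(102)

    @pytest.mark.parametrize("c,span", [(18, 6), (5, 3), (0.5, 10)])
    def test_constant_closed_form(self, c, span):
        assert trajectory_auc(traj((0, span), (c, c))) == pytest.approx(c * span)

    def test_triangle(self):
        assert trajectory_auc(traj((0, 6), (18, 0))) == pytest.approx(54)

    def test_linearity_in_totals(self):
        t1 = traj((0, 1, 3, 6), (18, 6, 12, 16))
        t2 = traj((0, 1, 3, 6), (9, 3, 6, 8))
        assert trajectory_auc(t1) == pytest.approx(2 * trajectory_auc(t2))

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientTrajectoryError):
            trajectory_auc(traj((1,), (10,)))

    def test_baseline_prepended_when_missing(self):
        comp = pd.DataFrame(
            {"animal_id": ["a1"] * 2, "group": ["naive"] * 2,
             "day": [1, 2], "total": [16, 17]}
        )
        (t,) = trajectories_from_composites(comp)
        assert t.days[0] == 0 and t.totals[0] == 18.0


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [rng.integers(0, 6, size=rng.integers(4, 9))
                      for _ in range(rng.integers(2, 5))]
            if all((g == groups[0][0]).all() for g in groups):
                continue
            ours = kruskal_wallis(groups, exact_max_n=0)
            ref = sps.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=7), rng.normal(1.0, 1.0, size=6)
        h1 = kruskal_wallis([a, b], exact_max_n=0).statistic
        h2 = kruskal_wallis([np.exp(a), np.exp(b)], exact_max_n=0).statistic
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_exact_p_matches_enumeration_for_two_small_groups(self):
        # For two groups without ties, KW is equivalent to the two-sided
        # Mann-Whitney test, whose exact p scipy enumerates independently.
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.permutation(20)[:4].astype(float)
            b = rng.permutation(40)[:4].astype(float) + 0.5
            p_exact = exact_kw_pvalue([a, b])
            p_mwu = sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
            assert p_exact == pytest.approx(p_mwu, abs=1e-9)


class TestDunn:
    def test_identical_groups_adjusted_p_one(self):
        res = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]}, reference="a")
        assert res["b"]["p_adj"] == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "ref": rng.normal(0, 1, 30),
            "same": rng.normal(0, 1, 30),
            "shifted": rng.normal(5, 1, 30),
        }
        res = dunn_posthoc(groups, reference="ref")
        assert res["shifted"]["p_adj"] < 0.05
        assert res["same"]["p_adj"] > 0.2

    def test_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i * 0.5, 1, 10)
                  for i, k in enumerate("abcd")}
        res = dunn_posthoc(groups, reference="a")
        for v in res.values():
            assert v["p_adj"] >= v["p"] - 1e-12

    def test_missing_reference(self):
        with pytest.raises(KeyError):
            dunn_posthoc({"a": [1], "b": [2]}, reference="zzz")


class TestSummaries:
    def test_single_animal(self):
        comp = pd.DataFrame({"animal_id": ["a"] * 3, "group": ["naive"] * 3,
                             "day": [1, 2, 3], "total": [16, 17, 18]})
        s = group_trajectory_summary(comp)
        assert (s["median"] == s["q1"]).all() and (s["q1"] == s["q3"]).all()

    def test_median_interpolates(self):
        comp = pd.DataFrame({"animal_id": list("abcdef"),
                             "group": ["g"] * 6, "day": [1] * 6,
                             "total": [4, 5, 6, 7, 8, 9]})
        s = group_trajectory_summary(comp)
        assert s.loc[0, "median"] == pytest.approx(6.5)


class TestSampleSize:
    def test_huge_effect_needs_minimum_two(self):
        assert required_sample_size(100, 0.1, 0.9) == 2

    def test_halving_sd_quarters_n_approximately(self):
        n1 = required_sample_size(10, 8, 0.25, power=0.9)
        n2 = required_sample_size(10, 4, 0.25, power=0.9)
        assert n2 == pytest.approx(n1 / 4, abs=2)

    def test_design_assumption_recovers_stated_power_in_simulation(self):
        """The n returned for the composite design assumption actually
        delivers ~80% power in a Monte-Carlo two-sample t-test."""
        mean, sd, red = 17.0, 4.0, 0.5
        n = required_sample_size(mean, sd, red, power=0.8, alpha=0.05)
        rng = np.random.default_rng(5)
        hits = sum(
            sps.ttest_ind(rng.normal(mean, sd, n),
                          rng.normal(mean * (1 - red), sd, n)).pvalue < 0.05
            for _ in range(2000)
        )
        assert hits / 2000 == pytest.approx(0.8, abs=0.07)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            required_sample_size(17, 4, 1.5)
        with pytest.raises(ValueError):
            required_sample_size(17, 0, 0.5)


class TestParametricDelegates:
    def test_rm_anova_detects_day_effect(self, small_measurements):
        from qorscore.scoring import score_measurements

        _, comp = score_measurements(small_measurements)
        lap = comp[comp["group"] == "laparotomy"]
        table = repeated_measures_anova(lap)
        assert table.loc["day", "Pr > F"] < 0.05

    def test_dunnett_flags_separated_group(self):
        rng = np.random.default_rng(6)
        groups = {"control": rng.normal(0, 1, 10),
                  "near": rng.normal(0.1, 1, 10),
                  "far": rng.normal(4, 1, 10)}
        res = dunnett_posthoc(groups, reference="control")
        assert res["far"] < 0.01 and res["near"] > 0.2
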