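"""The inferential layer: theoretical choice dataset, Bonferroni families,
ANOVA/Tukey, survival comparison, HPG regressions and the full report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nutrail as nt
from nutrail.errors import (
    ConfigError,
    DegenerateModelError,
    InsufficientDataError,
)
from nutrail.synthetic_cages import CageConfig, child_seed, simulate_cage


class TestTheoreticalChoiceDataset:
    def test_halving_and_point_arithmetic(self, diets):
        table = nt.theoretical_choice_dataset(
            {"P20:L30": 60.0, "P30:L20": 90.0},
            {"FPT1": ("P20:L30", "P30:L20")}, diets)
        assert table.per_dish["FPT1"] == pytest.approx(
            {"P20:L30": 30.0, "P30:L20": 45.0})
        pt = table.points["FPT1"]
        assert (pt.protein_mg, pt.lipid_mg) == pytest.approx((19.5, 18.0))
        assert table.ratios["FPT1"] == pytest.approx(19.5 / 18.0)

    def test_degenerate_all_zero_means_flagged(self, diets):
        table = nt.theoretical_choice_dataset(
            {"P20:L30": 0.0, "P30:L20": 0.0},
            {"FPT1": ("P20:L30", "P30:L20")}, diets)
        assert table.ratios["FPT1"] is None

    def test_missing_diet_rejected(self, diets):
        with pytest.raises(nt.regulation_stats.LookupError_):
            nt.theoretical_choice_dataset(
                {"P20:L30": 60.0}, {"FPT1": ("P20:L30", "P30:L20")}, diets)

    @given(st.floats(0.1, 200.0), st.floats(0.1, 200.0), st.floats(1.1, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_no_choice_means(self, diets, m1, m2, scale):
        pairing = {"F": ("P20:L30", "P35:L15")}
        base = nt.theoretical_choice_dataset(
            {"P20:L30": m1, "P35:L15": m2}, pairing, diets)
        scaled = nt.theoretical_choice_dataset(
            {"P20:L30": m1 * scale, "P35:L15": m2 * scale}, pairing, diets)
        assert scaled.per_dish["F"]["P20:L30"] == pytest.approx(
            base.per_dish["F"]["P20:L30"] * scale)
        assert scaled.ratios["F"] == pytest.approx(base.ratios["F"])


class TestBonferroniTTests:
    def test_printed_sixfold_adjusted_alpha(self):
        tests = nt.bonferroni_t_tests([[1.0, 2.0], [1.0, 3.0]], 0.0, m=6)
        assert tests[0].adjusted_alpha == pytest.approx(0.05 / 6)
        assert round(tests[0].adjusted_alpha, 4) == 0.0083

    def test_closed_form_t_statistic(self):
        (res,) = nt.bonferroni_t_tests([[1.0, 2.0, 3.0]], 0.0)
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))
        assert res.df == 2
        assert res.raw_p == pytest.approx(0.0742, abs=2e-4)

    def test_degenerate_zero_variance_at_null_is_defined(self):
        (res,) = nt.bonferroni_t_tests([[5.0, 5.0, 5.0]], 5.0)
        assert res.statistic == 0.0
        assert res.raw_p == 1.0

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(InsufficientDataError):
            nt.bonferroni_t_tests([[1, 2]] * 4, 0.0, m=3)

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            nt.bonferroni_t_tests([[1.0]], 0.0)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_bonferroni_monotonicity(self, sample, m):
        (res,) = nt.bonferroni_t_tests([sample], 0.0, m=m)
        assert res.adjusted_p >= res.raw_p
        assert res.adjusted_alpha == pytest.approx(0.05 / m)


class TestAnovaTukey:
    def test_paper_design_degrees_of_freedom(self, rng):
        groups = {f"g{i}": rng.normal(50, 5, 12).tolist() for i in range(5)}
        res = nt.anova_tukey(groups)
        assert res.df == (4, 55)

    def test_hand_computed_f(self):
        res = nt.anova_tukey({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f_statistic == pytest.approx(3.0)
        assert res.df == (2, 6)

    def test_identical_groups_degenerate_f_zero(self):
        res = nt.anova_tukey({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert set(res.letters.values()) == {"a"}

    def test_undersized_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            nt.anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_f_invariant_to_shift_and_scale(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 8) for i in range(3)}
        base = nt.anova_tukey({k: v.tolist() for k, v in groups.items()})
        shifted = nt.anova_tukey({k: (v + 100).tolist()
                                  for k, v in groups.items()})
        scaled = nt.anova_tukey({k: (v * 3.5).tolist()
                                 for k, v in groups.items()})
        assert shifted.f_statistic == pytest.approx(base.f_statistic)
        assert scaled.f_statistic == pytest.approx(base.f_statistic)

    def test_letters_separate_distinct_groups(self, rng):
        groups = {"low": rng.normal(0, 1, 12).tolist(),
                  "mid": rng.normal(0.2, 1, 12).tolist(),
                  "high": rng.normal(30, 1, 12).tolist()}
        res = nt.anova_tukey(groups)
        assert set(res.letters["low"]) & set(res.letters["high"]) == set()


class TestCoxSurvival:
    @staticmethod
    def cages_with_hazard(hazard, treatment, n_cages, seed, diets):
        out = []
        for i in range(n_cages):
            cid = f"{treatment}-{i}"
            cfg = CageConfig(cage_id=cid, dishes=(diets["P30:L20"],),
                             daily_mortality_hazard=hazard,
                             seed=child_seed(seed, cid))
            out.append(simulate_cage(cfg, treatment=treatment))
        return out

    def test_no_events_rejected(self, diets):
        cages = self.cages_with_hazard(0.0, "a", 2, 0, diets) + \
            self.cages_with_hazard(0.0, "b", 2, 0, diets)
        with pytest.raises(DegenerateModelError):
            nt.cox_survival_compare(nt.survival_long_table(cages))

    def test_single_treatment_rejected(self, diets):
        cages = self.cages_with_hazard(0.05, "a", 3, 0, diets)
        with pytest.raises(InsufficientDataError):
            nt.cox_survival_compare(nt.survival_long_table(cages))

    def test_equal_hazards_pvalues_roughly_uniform(self, diets):
        """Under equal hazards the LRT p-value should be non-significant in
        about 1 - alpha of seeds (20 seeds here: at most 3 rejections)."""
        rejections = 0
        for seed in range(20):
            cages = (self.cages_with_hazard(0.0267, "a", 12, seed, diets)
                     + self.cages_with_hazard(0.0267, "b", 12, 1000 + seed,
                                              diets))
            res = nt.cox_survival_compare(nt.survival_long_table(cages))
            rejections += res.raw_p < 0.05
        assert rejections <= 3

    def test_doubled_hazard_detected(self, diets):
        hits = 0
        for seed in range(10):
            cages = (self.cages_with_hazard(0.03, "a", 12, seed, diets)
                     + self.cages_with_hazard(0.10, "b", 12, 2000 + seed,
                                              diets))
            res = nt.cox_survival_compare(nt.survival_long_table(cages))
            hits += res.raw_p < 0.05
        assert hits >= 8


class TestHpgRegression:
    def test_perfect_line(self):
        fit = nt.hpg_intake_regression({"a": (0, 60.0), "b": (10, 65.0),
                                        "c": (20, 70.0)})
        assert fit["slope"] == pytest.approx(0.5)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_constant_response_zero_r2(self):
        fit = nt.hpg_intake_regression({"a": (0, 60.0), "b": (10, 60.0),
                                        "c": (20, 60.0)})
        assert fit["r_squared"] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            nt.hpg_intake_regression({"a": (0, 60.0), "b": (10, 65.0)})


@pytest.fixture(scope="module")
def report(default_experiment, diets):
    nc = [c for c in default_experiment.cages
          if c.arm == "no_choice" and c.dish_day_records]
    ch = [c for c in default_experiment.cages if c.arm == "choice"]
    table = nt.experiment_intake_table(nc, diets)
    means = {nt.parse_diet_name(d): float(v) for d, v in
             table.groupby("treatment")["total_food_mg_per_bee"]
             .mean().items()}
    target = nt.infer_intake_target(means)
    return nt.run_choice_regulation_analysis(
        nc, ch, diets, nt.FOOD_PAIRINGS, target), target


class TestChoiceRegulationReport:
    def test_experimental_ratio_near_target_theoretical_off(self, report):
        rep, target = report
        for fpt in ("FPT1", "FPT2"):
            assert rep["experimental_mean_ratios"][fpt] == pytest.approx(
                target.ratio, abs=0.1)
            assert abs(rep["theoretical_mean_ratios"][fpt]
                       - target.ratio) > 0.15
        by_label = {t["label"]: t for t in rep["ratio_vs_target_tests"]}
        assert by_label["FPT2: theoretical ratio vs target"]["significant"]
        assert not by_label["FPT2: experimental ratio vs target"]["significant"]

    def test_family_sizes_match_study(self, report):
        rep, _ = report
        assert all(t["m"] == 3 for t in rep["preference_tests"])
        assert all(t["m"] == 6 for t in rep["theoretical_vs_experimental"])
        assert all(round(t["adjusted_alpha"], 4) == 0.0083
                   for t in rep["theoretical_vs_experimental"])

    def test_self_comparison_is_null(self, default_experiment, diets):
        """Halving the no-choice data and comparing it against itself must
        produce non-significant theoretical-vs-experimental ratio tests."""
        nc = [c for c in default_experiment.cages
              if c.arm == "no_choice" and c.dish_day_records]
        table = nt.experiment_intake_table(nc, diets)
        sub = table[table["treatment"] == "P30:L20"]
        half = (sub["total_food_mg_per_bee"] / 2).to_numpy()
        tests = nt.bonferroni_welch_tests([(half, half)], m=6)
        assert tests[0].raw_p == 1.0

    def test_mismatched_arms_rejected(self, default_experiment, diets):
        nc = [c for c in default_experiment.cages
              if c.treatment == "P30:L20"]
        ch = [c for c in default_experiment.cages if c.arm == "choice"]
        target = nt.IntakeTarget(point=nt.NutrientPoint(30, 20))
        with pytest.raises(ConfigError):
            nt.run_choice_regulation_analysis(nc, ch, diets,
                                              nt.FOOD_PAIRINGS, target)

    def test_report_is_json_serializable(self, report):
        import json
        json.dumps(report[0])
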