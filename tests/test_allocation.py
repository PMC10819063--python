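import numpy as np
import pandas as pd
import pytest

from pyrethrisk import (
    MetaboliteLink,
    attribute_measured_level,
    contribution_percentages,
    cross_metabolite_regression,
    molar_parent_equivalent,
    predict_levels,
    summarize_contributions,
)
from pyrethrisk.errors import ConfigurationError, UndefinedFitError


def _levels_frame(cells):
    """cells: list of (metabolite, diet, year, scenario, substance, concentration)."""
    rows = [
        {"metabolite_id": m, "diet_id": d, "year": y, "scenario": sc,
         "diet_label": f"{d} general", "age_class": "adult",
         "substance": s, "concentration": c}
        for m, d, y, sc, s, c in cells
    ]
    return pd.DataFrame(rows)


class TestContributionPercentages:
    def test_two_equal_contributors_split_evenly(self):
        levels = _levels_frame([
            ("CFMP", "D1", 2018, "middle", "lambda-cyhalothrin", 3.0),
            ("CFMP", "D1", 2018, "middle", "bifenthrin", 3.0),
        ])
        out = contribution_percentages(levels)
        assert np.allclose(out["percent"], [50.0, 50.0])

    def test_ratio_1_2_7(self):
        levels = _levels_frame([
            ("DCCA", "D1", 2018, "middle", "cyfluthrin", 1.0),
            ("DCCA", "D1", 2018, "middle", "permethrin", 2.0),
            ("DCCA", "D1", 2018, "middle", "cypermethrin", 7.0),
        ])
        out = contribution_percentages(levels).set_index("substance")["percent"]
        assert out["cyfluthrin"] == pytest.approx(10.0)
        assert out["permethrin"] == pytest.approx(20.0)
        assert out["cypermethrin"] == pytest.approx(70.0)

    def test_percents_sum_to_100_within_each_cell(self, registry, default_generation):
        _, records, _ = default_generation
        levels = predict_levels(records, registry)
        out = contribution_percentages(levels, registry)
        sums = out.groupby(["metabolite_id", "diet_id", "year", "scenario"])["percent"].sum()
        assert np.allclose(sums.dropna(), 100.0, atol=1e-9)

    def test_cfmp_splits_only_between_its_two_producers(self, registry, default_generation):
        _, records, _ = default_generation
        out = contribution_percentages(predict_levels(records, registry), registry)
        cfmp = out[out.metabolite_id == "CFMP"]
        assert set(cfmp["substance"]) == {"lambda-cyhalothrin", "bifenthrin"}

    def test_absent_substance_completed_as_zero(self, registry):
        levels = _levels_frame([
            ("DCCA", "D1", 2018, "middle", "cypermethrin", 4.0),
            ("DCCA", "D1", 2018, "middle", "permethrin", 4.0),
        ])
        out = contribution_percentages(levels, registry).set_index("substance")["percent"]
        assert out["cyfluthrin"] == 0.0
        assert out["cypermethrin"] == 50.0

    def test_zero_total_cell_is_missing(self):
        levels = _levels_frame([
            ("DCCA", "D1", 2018, "lower", "cypermethrin", 0.0),
            ("DCCA", "D1", 2018, "lower", "permethrin", 0.0),
        ])
        out = contribution_percentages(levels)
        assert out["percent"].isna().all()

    def test_negative_prediction_rejected(self):
        levels = _levels_frame([("DCCA", "D1", 2018, "middle", "permethrin", -1.0)])
        with pytest.raises(ConfigurationError):
            contribution_percentages(levels)

    def test_scale_invariance(self):
        cells = [
            ("DCCA", "D1", 2018, "middle", "cyfluthrin", 1.5),
            ("DCCA", "D1", 2018, "middle", "permethrin", 2.5),
            ("DCCA", "D1", 2018, "middle", "cypermethrin", 6.0),
        ]
        base = contribution_percentages(_levels_frame(cells))["percent"]
        scaled = contribution_percentages(
            _levels_frame([(m, d, y, s, sub, 7.3 * c) for m, d, y, s, sub, c in cells])
        )["percent"]
        assert np.allclose(base, scaled)


class TestSummaries:
    def test_constant_percent_collapses_all_ranks(self):
        levels = _levels_frame([
            ("CFMP", f"D{i}", 2018, "middle", s, c)
            for i in range(8)
            for s, c in [("lambda-cyhalothrin", 6.0), ("bifenthrin", 4.0)]
        ])
        summ = summarize_contributions(contribution_percentages(levels))
        cyh = summ[summ.substance == "lambda-cyhalothrin"].iloc[0]
        assert (cyh.p10, cyh.p50, cyh.p90) == (60.0, 60.0, 60.0)

    def test_median_uses_inclusive_linear_interpolation(self):
        levels = _levels_frame([
            ("CFMP", f"D{i}", 2018, "middle", "lambda-cyhalothrin", v)
            for i, v in enumerate([10, 20, 30, 40, 50])
        ] + [
            ("CFMP", f"D{i}", 2018, "middle", "bifenthrin", 100 - v)
            for i, v in enumerate([10, 20, 30, 40, 50])
        ])
        summ = summarize_contributions(contribution_percentages(levels))
        med = summ.set_index("substance")["p50"]
        assert med["lambda-cyhalothrin"] == pytest.approx(30.0)

    def test_two_contributor_percentile_complementarity(self, registry, default_generation):
        """For a two-source metabolite, p_q(A) + p_{100-q}(B) = 100 exactly."""
        _, records, _ = default_generation
        contrib = contribution_percentages(predict_levels(records, registry), registry)
        summ = summarize_contributions(contrib)
        cfmp = summ[summ.metabolite_id == "CFMP"].set_index("substance")
        for age in ("adult", "child"):
            for scenario in ("lower", "middle", "upper"):
                cell = summ[(summ.metabolite_id == "CFMP") & (summ.age_class == age)
                            & (summ.scenario == scenario)].set_index("substance")
                a, b = cell.loc["lambda-cyhalothrin"], cell.loc["bifenthrin"]
                assert a.p10 + b.p90 == pytest.approx(100.0, abs=1e-9)
                assert a.p50 + b.p50 == pytest.approx(100.0, abs=1e-9)
                assert a.p90 + b.p10 == pytest.approx(100.0, abs=1e-9)


class TestAttribution:
    def test_full_percent_is_identity(self):
        assert attribute_measured_level(12.3, 100.0) == 12.3

    def test_quarter_share(self):
        assert attribute_measured_level(10.0, 25.0) == pytest.approx(2.5)

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ConfigurationError):
            attribute_measured_level(10.0, 101.0)

    def test_partition_sums_back_to_measured_level(self):
        percents = [12.69, 66.31, 21.0]  # one cell's shares
        level = 3.7
        assert sum(attribute_measured_level(level, p) for p in percents) == pytest.approx(
            level * sum(percents) / 100
        )


class TestMolarEquivalents:
    def test_unit_conversion(self):
        link = MetaboliteLink(metabolite_id="DCCA", mw_metabolite=208.1, fue=1.0)
        assert molar_parent_equivalent(208.1, 100.0, link) == pytest.approx(1.0)

    def test_halved_fue_doubles_estimate(self):
        full = MetaboliteLink(metabolite_id="3PBA", mw_metabolite=214.2, fue=0.18)
        half = MetaboliteLink(metabolite_id="3PBA", mw_metabolite=214.2, fue=0.09)
        assert molar_parent_equivalent(5.0, 40.0, half) == pytest.approx(
            2 * molar_parent_equivalent(5.0, 40.0, full)
        )


class TestCrossMetaboliteRegression:
    def test_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = cross_metabolite_regression(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_on_hand_points(self):
        x = np.array([0.5, 1.1, 1.9, 3.2, 4.0])
        y = np.array([0.2, 0.9, 1.5, 2.2, 3.1])
        # explicit normal equations for simple OLS
        slope_ne = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept_ne = y.mean() - slope_ne * x.mean()
        fit = cross_metabolite_regression(x, y)
        assert fit.slope == pytest.approx(slope_ne, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept_ne, rel=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(UndefinedFitError):
            cross_metabolite_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(UndefinedFitError):
            cross_metabolite_regression([1.0, 2.0], [1.0, 2.0])

    def test_misspecified_fue_produces_one_fifth_slope_noise_free(self, registry):
        """3-PBA generated at Fue 0.45 but analysed at 0.09 biases estimates 5x."""
        from pyrethrisk.studies import run_fue_misspecification_study

        result = run_fue_misspecification_study(
            n_groups=12, seed=7, noise_cv=0.0,
            generator_overrides={"sigma_diet_shared": 0.0, "sigma_diet_substance": 0.0},
        )
        assert result["slope"] == pytest.approx(0.2, rel=1e-9)
        assert result["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert result["r_squared"] > 1 - 1e-12
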