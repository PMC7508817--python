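"""Unit and property tests for the nutrient mass-balance core."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floatload.budget import (
    LOAD_FACTOR,
    ConcentrationSample,
    PlantNutrientPool,
    RiverLoad,
    TraitStudyRecord,
    TraitSynthesis,
    VegArea,
    aggregate_concentration,
    annual_load,
    compound_envelope,
    compute_budget_table,
    monte_carlo_sink_interval,
    plant_nutrient_pool,
    sensitivity_mean_vs_median,
    sink_fraction,
    synthesize_traits,
)


def _records(trait, values):
    return [TraitStudyRecord(f"s{i}", trait, v) for i, v in enumerate(values)]


def _samples(tp_values, tn=100.0):
    return [
        ConcentrationSample("x", date(2018, 3 + 0 * i, 1 + i), tp, tn)
        for i, tp in enumerate(tp_values)
    ]


class TestSynthesizeTraits:
    def test_closed_form_mean_and_se(self):
        syn = synthesize_traits(_records("biomass_per_area", [1.0, 2.0, 3.0]))
        s = syn["biomass_per_area"]
        assert s.mean == pytest.approx(2.0)
        assert s.se == pytest.approx(1.0 / math.sqrt(3))  # sd 1, n 3
        assert s.n_studies == 3

    def test_identical_values_have_zero_se(self):
        s = synthesize_traits(_records("n_content", [0.02] * 5))["n_content"]
        assert s.mean == pytest.approx(0.02)
        assert s.se == 0.0

    def test_matches_spreadsheet_style_recomputation(self):
        # 15 lognormal draws; oracle is a plain-Python mean and sd/sqrt(n)
        rng = np.random.default_rng(42)
        values = list(2.0 * np.exp(rng.normal(0, 0.3, 15)))
        s = synthesize_traits(_records("biomass_per_area", values))["biomass_per_area"]
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.se == pytest.approx(sd / math.sqrt(n), rel=1e-12)

    def test_empty_errors_and_single_study_flagged(self):
        with pytest.raises(ValueError):
            synthesize_traits([])
        with pytest.warns(UserWarning):
            s = synthesize_traits(_records("p_content", [0.005]))["p_content"]
        assert s.single_study and s.se == 0.0

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            TraitStudyRecord("s", "p_content", 1.5)  # content fraction must be < 1
        with pytest.raises(ValueError):
            TraitStudyRecord("s", "biomass_per_area", -1.0)


class TestPlantNutrientPool:
    def test_reproduces_per_area_phosphorus_density(self, traits):
        # 5.5 km^2 at 9.67 g P per m^2 -> 53.2 Mg bound phosphorus
        pool = plant_nutrient_pool(
            VegArea("kafue", 5.5), traits["biomass_per_area"], traits["p_content"]
        )
        assert pool.nutrient == "P"
        assert pool.mass_Mg == pytest.approx(53.2, abs=0.05)

    def test_reproduces_per_area_nitrogen_density(self, traits):
        pool = plant_nutrient_pool(
            VegArea("kafue", 5.5), traits["biomass_per_area"], traits["n_content"]
        )
        assert pool.mass_Mg == pytest.approx(263.0, abs=0.05)

    def test_small_reach_pool(self, traits):
        pool = plant_nutrient_pool(
            VegArea("maramba", 0.087), traits["biomass_per_area"], traits["p_content"]
        )
        assert pool.mass_Mg == pytest.approx(0.84, abs=0.005)

    def test_zero_area_gives_zero_pool(self, traits):
        pool = plant_nutrient_pool(
            VegArea("lc", 0.0), traits["biomass_per_area"], traits["n_content"]
        )
        assert pool.mass_Mg == 0.0 == pool.env_low_Mg == pool.env_high_Mg

    def test_trait_mismatch_errors(self, traits):
        with pytest.raises(ValueError):
            plant_nutrient_pool(VegArea("x", 1.0), traits["p_content"], traits["p_content"])
        with pytest.raises(ValueError):
            plant_nutrient_pool(
                VegArea("x", 1.0), traits["biomass_per_area"], traits["biomass_per_area"]
            )


class TestCompoundEnvelope:
    def test_zero_relative_se_collapses_to_point(self):
        assert compound_envelope(10.0, 0.0, 0.0) == (10.0, 10.0)

    def test_calibrated_envelope_and_propagated_ci(self):
        # published Kafue pool 53.2 Mg P against a 227 Mg/yr load
        lo, hi = compound_envelope(53.2, 0.13, 0.076)
        assert lo == pytest.approx(42.8, abs=0.1)
        assert hi == pytest.approx(64.7, abs=0.1)
        pool = PlantNutrientPool("P", 53.2, lo, hi)
        load = annual_load(989.0, 227.0 / (989.0 * LOAD_FACTOR), "P")
        sink = sink_fraction(pool, load)
        assert sink.ci_low_pct == pytest.approx(15.9, abs=0.1)
        assert sink.ci_high_pct == pytest.approx(22.2, abs=0.1)

    def test_negative_relative_se_errors(self):
        with pytest.raises(ValueError):
            compound_envelope(1.0, -0.1, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        mass=st.floats(0.001, 1e4),
        a=st.floats(0.0, 0.99),
        b=st.floats(0.0, 0.99),
    )
    def test_envelope_always_brackets_point(self, mass, a, b):
        lo, hi = compound_envelope(mass, a, b)
        assert lo <= mass <= hi

    def test_width_monotone_in_each_relative_se(self):
        widths = [np.diff(compound_envelope(10.0, a, 0.05))[0] for a in (0.0, 0.1, 0.2)]
        assert widths == sorted(widths)
        widths = [np.diff(compound_envelope(10.0, 0.05, b))[0] for b in (0.0, 0.1, 0.2)]
        assert widths == sorted(widths)


class TestAggregateConcentration:
    def test_mean_vs_median_with_outlier(self):
        s = _samples([10.0, 20.0, 30.0, 1000.0])
        assert aggregate_concentration(s, "P", "mean") == pytest.approx(265.0)
        assert aggregate_concentration(s, "P", "median") == pytest.approx(25.0)

    def test_single_sample_identical_for_both_methods(self):
        s = _samples([12.5])
        for method in ("mean", "median"):
            assert aggregate_concentration(s, "P", method) == 12.5

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(7)
        values = list(rng.lognormal(2.0, 0.5, 9))
        values[3] *= 20  # inject an outlier
        s = _samples(values)
        srt = sorted(values)
        assert aggregate_concentration(s, "P", "mean") == pytest.approx(sum(values) / len(values))
        assert aggregate_concentration(s, "P", "median") == pytest.approx(srt[len(srt) // 2])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_concentration([], "P")


class TestAnnualLoad:
    @pytest.mark.parametrize(
        "q,conc,expected,decimals",
        [
            (11.4, 15.6, 5.6, 1),    # small urbanized tributary, phosphorus
            (989.0, 289.0, 9014.0, 0),  # large river, nitrogen
            (1.9, 718.0, 43.0, 0),   # small urban stream, nitrogen
            (1.9, 32.4, 1.9, 1),     # same stream, phosphorus
        ],
    )
    def test_reproduces_printed_loads(self, q, conc, expected, decimals):
        load = annual_load(q, conc)
        assert abs(load.load_Mg_yr - expected) <= 10.0**-decimals

    def test_zero_discharge_zero_load(self):
        assert annual_load(0.0, 99.0).load_Mg_yr == 0.0

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            annual_load(-1.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(q=st.floats(0.01, 1e4), c=st.floats(0.01, 1e4))
    def test_bilinearity(self, q, c):
        base = annual_load(q, c).load_Mg_yr
        assert annual_load(2 * q, c).load_Mg_yr == pytest.approx(2 * base, rel=1e-12)
        assert annual_load(q, 2 * c).load_Mg_yr == pytest.approx(2 * base, rel=1e-12)

    def test_riverload_consistency_invariant(self):
        with pytest.raises(ValueError):
            RiverLoad("P", load_Mg_yr=99.0, q_mean_m3s=1.0, conc_mean_ugL=1.0)


def _pool(nutrient, mass, rel=0.0):
    lo, hi = compound_envelope(mass, rel, rel)
    return PlantNutrientPool(nutrient, mass, lo, hi)


def _load(nutrient, load_Mg_yr, q=10.0):
    return annual_load(q, load_Mg_yr / (q * LOAD_FACTOR), nutrient)


class TestSinkFraction:
    @pytest.mark.parametrize(
        "mass,load,expected",
        [
            (53.2, 227.0, 19.0),   # large river P
            (263.0, 9014.0, 2.8),  # large river N
            (4.2, 43.0, 8.9),      # urban stream N
        ],
    )
    def test_reproduces_printed_sink_fractions(self, mass, load, expected):
        sink = sink_fraction(_pool("P", mass), _load("P", load))
        assert sink.fraction_pct == pytest.approx(expected, abs=0.06)

    def test_zero_pool_gives_zero_percent(self):
        sink = sink_fraction(_pool("N", 0.0), _load("N", 10.0))
        assert sink.fraction_pct == 0.0

    def test_nutrient_mismatch_and_degenerate_errors(self):
        with pytest.raises(ValueError):
            sink_fraction(_pool("N", 1.0), _load("P", 1.0))
        with pytest.raises(ValueError):
            sink_fraction(_pool("P", 0.0), _load("P", 0.0))

    @settings(deadline=None, derandomize=True)
    @given(
        mass=st.floats(0.001, 1e4),
        load=st.floats(0.001, 1e5),
        bump=st.floats(0.01, 10.0),
    )
    def test_monotone_in_pool_and_load_and_bounded(self, mass, load, bump):
        f = sink_fraction(_pool("P", mass), _load("P", load)).fraction_pct
        f_more_pool = sink_fraction(_pool("P", mass + bump), _load("P", load)).fraction_pct
        f_more_load = sink_fraction(_pool("P", mass), _load("P", load + bump)).fraction_pct
        assert 0 <= f <= 100
        assert f_more_pool > f > f_more_load

    @settings(deadline=None, derandomize=True)
    @given(mass=st.floats(0.001, 1e4), load=st.floats(0.001, 1e5))
    def test_plant_and_water_shares_sum_to_100(self, mass, load):
        plant = sink_fraction(_pool("P", mass), _load("P", load)).fraction_pct
        water = 100.0 * load / (mass + load)
        assert plant + water == pytest.approx(100.0, abs=1e-9)


class TestSensitivityMeanVsMedian:
    def test_zero_for_constant_and_symmetric_series(self):
        pool = _pool("P", 5.0)
        assert sensitivity_mean_vs_median(_samples([20.0] * 4), pool, 5.0) == 0.0
        # symmetric set: mean == median
        assert sensitivity_mean_vs_median(_samples([10.0, 20.0, 30.0]), pool, 5.0) == 0.0

    def test_equals_brute_force_recomputation(self):
        values = [10.0, 14.0, 18.0, 220.0]  # one strong outlier
        pool = _pool("P", 5.0)
        q = 5.0
        delta = sensitivity_mean_vs_median(_samples(values), pool, q)
        # independent recomputation from first principles
        mean_c = sum(values) / 4
        med_c = (sorted(values)[1] + sorted(values)[2]) / 2
        f = lambda c: 100 * 5.0 / (5.0 + q * c * LOAD_FACTOR)
        assert delta == pytest.approx(f(mean_c) - f(med_c), rel=1e-12)
        assert delta < 0  # outlier inflates the mean load, deflating plant share


class TestMonteCarloCrossCheck:
    def test_simulation_agrees_with_analytic_envelope(self, traits):
        veg = VegArea("kafue", 5.5)
        pool = plant_nutrient_pool(veg, traits["biomass_per_area"], traits["p_content"])
        load = annual_load(989.0, 7.3, "P")
        mc_lo, mc_hi = monte_carlo_sink_interval(
            veg, traits["biomass_per_area"], traits["p_content"], load, seed=11
        )
        sink = sink_fraction(pool, load)
        assert mc_lo == pytest.approx(sink.ci_low_pct, abs=1.0)
        assert mc_hi == pytest.approx(sink.ci_high_pct, abs=1.0)


class TestBudgetTable:
    def test_demo_budget_reproduces_headline_numbers(self, demo, traits):
        table = compute_budget_table(demo["sites"], demo["concentrations"], traits)
        t = table.set_index(["site", "nutrient"])
        assert t.loc[("Kafue", "P"), "pool_Mg"] == pytest.approx(53.2, abs=0.05)
        assert t.loc[("Kafue", "N"), "load_Mg_yr"] == pytest.approx(9014, abs=1)
        assert t.loc[("Maramba", "P"), "sink_pct"] == pytest.approx(30.2, abs=0.1)
        # site with no floating vegetation: zero plant sink for both nutrients
        assert (t.loc["Little Chongwe", "sink_pct"] == 0).all()

    def test_median_aggregation_is_explicit_not_silent(self, demo, traits):
        import pandas as pd

        conc = demo["concentrations"].copy()
        base = conc[conc.site == "Kafue"]
        # three Kafue samples, one an outlier: mean pulled up, median stable
        conc = pd.concat(
            [conc, base.assign(tp_ugL=7.3), base.assign(tp_ugL=100.0, tn_ugL=1000.0)],
            ignore_index=True,
        )
        mean_t = compute_budget_table(demo["sites"], conc, traits, "mean")
        med_t = compute_budget_table(demo["sites"], conc, traits, "median")
        k_mean = mean_t.query("site == 'Kafue' and nutrient == 'P'")["load_Mg_yr"].iloc[0]
        k_med = med_t.query("site == 'Kafue' and nutrient == 'P'")["load_Mg_yr"].iloc[0]
        assert k_mean > k_med
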