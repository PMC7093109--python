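import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from smokemort.attribution import (
    AttributionError,
    ClampedSirWarning,
    CoverageError,
    InvalidReferenceError,
    MissingDenominatorError,
    ReferenceRates,
    ReferenceRateTable,
    attributable_deaths_lung,
    attribute_all,
    halve_excess_rr,
    population_af,
    smoking_impact_ratio,
)
from smokemort.riskmath import AgeBand, RelativeRiskEntry, attributable_fraction
from smokemort.synthetic import simulate_vital_stats

from conftest import make_cohort_config, microsim_oracle

REFS = ReferenceRates(
    never_rate_population=0.0001, smoker_rate_study=0.002, never_rate_study=0.0001
)


class TestSmokingImpactRatio:
    def test_never_smoker_population(self):
        assert smoking_impact_ratio(REFS.never_rate_population, REFS) == 0.0

    def test_all_smoker_population(self):
        assert smoking_impact_ratio(REFS.smoker_rate_study, REFS) == pytest.approx(1.0)

    def test_recovers_synthetic_prevalence(self):
        sim = simulate_vital_stats(make_cohort_config(p_current=0.30))
        refs = sim.reference_rates()
        stratum = sim.config.strata[0]
        lung = sim.mortality[sim.mortality["cause"] == "lung_cancer"].iloc[0]
        observed_rate = lung["deaths"] / lung["population"]
        ref = refs.get(stratum.sex, stratum.age_band)
        assert smoking_impact_ratio(observed_rate, ref) == pytest.approx(0.30, rel=1e-12)

    def test_clamping_flags(self):
        with pytest.warns(ClampedSirWarning):
            assert smoking_impact_ratio(0.0, REFS) == 0.0
        with pytest.warns(ClampedSirWarning):
            assert smoking_impact_ratio(0.5, REFS) == 1.0

    def test_invalid_reference(self):
        with pytest.raises(InvalidReferenceError):
            ReferenceRates(0.0001, 0.0001, 0.0002)


class TestHalveExcessRr:
    @pytest.mark.parametrize("rr,expected", [(1.0, 1.0), (3.0, 2.0), (21.0, 11.0)])
    def test_values(self, rr, expected):
        assert halve_excess_rr(rr) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            halve_excess_rr(0.0)


class TestPopulationAf:
    def test_zero_prevalence(self):
        assert population_af(0.0, 3.0) == 0.0

    def test_reduces_to_exposed_fraction(self):
        assert population_af(1.0, 3.0) == pytest.approx(attributable_fraction(3.0))

    def test_half_smokers_microsim(self, oracle):
        deaths, attributable = oracle(10_000, 0.5, {"x": 0.001}, {"x": 3.0})
        assert population_af(0.5, 3.0) == pytest.approx(
            attributable["x"] / deaths["x"], rel=1e-12
        )
        assert population_af(0.5, 3.0) == pytest.approx(0.5)

    def test_domain(self):
        with pytest.raises(ValueError):
            population_af(1.5, 3.0)
        with pytest.raises(ValueError):
            population_af(0.5, 0.0)


class TestAttributableDeathsLung:
    def test_zero_never_rate(self):
        refs = ReferenceRates(0.0, 0.002, 0.0001)
        assert attributable_deaths_lung(120.0, refs, None) == (120.0, False)

    def test_exact_never_expectation(self):
        attrib, floored = attributable_deaths_lung(10.0, REFS, 100_000)
        assert attrib == 0.0 and not floored

    def test_floor_flag(self):
        attrib, floored = attributable_deaths_lung(5.0, REFS, 100_000)
        assert attrib == 0.0 and floored

    def test_missing_population(self):
        with pytest.raises(MissingDenominatorError):
            attributable_deaths_lung(100.0, REFS, None)


def toy_mortality():
    return pd.DataFrame(
        [
            {
                "country": "X", "sex": "male", "age_lo": 35.0, "age_hi": 70.0,
                "cause": "lung_cancer", "year": 2000, "deaths": 100.0, "population": 100_000.0,
            },
            {
                "country": "X", "sex": "male", "age_lo": 35.0, "age_hi": 70.0,
                "cause": "coronary_heart_disease", "year": 2000, "deaths": 300.0,
                "population": 100_000.0,
            },
        ]
    )


def toy_inputs():
    # never-expected lung deaths = 10; sir = (100/1e5 - 1e-4)/(1e-3 - 1e-4) = 1.0
    refs = ReferenceRateTable()
    refs.add("male", AgeBand(35, 70), ReferenceRates(0.0001, 0.001, 0.0001))
    rrs = [RelativeRiskEntry("coronary_heart_disease", "male", AgeBand(35, 70), 3.0)]
    return rrs, refs


class TestAttributeAll:
    def test_toy_hand_arithmetic(self):
        rrs, refs = toy_inputs()
        result = attribute_all(toy_mortality(), rrs, refs, halve_non_lung=False)
        by_cause = result.table.set_index("cause")["attributable_deaths"]
        assert by_cause["lung_cancer"] == pytest.approx(90.0)
        assert by_cause["coronary_heart_disease"] == pytest.approx(200.0)

    def test_rr_one_gives_zero_everywhere(self):
        mort = toy_mortality()
        refs = ReferenceRateTable()
        # population rate equals never rate -> sir 0, and rr 1 -> paf 0
        refs.add("male", AgeBand(35, 70), ReferenceRates(0.001, 0.002, 0.001))
        rrs = [RelativeRiskEntry("coronary_heart_disease", "male", AgeBand(35, 70), 1.0)]
        result = attribute_all(mort, rrs, refs, halve_non_lung=False)
        assert (result.table["attributable_deaths"] == 0.0).all()

    def test_matches_generator_ground_truth(self, noiseless_sim):
        sim = noiseless_sim
        result = attribute_all(
            sim.mortality, sim.rr_entries(), sim.reference_rates(), halve_non_lung=False
        )
        merged = result.table.merge(
            sim.ground_truth, on=["country", "sex", "age_lo", "age_hi", "cause"]
        )
        assert len(merged) == len(sim.ground_truth)
        np.testing.assert_allclose(
            merged["attributable_deaths"], merged["true_attributable"], rtol=1e-9
        )

    def test_matches_microsimulation_oracle(self):
        config = make_cohort_config(population=100_000, p_current=0.25)
        sim = simulate_vital_stats(config)
        result = attribute_all(
            sim.mortality, sim.rr_entries(), sim.reference_rates(), halve_non_lung=False
        )
        deaths, attributable = microsim_oracle(
            100_000, 0.25, dict(config.baseline_never_rates), dict(config.rr_current)
        )
        got = result.table.set_index("cause")["attributable_deaths"]
        for cause, expected in attributable.items():
            assert got[cause] == pytest.approx(expected, rel=1e-9)

    def test_sir_one_consistency_with_attributable_fraction(self):
        rrs, refs = toy_inputs()
        result = attribute_all(toy_mortality(), rrs, refs, halve_non_lung=False)
        chd = result.table[result.table["cause"] == "coronary_heart_disease"].iloc[0]
        assert chd["sir"] == pytest.approx(1.0)
        assert chd["attributable_deaths"] == pytest.approx(
            chd["deaths"] * attributable_fraction(3.0), rel=1e-12
        )

    def test_halving_is_conservative(self, noiseless_sim):
        sim = noiseless_sim
        halved = attribute_all(
            sim.mortality, sim.rr_entries(), sim.reference_rates(), halve_non_lung=True
        )
        full = attribute_all(
            sim.mortality, sim.rr_entries(), sim.reference_rates(), halve_non_lung=False
        )
        non_lung = halved.table["cause"] != "lung_cancer"
        assert (
            halved.table.loc[non_lung, "attributable_deaths"].to_numpy()
            <= full.table.loc[non_lung, "attributable_deaths"].to_numpy() + 1e-12
        ).all()
        assert halved.table.loc[non_lung, "halved_rr"].all()
        assert (halved.total_attributable <= full.total_attributable)

    def test_bounded_by_observed_deaths(self, noiseless_sim):
        result = attribute_all(
            noiseless_sim.mortality,
            noiseless_sim.rr_entries(),
            noiseless_sim.reference_rates(),
        )
        t = result.table
        assert (t["attributable_deaths"] >= 0).all()
        assert (t["attributable_deaths"] <= t["deaths"] + 1e-9).all()

    def test_coverage_error_lists_missing(self):
        mort = toy_mortality()
        refs = ReferenceRateTable()  # empty: missing refs and rr
        with pytest.raises(CoverageError) as exc:
            attribute_all(mort, [], refs)
        msg = str(exc.value)
        assert "reference rates" in msg and "coronary_heart_disease" in msg

    def test_missing_population_is_an_error(self):
        mort = toy_mortality().drop(columns=["population"])
        rrs, refs = toy_inputs()
        with pytest.raises((MissingDenominatorError, AttributionError)):
            attribute_all(mort, rrs, refs)


class TestParameterRecovery:
    def test_sir_within_three_se_coverage(self):
        """Poisson replicates: recovered SIR within 3 SE of truth >= 99% of the time."""
        rng = np.random.default_rng(20240101)
        population = 500_000
        never_rate, rr = 0.0005, 20.0
        p_true = 0.3
        expected_rate = never_rate * (1.0 + p_true * (rr - 1.0))
        expected_deaths = population * expected_rate  # >> 500
        refs = ReferenceRates(never_rate, never_rate * rr, never_rate)
        draws = rng.poisson(expected_deaths, size=1000)
        denom = refs.smoker_rate_study - refs.never_rate_study
        se = np.sqrt(expected_deaths) / population / denom
        hits = 0
        for d in draws:
            sir = smoking_impact_ratio(d / population, refs)
            hits += abs(sir - p_true) <= 3 * se
        assert hits / 1000 >= 0.99
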