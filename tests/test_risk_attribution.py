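import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sanburden.panel_io import MortalityPanel, PopulationPanel, RRRecord, SanitationShares
from sanburden.risk_attribution import (
    BurdenPanel,
    age_standardized_rate,
    attributable_deaths,
    compute_paf_table,
    mean_relative_risk,
    paf_combined,
    paf_single,
)
from sanburden.schema import DEFAULT_AGE_SCHEMA, StandardPopulation


class TestMeanRelativeRisk:
    @pytest.mark.parametrize("p,rr,expected", [
        (0.0, 7.0, 1.0), (1.0, 2.0, 2.0), (0.5, 3.0, 2.0),
    ])
    def test_linear_interpolation_between_one_and_rr(self, p, rr, expected):
        assert mean_relative_risk(p, rr) == pytest.approx(expected)

    def test_out_of_range_prevalence_rejected(self):
        with pytest.raises(ValueError):
            mean_relative_risk(1.2, 2.0)


class TestPAFSingle:
    @pytest.mark.parametrize("p,rr,expected", [
        (1.0, 2.0, 0.5), (0.0, 10.0, 0.0), (0.5, 3.0, 0.5),
    ])
    def test_closed_form_cases(self, p, rr, expected):
        assert paf_single(p, rr) == pytest.approx(expected)

    def test_protective_rr_rejected_unless_clamped(self):
        with pytest.raises(ValueError):
            paf_single(0.5, 0.8)
        assert paf_single(0.5, 0.8, clamp_protective=True) == 0.0
        with pytest.raises(ValueError):
            paf_single(0.5, -1.0, clamp_protective=True)

    @given(st.floats(0, 1), st.floats(1, 50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, p, rr):
        assert 0.0 <= paf_single(p, rr) < 1.0

    @given(st.floats(0.01, 0.99), st.floats(1.01, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_increasing_in_prevalence_and_rr(self, p, rr):
        assert paf_single(p + 0.01, rr) > paf_single(p, rr)
        assert paf_single(p, rr + 0.5) > paf_single(p, rr)


class TestPAFCombined:
    @pytest.mark.parametrize("pafs,expected", [
        ([0.5, 0.5], 0.75), ([0.3], 0.3), ([0.2, 0.3, 0.5], 0.72),
    ])
    def test_multiplicative_combination(self, pafs, expected):
        assert paf_combined(pafs) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 0.99), min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_commutative_and_dominates_max(self, pafs):
        combined = paf_combined(pafs)
        assert combined == pytest.approx(paf_combined(list(reversed(pafs))))
        assert combined >= max(pafs) - 1e-12

    def test_invalid_fractions_rejected(self):
        for bad in ([1.0], [-0.1]):
            with pytest.raises(ValueError):
                paf_combined(bad)


def _shares(sewer=0.2, improved=0.4, unimproved=0.4):
    return SanitationShares(pd.DataFrame(
        [{"country": "AAA", "year": 2000, "sewer": sewer, "improved": improved,
          "unimproved": unimproved}]))


class TestComputePAFTable:
    def test_single_active_factor_matches_closed_form(self):
        rr = [RRRecord("unimproved", "diarrhea", 2.5, 2.5, 2.5)]
        table = compute_paf_table(_shares(), rr)
        assert table.data["paf"].iloc[0] == pytest.approx(0.6 / 1.6)

    def test_unit_relative_risks_give_zero_paf(self):
        rr = [RRRecord("unimproved", "diarrhea", 1.0, 1.0, 1.0),
              RRRecord("improved", "diarrhea", 1.0, 1.0, 1.0)]
        table = compute_paf_table(_shares(), rr)
        assert (table.data["paf"] == 0.0).all()

    def test_two_factors_combine_multiplicatively(self):
        rr = [RRRecord("unimproved", "diarrhea", 2.5, 2.5, 2.5),
              RRRecord("improved", "diarrhea", 1.3, 1.3, 1.3)]
        table = compute_paf_table(_shares(), rr)
        paf_u = paf_single(0.4, 2.5)
        paf_i = paf_single(0.4, 1.3)
        expected = 1.0 - (1.0 - paf_u) * (1.0 - paf_i)
        assert table.data["paf"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_record_for_category_missing_from_shares_rejected(self):
        shares = _shares()
        # a shares panel that somehow lost its 'improved' column (bypassing
        # the container validation) must be caught by the attribution step
        cut = SanitationShares.__new__(SanitationShares)
        cut.data = shares.data.drop(columns=["improved"])
        rec = RRRecord("improved", "diarrhea", 2.0, 2.0, 2.0)
        with pytest.raises(ValueError, match="improved"):
            compute_paf_table(cut, [rec])


def _population(countries=("AAA",), years=(2000,), total=1_000_000, rural=1.0,
                shares=(0.1, 0.2, 0.45, 0.15, 0.1)):
    rows = []
    for c in countries:
        for y in years:
            row = {"country": c, "year": y, "total_population": total,
                   "rural_share": rural}
            for band, s in zip(DEFAULT_AGE_SCHEMA, shares):
                row["share_" + band.label] = s
            rows.append(row)
    return PopulationPanel(pd.DataFrame(rows))


def _mortality(rates: dict[str, float], country="AAA", year=2000):
    return MortalityPanel(pd.DataFrame(
        [{"country": country, "year": year, "age_band": band, "cause": "diarrhea",
          "rate": r, "rate_lo": r, "rate_hi": r} for band, r in rates.items()]))


def _paf_table(paf: float):
    from sanburden.risk_attribution import PAFTable
    return PAFTable(pd.DataFrame(
        [{"country": "AAA", "year": 2000, "age_band": "*", "cause": "diarrhea",
          "paf": paf}]))


class TestAttributableDeaths:
    def test_single_cell_arithmetic(self):
        pop = _population()
        mort = _mortality({"<5": 50.0})
        burden = attributable_deaths(pop, mort, _paf_table(0.5))
        assert burden.data["deaths"].sum() == pytest.approx(25.0)

    def test_zero_paf_gives_zero_deaths_everywhere(self):
        pop = _population()
        mort = _mortality({b.label: 100.0 for b in DEFAULT_AGE_SCHEMA})
        burden = attributable_deaths(pop, mort, _paf_table(0.0))
        assert (burden.data["deaths"] == 0.0).all()

    def test_additive_over_age_bands(self):
        pop = _population(shares=(0.1, 0.2, 0.45, 0.15, 0.1))
        mort = _mortality({"<5": 50.0, "5-14": 100.0})
        burden = attributable_deaths(pop, mort, _paf_table(0.5))
        # 1e6 * 0.1 * 50/1e5 * 0.5 = 25 ; 1e6 * 0.2 * 100/1e5 * 0.5 = 100
        assert burden.data["deaths"].sum() == pytest.approx(125.0)

    def test_linear_in_population_and_rural_share(self):
        mort = _mortality({"<5": 50.0})
        d1 = attributable_deaths(_population(total=1e6), mort, _paf_table(0.5)
                                 ).data["deaths"].sum()
        d2 = attributable_deaths(_population(total=2e6), mort, _paf_table(0.5)
                                 ).data["deaths"].sum()
        d3 = attributable_deaths(_population(rural=0.5), mort, _paf_table(0.5)
                                 ).data["deaths"].sum()
        assert d2 == pytest.approx(2 * d1)
        assert d3 == pytest.approx(d1 / 2)

    def test_misaligned_population_keys_raise_join_error(self):
        pop = _population(years=(2001,))
        mort = _mortality({"<5": 50.0})
        with pytest.raises(KeyError):
            attributable_deaths(pop, mort, _paf_table(0.5))


class TestAgeStandardizedRate:
    def _burden(self, rates, pops):
        rows = []
        for (band, r), p in zip(rates.items(), pops):
            rows.append({"country": "AAA", "year": 2000, "age_band": band,
                         "cause": "diarrhea", "deaths": r * p / 1e5,
                         "at_risk_population": p})
        return BurdenPanel(pd.DataFrame(rows))

    def test_constant_rates_give_that_rate_for_any_weights(self):
        rates = {b.label: 40.0 for b in DEFAULT_AGE_SCHEMA}
        burden = self._burden(rates, [1e5] * 5)
        std = StandardPopulation.who_world(DEFAULT_AGE_SCHEMA)
        out = age_standardized_rate(burden, _population(), std)
        assert out["asr"].iloc[0] == pytest.approx(40.0)

    def test_degenerate_standard_returns_single_band_crude_rate(self):
        rates = {"<5": 10.0, "5-14": 30.0, "15-49": 5.0, "50-64": 5.0, "65+": 70.0}
        burden = self._burden(rates, [1e5] * 5)
        std = StandardPopulation.single_band(DEFAULT_AGE_SCHEMA, "65+")
        out = age_standardized_rate(burden, _population(), std)
        assert out["asr"].iloc[0] == pytest.approx(70.0)

    def test_two_band_weighted_mean(self):
        rates = {"<5": 10.0, "5-14": 30.0, "15-49": 0.0, "50-64": 0.0, "65+": 0.0}
        burden = self._burden(rates, [1e5] * 5)
        std = StandardPopulation({DEFAULT_AGE_SCHEMA[0]: 0.25,
                                  DEFAULT_AGE_SCHEMA[1]: 0.75,
                                  **{b: 0.0 for b in DEFAULT_AGE_SCHEMA[2:]}})
        out = age_standardized_rate(burden, _population(), std)
        assert out["asr"].iloc[0] == pytest.approx(0.25 * 10 + 0.75 * 30)

    def test_invariant_to_common_population_scaling(self):
        rates = {b.label: r for b, r in zip(DEFAULT_AGE_SCHEMA, (10, 20, 5, 8, 90))}
        std = StandardPopulation.who_world(DEFAULT_AGE_SCHEMA)
        a1 = age_standardized_rate(self._burden(rates, [1e5] * 5),
                                   _population(), std)["asr"].iloc[0]
        a2 = age_standardized_rate(self._burden(rates, [7e5] * 5),
                                   _population(), std)["asr"].iloc[0]
        assert a1 == pytest.approx(a2)
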