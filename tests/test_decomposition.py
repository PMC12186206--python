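import numpy as np
import pytest

from sanburden.driver_decomposition import (
    DEFAULT_FACTORS,
    FOUR_FACTOR_SET,
    FactorState,
    decompose,
    decompose_naive,
    decompose_timeline,
    evaluate_deaths,
    marginal_contribution,
    state_from_panels,
)
from sanburden.panel_io import RRRecord
from sanburden.synthetic_world import WorldConfig, generate_world

RR = (RRRecord("unimproved", "diarrhea", 2.5, 1.8, 3.2),
      RRRecord("improved", "diarrhea", 1.3, 1.1, 1.6))
RR_NULL = (RRRecord("unimproved", "diarrhea", 1.0, 1.0, 1.0),
           RRRecord("improved", "diarrhea", 1.0, 1.0, 1.0))


def _state(pop=1e6, age=(0.12, 0.2, 0.45, 0.13, 0.10),
           san=(0.2, 0.4, 0.4), rates=(150, 20, 10, 30, 250), rr=RR):
    return FactorState(pop, age, san, rates, rr)


def _random_state(rng, rr=RR):
    age = rng.dirichlet(np.ones(5) * 5)
    san = rng.dirichlet(np.ones(3) * 3)
    return FactorState(float(rng.uniform(1e5, 5e7)), tuple(age), tuple(san),
                       tuple(rng.uniform(1.0, 400.0, 5)), rr)


class TestEvaluateDeaths:
    def test_single_cell_arithmetic_matches_attribution_formula(self):
        s = _state(pop=1e6, age=(0.1, 0.3, 0.3, 0.2, 0.1), rates=(50, 0, 0, 0, 0),
                   san=(0.0, 0.0, 1.0),
                   rr=(RRRecord("unimproved", "diarrhea", 2.0, 2.0, 2.0),))
        # PAF = (2-1)/2 = 0.5 at full exposure; 1e6*0.1*50/1e5*0.5 = 25
        assert evaluate_deaths(s) == pytest.approx(25.0)

    def test_null_relative_risks_give_zero_deaths(self):
        assert evaluate_deaths(_state(rr=RR_NULL)) == 0.0

    def test_linear_in_population(self):
        assert evaluate_deaths(_state(pop=2e6)) == pytest.approx(
            2 * evaluate_deaths(_state(pop=1e6)))


class TestMarginalContribution:
    def test_identical_states_give_zero_deltas_for_every_ordering(self, rng):
        s = _random_state(rng)
        for _ in range(5):
            ordering = rng.permutation(DEFAULT_FACTORS)
            deltas = marginal_contribution(list(ordering), s, s)
            assert all(abs(d) < 1e-12 for d in deltas.values())

    def test_two_factor_product_toy_enumerates_both_orderings(self):
        s0 = _state(pop=100.0, rates=(0.1, 0, 0, 0, 0))
        s1 = _state(pop=200.0, rates=(0.05, 0, 0, 0, 0))
        val = lambda s: s.rural_population * s.mortality_rates[0]
        d_pr = marginal_contribution(["population", "mortality"], s0, s1, val)
        d_rp = marginal_contribution(["mortality", "population"], s0, s1, val)
        assert d_pr == pytest.approx({"population": 10.0, "mortality": -10.0})
        assert d_rp == pytest.approx({"mortality": -5.0, "population": 5.0})

    def test_deltas_telescope_to_the_total_change(self, rng):
        s0, s1 = _random_state(rng), _random_state(rng)
        for _ in range(10):
            ordering = list(rng.permutation(DEFAULT_FACTORS))
            deltas = marginal_contribution(ordering, s0, s1)
            total = evaluate_deaths(
                marginal_end := _apply_all(s0, s1)) - evaluate_deaths(s0)
            assert sum(deltas.values()) == pytest.approx(total, rel=1e-9)

    def test_incomplete_ordering_rejected(self):
        s = _state()
        with pytest.raises(ValueError):
            marginal_contribution(["population", "population"], s, s)


def _apply_all(s0, s1):
    from sanburden.driver_decomposition import _state_at
    return _state_at(s0, s1, frozenset(DEFAULT_FACTORS))


class TestDecompose:
    def test_two_factor_toy_shapley_values(self):
        s0 = _state(pop=100.0, rates=(0.1, 0, 0, 0, 0))
        s1 = _state(pop=200.0, rates=(0.05, 0, 0, 0, 0))
        val = lambda s: s.rural_population * s.mortality_rates[0]
        res = decompose(s0, s1, ("population", "mortality"), value=val)
        assert res.contributions == pytest.approx(
            {"population": 7.5, "mortality": -7.5})
        assert res.total_change == pytest.approx(0.0, abs=1e-12)

    def test_unchanged_factor_contributes_exactly_zero(self, rng):
        s0 = _random_state(rng)
        s1 = FactorState(s0.rural_population * 1.7, s0.age_shares,
                         s0.sanitation, tuple(r * 0.8 for r in s0.mortality_rates),
                         s0.rr)
        res = decompose(s0, s1)
        assert res.contributions["sanitation"] == 0.0
        assert res.contributions["share_65plus"] == 0.0
        assert res.contributions["share_under5"] == 0.0

    def test_memoized_equals_naive_enumeration(self, rng):
        for _ in range(5):
            s0, s1 = _random_state(rng), _random_state(rng)
            mem = decompose(s0, s1)
            naive = decompose_naive(s0, s1)
            for f in DEFAULT_FACTORS:
                assert mem.contributions[f] == pytest.approx(
                    naive.contributions[f], rel=1e-10, abs=1e-8)
            assert mem.meta["evaluations"] == 32

    def test_efficiency_sum_equals_total_change(self, rng):
        for _ in range(20):
            s0, s1 = _random_state(rng), _random_state(rng)
            res = decompose(s0, s1)
            assert sum(res.contributions.values()) == pytest.approx(
                res.total_change, rel=1e-9, abs=1e-9)

    def test_aging_only_change_is_fully_attributed_to_the_elderly_share(self):
        s0 = _state()
        age1 = list(s0.age_shares)
        # raise 65+ by 0.05, rescale interior, hold <5 fixed
        from sanburden.driver_decomposition import _swap_edge_share
        age1 = _swap_edge_share(s0.age_shares, 4, s0.age_shares[4] + 0.05, 0)
        s1 = FactorState(s0.rural_population, age1, s0.sanitation,
                         s0.mortality_rates, s0.rr)
        res = decompose(s0, s1)
        assert res.total_change > 0  # U-shaped rates: older world, more deaths
        assert res.contributions["share_65plus"] == pytest.approx(
            res.total_change, rel=1e-9)
        for f in ("population", "share_under5", "sanitation", "mortality"):
            assert res.contributions[f] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_factors_receive_equal_contributions(self):
        # a value function symmetric in population and mortality[0] with
        # symmetric changes must split the change equally
        s0 = _state(pop=2.0, rates=(2.0, 0, 0, 0, 0))
        s1 = _state(pop=3.0, rates=(3.0, 0, 0, 0, 0))
        val = lambda s: s.rural_population * s.mortality_rates[0]
        res = decompose(s0, s1, ("population", "mortality"), value=val)
        assert res.contributions["population"] == pytest.approx(
            res.contributions["mortality"])

    def test_four_factor_grouping_supported(self, rng):
        s0, s1 = _random_state(rng), _random_state(rng)
        res = decompose(s0, s1, FOUR_FACTOR_SET)
        assert set(res.contributions) == set(FOUR_FACTOR_SET)
        assert sum(res.contributions.values()) == pytest.approx(
            res.total_change, rel=1e-9)

    def test_too_many_factors_refused(self):
        s = _state()
        with pytest.raises(ValueError, match="8"):
            decompose(s, s, tuple(f"f{i}" for i in range(9)))


@pytest.fixture(scope="module")
def world():
    return generate_world(WorldConfig(n_countries=3, year_start=2000,
                                      year_end=2020, seed=77))


class TestDecomposeTimeline:
    def test_state_snapshot_matches_panel_cells(self, world):
        s = state_from_panels(world.config.countries[0], 2005, world.population,
                              world.sanitation, world.mortality, world.rr)
        row = world.population.data.query(
            "country == @world.config.countries[0] and year == 2005").iloc[0]
        assert s.rural_population == pytest.approx(
            row.total_population * row.rural_share)
        assert sum(s.age_shares) == pytest.approx(1.0)

    def test_single_interval_no_change_gives_zero_contributions(self, world):
        import pandas as pd
        from sanburden.panel_io import PopulationPanel, SanitationShares, MortalityPanel

        years = (2010, 2011)
        pop = PopulationPanel(pd.concat(
            [world.population.data.query("year == 2010").assign(year=y)
             for y in years], ignore_index=True))
        san = SanitationShares(pd.concat(
            [world.sanitation.data.query("year == 2010").assign(year=y)
             for y in years], ignore_index=True))
        mort = MortalityPanel(pd.concat(
            [world.mortality.data.query("year == 2010").assign(year=y)
             for y in years], ignore_index=True))
        table = decompose_timeline(pop, san, mort, world.rr, list(years))
        assert np.allclose(table["contribution_deaths"], 0.0, atol=1e-9)

    def test_interval_totals_telescope_across_breakpoints(self, world):
        table = decompose_timeline(world.population, world.sanitation,
                                   world.mortality, world.rr, [2000, 2010, 2020])
        g = table[table.group == "GLOBAL"].drop_duplicates(["interval"])
        total_by_interval = g.set_index("interval")["total_change_deaths"]
        full = decompose_timeline(world.population, world.sanitation,
                                  world.mortality, world.rr, [2000, 2020])
        full_total = full[full.group == "GLOBAL"]["total_change_deaths"].iloc[0]
        assert total_by_interval.sum() == pytest.approx(full_total, rel=1e-9)

    def test_global_rows_are_sums_of_country_rows(self, world):
        table = decompose_timeline(world.population, world.sanitation,
                                   world.mortality, world.rr, [2000, 2020])
        per_country = table[table.group != "GLOBAL"].groupby("factor")[
            "contribution_deaths"].sum()
        global_rows = table[table.group == "GLOBAL"].set_index("factor")[
            "contribution_deaths"]
        for f in DEFAULT_FACTORS:
            assert per_country[f] == pytest.approx(global_rows[f], rel=1e-12)

    def test_missing_breakpoint_year_raises_naming_the_year(self, world):
        with pytest.raises(KeyError, match="1999"):
            decompose_timeline(world.population, world.sanitation,
                               world.mortality, world.rr, [1999, 2020])
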