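"""Smoking-attributable deaths, vaping adjustment, deaths averted."""

import numpy as np
import pytest

from tobaccosim.demography import (
    N_AGES,
    N_STATUS,
    STATUS_CURRENT,
    STATUS_FORMER0,
    STATUS_NEVER,
    MortalitySchedule,
    PopulationState,
    RRLadder,
    former_death_rates,
)
from tobaccosim.nvp_inference import compound
from tobaccosim.sad_projection import (
    SADLedger,
    apply_nvp_adjustment,
    compute_sads,
    deaths_averted,
    make_adjustment_hook,
    sad_ledger,
)
from tobaccosim.workbench import run_counterfactual

from conftest import flat_mortality, random_state


class TestComputeSADs:
    def test_no_smokers_no_sads(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[:, :, STATUS_NEVER] = 100.0
        sads = compute_sads(PopulationState(2000, counts), flat_mortality(0.01, 0.02))
        assert np.all(sads == 0)

    def test_single_cell_product(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 50, STATUS_CURRENT] = 1000.0
        sads = compute_sads(PopulationState(2000, counts), flat_mortality(0.01, 0.02))
        assert sads[0] == pytest.approx(10.0)  # 1000 * (0.02 - 0.01)
        assert sads[1] == 0.0

    def test_brute_force_cell_ledger(self, rng):
        """Randomised toy state against an explicit cell-by-cell sum."""
        ages = [30, 45, 60, 75, 85]
        state = random_state(rng, ages=ages)
        dn = rng.uniform(0.001, 0.05, size=(2, N_AGES))
        dc = dn * rng.uniform(1.0, 3.0, size=dn.shape)
        mort = MortalitySchedule.constant(dn, dc, [2000])
        ladder = RRLadder()
        expected = np.zeros(2)
        df = former_death_rates(dn, dc, ladder)
        for g in range(2):
            for a in ages:
                expected[g] += state.counts[g, a, STATUS_CURRENT] * (
                    dc[g, a] - dn[g, a]
                )
                for b in range(6):
                    expected[g] += state.counts[g, a, STATUS_FORMER0 + b] * (
                        df[g, a, b] - dn[g, a]
                    )
        assert np.allclose(compute_sads(state, mort, ladder), expected)

    def test_nonnegative_under_rate_ordering(self, rng):
        state = random_state(rng)
        sads = compute_sads(state, flat_mortality(0.01, 0.04))
        assert np.all(sads >= 0)


class TestLedger:
    def test_totals_and_cumulative(self, rng):
        states = [random_state(rng, year=2000 + i, ages=[50, 60]) for i in range(4)]
        ledger = sad_ledger(states, flat_mortality(0.01, 0.03, years=range(2000, 2004)))
        assert ledger.years() == (2000, 2001, 2002, 2003)
        total = sum(ledger.annual(y) for y in ledger.years())
        assert ledger.cumulative(2000, 2003) == pytest.approx(total)
        for y in ledger.years():
            assert ledger.annual(y, "both") == pytest.approx(
                ledger.annual(y, "male") + ledger.annual(y, "female")
            )

    def test_cumulative_requires_coverage(self, rng):
        states = [random_state(rng, year=2000, ages=[50])]
        ledger = sad_ledger(states, flat_mortality(0.01, 0.03))
        with pytest.raises(ValueError):
            ledger.cumulative(2000, 2005)

    def test_misaligned_years_rejected(self, rng):
        a = sad_ledger([random_state(rng, year=2000, ages=[50])],
                       flat_mortality(0.01, 0.03))
        b = sad_ledger([random_state(rng, year=2001, ages=[50])],
                       flat_mortality(0.01, 0.03))
        with pytest.raises(ValueError):
            deaths_averted(a, b)


class TestAdjustmentHook:
    def _state(self, year=2013):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 20, STATUS_CURRENT] = 100.0
        counts[0, 30, STATUS_CURRENT] = 100.0
        counts[0, 50, STATUS_CURRENT] = 100.0
        return PopulationState(year, counts)

    def test_zero_adjustor_is_identity(self):
        hook = make_adjustment_hook({("male", "18-24"): 0.0})
        st = self._state()
        assert np.array_equal(hook(st).counts, st.counts)

    def test_reallocation_split_at_age_25(self):
        hook = make_adjustment_hook(
            {("male", "18-24"): 0.1, ("male", "25-44"): 0.1}, max_age=45
        )
        out = hook(self._state())
        assert out.counts[0, 20, STATUS_CURRENT] == pytest.approx(90.0)
        assert out.counts[0, 20, STATUS_NEVER] == pytest.approx(10.0)  # under 25
        assert out.counts[0, 30, STATUS_CURRENT] == pytest.approx(90.0)
        assert out.counts[0, 30, STATUS_FORMER0] == pytest.approx(10.0)  # 25 and over

    def test_cohort_age_restriction(self):
        hook = make_adjustment_hook({("male", "45-64"): 0.1}, max_age=45)
        out = hook(self._state())
        assert out.counts[0, 50, STATUS_CURRENT] == 100.0  # untouched
        unrestricted = make_adjustment_hook({("male", "45-64"): 0.1}, max_age=None)
        assert unrestricted(self._state()).counts[0, 50, STATUS_CURRENT] == 90.0

    def test_inert_outside_window(self):
        hook = make_adjustment_hook({("male", "18-24"): 0.1}, 2012, 2018)
        for year in (2012, 2019):
            st = self._state(year)
            assert np.array_equal(hook(st).counts, st.counts)

    def test_negative_adjustor_symmetric(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 50, STATUS_CURRENT] = 100.0
        counts[0, 50, STATUS_FORMER0] = 50.0
        st = PopulationState(2013, counts)
        hook = make_adjustment_hook({("male", "45-64"): -0.1}, max_age=None)
        out = hook(st)
        assert out.counts[0, 50, STATUS_CURRENT] == pytest.approx(110.0)
        assert out.counts[0, 50, STATUS_FORMER0] == pytest.approx(40.0)

    def test_compound_reduction_example(self):
        # an annual 2.1% adjustor compounds to about 11.9% over six years
        assert compound(0.021, 6) == pytest.approx(0.1195, abs=5e-4)


class TestScenarioAdjustment:
    @pytest.fixture(scope="class")
    def scenario_pair(self, small_world_cls):
        world = small_world_cls
        years = range(2010, 2021)
        baseline = run_counterfactual(world, None, years, label="no_nvp")
        adjusted = apply_nvp_adjustment(
            baseline,
            {("male", "18-24"): 0.05, ("female", "18-24"): 0.05,
             ("male", "25-44"): 0.03, ("female", "25-44"): 0.03},
            start_year=2012,
            end_year=2018,
            max_age=45,
        )
        return world, baseline, adjusted

    @pytest.fixture(scope="class")
    def small_world_cls(self):
        from tobaccosim.synthetic_data import WorldConfig, gen_world

        return gen_world(
            WorldConfig(seed=3, persons_per_gender=20_000, start_year=2010,
                        end_year=2021)
        )

    def test_zero_adjustor_reproduces_baseline(self, scenario_pair):
        world, baseline, _ = scenario_pair
        unadjusted = apply_nvp_adjustment(baseline, {("male", "18-24"): 0.0})
        for s0, s1 in zip(baseline.states, unadjusted.states):
            assert np.allclose(s0.counts, s1.counts)

    def test_adjusted_prevalence_lower_in_targeted_cells(self, scenario_pair):
        _, baseline, adjusted = scenario_pair
        for year in (2015, 2018, 2020):
            assert adjusted.prevalence_at(year, "male", "18-24") < (
                baseline.prevalence_at(year, "male", "18-24")
            )

    def test_deaths_averted_sign_and_additivity(self, scenario_pair):
        world, baseline, adjusted = scenario_pair
        base_ledger = sad_ledger(baseline.states, world.mortality, world.ladder)
        adj_ledger = sad_ledger(adjusted.states, world.mortality, world.ladder)
        averted = deaths_averted(base_ledger, adj_ledger)
        # adjusted world has uniformly fewer smokers: averted >= 0 every year
        assert (averted.data["both"] >= -1e-9).all()
        # gender additivity mirrors the both-gender ledger rows
        assert np.allclose(
            averted.data["both"], averted.data["male"] + averted.data["female"]
        )

    def test_averted_deaths_grow_over_time(self, scenario_pair):
        """With positive adjustors concentrated at young ages, annual averted
        deaths increase across the projection window."""
        world, baseline, adjusted = scenario_pair
        base_ledger = sad_ledger(baseline.states, world.mortality, world.ladder)
        adj_ledger = sad_ledger(adjusted.states, world.mortality, world.ladder)
        averted = deaths_averted(base_ledger, adj_ledger)
        series = averted.data.loc[2013:, "both"].to_numpy()
        assert series[-1] > series[0]

    def test_range_ordering_low_point_high(self, scenario_pair):
        world, baseline, _ = scenario_pair
        from tobaccosim.nvp_inference import NVPAdjustor

        adj = {
            ("male", "18-24"): NVPAdjustor("male", "18-24", "s", 0.05, 0.03, 0.07),
            ("female", "18-24"): NVPAdjustor("female", "18-24", "s", 0.05, 0.03, 0.07),
        }
        ledgers = {}
        base_ledger = sad_ledger(baseline.states, world.mortality, world.ladder)
        for which in ("low", "annual", "high"):
            run = apply_nvp_adjustment(baseline, adj, which=which)
            ledgers[which] = deaths_averted(
                base_ledger, sad_ledger(run.states, world.mortality, world.ladder)
            )
        y = ledgers["annual"].years()[-1]
        assert (
            ledgers["low"].annual(y) <= ledgers["annual"].annual(y) <= ledgers["high"].annual(y)
        )
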