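"""Policy effect algebra and schedule-to-delta translation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tobaccosim.demography import N_AGES, N_STATUS, STATUS_CURRENT, PopulationState
from tobaccosim.policy_engine import (
    EffectSizeTable,
    PolicySchedule,
    apply_prevalence_shock,
    combine_effects,
    combine_increases,
    deflate_effect,
    incremental_effect,
    price_effect,
    schedule_to_deltas,
    standing_effects,
)


class TestDeflateEffect:
    @pytest.mark.parametrize(
        "base, enforcement, publicity, expected",
        [
            (0.06, 8, 1, 0.06 * 0.95),  # 0.5*(1 + 0.5 + 0.4)
            (0.04, 10, 1, 0.04),  # deflator = 1 at full enforcement + publicity
            (0.04, 0, 0, 0.02),  # effects halved absent both
            (0.05, 5, 0, 0.05 * 0.625),
        ],
    )
    def test_examples(self, base, enforcement, publicity, expected):
        assert deflate_effect(base, enforcement, publicity) == pytest.approx(expected)

    def test_bounded_by_base(self):
        for enf in range(11):
            for pub in (0, 1):
                assert deflate_effect(0.08, enf, pub) <= 0.08 + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            deflate_effect(0.05, 11, 0)
        with pytest.raises(ValueError):
            deflate_effect(0.05, 5, 2)


class TestCombineEffects:
    @pytest.mark.parametrize(
        "effects, expected",
        [
            ([0.06, 0.02], 1 - 0.94 * 0.98),
            ([0.05], 0.05),
            ([], 0.0),
        ],
    )
    def test_examples(self, effects, expected):
        assert combine_effects(effects) == pytest.approx(expected)

    @given(st.lists(st.floats(0.0, 0.5), max_size=6))
    def test_order_invariant_and_dominates_max(self, effects):
        combined = combine_effects(effects)
        assert combined == pytest.approx(combine_effects(effects[::-1]))
        assert combined >= max(effects, default=0.0) - 1e-12
        assert combined < 1.0

    def test_rejects_unit_effect(self):
        with pytest.raises(ValueError):
            combine_effects([0.5, 1.0])


class TestPriceEffect:
    def test_examples(self):
        assert price_effect(1.0, 1.1, -0.2) == pytest.approx(-0.02)
        assert price_effect(4.2, 4.2, -0.4) == 0.0
        # price rise from 5.60 to 6.60, young-adult elasticity
        assert price_effect(5.60, 6.60, -0.4) == pytest.approx(-0.4 * 1.0 / 5.6)

    def test_sign_correct(self):
        assert price_effect(2.0, 3.0, -0.3) < 0  # price up, prevalence down
        assert price_effect(3.0, 2.0, -0.3) > 0

    def test_log_form(self):
        assert price_effect(2.0, 4.0, -0.3, form="log") == pytest.approx(
            -0.3 * np.log(2.0)
        )

    def test_nonpositive_price_rejected(self):
        with pytest.raises(ValueError):
            price_effect(0.0, 1.0, -0.2)


class TestIncrementalEffect:
    @pytest.mark.parametrize(
        "old, new, expected",
        [
            (0.0, 0.06, 0.06),
            (0.06, 0.06, 0.0),
            (0.02, 0.06, 1 - 0.94 / 0.98),
        ],
    )
    def test_examples(self, old, new, expected):
        assert incremental_effect(old, new) == pytest.approx(expected)

    def test_rollback_gives_negative_increment(self):
        assert incremental_effect(0.06, 0.02) < 0

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    def test_composes_with_combine(self, old, new):
        """Stacking the old effect with the increment reproduces the new level."""
        inc = incremental_effect(old, new)
        assert combine_effects([old, inc]) == pytest.approx(new, abs=1e-12)


class TestEffectSizeTable:
    def test_elasticity_bands(self):
        eps = EffectSizeTable().elasticity_by_age()
        assert eps[14] == -0.6 and eps[17] == -0.6
        assert eps[18] == -0.4 and eps[24] == -0.4
        assert eps[25] == -0.2 and eps[34] == -0.2
        assert eps[35] == -0.1 and eps[64] == -0.1
        assert eps[65] == -0.2 and eps[99] == -0.2
        assert eps[13] == 0.0

    def test_cessation_package_cap_consistency(self):
        """The calibrated component combination reproduces the stated full
        package (-5.68% prevalence, +29.4% cessation); the raw product is
        close but not exact, which is why the calibration exists."""
        from tobaccosim.policy_engine import _cessation_effects

        effects = EffectSizeTable()
        full = {c: 1.0 for c in effects.cessation_treatment}
        prev, cess = _cessation_effects(full, effects)
        assert prev == pytest.approx(0.0568)
        assert cess == pytest.approx(0.294)
        raw_prev = combine_effects(
            v["prevalence"] for v in effects.cessation_treatment.values()
        )
        raw_cess = combine_increases(
            v["cessation"] for v in effects.cessation_treatment.values()
        )
        assert raw_prev == pytest.approx(0.0568, abs=0.01)
        assert raw_cess == pytest.approx(0.294, abs=0.04)

    def test_scaled_factors(self):
        scaled = EffectSizeTable().scaled({"price": 1.25, "media": 0.5})
        assert scaled.elasticity_by_age()[20] == pytest.approx(-0.5)
        assert scaled.media["high"] == pytest.approx(0.0325)
        assert scaled.smoke_free_air == EffectSizeTable().smoke_free_air


class TestScheduleToDeltas:
    @pytest.fixture(scope="class")
    def schedule(self):
        return PolicySchedule.default()

    def test_default_schedule_loads(self, schedule):
        assert schedule.years[0] == 1993 and schedule.years[-1] == 2019
        assert schedule.price[1993] == 1.75
        assert schedule.price[2012] == 5.60
        assert schedule.media_mix[2003] == {"minimal": 0.0, "moderate": 1.0}
        assert schedule.youth_access[1997] == "none"
        assert schedule.youth_access[2003] == "mid"

    def test_all_policies_absent_gives_zero_deltas(self):
        sched = PolicySchedule.from_dict(
            {
                "years": {"start": 2000, "end": 2005},
                "price": {2000: 3.0},
                "smoke_free_air": {
                    "enforcement": 8,
                    "worksite": {2000: {"high": 0.0, "mid": 0.0, "low": 0.0}},
                    "restaurant": {2000: 0.0},
                    "bar": {2000: 0.0},
                    "other": {2000: 0.0},
                },
                "media": {2000: {"minimal": 1.0}},
                "marketing": {"enforcement": 9, "levels": {2000: {"none": 1.0}}},
                "cessation_treatment": {"pharmacotherapy": {2000: 0.0}},
                "youth_access": {2000: "none"},
            }
        )
        effects = EffectSizeTable(
            marketing={"none": {"prevalence": 0.0, "initiation": 0.0, "cessation": 0.0}},
            media={"minimal": 0.0},
        )
        deltas = schedule_to_deltas(sched, effects)
        for y in sched.years:
            shock, d_init, d_cess = deltas.for_year(y)
            assert np.all(shock == 0)
            assert np.all(d_init == 0)
            assert np.all(d_cess == 0)

    def test_worksite_ban_first_year_shock(self):
        """A full worksite ban appearing in one year shocks prevalence by the
        deflated effect 0.06 x 0.95 = 0.057."""
        base = {
            "years": {"start": 2000, "end": 2001},
            "price": {2000: 3.0},
            "smoke_free_air": {
                "enforcement": 8,
                "worksite": {
                    2000: {"high": 0.0, "mid": 0.0, "low": 0.0},
                    2001: {"high": 1.0, "mid": 0.0, "low": 0.0},
                },
                "restaurant": {2000: 0.0},
                "bar": {2000: 0.0},
                "other": {2000: 0.0},
            },
            "media": {2000: {"moderate": 1.0}},  # publicity indicator on
            "marketing": {"enforcement": 9, "levels": {2000: {"none": 1.0}}},
            "cessation_treatment": {"pharmacotherapy": {2000: 0.0}},
            "youth_access": {2000: "none"},
        }
        effects = EffectSizeTable(
            marketing={"none": {"prevalence": 0.0, "initiation": 0.0, "cessation": 0.0}},
            media={"moderate": 0.0},
        )
        deltas = schedule_to_deltas(PolicySchedule.from_dict(base), effects)
        shock, _, _ = deltas.for_year(2001)
        assert shock[40] == pytest.approx(0.057)

    def test_media_mixture_weighted_average(self):
        effects = EffectSizeTable()
        mix = {"minimal": 0.5, "moderate": 0.5}
        from tobaccosim.policy_engine import _media_effects

        prev, init, cess = _media_effects(mix, effects)
        assert prev == pytest.approx(0.5 * 0.0163 + 0.5 * 0.0325)
        assert init == prev and cess == prev

    def test_youth_access_restricted_to_stated_ages(self, schedule):
        eff = standing_effects(schedule, EffectSizeTable(), 2003)
        youth = eff["youth_access"]["prevalence"]
        assert youth[12] == pytest.approx(0.12)  # mid level, ages 10-15
        assert youth[16] == pytest.approx(0.08)  # mid level, ages 16-17
        assert youth[18] == 0.0 and youth[9] == 0.0

    def test_first_scheduled_year_has_no_shock(self, schedule):
        shock, _, _ = schedule_to_deltas(schedule).for_year(1993)
        assert np.all(shock == 0)

    def test_price_rise_appears_in_shock(self, schedule):
        deltas = schedule_to_deltas(schedule)
        shock, _, _ = deltas.for_year(2000)  # price rising 1993-2002
        assert shock[20] > 0  # young adults, elasticity -0.4
        assert shock[20] > shock[40]  # stronger response than ages 35-64

    def test_unknown_policy_rejected(self, schedule):
        with pytest.raises(ValueError):
            schedule.frozen_at(2012, ["no_such_policy"])


class TestApplyPrevalenceShock:
    def test_adult_shock_moves_smokers_to_recent_quit(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 40, STATUS_CURRENT] = 1000.0
        shock = np.zeros(N_AGES)
        shock[40] = 0.057
        out = apply_prevalence_shock(PopulationState(2000, counts), shock)
        assert out.counts[0, 40, STATUS_CURRENT] == pytest.approx(943.0)
        assert out.counts[0, 40, 2] == pytest.approx(57.0)  # former <1

    def test_young_shock_returns_smokers_to_never(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 16, STATUS_CURRENT] = 100.0
        shock = np.zeros(N_AGES)
        shock[16] = 0.10
        out = apply_prevalence_shock(PopulationState(2000, counts), shock)
        assert out.counts[0, 16, STATUS_CURRENT] == pytest.approx(90.0)
        assert out.counts[0, 16, 0] == pytest.approx(10.0)  # never

    def test_negative_shock_limited_by_pool(self):
        counts = np.zeros((2, N_AGES, N_STATUS))
        counts[0, 40, STATUS_CURRENT] = 100.0
        counts[0, 40, 2] = 3.0
        shock = np.zeros(N_AGES)
        shock[40] = -0.5  # would pull 50 back, only 3 available
        out = apply_prevalence_shock(PopulationState(2000, counts), shock)
        assert out.counts[0, 40, STATUS_CURRENT] == pytest.approx(103.0)
        assert out.counts[0, 40, 2] == pytest.approx(0.0)
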