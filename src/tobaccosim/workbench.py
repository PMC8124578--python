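"""End-to-end scenario orchestration.

Pipelines wired here: calibrate transition rates, run a multi-year scenario
(policy shocks -> mortality -> Markov transitions -> aging each year),
validate projected prevalence against survey series, infer vaping
adjustors, project smoking-attributable deaths under baseline and adjusted
scenarios, and sweep policy-effect bounds for sensitivity analysis.  All
runs are deterministic given their inputs; the only randomness in the
package lives in the synthetic survey sampler, and every consumer threads
an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .demography import (
    ADULT_AGE_GROUPS,
    GENDERS,
    MortalitySchedule,
    PopulationState,
    evolve_population,
)
from .nvp_inference import (
    annualize,
    infer_nvp_table,
    nvp_net_impact,
    outside_ci_flag,
    relative_reduction,
)
from .policy_engine import (
    POLICIES,
    EffectSizeTable,
    PolicyDeltas,
    PolicySchedule,
    apply_prevalence_shock,
    schedule_to_deltas,
)
from .sad_projection import sad_ledger
from .synthetic_data import (
    SyntheticWorld,
    aggregate_18plus,
    gen_survey_series,
    inject_nvp_effect,
)
from .transitions import CalibrationMultipliers, apply_calibration, markov_step

log = logging.getLogger(__name__)


@dataclass
class ScenarioResult:
    """A completed scenario run: yearly states and derived prevalence."""

    label: str
    years: tuple[int, ...]
    states: list[PopulationState]
    prevalence: pd.DataFrame  # year, gender, age_group, prevalence
    rerun: Callable[..., "ScenarioResult"] | None = None

    def state_for(self, year: int) -> PopulationState:
        return self.states[self.years.index(year)]

    def prevalence_at(self, year: int, gender: str, age_group: str = "18+") -> float:
        df = self.prevalence
        sel = df[
            (df["year"] == year)
            & (df["gender"] == gender)
            & (df["age_group"] == age_group)
        ]
        if sel.empty:
            raise KeyError(f"no prevalence recorded for {gender}/{age_group}/{year}")
        return float(sel["prevalence"].iloc[0])

    def relative_reduction(
        self, period: tuple[int, int], gender: str, age_group: str = "18+"
    ) -> float:
        p0 = self.prevalence_at(period[0], gender, age_group)
        p1 = self.prevalence_at(period[1], gender, age_group)
        return relative_reduction(p0, p1)


def run_scenario(
    world: SyntheticWorld,
    deltas: PolicyDeltas | None,
    years: Sequence[int],
    label: str = "scenario",
    calibration: CalibrationMultipliers | None = None,
    adjustment_hook: Callable[[PopulationState], PopulationState] | None = None,
) -> ScenarioResult:
    """Run the compartment model over a span of years.

    Within each year: the policy first-year prevalence shock is applied to
    the standing population, then the optional adjustment hook (vaping
    adjustor), then the recorded prevalence is taken; mortality, Markov
    transitions (with that year's ongoing policy deltas) and aging advance
    the population to the next year.  Deterministic and reproducible:
    identical inputs yield identical outputs.
    """
    years = tuple(int(y) for y in years)
    if years[0] < world.initial_state.year:
        raise ValueError("scenario starts before the world's initial state")
    rates = world.rates if calibration is None else apply_calibration(
        world.rates, calibration
    )
    deltas = deltas or PolicyDeltas.zeros(years)

    state = world.initial_state.copy()
    # roll forward with no policy change to the first scenario year if needed
    while state.year < years[0]:
        state = evolve_population(
            state,
            world.mortality,
            world.drivers,
            world.ladder,
            transition=lambda s: markov_step(s, rates, world.peak_ages),
        )

    states: list[PopulationState] = []
    prev_rows = []
    for y in years:
        shock, d_init, d_cess = deltas.for_year(y)
        if np.any(shock != 0):
            state = apply_prevalence_shock(state, shock, world.peak_ages)
        if adjustment_hook is not None:
            state = adjustment_hook(state)
        states.append(state)
        prev_rows.append(state.prevalence_by_group())
        if y != years[-1]:
            state = evolve_population(
                state,
                world.mortality,
                world.drivers,
                world.ladder,
                transition=lambda s: markov_step(
                    s,
                    rates,
                    world.peak_ages,
                    initiation_delta=d_init,
                    cessation_delta=d_cess,
                ),
            )

    def _rerun(adjustment_hook=None, label=label) -> ScenarioResult:
        return run_scenario(
            world, deltas, years, label=label, calibration=calibration,
            adjustment_hook=adjustment_hook,
        )

    return ScenarioResult(
        label=label,
        years=years,
        states=states,
        prevalence=pd.concat(prev_rows, ignore_index=True),
        rerun=_rerun,
    )


def run_counterfactual(
    world: SyntheticWorld,
    schedule: PolicySchedule | None,
    years: Sequence[int],
    effects: EffectSizeTable = EffectSizeTable(),
    calibration: CalibrationMultipliers | None = None,
    label: str = "counterfactual",
) -> ScenarioResult:
    """Run the no-vaping counterfactual under a policy schedule.

    A ``None`` schedule means frozen policies (no shocks or deltas), which
    is equivalent to an empty policy file.
    """
    years = tuple(int(y) for y in years)
    if schedule is None:
        deltas = None
    else:
        if schedule.years[-1] < years[-1]:
            schedule = schedule.extended_to(years[-1])
        deltas = schedule_to_deltas(schedule, effects, years=years)
    return run_scenario(
        world, deltas, years, label=label, calibration=calibration
    )


# --------------------------------------------------------------------------
# Validation report


def validate_report(
    sim_prevalence: pd.DataFrame,
    surveys: pd.DataFrame,
    periods: Sequence[tuple[int, int]],
    model_source: str = "model",
) -> pd.DataFrame:
    """Compare model prevalence levels and relative changes against surveys.

    ``sim_prevalence`` is a long frame (year, gender, age_group, prevalence)
    from a scenario run or a transcribed table; ``surveys`` is a survey
    series frame with confidence bounds.  For each (gender, age group,
    survey, period) the report gives model and survey relative changes,
    their difference, and flags for model levels falling outside the survey
    CI at each endpoint.  Totals are recomputed from the cells, not copied.
    """
    if not periods:
        raise ValueError("at least one comparison period is required")
    rows = []
    sim = sim_prevalence.copy()
    if "survey" in sim.columns:
        sim = sim[sim["survey"] == model_source]
    for (gender, group), cell in surveys.groupby(["gender", "age_group"], sort=False):
        sim_cell = sim[(sim["gender"] == gender) & (sim["age_group"] == group)]
        for survey, sv in cell.groupby("survey"):
            if survey == model_source:
                continue
            for y0, y1 in periods:
                try:
                    sp0 = float(
                        sim_cell.loc[sim_cell["year"] == y0, "prevalence"].iloc[0]
                    )
                    sp1 = float(
                        sim_cell.loc[sim_cell["year"] == y1, "prevalence"].iloc[0]
                    )
                    r0 = sv.loc[sv["year"] == y0].iloc[0]
                    r1 = sv.loc[sv["year"] == y1].iloc[0]
                except IndexError:
                    continue
                sim_change = relative_reduction(sp0, sp1)
                survey_change = relative_reduction(
                    float(r0["prevalence"]), float(r1["prevalence"])
                )

                def _outside(sim_level, row) -> bool | None:
                    lo, hi = row["ci_lower"], row["ci_upper"]
                    if not np.isfinite([lo, hi]).all():
                        return None
                    return outside_ci_flag(sim_level, (float(lo), float(hi)))

                rows.append(
                    {
                        "gender": gender,
                        "age_group": group,
                        "survey": survey,
                        "period": f"{y0}-{y1}",
                        "sim_start": sp0,
                        "sim_end": sp1,
                        "survey_start": float(r0["prevalence"]),
                        "survey_end": float(r1["prevalence"]),
                        "sim_reduction": sim_change,
                        "survey_reduction": survey_change,
                        "difference": nvp_net_impact(sim_change, survey_change),
                        "sim_outside_ci_start": _outside(sp0, r0),
                        "sim_outside_ci_end": _outside(sp1, r1),
                    }
                )
    if not rows:
        raise ValueError("no overlapping (gender, age group, year) cells to compare")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Sensitivity sweep


def sensitivity_sweep(
    world: SyntheticWorld,
    schedule: PolicySchedule,
    period: tuple[int, int],
    effects: EffectSizeTable = EffectSizeTable(),
    tax_bound: float = 0.25,
    other_bound: float = 0.50,
    calibration: CalibrationMultipliers | None = None,
) -> pd.DataFrame:
    """Marginal sensitivity of prevalence reductions to policy-effect bounds.

    Scenarios: no policy change (levels frozen at the period start); each
    policy alone evolving (others frozen) at low/central/high effect sizes
    (+/- ``tax_bound`` for price, +/- ``other_bound`` for the rest); and all
    policies evolving at low/central/high.  For each scenario and gender the
    report gives period-start and -end 18+ prevalence, the relative
    reduction, and the difference from the no-policy-change scenario.
    """
    y0, y1 = period
    years = tuple(range(y0, y1 + 1))
    frozen = schedule.frozen_at(y0)

    def run(label: str, sched: PolicySchedule, eff: EffectSizeTable) -> dict:
        res = run_counterfactual(
            world, sched, years, effects=eff, calibration=calibration, label=label
        )
        out = {"scenario": label}
        for gender in GENDERS:
            p0 = res.prevalence_at(y0, gender)
            p1 = res.prevalence_at(y1, gender)
            out[f"{gender}_start"] = p0
            out[f"{gender}_end"] = p1
            out[f"{gender}_reduction"] = relative_reduction(p0, p1)
        return out

    rows = [run("no_policy_change", frozen, effects)]
    bounds = {p: (tax_bound if p == "price" else other_bound) for p in POLICIES}
    swept = [p for p in POLICIES if p != "youth_access"]  # youth levels are static here
    for policy in swept:
        alone = schedule.frozen_at(y0, [p for p in POLICIES if p != policy])
        for tag, factor in (("central", 1.0), ("low", 1 - bounds[policy]),
                            ("high", 1 + bounds[policy])):
            rows.append(
                run(f"{policy}_alone_{tag}", alone, effects.scaled({policy: factor}))
            )
    for tag, f in (("central", 1.0), ("low", -1.0), ("high", 1.0)):
        if tag == "central":
            eff = effects
        else:
            sign = -1 if tag == "low" else 1
            eff = effects.scaled(
                {p: 1 + sign * bounds[p] for p in POLICIES}
            )
        rows.append(run(f"all_policies_{tag}", schedule, eff))

    df = pd.DataFrame(rows)
    base = df[df["scenario"] == "no_policy_change"].iloc[0]
    for gender in GENDERS:
        df[f"{gender}_diff_from_no_policy"] = (
            df[f"{gender}_reduction"] - base[f"{gender}_reduction"]
        )
    return df


# --------------------------------------------------------------------------
# Adjustor recovery experiment


def nvp_recovery_experiment(
    world: SyntheticWorld,
    a_star: Mapping[tuple[str, str], float],
    period: tuple[int, int] = (2012, 2018),
    wave_years: tuple[int, int] | None = (2011, 2015),
    n_reps: int = 200,
    n_per_wave: int = 25_000,
    seed: int = 0,
    tolerance_points: float = 1.5,
) -> pd.DataFrame:
    """Monte-Carlo recovery of an injected vaping adjustor from noisy surveys.

    The counterfactual 18+ trajectory is simulated once (deterministic); the
    true observed trajectory applies the injected annual adjustor ``a_star``
    per (gender, age group) from the period start.  Each replicate samples
    binomial surveys of ``n_per_wave`` respondents per gender/age-group cell
    and runs the indirect-inference pipeline on an 18+ aggregate.  The
    emulated instrument has no wave in the period-start year: the start
    estimate is the 60/40 weighted blend of the bracketing ``wave_years``
    (as with a periodic survey supplement), with its variance combined
    accordingly; pass ``wave_years=None`` for an annual survey observed
    directly at both endpoints.  The recovery target is the estimator's
    noiseless value, so the reported error is pure sampling error.

    Returns one row per (replicate, gender) with the estimated and true net
    impact over the period, the absolute-error success flag (within
    ``tolerance_points`` percentage points of truth) and a CI-coverage flag
    using the delta-method 95% interval propagated from all waves.
    """
    y0, y1 = period
    sampled_years = sorted(set((wave_years or (y0,)) + (y0, y1)) - ({y0} if wave_years else set()))
    sim_start = min(sampled_years + [y0])
    baseline = run_counterfactual(
        world, None, range(sim_start, y1 + 1), label="no_policy_counterfactual"
    )
    groups = list(ADULT_AGE_GROUPS)
    truth_rows = []
    for gender in GENDERS:
        for group in groups:
            for year in sampled_years:
                truth_rows.append(
                    {
                        "gender": gender,
                        "age_group": group,
                        "year": year,
                        "prevalence": baseline.prevalence_at(year, gender, group),
                    }
                )
    truth = inject_nvp_effect(pd.DataFrame(truth_rows), a_star, start_year=y0)

    # population weights for the 18+ aggregate, per gender, from the world
    weights = {}
    for gender in GENDERS:
        st = baseline.state_for(y0)
        g = GENDERS.index(gender)
        weights[gender] = {
            grp: float(st.counts[g, lo:hi].sum())
            for grp, (lo, hi) in ADULT_AGE_GROUPS.items()
        }

    Z95 = 1.959963984540054

    def blend(row_before, row_after):
        """60/40 wave blend with matching standard-error combination."""
        from .nvp_inference import WAVE_WEIGHT_AFTER, WAVE_WEIGHT_BEFORE, interpolate_wave

        p = interpolate_wave(row_before["prevalence"], row_after["prevalence"])
        se_b = (row_before["ci_upper"] - row_before["ci_lower"]) / (2 * Z95)
        se_a = (row_after["ci_upper"] - row_after["ci_lower"]) / (2 * Z95)
        se = np.sqrt((WAVE_WEIGHT_BEFORE * se_b) ** 2 + (WAVE_WEIGHT_AFTER * se_a) ** 2)
        return float(p), float(se)

    # gender shares of the adult population, for the overall pooled estimate
    gender_w = np.array([sum(weights[g].values()) for g in GENDERS])
    gender_w = gender_w / gender_w.sum()

    n_years = y1 - y0
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        sample = gen_survey_series(
            truth, n_per_wave, seed=int(rng.integers(2**31)), survey="synthetic"
        )
        per_gender = {}
        for gender in GENDERS:
            sub = sample[sample["gender"] == gender]
            agg = aggregate_18plus(sub, weights[gender]).set_index("year")
            true_sub = aggregate_truth_18plus(truth, weights[gender], gender)
            if wave_years:
                p0, se0 = blend(agg.loc[wave_years[0]], agg.loc[wave_years[1]])
                true_p0 = (
                    0.6 * true_sub[wave_years[0]] + 0.4 * true_sub[wave_years[1]]
                )
            else:
                row0 = agg.loc[y0]
                p0 = float(row0["prevalence"])
                se0 = float((row0["ci_upper"] - row0["ci_lower"]) / (2 * Z95))
                true_p0 = true_sub[y0]
            p1_row = agg.loc[y1]
            p1 = float(p1_row["prevalence"])
            se1 = float((p1_row["ci_upper"] - p1_row["ci_lower"]) / (2 * Z95))
            per_gender[gender] = {
                "p0": p0, "se0": se0, "true_p0": true_p0,
                "p1": p1, "se1": se1, "true_p1": true_sub[y1],
                "sim_p0": baseline.prevalence_at(y0, gender),
                "sim_p1": baseline.prevalence_at(y1, gender),
            }
        # overall adult estimate: gender-weighted pooling of the same cells
        per_gender["overall"] = {
            key: float(
                np.sqrt(sum(
                    (w * per_gender[g][key]) ** 2
                    for w, g in zip(gender_w, GENDERS)
                ))
            )
            if key.startswith("se")
            else float(sum(w * per_gender[g][key] for w, g in zip(gender_w, GENDERS)))
            for key in ("p0", "se0", "true_p0", "p1", "se1", "true_p1",
                        "sim_p0", "sim_p1")
        }
        for gender, d in per_gender.items():
            survey_R = relative_reduction(d["p0"], d["p1"])
            sim_R = relative_reduction(d["sim_p0"], d["sim_p1"])
            est_net = nvp_net_impact(sim_R, survey_R)
            est_adj = annualize(survey_R, n_years) - annualize(sim_R, n_years)

            true_R = relative_reduction(d["true_p0"], d["true_p1"])
            true_net = nvp_net_impact(sim_R, true_R)
            true_adj = annualize(true_R, n_years) - annualize(sim_R, n_years)

            ratio = d["p1"] / d["p0"]
            se_R = ratio * np.sqrt(
                (d["se1"] / d["p1"]) ** 2 + (d["se0"] / d["p0"]) ** 2
            )
            ci = (est_net - Z95 * se_R, est_net + Z95 * se_R)

            rows.append(
                {
                    "replicate": rep,
                    "gender": gender,
                    "net_impact_est": est_net,
                    "net_impact_true": true_net,
                    "adjustor_est": est_adj,
                    "adjustor_true": true_adj,
                    "abs_error_points": abs(est_net - true_net) * 100,
                    "within_tolerance": abs(est_net - true_net) * 100
                    <= tolerance_points,
                    "ci_covers_truth": ci[0] <= true_net <= ci[1],
                }
            )
    return pd.DataFrame(rows)


def aggregate_truth_18plus(
    truth: pd.DataFrame, weights: Mapping[str, float], gender: str
) -> dict[int, float]:
    """Noiseless population-weighted 18+ prevalence per year for one gender."""
    w = pd.Series(weights, dtype=float)
    w = w / w.sum()
    out = {}
    for year, cell in truth[truth["gender"] == gender].groupby("year"):
        cell = cell.set_index("age_group").reindex(w.index)
        out[int(year)] = float((w * cell["prevalence"]).sum())
    return out


# --------------------------------------------------------------------------
# Run manifests


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    scenario: str
    seed: int | None
    config_paths: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S%z")
    )

    def register(self, name: str, path) -> None:
        self.outputs[name] = str(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
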