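"""Synthetic worlds with known ground truth.

Every stage of the pipeline is testable without external data: this module
generates an internally consistent starting population, mortality schedules,
transition rates, policy schedules, noisy survey series, and an injected
"true" vaping effect, all from a single seed.

What the generator emulates: single-age population counts with a gently
declining old-age pyramid; never/current-smoker death-rate schedules with a
Gompertz-shaped never-smoker rate and a smoker relative risk ramping up
through mid-life; a cross-sectional smoking prevalence curve rising from
age 10 to a gender-specific peak then declining with age; former smokers
spread over years-since-quit bins consistent with time since the peak; and
binomial survey sampling with normal-approximation (optionally Wilson)
confidence intervals.  What it does not emulate: survey design effects,
nonresponse, mode effects, cohort-specific initiation history, or
cause-specific mortality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import (
    ADULT_AGE_GROUPS,
    FEMALE,
    GENDERS,
    MALE,
    N_AGES,
    N_BINS,
    N_STATUS,
    QUIT_BIN_WIDTHS,
    STATUS_CURRENT,
    STATUS_FORMER0,
    STATUS_NEVER,
    DemographyDrivers,
    MortalitySchedule,
    PopulationState,
    RRLadder,
)
from .transitions import (
    FIRST_INITIATION_AGE,
    PeakAges,
    TransitionRates,
    net_initiation_from_cross_section,
)

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    Defaults describe a population of 1e5 persons per gender with adult
    smoking prevalence in the low twenties of percent, a never-smoker
    mortality doubling roughly every 8 years of age, a smoker relative risk
    of 2.5 in mid-life, and surveys of 25,000 respondents per gender and
    age-group cell per wave.
    """

    seed: int = 0
    persons_per_gender: float = 100_000.0
    start_year: int = 2006
    end_year: int = 2020
    peak_prevalence: tuple[float, float] = (0.28, 0.24)  # male, female
    old_age_decline: float = 0.004  # absolute prevalence drop per year of age
    pyramid_decline_age: int = 50  # cohort sizes shrink linearly beyond this age
    gompertz_rate: float = 0.085
    death_rate_at_80: float = 0.05  # never smokers
    smoker_rr_max: float = 2.5
    rr_ramp_ages: tuple[int, int] = (18, 45)
    cessation_rate: float = 0.045
    relapse_by_bin: tuple[float, ...] = (0.12, 0.08, 0.05, 0.03, 0.02, 0.01)
    peak_ages: PeakAges = field(default_factory=PeakAges)
    true_adjustor: Mapping[tuple[str, str], float] | None = None
    nvp_start_year: int = 2012
    survey_n_per_wave: int = 25_000

    def __post_init__(self) -> None:
        if self.persons_per_gender <= 0:
            raise ValueError("persons_per_gender must be positive")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        for p in self.peak_prevalence:
            if not 0 <= p < 1:
                raise ValueError("peak prevalence must lie in [0, 1)")
        if any(np.diff(self.relapse_by_bin) > 0):
            raise ValueError("relapse rates must be non-increasing in quit bin")


@dataclass
class SyntheticWorld:
    """A complete, internally consistent set of simulation inputs."""

    config: WorldConfig
    initial_state: PopulationState
    mortality: MortalitySchedule
    rates: TransitionRates
    drivers: DemographyDrivers
    ladder: RRLadder
    peak_ages: PeakAges


def _cohort_sizes(config: WorldConfig) -> np.ndarray:
    """Persons per single age, shrinking linearly past the pyramid knee."""
    sizes = np.ones(N_AGES)
    knee = config.pyramid_decline_age
    old = np.arange(knee, N_AGES)
    sizes[old] = np.maximum(1.0 - (old - knee) / (N_AGES - knee), 0.02)
    return sizes / sizes.sum() * config.persons_per_gender


def prevalence_curve(config: WorldConfig, gender: int) -> np.ndarray:
    """Cross-sectional current-smoking prevalence by single age."""
    peak_age = config.peak_ages.for_gender(gender)
    peak = config.peak_prevalence[gender]
    prev = np.zeros(N_AGES)
    rise = np.arange(FIRST_INITIATION_AGE, peak_age + 1)
    prev[rise] = peak * (rise - FIRST_INITIATION_AGE) / (peak_age - FIRST_INITIATION_AGE)
    older = np.arange(peak_age + 1, N_AGES)
    floor = min(0.02, peak)  # old-age prevalence never quite reaches zero
    prev[older] = np.maximum(peak - config.old_age_decline * (older - peak_age), floor)
    return prev


def _former_bin_split(years_since_peak: int) -> np.ndarray:
    """Spread former smokers over quit bins, uniform in years since quitting."""
    horizon = max(min(years_since_peak, 40), 1)
    weights = np.zeros(N_BINS)
    edges = np.cumsum([0] + [w if np.isfinite(w) else horizon for w in QUIT_BIN_WIDTHS])
    for b in range(N_BINS):
        lo, hi = edges[b], min(edges[b + 1], horizon)
        weights[b] = max(hi - lo, 0.0)
    total = weights.sum()
    return weights / total if total > 0 else np.eye(N_BINS)[0]


def gen_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a synthetic world from its configuration.

    The starting population's prevalence curve below each gender's peak age
    is exactly reproducible by forward replay of the generated net
    initiation rates (never-smoker hazards), and the mortality schedule
    satisfies ``d_current >= d_never`` everywhere.
    """
    ages = np.arange(N_AGES)
    sizes = _cohort_sizes(config)

    counts = np.zeros((len(GENDERS), N_AGES, N_STATUS))
    init_rates = np.zeros((len(GENDERS), N_AGES))
    for g in (MALE, FEMALE):
        peak_age = config.peak_ages.for_gender(g)
        prev = prevalence_curve(config, g)
        ever = prev.copy()
        older = ages > peak_age
        ever[older] = config.peak_prevalence[g]  # quitting, not never-smoking, above peak
        never = 1.0 - ever
        former_total = ever - prev
        counts[g, :, STATUS_NEVER] = sizes * never
        counts[g, :, STATUS_CURRENT] = sizes * prev
        for a in ages[older]:
            counts[g, a, STATUS_FORMER0:] = (
                sizes[a] * former_total[a] * _former_bin_split(int(a - peak_age))
            )
        init_rates[g] = net_initiation_from_cross_section(prev, never, peak_age)

    state = PopulationState(year=config.start_year, counts=counts)

    a0 = config.death_rate_at_80 / np.exp(config.gompertz_rate * 80)
    d_never_age = np.minimum(a0 * np.exp(config.gompertz_rate * ages), 0.7)
    lo, hi = config.rr_ramp_ages
    rr = 1.0 + (config.smoker_rr_max - 1.0) * np.clip((ages - lo) / (hi - lo), 0, 1)
    d_current_age = np.minimum(d_never_age * rr, 0.95)
    years = range(config.start_year, config.end_year + 1)
    mortality = MortalitySchedule.constant(d_never_age, d_current_age, years)

    cess = np.zeros((len(GENDERS), N_AGES))
    relapse = np.zeros((len(GENDERS), N_AGES, N_BINS))
    for g in (MALE, FEMALE):
        peak_age = config.peak_ages.for_gender(g)
        cess[g, peak_age + 1 :] = config.cessation_rate
        relapse[g, peak_age + 1 :, :] = np.asarray(config.relapse_by_bin)
    rates = TransitionRates(net_initiation=init_rates, cessation=cess, relapse=relapse)

    births = {
        y: np.array([sizes[0], sizes[0]]) for y in range(config.start_year, config.end_year)
    }
    drivers = DemographyDrivers(births=births)

    return SyntheticWorld(
        config=config,
        initial_state=state,
        mortality=mortality,
        rates=rates,
        drivers=drivers,
        ladder=RRLadder(),
        peak_ages=config.peak_ages,
    )


# --------------------------------------------------------------------------
# Survey sampling


def _ci(phat: np.ndarray, n: int, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "normal":
        se = np.sqrt(np.clip(phat * (1 - phat), 0, None) / n)
        return np.clip(phat - Z95 * se, 0, 1), np.clip(phat + Z95 * se, 0, 1)
    if method == "wilson":
        z2 = Z95**2
        denom = 1 + z2 / n
        centre = (phat + z2 / (2 * n)) / denom
        half = Z95 * np.sqrt(phat * (1 - phat) / n + z2 / (4 * n**2)) / denom
        return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)
    raise ValueError(f"unknown CI method {method!r}")


def gen_survey_series(
    truth: pd.DataFrame,
    n_per_wave: int,
    seed: int,
    survey: str = "synthetic",
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Sample a noisy survey series around a true prevalence trajectory.

    ``truth`` is a long frame with columns gender, age_group, year,
    prevalence (fractions).  Each row is sampled independently as a binomial
    proportion with ``n_per_wave`` respondents; 95% CIs use the normal
    approximation by default (symmetric, as published survey tables
    typically report) or Wilson intervals.
    """
    if n_per_wave <= 0:
        raise ValueError("n_per_wave must be positive")
    rng = np.random.default_rng(seed)
    p = truth["prevalence"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("true prevalences must lie in [0, 1]")
    phat = rng.binomial(n_per_wave, p) / n_per_wave
    lo, hi = _ci(phat, n_per_wave, ci_method)
    out = truth[["gender", "age_group", "year"]].copy()
    out.insert(0, "survey", survey)
    out["prevalence"] = phat
    out["ci_lower"] = lo
    out["ci_upper"] = hi
    out["n"] = n_per_wave
    return out


def aggregate_18plus(series: pd.DataFrame, weights: Mapping[str, float]) -> pd.DataFrame:
    """Pool age-group rows into an 18+ estimate per (survey, gender, year).

    ``weights`` maps age-group labels to population shares (normalised
    internally).  The pooled point estimate is the weighted mean; the pooled
    standard error combines cell standard errors as ``sqrt(sum w_i^2
    se_i^2)``, from which symmetric 95% bounds are rebuilt.
    """
    w = pd.Series(weights, dtype=float)
    w = w / w.sum()
    rows = []
    for (survey, gender, year), cell in series.groupby(["survey", "gender", "year"]):
        cell = cell.set_index("age_group").reindex(w.index)
        if cell["prevalence"].isna().any():
            raise ValueError(f"missing age-group rows for {survey}/{gender}/{year}")
        p = float((w * cell["prevalence"]).sum())
        se_cells = (cell["ci_upper"] - cell["ci_lower"]) / (2 * Z95)
        se = float(np.sqrt((w**2 * se_cells**2).sum()))
        rows.append(
            {
                "survey": survey,
                "gender": gender,
                "age_group": "18+",
                "year": year,
                "prevalence": p,
                "ci_lower": max(p - Z95 * se, 0.0),
                "ci_upper": min(p + Z95 * se, 1.0),
            }
        )
    return pd.DataFrame(rows)


def inject_nvp_effect(
    truth: pd.DataFrame, a_star: float | Mapping[tuple[str, str], float], start_year: int
) -> pd.DataFrame:
    """Scale a true trajectory by ``(1 - a*)**(t - start_year)`` from ``start_year``.

    ``a_star`` may be a single annual rate or a mapping from (gender,
    age_group) to rates.  Years at or before ``start_year`` are unchanged.
    """
    out = truth.copy()

    def rate(row) -> float:
        if isinstance(a_star, Mapping):
            return float(a_star.get((row.gender, row.age_group), 0.0))
        return float(a_star)

    factors = np.array(
        [
            (1.0 - rate(row)) ** max(row.year - start_year, 0)
            for row in out.itertuples(index=False)
        ]
    )
    if np.any(factors < 0):
        raise ValueError("annual adjustor must be below 1")
    out["prevalence"] = out["prevalence"].to_numpy() * factors
    return out
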