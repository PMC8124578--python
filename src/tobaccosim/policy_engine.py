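"""Translate tobacco-control policy schedules into simulation deltas.

Policies act on the model through three channels:

* a *first-year prevalence shock* -- a fractional reduction of current
  smokers in the year a policy is newly implemented or strengthened,
  computed on the residual scale from the increment over the policy's
  previous level;
* an ongoing *initiation delta* -- a fractional reduction of net initiation
  rates for every year the policy is in effect;
* an ongoing *cessation delta* -- a fractional increase of cessation rates
  for every year the policy is in effect.

Effect sizes for smoke-free air laws are deflated for imperfect enforcement
and publicity by ``0.5 * (1 + 0.5 * publicity + 0.5 * enforcement / 10)``
(so effects are halved when both are absent, and undiminished at full
enforcement with publicity); marketing restrictions use the enforcement-only
analogue.  Simultaneous policies combine multiplicatively on the residual
scale: a set of fractional reductions ``e_i`` yields ``1 - prod(1 - e_i)``.

Cigarette price changes act through age-specific price elasticities: a
relative price change ``dp / p`` shifts smoking prevalence by
``elasticity * dp / p`` in that year's shock channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .demography import (
    N_AGES,
    STATUS_CURRENT,
    STATUS_FORMER0,
    STATUS_NEVER,
    GENDERS,
    PopulationState,
)
from .transitions import PeakAges

log = logging.getLogger(__name__)

POLICIES = (
    "price",
    "smoke_free_air",
    "media",
    "marketing",
    "cessation_treatment",
    "youth_access",
)

#: Ban-strength weights for worksite bans: a full ban counts fully, one with
#: ventilated smoking areas is reduced by one third, one merely restricting
#: to common areas by two thirds.
WORKSITE_STRENGTH_WEIGHTS = {"high": 1.0, "mid": 2.0 / 3.0, "low": 1.0 / 3.0}

YOUTH_BANDS = {"10-15": (10, 16), "16-17": (16, 18)}


def deflate_effect(
    base_effect: float, enforcement: float, publicity: int | bool
) -> float:
    """Deflate a policy effect size for enforcement (0-10) and publicity (0/1).

    Returns ``base_effect * 0.5 * (1 + 0.5 * publicity + 0.5 * enforcement/10)``,
    which ranges from half the base effect (no enforcement, no publicity) to
    the full base effect (enforcement 10 with publicity).
    """
    if not 0 <= enforcement <= 10:
        raise ValueError("enforcement must lie in [0, 10]")
    pub = int(bool(publicity))
    if publicity not in (0, 1, True, False):
        raise ValueError("publicity must be a 0/1 indicator")
    return base_effect * 0.5 * (1.0 + 0.5 * pub + 0.5 * enforcement / 10.0)


def combine_effects(effects: Iterable[float]) -> float:
    """Combine fractional reductions multiplicatively on the residual scale.

    ``1 - prod(1 - e_i)``: order-invariant, at least as large as any single
    effect, and strictly below 1.  Negative entries (effect reversals from
    policy rollback) are permitted; entries >= 1 are rejected.
    """
    residual = 1.0
    for e in effects:
        if e >= 1.0:
            raise ValueError("individual effects must be below 1")
        residual *= 1.0 - e
    return 1.0 - residual


def combine_increases(effects: Iterable[float]) -> float:
    """Combine fractional increases multiplicatively: ``prod(1 + c_i) - 1``."""
    out = 1.0
    for c in effects:
        out *= 1.0 + c
    return out - 1.0


def price_effect(
    price_old: float,
    price_new: float,
    elasticity: float,
    form: str = "relative",
) -> float:
    """Relative change in smoking prevalence implied by a price change.

    The default functional form is ``elasticity * (price_new - price_old) /
    price_old``; ``form="log"`` uses ``elasticity * ln(price_new /
    price_old)`` instead.  With a negative elasticity, a price rise yields a
    negative value (prevalence falls).
    """
    if price_old <= 0 or price_new <= 0:
        raise ValueError("prices must be positive")
    if form == "relative":
        return elasticity * (price_new - price_old) / price_old
    if form == "log":
        return elasticity * float(np.log(price_new / price_old))
    raise ValueError(f"unknown price equation form {form!r}")


def incremental_effect(effect_old_level: float, effect_new_level: float) -> float:
    """Residual-scale increment between two levels of the same policy.

    ``1 - (1 - new) / (1 - old)``: the additional fractional reduction needed
    on top of the old level to reach the new one.  Negative when the policy
    is rolled back.
    """
    for e in (effect_old_level, effect_new_level):
        if not e < 1.0:
            raise ValueError("effects must be below 1")
    return 1.0 - (1.0 - effect_new_level) / (1.0 - effect_old_level)


# --------------------------------------------------------------------------
# Effect-size constants


def _default_elasticities() -> tuple[tuple[int, int, float], ...]:
    # (age_lo, age_hi_inclusive, elasticity)
    return ((14, 17, -0.6), (18, 24, -0.4), (25, 34, -0.2), (35, 64, -0.1), (65, 99, -0.2))


@dataclass(frozen=True)
class EffectSizeTable:
    """Per-policy effect-size constants.

    Fractional reductions apply to prevalence (first-year) and initiation
    (ongoing); fractional increases apply to cessation (ongoing).  The
    cessation-treatment block carries a combined full-package figure used to
    calibrate the multiplicative combination of its components.
    """

    elasticities: tuple[tuple[int, int, float], ...] = field(
        default_factory=_default_elasticities
    )
    smoke_free_air: Mapping[str, float] = field(
        default_factory=lambda: {
            "worksite": 0.06,
            "restaurant": 0.02,
            "bar": 0.01,
            "other": 0.01,
        }
    )
    media: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.065, "moderate": 0.0325, "minimal": 0.0163}
    )
    marketing: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "comprehensive": {"prevalence": 0.05, "initiation": 0.08, "cessation": 0.04},
            "moderate": {"prevalence": 0.03, "initiation": 0.04, "cessation": 0.02},
            "minimal": {"prevalence": 0.01, "initiation": 0.01, "cessation": 0.0},
        }
    )
    cessation_treatment: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "pharmacotherapy": {"prevalence": 0.01, "cessation": 0.04},
            "coverage": {"prevalence": 0.0225, "cessation": 0.08},
            "quitline": {"prevalence": 0.01, "cessation": 0.06},
            "brief_intervention": {"prevalence": 0.01, "cessation": 0.06},
        }
    )
    cessation_full_package: Mapping[str, float] = field(
        default_factory=lambda: {"prevalence": 0.0568, "cessation": 0.294}
    )
    youth_access: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "none": {"16-17": 0.0, "10-15": 0.0},
            "low": {"16-17": 0.02, "10-15": 0.03},
            "mid": {"16-17": 0.08, "10-15": 0.12},
            "strong": {"16-17": 0.16, "10-15": 0.24},
        }
    )

    def elasticity_by_age(self) -> np.ndarray:
        """Length-100 vector of price elasticities (0 outside defined bands)."""
        eps = np.zeros(N_AGES)
        for lo, hi, e in self.elasticities:
            eps[lo : hi + 1] = e
        return eps

    def scaled(self, factors: Mapping[str, float]) -> "EffectSizeTable":
        """Scale per-policy effect magnitudes by ``factors`` (policy -> multiplier).

        Used for sensitivity analysis; elasticity magnitudes scale under the
        ``"price"`` key.  Unlisted policies are unchanged.
        """

        def scale_map(m: Mapping[str, float], f: float) -> dict[str, float]:
            return {k: v * f for k, v in m.items()}

        def scale_nested(m, f):
            return {k: scale_map(v, f) for k, v in m.items()}

        out = self
        if "price" in factors:
            f = factors["price"]
            out = replace(
                out,
                elasticities=tuple((lo, hi, e * f) for lo, hi, e in out.elasticities),
            )
        if "smoke_free_air" in factors:
            out = replace(
                out, smoke_free_air=scale_map(out.smoke_free_air, factors["smoke_free_air"])
            )
        if "media" in factors:
            out = replace(out, media=scale_map(out.media, factors["media"]))
        if "marketing" in factors:
            out = replace(out, marketing=scale_nested(out.marketing, factors["marketing"]))
        if "cessation_treatment" in factors:
            f = factors["cessation_treatment"]
            out = replace(
                out,
                cessation_treatment=scale_nested(out.cessation_treatment, f),
                cessation_full_package=scale_map(out.cessation_full_package, f),
            )
        if "youth_access" in factors:
            out = replace(
                out, youth_access=scale_nested(out.youth_access, factors["youth_access"])
            )
        return out


# --------------------------------------------------------------------------
# Policy schedules


def _interp_anchor_series(anchors: Mapping[int, float], years: Sequence[int]) -> dict:
    """Linearly interpolate an anchor-year series onto a full year range.

    Values before the first anchor hold the first value; values after the
    last anchor hold the last.
    """
    ax = sorted(anchors)
    ay = [float(anchors[a]) for a in ax]
    return {
        int(y): float(np.interp(y, ax, ay)) for y in years
    }


def _interp_mix(anchors: Mapping[int, Mapping[str, float]], years, keys) -> dict:
    """Interpolate mixture weights per key, renormalising to sum 1."""
    out = {}
    per_key = {
        k: _interp_anchor_series({y: m.get(k, 0.0) for y, m in anchors.items()}, years)
        for k in keys
    }
    for y in years:
        w = {k: per_key[k][y] for k in keys}
        total = sum(w.values())
        if total <= 0:
            raise ValueError(f"mixture weights sum to zero in {y}")
        out[int(y)] = {k: v / total for k, v in w.items()}
    return out


def _step_series(anchors: Mapping[int, str], years) -> dict:
    ax = sorted(anchors)
    out = {}
    for y in years:
        prior = [a for a in ax if a <= y]
        out[int(y)] = anchors[prior[-1]] if prior else anchors[ax[0]]
    return out


@dataclass
class PolicySchedule:
    """Resolved year-by-year policy levels.

    All mappings are keyed by calendar year over ``years``; construct from a
    compact anchor-year YAML file with :meth:`from_yaml` (linear
    interpolation for numeric levels, step interpolation for categorical
    ones).
    """

    years: tuple[int, ...]
    price: dict[int, float]
    sfa_coverage: dict[int, dict]  # worksite: strength shares; other venues: fraction
    sfa_enforcement: float
    media_mix: dict[int, dict[str, float]]
    marketing_mix: dict[int, dict[str, float]]
    marketing_enforcement: float
    cessation_coverage: dict[int, dict[str, float]]
    youth_access: dict[int, str]

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        for y in self.years:
            for m in (self.price, self.sfa_coverage, self.media_mix,
                      self.marketing_mix, self.cessation_coverage, self.youth_access):
                if y not in m:
                    raise ValueError(f"policy schedule does not cover year {y}")
            mix = self.media_mix[y]
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"media mixture weights must sum to 1 in {y}")
            for venue, cov in self.sfa_coverage[y].items():
                vals = cov.values() if isinstance(cov, Mapping) else [cov]
                if any(not 0 <= v <= 1 for v in vals):
                    raise ValueError(f"coverage fractions out of [0, 1] in {y}/{venue}")
        if not 0 <= self.sfa_enforcement <= 10:
            raise ValueError("enforcement must lie in [0, 10]")

    @classmethod
    def from_yaml(cls, path) -> "PolicySchedule":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PolicySchedule":
        start, end = int(raw["years"]["start"]), int(raw["years"]["end"])
        years = tuple(range(start, end + 1))
        sfa = raw["smoke_free_air"]
        worksite = {
            int(y): v for y, v in sfa["worksite"].items()
        }
        worksite_by_year = {
            s: _interp_anchor_series({y: m.get(s, 0.0) for y, m in worksite.items()}, years)
            for s in WORKSITE_STRENGTH_WEIGHTS
        }
        sfa_cov = {}
        venue_series = {
            v: _interp_anchor_series(sfa[v], years) for v in ("restaurant", "bar", "other")
        }
        for y in years:
            sfa_cov[y] = {
                "worksite": {s: worksite_by_year[s][y] for s in WORKSITE_STRENGTH_WEIGHTS},
                **{v: venue_series[v][y] for v in ("restaurant", "bar", "other")},
            }
        media_keys = sorted({k for m in raw["media"].values() for k in m})
        marketing = raw["marketing"]
        marketing_keys = sorted({k for m in marketing["levels"].values() for k in m})
        cess = raw["cessation_treatment"]
        cess_cov = {
            comp: _interp_anchor_series(series, years) for comp, series in cess.items()
        }
        return cls(
            years=years,
            price=_interp_anchor_series(raw["price"], years),
            sfa_coverage=sfa_cov,
            sfa_enforcement=float(sfa.get("enforcement", 8)),
            media_mix=_interp_mix(raw["media"], years, media_keys),
            marketing_mix=_interp_mix(marketing["levels"], years, marketing_keys),
            marketing_enforcement=float(marketing.get("enforcement", 9)),
            cessation_coverage={
                y: {comp: cess_cov[comp][y] for comp in cess_cov} for y in years
            },
            youth_access=_step_series(raw["youth_access"], years),
        )

    @classmethod
    def default(cls) -> "PolicySchedule":
        """The packaged US policy-level schedule, 1993-2019."""
        ref = resources.files("tobaccosim.data").joinpath("us_policy_schedule.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def extended_to(self, end_year: int) -> "PolicySchedule":
        """Hold every policy at its final level through ``end_year``."""
        if end_year <= self.years[-1]:
            return self
        last = self.years[-1]
        years = tuple(range(self.years[0], end_year + 1))

        def extend(m):
            out = dict(m)
            for y in range(last + 1, end_year + 1):
                out[y] = m[last]
            return out

        return PolicySchedule(
            years=years,
            price=extend(self.price),
            sfa_coverage=extend(self.sfa_coverage),
            sfa_enforcement=self.sfa_enforcement,
            media_mix=extend(self.media_mix),
            marketing_mix=extend(self.marketing_mix),
            marketing_enforcement=self.marketing_enforcement,
            cessation_coverage=extend(self.cessation_coverage),
            youth_access=extend(self.youth_access),
        )

    def frozen_at(
        self, year: int, policies: Sequence[str] | None = None
    ) -> "PolicySchedule":
        """Hold the given policies (default: all) constant at their ``year`` level.

        Years before ``year`` are unchanged; this is the 'no further policy
        change' counterfactual device.
        """
        policies = set(POLICIES if policies is None else policies)
        unknown = policies - set(POLICIES)
        if unknown:
            raise ValueError(f"unknown policies {sorted(unknown)}")

        def freeze(m, active):
            if not active:
                return dict(m)
            return {y: (m[y] if y <= year else m[year]) for y in self.years}

        return PolicySchedule(
            years=self.years,
            price=freeze(self.price, "price" in policies),
            sfa_coverage=freeze(self.sfa_coverage, "smoke_free_air" in policies),
            sfa_enforcement=self.sfa_enforcement,
            media_mix=freeze(self.media_mix, "media" in policies),
            marketing_mix=freeze(self.marketing_mix, "marketing" in policies),
            marketing_enforcement=self.marketing_enforcement,
            cessation_coverage=freeze(
                self.cessation_coverage, "cessation_treatment" in policies
            ),
            youth_access=freeze(self.youth_access, "youth_access" in policies),
        )


# --------------------------------------------------------------------------
# Standing effects and deltas


def publicity_indicator(media_mix: Mapping[str, float]) -> int:
    """1 when media campaigns are at least at a medium level (weight >= 0.5)."""
    return int(media_mix.get("moderate", 0.0) + media_mix.get("high", 0.0) >= 0.5)


def _sfa_effects(
    coverage: Mapping, enforcement: float, publicity: int, effects: EffectSizeTable
) -> tuple[float, float, float]:
    """(prevalence, initiation, cessation) effects of smoke-free air laws."""
    prev_parts, cess_parts = [], []
    for venue, base in effects.smoke_free_air.items():
        cov = coverage[venue]
        if isinstance(cov, Mapping):  # worksite: shares by ban strength
            cov = sum(WORKSITE_STRENGTH_WEIGHTS[s] * cov.get(s, 0.0) for s in cov)
        e = deflate_effect(base * cov, enforcement, publicity)
        prev_parts.append(e)
        cess_parts.append(e)
    prev = combine_effects(prev_parts)
    return prev, prev, combine_increases(cess_parts)


def _media_effects(
    mix: Mapping[str, float], effects: EffectSizeTable
) -> tuple[float, float, float]:
    e = sum(w * effects.media.get(level, 0.0) for level, w in mix.items())
    return e, e, e


def _marketing_effects(
    mix: Mapping[str, float], enforcement: float, effects: EffectSizeTable
) -> tuple[float, float, float]:
    defl = 0.5 * (1.0 + enforcement / 10.0)
    prev = sum(w * effects.marketing[l]["prevalence"] for l, w in mix.items()) * defl
    init = sum(w * effects.marketing[l]["initiation"] for l, w in mix.items()) * defl
    cess = sum(w * effects.marketing[l]["cessation"] for l, w in mix.items()) * defl
    return prev, init, cess


def _cessation_effects(
    coverage: Mapping[str, float], effects: EffectSizeTable
) -> tuple[float, float]:
    """(prevalence, cessation) effect of the cessation-treatment package.

    Components scale with their coverage and combine multiplicatively; the
    combination is then calibrated so that a fully implemented package
    reproduces the stated combined effect (5.68% prevalence, +29.4%
    cessation by default), which is slightly above the raw product.
    """
    comps = effects.cessation_treatment
    raw_prev = combine_effects(
        comps[c]["prevalence"] * coverage.get(c, 0.0) for c in comps
    )
    raw_cess = combine_increases(
        comps[c]["cessation"] * coverage.get(c, 0.0) for c in comps
    )
    full_prev = combine_effects(comps[c]["prevalence"] for c in comps)
    full_cess = combine_increases(comps[c]["cessation"] for c in comps)
    prev_scale = effects.cessation_full_package["prevalence"] / full_prev
    cess_scale = effects.cessation_full_package["cessation"] / full_cess
    return raw_prev * prev_scale, raw_cess * cess_scale


def _youth_effect_vector(level: str, effects: EffectSizeTable) -> np.ndarray:
    out = np.zeros(N_AGES)
    for band, (lo, hi) in YOUTH_BANDS.items():
        out[lo:hi] = effects.youth_access[level][band]
    return out


def standing_effects(
    schedule: PolicySchedule, effects: EffectSizeTable, year: int
) -> dict[str, dict[str, np.ndarray]]:
    """Age-resolved standing effect vectors for each policy in one year.

    Returns ``{policy: {"prevalence": v, "initiation": v, "cessation": v}}``
    with length-100 age vectors (price is excluded -- it acts through price
    *changes*, not a standing level).
    """
    ones = np.ones(N_AGES)
    pub = publicity_indicator(schedule.media_mix[year])
    sfa = _sfa_effects(
        schedule.sfa_coverage[year], schedule.sfa_enforcement, pub, effects
    )
    med = _media_effects(schedule.media_mix[year], effects)
    mkt = _marketing_effects(
        schedule.marketing_mix[year], schedule.marketing_enforcement, effects
    )
    ct = _cessation_effects(schedule.cessation_coverage[year], effects)
    youth = _youth_effect_vector(schedule.youth_access[year], effects)
    return {
        "smoke_free_air": {
            "prevalence": sfa[0] * ones,
            "initiation": sfa[1] * ones,
            "cessation": sfa[2] * ones,
        },
        "media": {
            "prevalence": med[0] * ones,
            "initiation": med[1] * ones,
            "cessation": med[2] * ones,
        },
        "marketing": {
            "prevalence": mkt[0] * ones,
            "initiation": mkt[1] * ones,
            "cessation": mkt[2] * ones,
        },
        "cessation_treatment": {
            "prevalence": ct[0] * ones,
            "initiation": np.zeros(N_AGES),
            "cessation": ct[1] * ones,
        },
        "youth_access": {
            "prevalence": youth,
            "initiation": youth,
            "cessation": np.zeros(N_AGES),
        },
    }


@dataclass
class PolicyDeltas:
    """Per-year, age-resolved simulation deltas derived from a policy schedule.

    ``prevalence_shock[y]`` is the fractional reduction applied to current
    smokers at the start of year ``y``; ``initiation_delta`` and
    ``cessation_delta`` are fractional changes to that year's transition
    rates.  All are length-100 age vectors, identical across genders.
    """

    years: tuple[int, ...]
    prevalence_shock: dict[int, np.ndarray]
    initiation_delta: dict[int, np.ndarray]
    cessation_delta: dict[int, np.ndarray]

    def for_year(self, year: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if year not in self.prevalence_shock:
            zero = np.zeros(N_AGES)
            return zero, zero.copy(), zero.copy()
        return (
            self.prevalence_shock[year],
            self.initiation_delta[year],
            self.cessation_delta[year],
        )

    @classmethod
    def zeros(cls, years: Sequence[int]) -> "PolicyDeltas":
        years = tuple(int(y) for y in years)
        z = {y: np.zeros(N_AGES) for y in years}
        return cls(
            years=years,
            prevalence_shock={y: z[y].copy() for y in years},
            initiation_delta={y: z[y].copy() for y in years},
            cessation_delta={y: z[y].copy() for y in years},
        )


def schedule_to_deltas(
    schedule: PolicySchedule,
    effects: EffectSizeTable = EffectSizeTable(),
    years: Sequence[int] | None = None,
) -> PolicyDeltas:
    """Convert a policy schedule into yearly prevalence shocks and rate deltas.

    The first scheduled year carries no shock: its policy levels are part of
    the baseline to which the starting population is already calibrated.
    From the second year on, each policy contributes the residual-scale
    increment of its standing prevalence effect over the previous year, and
    price changes contribute ``-elasticity * dp / p`` by age band; increments
    combine multiplicatively.  Ongoing deltas reflect the standing initiation
    and cessation effects of all active policies in that year.
    """
    years = tuple(int(y) for y in (years or schedule.years))
    for y in years:
        if y not in schedule.price:
            raise ValueError(f"policy schedule does not cover year {y}")
    eps = effects.elasticity_by_age()
    shocks, inits, cesss = {}, {}, {}
    prev_standing = None
    for i, y in enumerate(years):
        standing = standing_effects(schedule, effects, y)

        shock = np.zeros(N_AGES)
        if i > 0:
            residual = np.ones(N_AGES)
            for policy, eff in standing.items():
                old = prev_standing[policy]["prevalence"]
                new = eff["prevalence"]
                inc = 1.0 - (1.0 - new) / (1.0 - old)
                residual *= 1.0 - inc
            p_old, p_new = schedule.price[years[i - 1]], schedule.price[y]
            price_red = -eps * (p_new - p_old) / p_old  # positive when price rises
            residual *= 1.0 - price_red
            shock = 1.0 - residual

        init_residual = np.ones(N_AGES)
        cess_factor = np.ones(N_AGES)
        for eff in standing.values():
            init_residual *= 1.0 - eff["initiation"]
            cess_factor *= 1.0 + eff["cessation"]
        shocks[y] = shock
        inits[y] = -(1.0 - init_residual)
        cesss[y] = cess_factor - 1.0
        prev_standing = standing
    return PolicyDeltas(
        years=years,
        prevalence_shock=shocks,
        initiation_delta=inits,
        cessation_delta=cesss,
    )


def apply_prevalence_shock(
    state: PopulationState,
    shock: np.ndarray,
    peak_ages: PeakAges = PeakAges(),
) -> PopulationState:
    """Apply a first-year prevalence shock to current smokers.

    A positive shock removes the given fraction of current smokers in each
    age cell; those below or at the gender's peak initiation age return to
    never smokers (the shock suppresses recent net initiation), those above
    it move to the <1-year former-smoker bin.  A negative shock (policy
    rollback or a price drop) draws persons back into smoking from the same
    pools, limited by the pool size.
    """
    shock = np.asarray(shock, dtype=float)
    if shock.shape != (N_AGES,):
        raise ValueError("shock must be a length-100 age vector")
    if np.any(shock >= 1.0):
        raise ValueError("shock fractions must be below 1")
    counts = state.counts.copy()
    ages = np.arange(N_AGES)
    for g in range(len(GENDERS)):
        peak = peak_ages.for_gender(g)
        young = ages <= peak
        removed = counts[g, :, STATUS_CURRENT] * shock
        # negative removals (re-entry) cannot exceed the source pool
        source = np.where(
            young, counts[g, :, STATUS_NEVER], counts[g, :, STATUS_FORMER0]
        )
        removed = np.maximum(removed, -source)
        counts[g, :, STATUS_CURRENT] -= removed
        counts[g, young, STATUS_NEVER] += removed[young]
        counts[g, ~young, STATUS_FORMER0] += removed[~young]
    return PopulationState(year=state.year, counts=counts)
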