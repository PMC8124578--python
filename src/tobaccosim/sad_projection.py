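"""Smoking-attributable deaths (SADs) and deaths averted.

A smoking-attributable death is the excess mortality of a smoker over a
never smoker: SADs in a year are ``sum_age current(age) * (d_current -
d_never) + sum_{age,bin} former(age, bin) * (d_former(bin) - d_never)``,
with former-smoker rates from the quit-bin relative-risk ladder.

Deaths averted compare a baseline (no-vaping counterfactual) scenario with
a vaping-adjusted scenario in which current-smoker prevalence is reduced
each year of the adjustment window by the annual vaping adjustor; removed
smokers are reallocated to never smokers below age 25 and to the <1-year
former-smoker bin at 25 and above, after which they follow ordinary
mortality and relapse dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import (
    ADULT_AGE_GROUPS,
    GENDERS,
    N_AGES,
    STATUS_CURRENT,
    STATUS_FORMER0,
    STATUS_NEVER,
    MortalitySchedule,
    PopulationState,
    RRLadder,
    former_death_rates,
)
from .nvp_inference import NVPAdjustor

log = logging.getLogger(__name__)

#: Removed smokers at or above this age become former smokers; below, never.
NEVER_REALLOCATION_AGE = 25


def compute_sads(
    state: PopulationState,
    mortality: MortalitySchedule,
    ladder: RRLadder = RRLadder(),
) -> np.ndarray:
    """Smoking-attributable deaths in the state's year, by gender.

    Returns a length-2 array (male, female).  Non-negative whenever current
    rates dominate former rates dominate never rates.
    """
    dn, dc = mortality.for_year(state.year)
    df = former_death_rates(dn, dc, ladder)
    current = state.counts[:, :, STATUS_CURRENT]
    former = state.counts[:, :, STATUS_FORMER0:]
    sads = (current * (dc - dn)).sum(axis=1)
    sads += (former * (df - dn[..., None])).sum(axis=(1, 2))
    return sads


@dataclass
class SADLedger:
    """Annual smoking-attributable deaths by gender, with optional ranges.

    ``data`` has index year and columns male, female, both (and, when
    ranges are attached, ``<col>_low`` / ``<col>_high``).
    """

    label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("male", "female", "both"):
            if col not in self.data.columns:
                raise ValueError(f"SAD ledger is missing column {col!r}")
        if not np.allclose(
            self.data["both"], self.data["male"] + self.data["female"], atol=1e-6
        ):
            raise ValueError("both-gender totals must equal male + female")

    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.data.index)

    def annual(self, year: int, column: str = "both") -> float:
        return float(self.data.loc[year, column])

    def cumulative(
        self, start: int, end: int, column: str = "both"
    ) -> float:
        """Sum of annual values over the closed year window [start, end]."""
        window = self.data.loc[start:end, column]
        if len(window) != end - start + 1:
            raise ValueError(f"ledger does not cover {start}-{end}")
        return float(window.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.data.reset_index(names="year")
        out.insert(0, "scenario", self.label)
        return out


def sad_ledger(
    states: Sequence[PopulationState],
    mortality: MortalitySchedule,
    ladder: RRLadder = RRLadder(),
    label: str = "baseline",
) -> SADLedger:
    """Build a SAD ledger from a sequence of yearly population states."""
    rows = {}
    for st in states:
        m, f = compute_sads(st, mortality, ladder)
        rows[st.year] = {"male": m, "female": f, "both": m + f}
    data = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    data.index.name = "year"
    return SADLedger(label=label, data=data)


def deaths_averted(
    baseline: SADLedger, adjusted: SADLedger, label: str | None = None
) -> SADLedger:
    """Year-by-year difference baseline minus adjusted (positive = averted).

    Ledgers must cover identical year sets.  When the adjusted scenario was
    run only for persons below a given age at adjustment time, the
    difference automatically tracks those birth cohorts as they age.
    """
    if baseline.years() != adjusted.years():
        raise ValueError("ledgers must cover identical years")
    cols = ["male", "female", "both"]
    diff = baseline.data[cols] - adjusted.data[cols]
    return SADLedger(label=label or f"{baseline.label} - {adjusted.label}", data=diff)


def make_adjustment_hook(
    adjustors: Mapping[tuple[str, str], NVPAdjustor | float],
    start_year: int = 2012,
    end_year: int = 2018,
    max_age: int | None = 45,
    which: str = "annual",
) -> Callable[[PopulationState], PopulationState]:
    """Build a per-year hook applying the vaping adjustment to a state.

    For each year in ``(start_year, end_year]`` the hook removes the
    fraction ``a`` of current smokers in every (gender, age-group) cell with
    an adjustor, so the cumulative effect by the end of the window is
    ``(1 - a)**(end_year - start_year)`` relative to baseline (before
    dynamics).  After ``end_year`` the hook is inert and the accumulated
    reduction persists through ordinary dynamics.

    ``max_age`` restricts the adjustment to persons below that age at
    adjustment time (cohort restriction); ``None`` adjusts all ages with an
    adjustor.  ``which`` selects the point estimate (``"annual"``) or a
    bound (``"low"``/``"high"``).  Negative adjustors (vaping-related
    increases in smoking) move persons back into smoking from the
    reallocation pool, limited by the pool size and logged.
    """

    def value(a) -> float:
        if isinstance(a, NVPAdjustor):
            return getattr(a, "annual" if which == "annual" else which)
        return float(a)

    groups = {
        key: (ADULT_AGE_GROUPS[group], value(a))
        for key, a in adjustors.items()
        for group in [key[1]]
    }

    def hook(state: PopulationState) -> PopulationState:
        if not (start_year < state.year <= end_year):
            return state
        counts = state.counts.copy()
        for (gender, _group), ((lo, hi), a) in groups.items():
            if a == 0.0:
                continue
            g = GENDERS.index(gender)
            hi_eff = min(hi, max_age) if max_age is not None else hi
            if hi_eff <= lo:
                continue
            ages = np.arange(lo, hi_eff)
            removed = counts[g, ages, STATUS_CURRENT] * a
            if a < 0:
                # re-entry into smoking: draw from the destination pools
                never_src = ages < NEVER_REALLOCATION_AGE
                pool = np.where(
                    never_src,
                    counts[g, ages, STATUS_NEVER],
                    counts[g, ages, STATUS_FORMER0],
                )
                clipped = np.maximum(removed, -pool)
                if np.any(clipped > removed):
                    log.warning(
                        "negative adjustor limited by pool size for %s/%s in %d",
                        gender,
                        _group,
                        state.year,
                    )
                removed = clipped
            counts[g, ages, STATUS_CURRENT] -= removed
            young = ages[ages < NEVER_REALLOCATION_AGE]
            old = ages[ages >= NEVER_REALLOCATION_AGE]
            counts[g, young, STATUS_NEVER] += removed[ages < NEVER_REALLOCATION_AGE]
            counts[g, old, STATUS_FORMER0] += removed[ages >= NEVER_REALLOCATION_AGE]
        return PopulationState(year=state.year, counts=counts)

    return hook


if TYPE_CHECKING:  # pragma: no cover
    from .workbench import ScenarioResult


def apply_nvp_adjustment(
    baseline: "ScenarioResult",
    adjustors: Mapping[tuple[str, str], NVPAdjustor | float],
    start_year: int = 2012,
    end_year: int = 2018,
    max_age: int | None = 45,
    which: str = "annual",
    label: str | None = None,
) -> "ScenarioResult":
    """Re-run a baseline scenario with the vaping adjustment applied.

    The baseline result must have been produced by the workbench (it carries
    a replay closure over its own inputs).  Returns a new scenario whose
    yearly states embed the adjustment; everything downstream (mortality,
    relapse, SADs) follows ordinary dynamics.
    """
    if baseline.rerun is None:
        raise ValueError("baseline scenario does not support replay")
    hook = make_adjustment_hook(adjustors, start_year, end_year, max_age, which)
    return baseline.rerun(
        adjustment_hook=hook, label=label or f"{baseline.label}+nvp[{which}]"
    )
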