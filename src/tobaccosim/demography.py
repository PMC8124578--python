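"""Population accounting for a deterministic smoking-status compartment model.

The population is tracked by gender, single year of age (0--99) and smoking
status: never smoker, current smoker, and former smoker split into six
years-since-quit bins (<1, 1-2, 3-5, 6-10, 11-15, >15 years).  Counts are
expected-value (fractional) persons, not stochastic agents; every operation
is deterministic and conserves persons up to an explicit ledger of deaths,
births and net migration.

Former-smoker mortality follows a log-linear decay of the current-smoker
excess risk with time since quitting:

    former RR = exp(X_b * ln(smoker RR)),   smoker RR = d_current / d_never,

where X_b is the quit-bin exponent fraction (1.00 down to 0.08 for long-quit
former smokers), so the former-smoker death rate interpolates between the
current- and never-smoker rates on the log-relative-risk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GENDERS: tuple[str, str] = ("male", "female")
MALE, FEMALE = 0, 1
N_AGES = 100
AGES = np.arange(N_AGES)

QUIT_BINS: tuple[str, ...] = ("<1", "1-2", "3-5", "6-10", "11-15", ">15")
#: Width in years of each years-since-quit bin (last bin is open-ended).
QUIT_BIN_WIDTHS: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 5.0, float("inf"))
N_BINS = len(QUIT_BINS)

STATUS_NEVER, STATUS_CURRENT, STATUS_FORMER0 = 0, 1, 2
N_STATUS = 2 + N_BINS
STATUSES: tuple[str, ...] = ("never", "current") + tuple(
    f"former_{b}" for b in QUIT_BINS
)

#: Age-group labels used for survey comparison and reporting.
ADULT_AGE_GROUPS: dict[str, tuple[int, int]] = {
    "18-24": (18, 25),
    "25-44": (25, 45),
    "45-64": (45, 65),
    "65+": (65, N_AGES),
}

_DEFAULT_X = (1.00, 0.92, 0.79, 0.58, 0.325, 0.08)


def _bin_index(quit_bin: int | str) -> int:
    if isinstance(quit_bin, str):
        try:
            return QUIT_BINS.index(quit_bin)
        except ValueError:
            raise ValueError(f"unknown quit bin {quit_bin!r}") from None
    if not 0 <= int(quit_bin) < N_BINS:
        raise ValueError(f"quit bin index {quit_bin} out of range")
    return int(quit_bin)


def gender_index(gender: int | str) -> int:
    if isinstance(gender, str):
        try:
            return GENDERS.index(gender)
        except ValueError:
            raise ValueError(f"unknown gender {gender!r}") from None
    if gender not in (MALE, FEMALE):
        raise ValueError(f"gender index {gender} out of range")
    return int(gender)


@dataclass(frozen=True)
class RRLadder:
    """Exponent fractions X_b governing the decay of former-smoker excess risk.

    X_b must be strictly decreasing across quit bins and lie in (0, 1]: a
    just-quit former smoker carries the full smoker relative risk (X = 1),
    and the residual risk shrinks monotonically with years since quitting.
    """

    x: tuple[float, ...] = _DEFAULT_X

    def __post_init__(self) -> None:
        if len(self.x) != N_BINS:
            raise ValueError(f"expected {N_BINS} exponents, got {len(self.x)}")
        arr = np.asarray(self.x, dtype=float)
        if not (np.all(arr > 0) and np.all(arr <= 1)):
            raise ValueError("ladder exponents must lie in (0, 1]")
        if not np.all(np.diff(arr) < 0):
            raise ValueError("ladder exponents must be strictly decreasing")

    def exponent(self, quit_bin: int | str) -> float:
        return self.x[_bin_index(quit_bin)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.x, dtype=float)


def former_smoker_rr(
    smoker_rr: float | np.ndarray,
    quit_bin: int | str,
    ladder: RRLadder = RRLadder(),
) -> float | np.ndarray:
    """Relative risk of a former smoker given the current-smoker RR.

    Evaluates ``exp(X_b * ln(smoker_rr))`` = ``smoker_rr ** X_b``.  The
    result is 1 when ``smoker_rr`` is 1 and always lies between the smoker
    RR and 1.
    """
    rr = np.asarray(smoker_rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("smoker relative risk must be positive")
    out = np.exp(ladder.exponent(quit_bin) * np.log(rr))
    return float(out) if np.isscalar(smoker_rr) else out


def former_death_rate(
    d_never: float | np.ndarray,
    d_current: float | np.ndarray,
    quit_bin: int | str,
    ladder: RRLadder = RRLadder(),
) -> float | np.ndarray:
    """Annual death probability for a former smoker in a given quit bin.

    Computed as ``d_never * former_smoker_rr(d_current / d_never)``, which
    equals the current-smoker rate scaled down by the ratio of the former
    to current relative risks.  The result lies in [d_never, d_current].
    """
    dn = np.asarray(d_never, dtype=float)
    dc = np.asarray(d_current, dtype=float)
    scalar = np.isscalar(d_never) and np.isscalar(d_current)
    if np.any(dn < 0) or np.any(dc > 1) or np.any(dn > dc):
        raise ValueError("need 0 <= d_never <= d_current <= 1")
    if np.any((dn == 0) & (dc > 0)):
        raise ValueError("relative risk undefined where d_never is 0 but d_current > 0")
    out = np.zeros(np.broadcast(dn, dc).shape)
    pos = np.broadcast_to(dn, out.shape) > 0
    dn_b = np.broadcast_to(dn, out.shape)
    dc_b = np.broadcast_to(dc, out.shape)
    x = ladder.exponent(quit_bin)
    out[pos] = dn_b[pos] * (dc_b[pos] / dn_b[pos]) ** x
    return float(out) if scalar else out


def former_death_rates(
    d_never: np.ndarray, d_current: np.ndarray, ladder: RRLadder = RRLadder()
) -> np.ndarray:
    """Former-smoker death rates for all quit bins, stacked on a last axis.

    Cells with ``d_never == d_current == 0`` yield 0 for every bin.
    """
    dn = np.asarray(d_never, dtype=float)
    dc = np.asarray(d_current, dtype=float)
    out = np.zeros(dn.shape + (N_BINS,))
    pos = dn > 0
    rr = np.ones_like(dn)
    rr[pos] = dc[pos] / dn[pos]
    for b in range(N_BINS):
        out[..., b] = np.where(pos, dn * rr ** ladder.x[b], 0.0)
    return out


@dataclass
class MortalitySchedule:
    """Annual death probabilities for never and current smokers.

    Arrays are indexed (year, gender, age).  Former-smoker rates are not
    stored: they are derived on demand through the quit-bin RR ladder.
    """

    years: tuple[int, ...]
    d_never: np.ndarray
    d_current: np.ndarray

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.d_never = np.asarray(self.d_never, dtype=float)
        self.d_current = np.asarray(self.d_current, dtype=float)
        shape = (len(self.years), len(GENDERS), N_AGES)
        for name, arr in (("d_never", self.d_never), ("d_current", self.d_current)):
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.d_current < self.d_never):
            raise ValueError("current-smoker death rates must be >= never-smoker rates")
        self._index = {y: i for i, y in enumerate(self.years)}

    @classmethod
    def constant(
        cls, d_never: np.ndarray, d_current: np.ndarray, years: Sequence[int]
    ) -> "MortalitySchedule":
        """Replicate a single (gender, age) rate surface across years."""
        years = tuple(int(y) for y in years)
        dn = np.broadcast_to(d_never, (len(GENDERS), N_AGES))
        dc = np.broadcast_to(d_current, (len(GENDERS), N_AGES))
        return cls(
            years=years,
            d_never=np.tile(dn, (len(years), 1, 1)),
            d_current=np.tile(dc, (len(years), 1, 1)),
        )

    def for_year(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        try:
            i = self._index[int(year)]
        except KeyError:
            raise KeyError(f"mortality schedule does not cover year {year}") from None
        return self.d_never[i], self.d_current[i]

    def smoker_rr(self, year: int) -> np.ndarray:
        """Ratio of current- to never-smoker death rates (1 where both are 0)."""
        dn, dc = self.for_year(year)
        rr = np.ones_like(dn)
        pos = dn > 0
        rr[pos] = dc[pos] / dn[pos]
        return rr

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(self.years):
            for g, gender in enumerate(GENDERS):
                for status, arr in (("never", self.d_never), ("current", self.d_current)):
                    rows.append(
                        pd.DataFrame(
                            {
                                "year": y,
                                "gender": gender,
                                "age": AGES,
                                "status": status,
                                "value": arr[i, g],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MortalitySchedule":
        required = {"year", "gender", "age", "status", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"mortality table is missing columns {sorted(missing)}")
        years = tuple(sorted(frame["year"].unique()))
        dn = np.zeros((len(years), len(GENDERS), N_AGES))
        dc = np.zeros_like(dn)
        for (year, gender, status), grp in frame.groupby(["year", "gender", "status"]):
            tgt = {"never": dn, "current": dc}.get(status)
            if tgt is None:
                raise ValueError(f"unknown mortality status {status!r}")
            vals = grp.set_index("age")["value"].reindex(AGES)
            if vals.isna().any():
                raise ValueError(
                    f"mortality table incomplete for {gender}/{status}/{year}"
                )
            tgt[years.index(year), gender_index(gender)] = vals.to_numpy()
        return cls(years=years, d_never=dn, d_current=dc)

    @classmethod
    def from_csv(cls, path) -> "MortalitySchedule":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class DemographyDrivers:
    """Births and net migration feeding the population each simulated year.

    ``births[year]`` is a length-2 array of newborns by gender; migration
    maps year to a (gender, age) array of net migrants (possibly negative).
    Years absent from either mapping contribute zero.
    """

    births: dict[int, np.ndarray] = field(default_factory=dict)
    net_migration: dict[int, np.ndarray] = field(default_factory=dict)

    def births_for(self, year: int) -> np.ndarray:
        b = np.asarray(self.births.get(int(year), np.zeros(2)), dtype=float)
        if b.shape != (2,) or np.any(b < 0):
            raise ValueError("births must be a non-negative length-2 vector")
        return b

    def migration_for(self, year: int) -> np.ndarray:
        m = self.net_migration.get(int(year))
        if m is None:
            return np.zeros((len(GENDERS), N_AGES))
        m = np.asarray(m, dtype=float)
        if m.shape != (len(GENDERS), N_AGES):
            raise ValueError("net migration must have shape (gender, age)")
        return m


@dataclass
class PopulationState:
    """Population counts for one calendar year.

    ``counts`` has shape (gender, age, status) with the status axis ordered
    never, current, former by quit bin.
    """

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(GENDERS), N_AGES, N_STATUS):
            raise ValueError(
                f"counts must have shape {(len(GENDERS), N_AGES, N_STATUS)}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < -1e-9):
            raise ValueError("counts must be non-negative")
        np.clip(self.counts, 0.0, None, out=self.counts)

    def copy(self) -> "PopulationState":
        return PopulationState(self.year, self.counts.copy())

    def total(self) -> float:
        return float(self.counts.sum())

    def never(self) -> np.ndarray:
        return self.counts[:, :, STATUS_NEVER]

    def current(self) -> np.ndarray:
        return self.counts[:, :, STATUS_CURRENT]

    def former(self) -> np.ndarray:
        return self.counts[:, :, STATUS_FORMER0:]

    def smoking_prevalence(
        self, gender: int | str | None = None, age_range: tuple[int, int] = (18, N_AGES)
    ) -> float:
        """Current-smoker share of the population in an age range."""
        lo, hi = age_range
        sel = self.counts[:, lo:hi, :]
        if gender is not None:
            sel = sel[gender_index(gender)][None, ...]
        tot = sel.sum()
        return float(sel[..., STATUS_CURRENT].sum() / tot) if tot > 0 else 0.0

    def prevalence_by_group(self) -> pd.DataFrame:
        """Adult smoking prevalence by gender for standard age groups and 18+."""
        rows = []
        groups = dict(ADULT_AGE_GROUPS, **{"18+": (18, N_AGES)})
        for gender in GENDERS:
            for label, rng in groups.items():
                rows.append(
                    {
                        "year": self.year,
                        "gender": gender,
                        "age_group": label,
                        "prevalence": self.smoking_prevalence(gender, rng),
                    }
                )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        g, a, s = np.meshgrid(
            np.arange(len(GENDERS)), AGES, np.arange(N_STATUS), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": self.year,
                "gender": np.asarray(GENDERS)[g.ravel()],
                "age": a.ravel(),
                "status": np.asarray(STATUSES)[s.ravel()],
                "value": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationState":
        required = {"year", "gender", "age", "status", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"population table is missing columns {sorted(missing)}")
        years = frame["year"].unique()
        if len(years) != 1:
            raise ValueError("population table must describe a single year")
        counts = np.zeros((len(GENDERS), N_AGES, N_STATUS))
        status_idx = {s: i for i, s in enumerate(STATUSES)}
        for row in frame.itertuples(index=False):
            counts[gender_index(row.gender), int(row.age), status_idx[row.status]] = (
                row.value
            )
        return cls(year=int(years[0]), counts=counts)


def evolve_population(
    state: PopulationState,
    mortality: MortalitySchedule,
    drivers: DemographyDrivers | None = None,
    ladder: RRLadder = RRLadder(),
    transition: Callable[[PopulationState], PopulationState] | None = None,
) -> PopulationState:
    """Advance the population one calendar year.

    The within-year order of operations is fixed: status-specific mortality,
    then smoking-status transitions (the optional ``transition`` callable,
    typically a Markov step), then quit-bin advancement and aging, then
    births and net migration.  Age 99 is a closed terminal age: survivors of
    ages 98 and 99 pool there and leave only through death.

    Quit-bin advancement assumes a uniform distribution of former smokers
    within each bin, so the fraction ``1 / width`` of each bin's survivors
    crosses into the next bin every year.

    Returns the state for ``state.year + 1``.  Raises ``KeyError`` if the
    mortality schedule does not cover the state's year and ``ValueError`` if
    migration would drive a cell negative.
    """
    drivers = drivers or DemographyDrivers()
    dn, dc = mortality.for_year(state.year)
    rates = np.concatenate(
        [dn[..., None], dc[..., None], former_death_rates(dn, dc, ladder)], axis=-1
    )
    survivors = state.counts * (1.0 - rates)

    if transition is not None:
        survivors = transition(PopulationState(state.year, survivors)).counts

    former = survivors[:, :, STATUS_FORMER0:].copy()
    frac = np.array([1.0 / w if np.isfinite(w) else 0.0 for w in QUIT_BIN_WIDTHS])
    moved = former * frac
    former -= moved
    former[:, :, 1:] += moved[:, :, :-1]
    survivors = np.concatenate([survivors[:, :, :STATUS_FORMER0], former], axis=-1)

    new = np.zeros_like(survivors)
    new[:, 1:, :] = survivors[:, :-1, :]
    new[:, N_AGES - 1, :] += survivors[:, N_AGES - 1, :]
    new[:, 0, STATUS_NEVER] = drivers.births_for(state.year)

    mig = drivers.migration_for(state.year)
    if np.any(mig):
        totals = new.sum(axis=-1)
        dist = np.zeros_like(new)
        nonzero = totals > 0
        dist[nonzero] = new[nonzero] / totals[nonzero][..., None]
        dist[~nonzero, STATUS_NEVER] = 1.0  # migrants into empty cells: never smokers
        new = new + mig[..., None] * dist
        if np.any(new < -1e-9):
            raise ValueError("net migration would drive a population cell negative")
        np.clip(new, 0.0, None, out=new)

    return PopulationState(year=state.year + 1, counts=new)
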