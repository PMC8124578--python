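"""First-order Markov smoking-status transitions.

Three flows move persons between smoking statuses each year: net initiation
(never to current, ages 10 up to the gender-specific peak-prevalence age),
cessation (current to former, from the age after the peak), and relapse
(former to current, by years-since-quit bin).  Initiation is *net* of early
cessation: it is estimated from differences in cross-sectional smoking
prevalence between consecutive ages rather than from observed uptake, so no
separate early-cessation flow exists below the peak age.

The cessation input is expected to measure people who quit in the last year
but not in the last three months; that labeling contract is metadata on the
input data and is not enforced numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .demography import (
    FEMALE,
    GENDERS,
    MALE,
    N_AGES,
    N_BINS,
    STATUS_CURRENT,
    STATUS_FORMER0,
    STATUS_NEVER,
    PopulationState,
    gender_index,
)

log = logging.getLogger(__name__)

#: First age at which net initiation can occur.
FIRST_INITIATION_AGE = 10


@dataclass(frozen=True)
class PeakAges:
    """Ages at which cross-sectional smoking prevalence peaks, by gender."""

    male: int = 22
    female: int = 25

    def __post_init__(self) -> None:
        for v in (self.male, self.female):
            if not FIRST_INITIATION_AGE < v < N_AGES - 1:
                raise ValueError("peak age must lie strictly inside the age domain")

    def for_gender(self, gender: int | str) -> int:
        return (self.male, self.female)[gender_index(gender)]


@dataclass(frozen=True)
class CalibrationMultipliers:
    """Gender-specific scaling of net initiation rates.

    Defaults reflect a calibration that raises male initiation by 30% and
    female initiation by 15% to match rising young-adult smoking in the
    baseline period.
    """

    male: float = 1.30
    female: float = 1.15

    def __post_init__(self) -> None:
        if self.male <= 0 or self.female <= 0:
            raise ValueError("calibration multipliers must be positive")

    def for_gender(self, gender: int | str) -> float:
        return (self.male, self.female)[gender_index(gender)]


@dataclass
class TransitionRates:
    """Annual transition probabilities.

    ``net_initiation`` and ``cessation`` are (gender, age) arrays; ``relapse``
    is (gender, age, quit bin).  All probabilities must lie in [0, 1].
    Initiation should be zero above the peak age and cessation zero at or
    below it; :func:`markov_step` masks them accordingly regardless.
    """

    net_initiation: np.ndarray
    cessation: np.ndarray
    relapse: np.ndarray

    def __post_init__(self) -> None:
        self.net_initiation = np.asarray(self.net_initiation, dtype=float)
        self.cessation = np.asarray(self.cessation, dtype=float)
        self.relapse = np.asarray(self.relapse, dtype=float)
        expected = {
            "net_initiation": (len(GENDERS), N_AGES),
            "cessation": (len(GENDERS), N_AGES),
            "relapse": (len(GENDERS), N_AGES, N_BINS),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def zeros(cls) -> "TransitionRates":
        return cls(
            net_initiation=np.zeros((len(GENDERS), N_AGES)),
            cessation=np.zeros((len(GENDERS), N_AGES)),
            relapse=np.zeros((len(GENDERS), N_AGES, N_BINS)),
        )


def net_initiation_from_cross_section(
    prev: np.ndarray,
    never: np.ndarray,
    peak_age: int,
    first_age: int = FIRST_INITIATION_AGE,
) -> np.ndarray:
    """Estimate net initiation rates from a cross-sectional prevalence curve.

    For ages a from ``first_age`` to ``peak_age - 1``::

        rate(a + 1) = (prev(a + 1) - prev(a)) / never(a)

    i.e., the rise in smoking prevalence between consecutive ages expressed
    as a hazard on the never-smoker pool at the younger age.  Negative raw
    differences (prevalence dipping with age before the peak, e.g., from
    sampling noise) are clipped to zero with a logged warning, as are rates
    exceeding 1.

    Parameters are length-100 age vectors of smoking and never-smoking
    prevalence in [0, 1].  Returns a length-100 vector of rates, zero
    outside (first_age, peak_age].
    """
    prev = np.asarray(prev, dtype=float)
    never = np.asarray(never, dtype=float)
    if prev.shape != (N_AGES,) or never.shape != (N_AGES,):
        raise ValueError("prevalence curves must be length-100 age vectors")
    if np.any(prev < 0) or np.any(prev > 1) or np.any(never < 0) or np.any(never > 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if not first_age < peak_age < N_AGES:
        raise ValueError("need first_age < peak_age < 100")
    if np.any(never[first_age:peak_age] <= 0):
        raise ValueError("never-smoking prevalence must be positive below the peak age")

    rates = np.zeros(N_AGES)
    ages = np.arange(first_age, peak_age)
    raw = (prev[ages + 1] - prev[ages]) / never[ages]
    if np.any(raw < 0):
        log.warning(
            "negative net-initiation differences at ages %s clipped to 0",
            (ages + 1)[raw < 0].tolist(),
        )
    if np.any(raw > 1):
        log.warning("net-initiation rates above 1 clipped at ages %s",
                    (ages + 1)[raw > 1].tolist())
    rates[ages + 1] = np.clip(raw, 0.0, 1.0)
    return rates


def apply_calibration(
    rates: TransitionRates, mult: CalibrationMultipliers = CalibrationMultipliers()
) -> TransitionRates:
    """Scale net initiation by the gender calibration multipliers.

    Cessation and relapse are unchanged.  Scaled rates above 1 are clipped
    with a warning.
    """
    init = rates.net_initiation.copy()
    init[MALE] *= mult.male
    init[FEMALE] *= mult.female
    if np.any(init > 1):
        log.warning("calibrated initiation rates above 1 were clipped")
        init = np.clip(init, 0.0, 1.0)
    return TransitionRates(
        net_initiation=init, cessation=rates.cessation, relapse=rates.relapse
    )


def _effective(base: np.ndarray, delta: float | np.ndarray | None) -> np.ndarray:
    """Apply a fractional policy delta to a base rate vector, clipped to [0, 1]."""
    if delta is None:
        return base
    eff = base * (1.0 + np.asarray(delta, dtype=float))
    if np.any(eff < 0) or np.any(eff > 1):
        log.debug("effective transition rates clipped to [0, 1]")
    return np.clip(eff, 0.0, 1.0)


def markov_step(
    state: PopulationState,
    rates: TransitionRates,
    peak_ages: PeakAges = PeakAges(),
    initiation_delta: float | np.ndarray | None = None,
    cessation_delta: float | np.ndarray | None = None,
) -> PopulationState:
    """Apply one year of smoking-status transitions.

    All flows are computed simultaneously from the pre-step state (first-order
    Markov): never-smokers initiate at the (policy-adjusted) net initiation
    rate for ages up to the peak age, current smokers quit into the <1-year
    former bin at the cessation rate for ages above the peak, and former
    smokers relapse to current at bin-specific rates.  Counts are conserved
    within each (gender, age) cell; the returned state keeps the same year.

    ``initiation_delta`` and ``cessation_delta`` are fractional changes
    (e.g., -0.06 lowers initiation by 6%); effective rates are clipped to
    [0, 1].
    """
    counts = state.counts.copy()
    if not np.all(np.isfinite(counts)):
        raise ValueError("population counts must be finite")
    for g in (MALE, FEMALE):
        peak = peak_ages.for_gender(g)
        init = _effective(rates.net_initiation[g], initiation_delta)
        cess = _effective(rates.cessation[g], cessation_delta)
        init = np.where(np.arange(N_AGES) <= peak, init, 0.0)
        cess = np.where(np.arange(N_AGES) > peak, cess, 0.0)

        never = counts[g, :, STATUS_NEVER]
        current = counts[g, :, STATUS_CURRENT]
        former = counts[g, :, STATUS_FORMER0:]

        new_smokers = never * init
        quitters = current * cess
        relapsers = former * rates.relapse[g]

        counts[g, :, STATUS_NEVER] = never - new_smokers
        counts[g, :, STATUS_CURRENT] = (
            current + new_smokers - quitters + relapsers.sum(axis=-1)
        )
        counts[g, :, STATUS_FORMER0:] = former - relapsers
        counts[g, :, STATUS_FORMER0] += quitters
    return PopulationState(year=state.year, counts=counts)
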