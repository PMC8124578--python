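"""Indirect inference of vaping impacts on smoking prevalence.

The vaping (NVP) impact is not modelled mechanistically.  Instead the
model's counterfactual projection -- smoking prevalence had vaping products
never existed, with cigarette-oriented policies at their observed levels --
is compared with survey prevalence trends over the same window.  The
workhorse statistics:

* relative reduction ``R = (p_start - p_end) / p_start`` over a period,
  reported as a positive fraction when prevalence declines;
* annualisation ``r = 1 - (1 - R)**(1/n)``, the constant annual relative
  reduction that compounds to ``R`` over ``n`` years;
* the *net vaping impact* ``R_survey - R_model``;
* the *vaping adjustor* ``a = annualize(R_survey) - annualize(R_model)``,
  the extra annual relative decline attributable to vaping, applied back to
  the counterfactual to produce a vaping-adjusted scenario;
* survey-CI propagation: upper/lower bounds of the end-year prevalence map
  to lower/upper bounds of the reduction, and onward to adjustor bounds.

All fractions are stored at full precision; table reproduction rounds
half-even to one decimal in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AGE_GROUPS = ("18+", "18-24", "25-44", "45-64", "65+")
SURVEY_COLUMNS = (
    "survey",
    "gender",
    "age_group",
    "year",
    "prevalence",
    "ci_lower",
    "ci_upper",
)

#: Weights of the survey waves bracketing a missing wave year.
WAVE_WEIGHT_BEFORE = 0.6
WAVE_WEIGHT_AFTER = 0.4


def relative_reduction(p_start: float, p_end: float) -> float:
    """Relative reduction ``(p_start - p_end) / p_start``; positive = decline."""
    if p_start <= 0:
        raise ValueError("starting prevalence must be positive")
    return (p_start - p_end) / p_start


def interpolate_wave(
    p_before: float,
    p_after: float,
    w_before: float = WAVE_WEIGHT_BEFORE,
    w_after: float = WAVE_WEIGHT_AFTER,
) -> float:
    """Weighted average standing in for a missing survey wave."""
    if w_before < 0 or w_after < 0 or abs(w_before + w_after - 1.0) > 1e-9:
        raise ValueError("wave weights must be non-negative and sum to 1")
    return w_before * p_before + w_after * p_after


def annualize(total_reduction: float, n_years: int = 6) -> float:
    """Constant annual relative reduction compounding to ``total_reduction``.

    ``1 - (1 - R)**(1/n)``; compounding the result ``n`` times recovers ``R``
    exactly.  Negative ``R`` (an increase) yields a negative annual rate.
    """
    if total_reduction >= 1:
        raise ValueError("total relative reduction must be below 1")
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    return 1.0 - (1.0 - total_reduction) ** (1.0 / n_years)


def compound(annual_reduction: float, n_years: int) -> float:
    """Total relative reduction after ``n_years`` at a constant annual rate."""
    return 1.0 - (1.0 - annual_reduction) ** n_years


def nvp_net_impact(sim_reduction: float, survey_reduction: float) -> float:
    """Survey-minus-model relative reduction: the net vaping impact.

    Positive values are extra decline associated with vaping; negative
    values indicate the survey declined less than the counterfactual.
    """
    return survey_reduction - sim_reduction


def nvp_adjustor(
    sim_reduction: float, survey_reduction: float, n_years: int = 6
) -> float:
    """Annual vaping adjustor: difference of annualised reduction rates.

    Equals ``(1 - R_sim)**(1/n) - (1 - R_survey)**(1/n)`` in survival-ratio
    form.  Antisymmetric in its arguments.
    """
    return annualize(survey_reduction, n_years) - annualize(sim_reduction, n_years)


def propagate_bounds(
    p_start: float, ci_end: tuple[float, float]
) -> tuple[float, float]:
    """Reduction bounds implied by the end-year survey confidence interval.

    The upper prevalence bound gives the smaller reduction and vice versa;
    the result is ordered (low, high).
    """
    lo, hi = ci_end
    if lo > hi:
        raise ValueError("confidence interval must be ordered")
    if p_start <= 0:
        raise ValueError("starting prevalence must be positive")
    return ((p_start - hi) / p_start, (p_start - lo) / p_start)


def outside_ci_flag(sim_value: float, ci: tuple[float, float]) -> bool:
    """True iff the simulated value falls outside the closed interval."""
    lo, hi = ci
    if lo > hi:
        raise ValueError("confidence interval must be ordered")
    return sim_value < lo or sim_value > hi


def round_pct(fraction: float, decimals: int = 1) -> float:
    """Round a fraction to percent with the given decimals, half-even."""
    return float(np.round(fraction * 100.0, decimals))


@dataclass
class NVPAdjustor:
    """Annual vaping adjustor for one gender and age group, with bounds."""

    gender: str
    age_group: str
    survey: str
    annual: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.annual, self.low, self.high]).all():
            raise ValueError("adjustor values must be finite")
        if not self.low <= self.annual <= self.high:
            raise ValueError("adjustor bounds must bracket the point estimate")


# --------------------------------------------------------------------------
# Table-level pipeline


def load_survey_csv(path) -> pd.DataFrame:
    """Load a survey prevalence series with strict header validation.

    Expected columns: survey, gender, age_group, year, prevalence, ci_lower,
    ci_upper (prevalence and bounds as fractions; bounds may be missing).
    """
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey table is missing columns {sorted(missing)}")
    bad = df["prevalence"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("prevalences must be fractions in [0, 1]")
    ok = df.dropna(subset=["ci_lower", "ci_upper"])
    if ((ok["ci_lower"] > ok["prevalence"]) | (ok["prevalence"] > ok["ci_upper"])).any():
        raise ValueError("confidence bounds must bracket the point estimate")
    return df


def _packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("tobaccosim.data").joinpath(name)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df


def load_trend_table() -> pd.DataFrame:
    """Packaged 1993-2012 model-versus-survey prevalence series (fractions)."""
    df = _packaged_csv("survey_trends.csv")
    for c in ("prevalence", "ci_lower", "ci_upper"):
        df[c] = df[f"{c}_pct"] / 100.0
    return df[list(SURVEY_COLUMNS)]


def load_trend_changes() -> pd.DataFrame:
    """Published percent changes accompanying the 1993-2012 series."""
    return _packaged_csv("survey_trend_changes.csv")


def load_nvp_period_table() -> pd.DataFrame:
    """Packaged 2012-2018 counterfactual-versus-survey series (fractions)."""
    df = _packaged_csv("nvp_period.csv")
    for c in ("prevalence", "ci_lower", "ci_upper"):
        df[c] = df[f"{c}_pct"] / 100.0
    return df[list(SURVEY_COLUMNS)]


def load_nvp_period_stats() -> pd.DataFrame:
    """Published derived statistics (reductions, net impacts, annual rates)."""
    return _packaged_csv("nvp_period_stats.csv")


def infer_nvp_table(
    prev: pd.DataFrame,
    model_source: str = "model",
    period: tuple[int, int] = (2012, 2018),
) -> pd.DataFrame:
    """Full indirect-inference table for one comparison period.

    ``prev`` is a long survey-series frame (see :data:`SURVEY_COLUMNS`)
    containing the counterfactual model under ``model_source`` and one or
    more surveys, with prevalences for both period endpoints and confidence
    bounds for the end year.  Returns one row per (gender, age group,
    survey) with the relative reductions, net vaping impact, annualised
    rates, the annual adjustor, CI-propagated bounds for each, and a flag
    marking the model reduction falling outside the survey's reduction CI.
    """
    y0, y1 = period
    n_years = y1 - y0
    rows = []
    for (gender, group), cell in prev.groupby(["gender", "age_group"], sort=False):
        sim = cell[cell["survey"] == model_source]
        try:
            sim_p0 = float(sim.loc[sim["year"] == y0, "prevalence"].iloc[0])
            sim_p1 = float(sim.loc[sim["year"] == y1, "prevalence"].iloc[0])
        except IndexError:
            raise ValueError(
                f"model series incomplete for {gender}/{group} over {period}"
            ) from None
        sim_R = relative_reduction(sim_p0, sim_p1)
        sim_annual = annualize(sim_R, n_years)
        rows.append(
            {
                "gender": gender,
                "age_group": group,
                "survey": model_source,
                "p_start": sim_p0,
                "p_end": sim_p1,
                "reduction": sim_R,
                "annual_reduction": sim_annual,
            }
        )
        for survey, sv in cell[cell["survey"] != model_source].groupby("survey"):
            try:
                p0 = float(sv.loc[sv["year"] == y0, "prevalence"].iloc[0])
                end = sv.loc[sv["year"] == y1].iloc[0]
            except IndexError:
                log.warning("survey %s incomplete for %s/%s", survey, gender, group)
                continue
            p1 = float(end["prevalence"])
            R = relative_reduction(p0, p1)
            r_lo, r_hi = (
                propagate_bounds(p0, (float(end["ci_lower"]), float(end["ci_upper"])))
                if np.isfinite([end["ci_lower"], end["ci_upper"]]).all()
                else (np.nan, np.nan)
            )
            annual = annualize(R, n_years)
            rows.append(
                {
                    "gender": gender,
                    "age_group": group,
                    "survey": survey,
                    "p_start": p0,
                    "p_end": p1,
                    "reduction": R,
                    "reduction_low": r_lo,
                    "reduction_high": r_hi,
                    "net_impact": nvp_net_impact(sim_R, R),
                    "net_impact_low": r_lo - sim_R if np.isfinite(r_lo) else np.nan,
                    "net_impact_high": r_hi - sim_R if np.isfinite(r_hi) else np.nan,
                    "annual_reduction": annual,
                    "annual_reduction_low": (
                        annualize(r_lo, n_years) if np.isfinite(r_lo) else np.nan
                    ),
                    "annual_reduction_high": (
                        annualize(r_hi, n_years) if np.isfinite(r_hi) else np.nan
                    ),
                    "adjustor": nvp_adjustor(sim_R, R, n_years),
                    "adjustor_low": (
                        annualize(r_lo, n_years) - sim_annual
                        if np.isfinite(r_lo)
                        else np.nan
                    ),
                    "adjustor_high": (
                        annualize(r_hi, n_years) - sim_annual
                        if np.isfinite(r_hi)
                        else np.nan
                    ),
                    "model_outside_ci": (
                        outside_ci_flag(sim_R, (r_lo, r_hi))
                        if np.isfinite([r_lo, r_hi]).all()
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def adjustors_from_table(
    table: pd.DataFrame, survey: str
) -> dict[tuple[str, str], NVPAdjustor]:
    """Extract per-(gender, age group) adjustors for one survey.

    Only the four mutually exclusive adult age groups are returned (the 18+
    aggregate row, if present, is skipped).
    """
    out: dict[tuple[str, str], NVPAdjustor] = {}
    sub = table[(table["survey"] == survey) & (table["age_group"] != "18+")]
    for row in sub.itertuples(index=False):
        lo = min(row.adjustor_low, row.adjustor_high)
        hi = max(row.adjustor_low, row.adjustor_high)
        out[(row.gender, row.age_group)] = NVPAdjustor(
            gender=row.gender,
            age_group=row.age_group,
            survey=survey,
            annual=row.adjustor,
            low=lo,
            high=hi,
        )
    return out
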