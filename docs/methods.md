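# Methods

## Model structure

The population model is a deterministic cohort-component projection with
smoking-status compartments. State: persons (fractional, expected values —
not stochastic agents) by gender × single age 0–99 × status {never,
current, former(<1), former(1–2), former(3–5), former(6–10), former(11–15),
former(>15) years quit}. The within-year order of operations is fixed and
documented rather than inferred: (1) policy first-year prevalence shock,
(2) any scenario adjustment hook, (3) status-specific mortality, (4) Markov
transitions, (5) quit-bin advancement and aging, (6) births and net
migration. Age 99 is a closed terminal age: survivors of 98 and 99 pool
there and exit only through death. Migrants adopt the smoking-status mix of
their destination age/gender cell (never smokers when the cell is empty);
newborns are never smokers.

### Mortality

Never- and current-smoker annual death probabilities are exogenous
schedules by age, gender and year. Former-smoker rates are derived, not
stored: with smoker relative risk `RR = d_current/d_never`, the former
smoker in quit bin `b` carries `RR_former = exp(X_b · ln RR)` with
exponents `X = (1.00, 0.92, 0.79, 0.58, 0.325, 0.08)`, so the former rate
`d_never · RR^X_b` interpolates between the current and never rates on the
log-RR scale and is monotone in time quit. Cells with `d_never = 0` and
`d_current > 0` are rejected (undefined RR).

### Quit-bin aging

The state stores one count per bin, not per year-since-quit. Assuming a
uniform distribution of quitters within each bin, the fraction `1/width`
of each bin's survivors crosses the bin boundary every year (widths 1, 2,
3, 5, 5, ∞). This is the expected-value equivalent of tracking per-bin
sub-counters and keeps the state a single array; it slightly smears cohorts
within wide bins, which matters only for the former-smoker RR ladder and is
small relative to the ladder's own step sizes.

### Transitions

Initiation is *net* (net of early cessation): estimated from a
cross-sectional prevalence curve as
`rate(a+1) = (prev(a+1) − prev(a)) / never(a)` for ages 10 up to the
gender-specific peak-prevalence age (male 22, female 25). Negative raw
differences are clipped to zero with a logged warning — a net measure can
dip with sampling noise. Cessation applies from the age after the peak;
the input is expected to measure quit-in-last-year-but-not-last-3-months
(a labelling contract on data, not enforced numerically). Relapse rates by
quit bin are applied to all former smokers, including those created by the
vaping adjustment. Relapse values are not published; the packaged synthetic
defaults decline by bin (0.12, 0.08, 0.05, 0.03, 0.02, 0.01 per year) and
are overridable. Calibration multiplies net initiation by 1.30 (male) and
1.15 (female), reflecting the rising young-adult smoking of the baseline
period.

## Policy engine

Policy levels are resolved year by year from a compact anchor-year YAML
(linear interpolation for numeric levels, stepwise for categorical). Three
channels per policy: a first-year prevalence shock, ongoing initiation
deltas, ongoing cessation deltas.

* **Shocks** use residual-scale increments: moving a policy's standing
  effect from `e_old` to `e_new` contributes `1 − (1−e_new)/(1−e_old)`
  (negative for rollback). Increments across policies combine
  multiplicatively, `1 − ∏(1 − inc)`. The first scheduled year carries no
  shock: its levels are the baseline the starting population embodies.
* **Price** acts through age-band elasticities (−0.6 ages 14–17, −0.4
  18–24, −0.2 25–34, −0.1 35–64, −0.2 65+): each year's relative price
  change `Δp/p` shifts prevalence by `ε·Δp/p` in the shock channel (a
  log-ratio form is available via `price_effect(..., form="log")`). Price
  is not separately applied to initiation rates; the youth band's response
  enters through its elasticity in the shock. No tax-to-price pass-through
  is modelled — observed inflation-adjusted prices are the input.
* **Smoke-free air** venue effects (worksite 6%, restaurant 2%, bars 1%,
  other 1%) scale linearly with population coverage (worksite bans weighted
  1, 2/3, 1/3 for full/ventilated/common-area bans) and are deflated by
  `0.5·(1 + 0.5·publicity + 0.5·enforcement/10)` — half the effect with
  neither, the full effect at enforcement 10 with publicity. The publicity
  indicator is on when media campaigns are at least at a medium level
  (moderate-or-higher mixture weight ≥ 0.5).
* **Marketing restrictions** use the enforcement-only deflator
  `0.5·(1 + enforcement/10)` (the published specification states only
  "reduced 50% absent enforcement" for this policy).
* **Mixed levels** (e.g. media at 25% minimal / 75% moderate) are
  coverage-weighted averages of the level effect sizes.
* **Cessation treatment** components (pharmacotherapy availability,
  financial coverage, quitline, brief interventions) scale with coverage
  and combine multiplicatively, then the combination is rescaled so a fully
  implemented package reproduces the published package totals (−5.68%
  prevalence, +29.4% cessation). The raw product (−5.15%, +26.2%) does not
  equal the published package figure, so a calibration constant is the only
  way to honour both the component and package numbers; tests assert both
  the calibrated cap (exactly) and the raw product (within one point).
* **Youth access** effects apply only to ages 10–15 and 16–17.
* First-year shocks remove current smokers proportionally; those at or
  below the peak initiation age return to never smokers (the shock
  suppresses recent net initiation), older ones enter the <1-year former
  bin. Negative shocks draw people back symmetrically, limited by the pool.

## Indirect vaping inference

Relative reduction `R = (p_start − p_end)/p_start` (positive = decline,
reported sign conventions follow the published tables: vaping-related
*increases* in smoking appear as negative net impacts). Annualisation
`r = 1 − (1−R)^{1/n}` is exactly invertible by compounding. The net vaping
impact is `R_survey − R_model`; the annual adjustor is the difference of
annualised rates, antisymmetric in its arguments. Survey uncertainty is
propagated by mapping the end-year 95% CI bounds through the reduction:
`((p0 − hi)/p0, (p0 − lo)/p0)`; CI comparisons use closed intervals. A
missing survey wave at the period start is replaced by a 60/40 weighted
average of the bracketing waves. Percentages are rounded half-even to one
decimal for table reproduction; full precision is kept internally.

## Deaths averted

SADs in a year: `Σ current·(d_current − d_never) + Σ former_b·(d_former(b)
− d_never)`, summed over ages, per gender. The vaping-adjusted scenario
re-runs the simulation applying, in each year of the 2012–2018 adjustment
window, the per-(gender, age-group) annual adjustor to current smokers —
so the cumulative displacement compounds as `(1−a)^t` before dynamics —
with removed smokers reallocated (never if under 25, former(<1) at 25+; age
exactly 25 goes to former) and thereafter subject to ordinary mortality and
relapse. After 2018 the hook is inert and the accumulated difference
evolves freely (no further vaping effect is assumed). The headline variant
restricts adjustment to persons under 45 at adjustment time, tracking those
cohorts as they age; uncertainty ranges re-run the adjusted scenario with
the CI-propagated low/high adjustors, which derive from the 2018 survey
bounds only.

## Synthetic worlds

The generator emulates the input structure the model needs with known
ground truth: a flat-then-declining age pyramid (cohorts shrink linearly
past age 50); a prevalence curve rising linearly from age 10 to the peak
age (defaults 28% male / 24% female at peak — adult 18+ prevalence lands in
the mid-teens, comparable to US surveys in the 2010s) then declining 0.4
points per year of age; former smokers above the peak spread uniformly over
years-since-quit; Gompertz never-smoker mortality (rate 0.085/year of age,
0.05 at age 80) with a smoker RR ramping 1→2.5 over ages 18–45; cessation
4.5%/year above the peak age. Net initiation is derived from the prevalence
curve through the same cross-sectional identity the estimator uses, so
forward replay reproduces the curve exactly — the generator's core
consistency contract. Surveys are binomial draws per gender × age-group
cell with normal-approximation 95% CIs (Wilson optional); 18+ estimates
pool the four adult cells by population weight. Not emulated: design
effects, nonresponse, mode effects, cohort-specific initiation history,
cause-specific mortality — so passing tests show estimator correctness
under clean sampling, not robustness to survey artefacts.

### Adjustor-recovery study design

The recovery experiment injects a known annual adjustor (defaults mirror
the inferred pattern: 9%/yr at 18–24, 3%/yr at 25–44, zero at 45+) into the
deterministic counterfactual trajectory and re-estimates it from sampled
surveys of n = 25,000 per gender × age-group cell per wave. The emulated
instrument has no wave in 2012: the period-start estimate is the 60/40
blend of the 2011 and 2015 waves, with variance combined accordingly —
matching the periodic-supplement design the inference was built for. The
recovery target is the estimator's noiseless value, so the reported error
is pure sampling error. Over 200 replicates the overall adult
(gender-pooled) net-impact estimate falls within ±1.5 points of truth in
well over 90% of replicates, and the delta-method 95% CI (propagating both
waves) covers truth at the nominal rate for each gender. Per-gender
absolute errors are larger for women (lower prevalence → larger relative
sampling error), which is why the absolute band is stated for the overall
estimate and the per-gender contract is interval coverage.

## Numerical choices and scales

Tolerances: population conservation is exact to accumulation error (tested
at 1e−9 per cell); annualise/compound round-trips to 1e−12; effective
transition rates are clipped to [0, 1] with logging. Ties/degenerate
inputs: empty effect lists combine to zero; a degenerate CI yields a point
reduction; boundary CI values count as inside. Simulation problem sizes in
the tests — 10–50k persons per gender, 10–15 year horizons, 200-replicate
Monte-Carlo — were chosen so the full suite exercises every pipeline stage
end to end in seconds while keeping binomial sampling at the stated n;
results are scale-free in the population size because the model is
deterministic in expected values.

## Known limitations

* The policy effect algebra reproduces the published constants and
  deflators, but the exact price-equation functional form used by the
  original model is not published; the relative-change form here is a
  documented choice with a log-ratio alternative.
* Full-scale historical projections (absolute prevalence levels and SAD
  counts) require the original survey initialisation, consortium mortality
  schedules and relapse rates, none of which are published; the package
  therefore validates structure and arithmetic on transcribed tables and
  properties on synthetic worlds rather than reproducing those levels.
* The indirect method attributes to vaping every post-2012 deviation of
  surveys from the counterfactual; unmodelled secular changes (attitudes,
  unincluded policies) land in the same bucket.
* Survey variance enters only through published CIs; no design-effect or
  microdata variance estimation.
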