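# US tobacco-control policy levels, 1993-2019.
# Anchor years are interpolated linearly for numeric levels and stepwise for
# categorical ones; effect-size constants live in code (EffectSizeTable).
years: {start: 1993, end: 2019}

# Inflation-adjusted cigarette price, USD per pack.
price:
  1993: 1.75
  2002: 3.60
  2012: 5.60
  2019: 6.60

smoke_free_air:
  enforcement: 8           # constant 8/10 across years
  # Worksite bans: population shares by ban strength (high = full indoor ban,
  # mid = ventilated areas allowed, low = common areas allowed).
  worksite:
    1993: {high: 0.015, mid: 0.07, low: 0.37}
    2002: {high: 0.03, mid: 0.08, low: 0.40}
    2019: {high: 0.761, mid: 0.104, low: 0.135}
  restaurant:
    1993: 0.005
    2002: 0.01
    2014: 0.77
    2019: 0.778
  bar:
    1993: 0.0
    2001: 0.0
    2014: 0.65
    2019: 0.664
  other:
    1993: 0.50
    1999: 0.50
    2012: 0.948
    2019: 0.95

# Mass-campaign level mixtures (shares sum to 1 after normalisation).
media:
  1993: {minimal: 0.90, moderate: 0.10}
  1994: {minimal: 0.90, moderate: 0.10}
  2003: {moderate: 1.0}
  2010: {moderate: 1.0}
  2011: {minimal: 0.50, moderate: 0.50}
  2017: {minimal: 0.50, moderate: 0.50}
  2018: {minimal: 0.25, moderate: 0.75}
  2019: {minimal: 0.25, moderate: 0.75}

marketing:
  enforcement: 9
  levels:
    1993: {minimal: 1.0}
    2009: {minimal: 1.0}
    2010: {minimal: 0.75, moderate: 0.25}
    2019: {minimal: 0.75, moderate: 0.25}

# Component coverage fractions of the cessation-treatment package.
cessation_treatment:
  pharmacotherapy:
    1993: 1.0
    2019: 1.0
  coverage:
    1993: 0.0
    1996: 0.0
    1997: 0.30
    2001: 0.30
    2002: 0.40
    2006: 0.40
    2007: 0.50
    2013: 0.50
    2014: 0.75
    2019: 0.75
  quitline:
    1993: 0.0
    2002: 0.0
    2003: 0.50
    2006: 0.50
    2007: 0.90
    2019: 0.90
  brief_intervention:
    1993: 0.50
    2019: 0.50

# Youth-access enforcement level (stepwise).
youth_access:
  1993: none
  1998: low
  2003: mid
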