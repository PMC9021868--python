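# Methods

This note documents the models, conventions and numerical choices behind
`chillbreak`, and what the synthetic-data experiments do and do not show.

## Calendar conventions

A dormancy **season** runs from 1 September to 30 April of the following
year (both configurable).  The **day-of-season index** anchors 1 October as
day 1, so 30 April is day 212 in seasons whose February has 28 days.  In
leap seasons 29 February receives its own index and 30 April becomes
day 213 — a real day of weather is never dropped; the statistical
estimators report calendar dates, not raw indices, so results remain
comparable across season types.  September dates carry indices ≤ 0
(1 September = −29).  Cross-season alignment is by this index, i.e. by
days elapsed since 1 October; after a leap February the aligned calendar
dates differ by one day between season types, which is negligible at the
estimators' resolution.  Timestamps are naive local standard time; DST
artefacts must be cleaned upstream or they trip the gap policy.

When a single calendar date per cultivar must be reported (statistical
estimators, mean dates), day-of-season ordinals are averaged and rounded
half-up, then mapped to a month–day on the 28-day-February reference
calendar.

## Accumulation models

All models consume strictly hourly series; gaps of ≤ 6 h in input files may
be filled by linear interpolation (longer gaps are an error, never filled
silently).

**Dynamic model (chill portions, CP).**  The canonical two-step
formulation: per hour, the intermediate pool relaxes toward the
temperature-dependent equilibrium `xs = (a0/a1)·exp((e1−e0)/T_K)` with rate
`k1 = a1·exp(−e1/T_K)`; when the relaxed pool reaches 1, the fraction
`ξ = sr/(1+sr)` with `sr = exp(slp·tetmlt·(T_K−tetmlt)/T_K)` converts
irreversibly to portions.  The constants (slp 1.6, tetmlt 277 K,
e0 4153.5 K, e1 12888.8 K, a0 1.395·10⁵, a1 2.567·10¹⁸) and the 273 Kelvin
offset are frozen verbatim from the standard hourly transcription of the
model in `chillbreak.constants`, for bit-reproducibility.  Portions are
never destroyed: the cumulative series is non-decreasing even though warm
hours deplete the intermediate pool.  The implementation is vectorised
across series (one Python loop over hours); tests pin it to a scalar
straight-line transcription at 10⁻⁹ on thousands of random series.

**Utah model (chill units, CU).**  Stepwise hourly weights with half-open
intervals `(lower, upper]`: 0 below 1.4 °C, 0.5 to 2.4, 1.0 to 9.1, 0.5 to
12.4, 0 to 15.9, −0.5 to 18, −1 above.  The negative bands matter: the
model's accumulation start is the day of *maximum negative effect* — the
day whose end-of-day running total is minimal (ties broken by the latest
such day), with accumulation toward the requirement restarting at zero
afterwards.  If the running total never goes negative the series start is
used.

**Weinberger model (chilling hours, CH).**  One unit per hour strictly
below 7.2 °C (the 1-decimal Celsius equivalent of 45 °F; the boundary hour
at exactly 7.2 °C does not count).  Accumulation effectively starts at the
first qualifying autumn hour.

**Growing degree hours (GDH).**  `max(0, min(T, 25) − 4.5)` °C·h per hour.
"Hours above 4.5 °C" is ambiguous between an hour count and degree-hours;
the capped-linear degree-hour form is used because reported heat
requirements of several thousand GDH over a few forcing weeks are
incompatible with a plain hour count (a 40-day forcing phase has only 960
hours).  The curvilinear (asin-based) variant of the same framework is not
implemented.

## Break-date estimators

**Forcing test.**  Trials are ordered by collection date; the break is the
first trial whose mean chamber bud weight (n = 10) is ≥ 1.30 × the mean
field weight, inclusive at the boundary.  Sample means, not medians, are
compared.  If no trial qualifies the season is reported "not released"
(`None`).

**Correlation sign-transition.**  The predictor for day *d* is the mean of
daily mean temperatures over the 15-day window centred on *d* (window
configurable, must be odd; truncated at the 1…212 grid edges).  The
per-day Pearson correlation with bloom day-of-season across years is
compared with the two-sided threshold `r* = t_{1−α/2,n−2}/√(t² + n − 2)`.
With L the last day ≥ +r\* and F the first later day ≤ −r\*, the break is
`round((L+F)/2)` (half-up).  Degenerate cases return an explicit
undetermined sentinel with a reason (constant bloom dates, no significant
positive day, no significant negative day after L).  Seasons lacking a
bloom record are dropped with a warning; at least 3 common seasons are
required (in practice the method needs 11+).

**PLS phase delineation.**  Bloom day-of-season is regressed on the
seasons × days matrix of daily CP (chill model) or daily GDH (heat model)
increments over the −29…212 grid.  Daily increments are smoothed with a
centred 11-day running mean by default (configurable; damps day-to-day
weather noise).  The PLS1 fit is NIPALS with 2 components by default,
predictors centred and scaled by the sample (n−1) standard deviation and
the response centred; zero-variance predictor columns are excluded and get
coefficient 0 and VIP 0.  VIP uses the standard formula
`VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_aᵀt_a`.  Component extraction stops early when the
residual covariance vanishes (a constant response yields an all-zero
model), and requesting more components than the rank is an error.

A day is phase-significant when its coefficient is negative (more
accumulation that day advances bloom) and VIP > 0.8.  The chilling phase
is the longest such run in the chill profile, merging runs separated by at
most 5 non-significant days (the observed phases are contiguous trends,
not strict runs); its last day is the break.  Candidate chilling runs are
restricted to days before the earliest observed bloom — days at or after
bloom cannot belong to a dormancy phase, and without the restriction
chance significant runs in late spring are occasionally selected.  The
forcing phase is the longest significant run in the heat profile starting
after the break; `transition_days` is the gap between the phases.

**Biomarker pass-through.**  Observed dates are validated against their
seasons and averaged on day-of-season ordinals.

## Requirements and classification

CR is the model's cumulative value at 24:00 of the break date, from the
model-specific start (Dynamic: 1 September; Utah: restart rule above;
Weinberger: implicit first cold hour).  A break before the accumulation
start, or a negative Utah total after restart, returns 0 with a warning.
HR is the GDH total over [break 00:00, F50 24:00).

Experimental and biomarker methods have one break date per season: CR/HR
are computed per season and summarised as mean, sample SD (n−1) and
cv = 100·SD/mean.  Statistical methods yield a single calendar date per
cultivar; the same month–day is placed in every season and the SD/cv
describe the between-season spread of accumulation to that fixed date —
this is the only construction under which a single-date method can report
a dispersion, and it is noted here as a package convention.  A single
season reports SD = 0; a zero mean makes cv undefined (NaN).

Classification bands (CP: high ≥ 66, medium 56–65, low-medium 50–55;
GDH: high ≥ 4101, medium 3901–4100, low ≤ 3900) are printed as integers
and leave real-valued gaps; bands close as half-open intervals at the
upper printed bound (e.g. medium chill is [56, 66), and a value of
3900.5 GDH is medium).  CP values below 50 are flagged `below_range`
rather than silently binned.

## Method agreement

Bland–Altman on per-cultivar values: differences `d_i = a_i − b_i`, limits
of agreement `mean(d) ± 1.96·SD(d)` with the sample SD and the fixed
normal multiplier 1.96 (not re-derived from t).  Points exactly on a limit
count as inside (conservative toward agreement).  Two methods agree when
the inside fraction is ≥ 0.95.  Note that with ~20 cultivars a single
outlying pair beyond one limit already drops the fraction to 0.95 and two
drop it below — with normally scattered differences roughly one point in
twenty is outside by construction, so the verdict is knife-edged at this
sample size.  All 6 unordered pairs of the 4 methods are compared.

## Synthetic data

The generator emulates the *statistical structure* of a long-term
orchard/weather-station study, not any physical climate: per season,
hourly temperature = seasonal sinusoid + per-season mean shift + diurnal
sinusoid + AR(1) daily-mean anomalies held over each day's hours; bloom
dates follow a sequential truth model (Dynamic CP from 1 September to
CR\*, then GDH to HR\*, plus rounded Gaussian observation noise).  Random
streams derive from `(seed, cultivar, season, stream)`, so adding
cultivars or seasons never perturbs existing ones.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| annual mean / amplitude | 14.5 / 6.5 °C | winter daily means ~8–12 °C: chill stays temperature-limited through the whole chilling phase (the regime the statistical estimators assume) while seasons still total ~100–115 CP, so CR\* up to 85 CP is attainable |
| coldest day | 15 Jan | mid-latitude winter minimum |
| diurnal half-range | 4 °C | typical winter diurnal range ~8 °C |
| AR(1) daily anomalies | φ = 0.8, innovation 1.5 °C | synoptic persistence of a few days; stationary sd 2.5 °C |
| per-season shift | sd 0.7 °C | interannual variability beyond the synoptic component |
| CR\*, HR\* | 55 CP, 4000 GDH | mid-range apricot values |
| bloom / biomarker noise | sd 2 d | twice-weekly phenology scoring resolution |
| forcing ratios | 1.10 dormant, 1.45 released, sd 0.05 | clear 30 %-criterion separation with realistic trial noise |

In this regime a +1 °C season-wide shift delays the break by ~9 days
(chill-limited winter) and shortens forcing by a similar amount, so the
two year-level pathways roughly cancel and the correlation profile shows
the textbook shape: positive during chilling, negative during forcing.

What the generator does **not** emulate: real station records (no missing
hours, no DST artefacts, no skewed or heavy-tailed anomalies, no
multi-week blocking episodes), any specific site's seasonal asymmetry, or
biological year-to-year variation in CR\*/HR\* themselves.  Passing tests
therefore demonstrate correctness of the pipeline and the estimators'
behaviour under the assumed structure — not that any estimator is accurate
for a particular orchard.

## Ground-truth recovery: what the experiments show

`scripts/acceptance.py` (and the corresponding acceptance test) scores the
estimators against synthetic truth.

*Forcing test*: with weekly sampling and the default trial noise, the
estimated break is within 14 days of truth in ~100 % of 100
cultivar-seasons — the criterion is sharp and the only error is the
sampling resolution.  *Biomarker pass-through*: with ±2-day date jitter
the implied CR is unbiased (mean difference ≪ 5 CP against truth).

*Statistical estimators*: both are markedly less reliable at the
configured study size (20 seasons, 100 cultivars with CR\* in 45–85 CP,
HR\* in 3500–5500 GDH).  The recovery rates and break-day biases are
computed and reported by the acceptance script; at these conditions the
correlation midpoint is undetermined for roughly half the cultivars
(no significant band on one side) and biased early by ~2–3 weeks
otherwise, and the PLS longest-run rule locks onto the chill-onset period
(where daily-chill variance is largest) rather than the chill-fulfilment
date.  The mechanism is intrinsic: the truth break date varies by
±11–14 days across seasons — that variance *is* the estimators' signal —
which smears the sign-transition band, while the significance threshold
(r\* = 0.444 at 20 seasons) leaves the band endpoints with a sampling
noise of one to two window widths.  This matches the known caution that
these regression methods need long records and delineate phases only
approximately; their dates should be read as phase boundaries, not as
precise break dates.

## Degenerate inputs and numerical details

- Empty temperature series → zero-length accumulation, total 0.
- Partial days are excluded from daily means with a warning.
- Hourly interpolation from daily extremes uses a quarter-sine rise
  (minimum at 05:00, maximum at 14:00) and linear decay to the next dawn,
  clamped per day to [tmin, tmax] so the daily extremes are exact.
- All date averaging rounds half-up; the correlation midpoint of an
  odd-sum transition rounds up (e.g. L=40, F=61 → day 51).
- Oracle comparisons in tests are at 10⁻⁹ absolute; PLS is additionally
  cross-checked against an independent library implementation.

## Limitations

Only the four implemented break-estimation routes are supported; no other
chill models (North Carolina, positive Utah), no frost-risk or yield
modelling, no weather QC beyond the gap policy, and no gene-expression or
imaging biomarkers — external break dates enter only as observed dates.
The Bland–Altman analysis uses plain limits of agreement, not confidence
intervals around them, and no regression-based bias models
(Passing–Bablok, Deming) are provided.
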