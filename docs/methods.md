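# Methods

## Model

Olive phenological development between two BBCH events is summarised by the
developmental rate DR = 1/S, with S the phase length in whole days. Three
response functions of the mean conditions experienced during the phase are
supported: linear in temperature (DR = a + bT), multiple linear in
temperature and daylength (DR = a + bT + cP), and a second-degree
polynomial in temperature (DR = a + bT + cT²). Each carries clipping rules
that set the daily rate to zero outside its favourable range:

* linear: zero at and below the base temperature T₀ = −a/b (strict
  comparison T > T₀; at exactly T₀ the rate is zero by both rule and
  formula);
* multiple: zero unless T > T₀ₘ and P > P₀ₘ. The critical pair is defined
  as the x-intercepts of the fitted plane's two univariate projections,
  each taken at the training-sample mean of the other predictor; the model
  object therefore carries those means (`t_ref`, `p_ref`). When c = 0 the
  daylength gate is vacuous and the model collapses onto the simple linear
  DR;
* polynomial: zero outside the open interval (T_p1, T_p2) between the
  parabola's roots. A fitted c ≥ 0 (upward parabola) has no meaningful
  upper cut-off; such fits are flagged `valid_for_simulation=False` and
  excluded from simulation rather than raised as errors.

Under the linear model the reciprocal slope 1/b is the thermal constant
(degree-day requirement above T₀) of the classical thermal-sum model; this
equivalence is enforced as a test property (degree-days accumulated at
completion equal 1/b up to one day's contribution when no day is clipped).

## Summing-rates simulation

The phase length from a start date is the smallest S with
Σ_{j=1..S} DR_j ≥ 1, where day j = 1 is the first day *after* the start
event — the start day contributes no rate, so the predicted end date is
exactly `start + S` days and round-trips with observed lengths
S_obs = date_end − date_start. Resolution is one whole day (first day the
running sum reaches 1, no fractional interpolation), matching the precision
of field surveys. All arithmetic is on calendar dates, so phases may cross
31 December.

Numerical choice: completion is tested against 1 − 1e-9 rather than 1.0.
The tolerance only absorbs float rounding when daily rates are exact
reciprocals of an integer length (S days at 1/S per day must complete at
day S, not S + 1); it is far below any physically meaningful rate
difference.

Weather gaps of up to 3 consecutive days are filled by linear interpolation
in time; longer gaps are a hard error, as is a series that ends before the
phase completes or the horizon (default 366 days) elapses.

### Reverse reconstruction

`reverse_budbreak` returns the latest date s such that the rates
accumulated over (s, end] reach 1 — equivalently, the latest start from
which a forward simulation still completes no later than the observed end.
Applied to a forward simulation's own end date, the estimate is never
earlier than the true start and equals it exactly whenever the rate on the
day after the start exceeds the forward run's overshoot (the cumulative
sum's excess over 1 at completion). Otherwise it lands later: leading days
whose rates fit inside the overshoot — in particular zero-rate days below
the base temperature, common after an early budbreak — are
indistinguishable from the observation. This is an identifiability limit of
the observation model, not an algorithmic error; the tests verify the
latest-feasible-start property exactly. The lookback window (default
366 days) is truncated at the first available weather date when the series
starts later.

## Phase records and calibration

From dated observations, every pair of events observed within the same
(site, variety, year) with ascending BBCH codes yields one record: S_obs as
the day difference, and temperature/daylength averaged over the S_obs days
after the start date — the same days that carry rate in the simulator,
keeping calibration and simulation self-consistent. Records with
non-positive lengths (reversed dates) or unusable weather are rejected with
a logged warning, never inverted. Inputs are expected reduced to one date
per (site, variety, year, event); a helper reduces raw per-plant dates by
the lower median (deterministic for even counts).

Phases with records from fewer than five distinct sites are discarded to
guarantee environmental heterogeneity. Fitting is ordinary least squares of
DR_obs on [1, T], [1, T, P] or [1, T, T²] (via statsmodels); reported r² is
the squared Pearson correlation between fitted and observed rates
(identical to the classical coefficient of determination for an intercept
OLS fit) and the p-value is the regression F-test. Daylength is the FAO-56
daylight formula (declination 0.409·sin(2π·doy/365 − 1.39), sunset hour
angle from latitude, N = 24ω_s/π), with doy 366 mapped to 365 and the
arccos argument clamped so polar latitudes degenerate to 0 or 24 h.

The six bundled final linear calibrations cover budbreak (BBCH 01, 07) and
inflorescence swelling (51) to beginning of flowering (61) and full
flowering (65). For two of them, (01, 65) and (51, 65), the published base
temperature differs from −a/b computed from the published rounded
coefficients by 0.1 °C; `bundled_table()` exposes both values rather than
silently preferring either.

## Cross-validation

Repeated K-fold cross-validation at the phase level, K = 5 and N = 10 by
default. Per repeat the records are shuffled (repeat i uses an RNG stream
derived from (seed, i), so reports are bit-reproducible) and split into K
folds differing in size by at most one. Each fold is held out in turn: the
DR function is refitted on the other K − 1 folds and every held-out
record's length is re-simulated from its own observed start date with its
site's weather. r² (adjusted for the two predictors of the multiple kind,
which is also how its published scores are reported), RMSE and MBE are
computed per fold run and the report is the ensemble mean over all K·N
runs; pooling the predictions within each repeat before computing metrics
is available behind `pool_per_repeat=True`. Phases clear the selection gate
when the ensemble r² exceeds 0.8 and RMSE is below 7 days (both strict);
the RMSE threshold reflects the uncertainty of weekly field surveys.

## Synthetic survey generator

The generator reproduces the structure of the multi-site Italian survey
behind the calibrations with a fully known truth:

* **sites** — seven, at the survey's latitudes (37.41–43.66 °N), annual
  mean temperature 15.0 + 0.6·(40.5 − lat) °C (cooler northwards),
  sinusoidal annual cycle of amplitude 8.5 °C peaking near DOY 200, daily
  Gaussian noise σ_T = 2 °C;
* **varieties** — seventeen, distributed 7/5/4/5/5/5/5 over sites with
  three common to (almost) all, mirroring the survey layout;
* **phenology** — per (site, variety, year ∈ 1997–1999): budbreak DOY
  uniform in [30, 120], then the chain 01 → 61 → 65 forward-simulated under
  the true models (the published (01, 61) calibration, plus an invented
  short (61, 65) model, a = −0.10, b = 0.0143, ≈7 days at 17 °C);
* **observation noise** — whole-day Gaussian jitter σ_obs = 3.5 days (half
  the 7-day survey interval) applied independently per event and redrawn if
  it would produce a non-positive phase length, plus independent per-event
  missingness p = 0.2, leaving ≈0.8²·108 ≈ 69 usable records per two-event
  phase — the survey's per-phase sample size.

What the generator does *not* emulate: temperature autocorrelation (daily
noise is white), precipitation and any non-thermal driver, per-variety rate
differences, chilling/endodormancy before budbreak, and the 4-day survey
cadence during flowering. Passing tests therefore show that the estimation
and simulation machinery is correct under the stated thermal model, not
that real olive data satisfy that model.

Two structural biases of the noiseless weather-driven pipeline are worth
knowing. Observed rates are 1/⌈·⌉ of the exact lengths (integer-day
discretisation), and early-season days below the base temperature enter the
phase-mean temperature while contributing no rate; together they depress
the refitted slope by a few percent even at zero survey noise. Exact
coefficient recovery (relative error at machine precision) is available —
and tested — with `integer_consistent_records`, which chooses integer
lengths and matching constant temperatures so that records lie exactly on
the model and round-trip exactly through the simulator.

## Problem sizes

The test suite and the acceptance script run the synthetic survey at its
natural scale (7 sites × 36 site-variety pairs × 3 years), 500 Monte-Carlo
replicates for the noisy-recovery coverage check, and 1000 random series
for the simulator/oracle comparison; the whole suite completes in well
under a minute.

## Known limitations

* Chilling requirements and endodormancy release are not modelled; the
  budbreak date is an input (or the object of reverse reconstruction), not
  a prediction.
* Calibrations are site-enlarged: no per-variety or mixed-effects terms.
* Sub-daily temperature structure is ignored (daily means only).
* Reverse reconstruction cannot recover start days followed by zero-rate
  spells (see above); its uncertainty grows with the number of clipped days
  after budbreak.
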