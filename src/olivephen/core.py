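"""Domain types and response functions for temperature-driven olive phenology.

The timing of olive (*Olea europaea*) phenological phases is modelled with
developmental-rate (DR) functions: the reciprocal of a phase's length in days
is regressed on the mean air temperature (and optionally daylength)
experienced during that phase.  Evaluated on daily weather, the same
functions drive a summing-rates simulator (:mod:`olivephen.simulate`).

Three response shapes are supported:

``linear``
    ``DR = a + b*T``; zero at and below the base temperature ``T0 = -a/b``.
    Under linearity ``1/b`` is the thermal constant (growing degree-day
    requirement above ``T0``) of the classical thermal-sum model.
``multiple``
    ``DR = a + b*T + c*P`` with ``P`` the daylength in hours; zero whenever
    either predictor falls below its critical value (``T0m``, ``P0m``).
``polynomial``
    ``DR = a + b*T + c*T**2``, a downward parabola; zero outside its two
    real roots ``Tp1 < Tp2`` (development also stops at supra-optimal
    temperature).

Units are fixed throughout the package: temperature in degC, daylength in
hours, rates in d^-1, phase lengths in whole days.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("olivephen")

__all__ = [
    "BBCH_CATALOGUE",
    "BBCHEvent",
    "PhenologicalObservation",
    "DailyWeather",
    "DRModel",
    "LinearThresholds",
    "MultipleThresholds",
    "PolynomialThresholds",
    "critical_thresholds",
    "dr_linear",
    "dr_multiple",
    "dr_polynomial",
    "compute_daylength",
    "PhenologyError",
    "ModelKindError",
    "InvalidModelError",
    "ThresholdUndefinedError",
    "ConfigurationError",
    "WeatherGapError",
    "MissingWeatherError",
    "NoSolutionError",
    "FitError",
    "UnknownPhaseError",
    "DataFormatError",
    "EvaluationError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PhenologyError(Exception):
    """Base class for all errors raised by olivephen."""


class ModelKindError(PhenologyError):
    """A DR function was called with a model of the wrong kind."""


class InvalidModelError(PhenologyError):
    """Model coefficients are unusable for simulation (e.g. upward parabola)."""


class ThresholdUndefinedError(PhenologyError):
    """Critical thresholds cannot be derived from the coefficients."""


class ConfigurationError(PhenologyError):
    """Required configuration (e.g. predictor reference means) is missing."""


class WeatherGapError(PhenologyError):
    """A gap in the daily weather series exceeds the interpolation tolerance."""


class MissingWeatherError(PhenologyError):
    """The weather series does not cover the requested span."""


class NoSolutionError(PhenologyError):
    """Reverse reconstruction found no start date within the lookback window."""


class FitError(PhenologyError):
    """Regression could not be carried out (too few records, degenerate X)."""


class UnknownPhaseError(PhenologyError, LookupError):
    """Requested phase has no bundled calibration."""


class DataFormatError(PhenologyError):
    """An input table violates the expected schema."""


class EvaluationError(PhenologyError):
    """Cross-validation produced no usable fold runs."""


# ---------------------------------------------------------------------------
# BBCH events
# ---------------------------------------------------------------------------

#: The 19 phenological events of the olive BBCH centesimal scale observed in
#: the calibration survey; all observation inputs must use one of these codes.
BBCH_CATALOGUE: dict[int, str] = {
    1: "Foliar buds start to swell and open",
    3: "Foliar buds lengthen and separate from base",
    7: "External small leaves open, not completely separated",
    11: "First leaves completely separated",
    50: "Inflorescence buds leaf axils completely closed",
    51: "Inflorescence buds start to swell",
    55: "Flower cluster totally expanded",
    61: "Beginning of flowering",
    65: "Full flowering, at least 50% of flowers open",
    68: "Majority of petals fallen or faded",
    69: "End of flowering, non-fertilized ovaries fallen",
    71: "Fruits at 10% of final size",
    75: "Fruits at 50% of final size",
    80: "Fruit becoming light green or yellowish",
    81: "Beginning of fruit coloring",
    85: "Increasing specific fruit coloring",
    89: "Harvest maturity",
    92: "Overripe with fruits that start to fall",
    99: "At least 50% of fruits fallen",
}


@dataclass(frozen=True, order=True)
class BBCHEvent:
    """One stage of the BBCH centesimal scale (0-99) for olive.

    Only codes present in :data:`BBCH_CATALOGUE` are accepted; ordering
    follows the numeric code.
    """

    code: int
    description: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not 0 <= self.code <= 99:
            raise ValueError(f"BBCH code {self.code} outside [0, 99]")
        if self.code not in BBCH_CATALOGUE:
            raise ValueError(
                f"BBCH code {self.code:02d} is not in the supported catalogue "
                f"({sorted(BBCH_CATALOGUE)})"
            )
        if not self.description:
            object.__setattr__(self, "description", BBCH_CATALOGUE[self.code])

    @classmethod
    def from_code(cls, code: int) -> "BBCHEvent":
        return cls(code=int(code))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"BBCH {self.code:02d}"


# ---------------------------------------------------------------------------
# Observations and weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenologicalObservation:
    """One dated BBCH event at a (site, variety, year)."""

    site_id: str
    latitude: float
    variety: str
    year: int
    event: BBCHEvent
    date: dt.date

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.date.year != self.year:
            raise ValueError(
                f"observation date {self.date} does not fall in year {self.year}"
            )


TEMP_RANGE = (-30.0, 50.0)  # plausible daily-mean air temperature, degC


@dataclass
class DailyWeather:
    """Per-site daily mean air temperature series with the site latitude.

    ``series`` is a float Series of temperatures (degC) indexed by a
    normalised, strictly increasing ``DatetimeIndex``.  Gaps may exist in the
    stored index; consumers request contiguous daily windows through
    :meth:`daily`, which linearly interpolates gaps of at most ``max_gap``
    consecutive missing days and raises on anything longer.
    """

    site_id: str
    latitude: float
    series: pd.Series

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        s = pd.Series(self.series, dtype=float)
        s.index = pd.DatetimeIndex(s.index).normalize()
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0].date()
            raise DataFormatError(f"duplicate weather date {dup} for site {self.site_id}")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
        lo, hi = TEMP_RANGE
        bad = s[(s < lo) | (s > hi)]
        if len(bad):
            raise DataFormatError(
                f"site {self.site_id}: temperature {bad.iloc[0]:.1f} degC on "
                f"{bad.index[0].date()} outside plausible range {TEMP_RANGE}"
            )
        self.series = s

    @classmethod
    def from_arrays(cls, site_id: str, latitude: float, dates, temps) -> "DailyWeather":
        return cls(site_id, latitude, pd.Series(np.asarray(temps, dtype=float),
                                                index=pd.DatetimeIndex(dates)))

    @property
    def first_date(self) -> dt.date:
        return self.series.index[0].date()

    @property
    def last_date(self) -> dt.date:
        return self.series.index[-1].date()

    def daily(self, first: dt.date, last: dt.date, max_gap: int = 3) -> pd.Series:
        """Contiguous daily temperatures for ``first .. last`` (both inclusive).

        Interior gaps of up to ``max_gap`` consecutive missing days are filled
        by linear interpolation in time; longer gaps raise
        :class:`WeatherGapError` and spans outside the stored series raise
        :class:`MissingWeatherError`.
        """
        first_ts = pd.Timestamp(first)
        last_ts = pd.Timestamp(last)
        if last_ts < first_ts:
            raise ValueError(f"empty window {first}..{last}")
        if first_ts < self.series.index[0] or last_ts > self.series.index[-1]:
            raise MissingWeatherError(
                f"site {self.site_id}: weather covers {self.first_date}.."
                f"{self.last_date}, requested {first}..{last}"
            )
        window = self.series.reindex(pd.date_range(first_ts, last_ts, freq="D"))
        if window.isna().any():
            run = _longest_nan_run(window.to_numpy())
            if run > max_gap:
                raise WeatherGapError(
                    f"site {self.site_id}: gap of {run} consecutive days in "
                    f"{first}..{last} exceeds the {max_gap}-day tolerance"
                )
            # Window edges are guaranteed observed (checked above via stored
            # index bounds only when the edge dates are present); extend by one
            # stored observation on each side so edge gaps interpolate too.
            lo_pos = self.series.index.searchsorted(first_ts, side="right") - 1
            hi_pos = self.series.index.searchsorted(last_ts, side="left")
            lo_anchor = self.series.index[max(lo_pos, 0)]
            hi_anchor = self.series.index[min(hi_pos, len(self.series) - 1)]
            padded = self.series.loc[lo_anchor:hi_anchor]
            padded = padded.reindex(pd.date_range(lo_anchor, hi_anchor, freq="D"))
            run = _longest_nan_run(padded.to_numpy())
            if run > max_gap:
                raise WeatherGapError(
                    f"site {self.site_id}: gap of {run} consecutive days around "
                    f"{first}..{last} exceeds the {max_gap}-day tolerance"
                )
            window = padded.interpolate(method="time").loc[first_ts:last_ts]
        return window


def _longest_nan_run(values: np.ndarray) -> int:
    isna = np.isnan(values)
    if not isna.any():
        return 0
    best = cur = 0
    for flag in isna:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# DR models
# ---------------------------------------------------------------------------

VALID_KINDS = ("linear", "multiple", "polynomial")


@dataclass(frozen=True)
class DRModel:
    """A developmental-rate function with its coefficients.

    Parameters
    ----------
    kind:
        ``"linear"``, ``"multiple"`` or ``"polynomial"``.
    a:
        Intercept [d^-1].
    b:
        Temperature slope [degC^-1 d^-1].
    c:
        Second coefficient: daylength slope [h^-1 d^-1] for ``multiple``,
        quadratic temperature coefficient [degC^-2 d^-1] for ``polynomial``;
        unused for ``linear``.
    t_ref, p_ref:
        Training-sample means of temperature and daylength.  Required only by
        the ``multiple`` kind, whose critical values are defined as the
        x-intercepts of the two univariate projections of the fitted plane,
        each holding the other predictor at its training mean.
    """

    kind: str
    a: float
    b: float
    c: float | None = None
    t_ref: float | None = None
    p_ref: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ModelKindError(
                f"unknown model kind {self.kind!r}; expected one of {VALID_KINDS}"
            )
        if self.kind == "linear" and self.b == 0:
            raise InvalidModelError("linear DR requires b != 0")
        if self.kind in ("multiple", "polynomial") and self.c is None:
            raise InvalidModelError(f"{self.kind} DR requires coefficient c")

    @property
    def n_coefficients(self) -> int:
        return 2 if self.kind == "linear" else 3

    def thresholds(self):
        """Derived critical values; see :func:`critical_thresholds`."""
        return critical_thresholds(self)


class LinearThresholds(NamedTuple):
    t0: float  #: base temperature [degC], -a/b


class MultipleThresholds(NamedTuple):
    t0m: float  #: critical temperature [degC] at the training-mean daylength
    p0m: float  #: critical daylength [h] at the training-mean temperature


class PolynomialThresholds(NamedTuple):
    tp1: float  #: lower zero of the parabola [degC]
    tp2: float  #: upper zero of the parabola [degC]


def critical_thresholds(model: DRModel):
    """Derive the critical predictor values at which development stops.

    * linear: base temperature ``T0 = -a/b``;
    * polynomial: the two real roots of ``a + b*T + c*T**2 = 0`` in ascending
      order (requires a downward parabola, ``c < 0``, with positive
      discriminant);
    * multiple: ``(T0m, P0m)``, the x-intercepts of the fitted plane's two
      univariate projections taken at the training means carried by the model.
    """
    if model.kind == "linear":
        if model.b == 0:
            raise ThresholdUndefinedError("base temperature undefined for b = 0")
        return LinearThresholds(t0=-model.a / model.b)
    if model.kind == "polynomial":
        a, b, c = model.a, model.b, float(model.c)
        if c >= 0:
            raise InvalidModelError(
                "polynomial DR requires c < 0 (downward parabola) for simulation"
            )
        disc = b * b - 4.0 * c * a
        if disc < 0:
            raise ThresholdUndefinedError(
                "polynomial DR has no real roots (discriminant < 0)"
            )
        r1 = (-b + math.sqrt(disc)) / (2.0 * c)
        r2 = (-b - math.sqrt(disc)) / (2.0 * c)
        tp1, tp2 = sorted((r1, r2))
        return PolynomialThresholds(tp1=tp1, tp2=tp2)
    # multiple
    if model.t_ref is None or model.p_ref is None:
        raise ConfigurationError(
            "multiple DR thresholds need training means t_ref and p_ref"
        )
    if model.b == 0:
        raise ThresholdUndefinedError("multiple DR thresholds need b != 0")
    t0m = -(model.a + float(model.c) * model.p_ref) / model.b
    if model.c == 0:
        # Degenerate daylength coefficient: no daylength gate, the model
        # collapses onto the simple linear DR.
        p0m = -math.inf
    else:
        p0m = -(model.a + model.b * model.t_ref) / float(model.c)
    return MultipleThresholds(t0m=t0m, p0m=p0m)


ArrayLike = Union[float, np.ndarray]


def _check_kind(model: DRModel, kind: str) -> None:
    if model.kind != kind:
        raise ModelKindError(f"expected a {kind} model, got {model.kind!r}")


def _as_rate(raw: np.ndarray, mask: np.ndarray, scalar: bool) -> ArrayLike:
    rate = np.where(mask, raw, 0.0)
    rate = np.maximum(rate, 0.0)  # rates are never negative
    return float(rate) if scalar else rate


def dr_linear(t: ArrayLike, model: DRModel) -> ArrayLike:
    """Daily developmental rate ``a + b*T`` [d^-1], zero at and below T0.

    The comparison with the base temperature is strict (``T > T0``); at
    exactly T0 the rate is zero both by rule and by construction.
    """
    _check_kind(model, "linear")
    t0 = critical_thresholds(model).t0
    t_arr = np.asarray(t, dtype=float)
    return _as_rate(model.a + model.b * t_arr, t_arr > t0, np.isscalar(t))


def dr_multiple(t: ArrayLike, p: ArrayLike, model: DRModel) -> ArrayLike:
    """Daily rate ``a + b*T + c*P`` [d^-1]; zero unless T > T0m and P > P0m."""
    _check_kind(model, "multiple")
    th = critical_thresholds(model)
    t_arr = np.asarray(t, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    raw = model.a + model.b * t_arr + float(model.c) * p_arr
    mask = (t_arr > th.t0m) & (p_arr > th.p0m)
    return _as_rate(raw, mask, np.isscalar(t) and np.isscalar(p))


def dr_polynomial(t: ArrayLike, model: DRModel) -> ArrayLike:
    """Daily rate ``a + b*T + c*T**2`` [d^-1]; zero outside (Tp1, Tp2)."""
    _check_kind(model, "polynomial")
    th = critical_thresholds(model)
    t_arr = np.asarray(t, dtype=float)
    raw = model.a + model.b * t_arr + float(model.c) * t_arr * t_arr
    mask = (t_arr > th.tp1) & (t_arr < th.tp2)
    return _as_rate(raw, mask, np.isscalar(t))


def daily_rate(t: ArrayLike, p: ArrayLike | None, model: DRModel) -> ArrayLike:
    """Dispatch to the DR function matching ``model.kind``.

    ``p`` (daylength, hours) is required only for the ``multiple`` kind.
    """
    if model.kind == "linear":
        return dr_linear(t, model)
    if model.kind == "polynomial":
        return dr_polynomial(t, model)
    if p is None:
        raise ConfigurationError("multiple DR needs daylength values")
    return dr_multiple(t, p, model)


# ---------------------------------------------------------------------------
# Daylength (FAO-56 daylight hours)
# ---------------------------------------------------------------------------

def compute_daylength(latitude: float, doy: ArrayLike) -> ArrayLike:
    """Daylight hours from latitude and day of year (FAO-56).

    Solar declination ``delta = 0.409*sin(2*pi*doy/365 - 1.39)`` [rad], sunset
    hour angle ``omega_s = arccos(-tan(phi)*tan(delta))`` and daylength
    ``N = 24/pi * omega_s``.  Day 366 is treated as day 365 and the arccos
    argument is clamped to [-1, 1], so polar latitudes degenerate to 0 or 24 h
    rather than erroring.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    scalar = np.isscalar(doy)
    d = np.asarray(doy, dtype=float)
    if np.any((d < 1) | (d > 366)):
        raise ValueError("day of year must lie in [1, 366]")
    d = np.minimum(d, 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * d / 365.0 - 1.39)
    x = -np.tan(np.radians(latitude)) * np.tan(delta)
    omega_s = np.arccos(np.clip(x, -1.0, 1.0))
    n = 24.0 / np.pi * omega_s
    return float(n) if scalar else n


def daylength_for_dates(latitude: float, dates: pd.DatetimeIndex) -> np.ndarray:
    """Vectorised daylength for a DatetimeIndex."""
    return compute_daylength(latitude, dates.dayofyear.to_numpy())
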