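"""Summing-rates simulation of phenological phases.

A phase that started on day ``s`` completes on the first day for which the
cumulative sum of daily developmental rates reaches 1: the rate being the
reciprocal of the phase length, its integral over the true phase is 1 by
definition.  Day counting: day ``j = 1`` is the first day *after* the start
event, so the predicted length ``S`` satisfies ``end = start + S`` days and
round-trips with observed lengths ``S_obs = date_end - date_start``.

The reverse operation reconstructs a start (budbreak) date from an observed
end (flowering) date by accumulating rates backwards from the end day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DailyWeather,
    DRModel,
    MissingWeatherError,
    NoSolutionError,
    daily_rate,
    daylength_for_dates,
)

logger = logging.getLogger("olivephen")

__all__ = ["SimulationResult", "simulate_phase", "reverse_budbreak"]

#: Completion tolerance on the cumulative rate.  The target sum is exactly 1;
#: the tolerance only absorbs float rounding when daily rates are exact
#: reciprocals of an integer length (e.g. S days at 1/S per day).
COMPLETION_EPS = 1e-9

DEFAULT_HORIZON = 366  # days; one year covers any within-season phase


@dataclass
class SimulationResult:
    """Outcome of a forward phase simulation.

    ``trajectory`` holds one row per simulated day (date, daily rate,
    running cumulative sum); when ``completed`` it is truncated at day ``s``,
    otherwise it spans the whole horizon.
    """

    start_date: dt.date
    completed: bool
    s: int | None
    end_date: dt.date | None
    trajectory: pd.DataFrame

    def __post_init__(self) -> None:
        if self.completed:
            assert self.s is not None and self.s >= 1
            assert self.end_date == self.start_date + dt.timedelta(days=self.s)


def _rates(weather: DailyWeather, first: dt.date, last: dt.date, model: DRModel,
           max_gap: int) -> tuple[pd.DatetimeIndex, np.ndarray]:
    temps = weather.daily(first, last, max_gap=max_gap)
    p = None
    if model.kind == "multiple":
        p = daylength_for_dates(weather.latitude, temps.index)
    rates = daily_rate(temps.to_numpy(), p, model)
    return temps.index, np.asarray(rates, dtype=float)


def simulate_phase(
    start_date: dt.date,
    weather: DailyWeather,
    model: DRModel,
    max_horizon: int = DEFAULT_HORIZON,
    max_gap: int = 3,
) -> SimulationResult:
    """Predict a phase length by accumulating daily developmental rates.

    Rates are evaluated on days ``start_date + 1 .. start_date + max_horizon``
    (the start day itself contributes nothing).  The predicted length ``S`` is
    the smallest ``n`` with ``sum(DR_1..DR_n) >= 1``; if the sum never reaches
    1 within the horizon the result is returned with ``completed=False``.

    Raises
    ------
    MissingWeatherError
        If the weather series ends before either completion or the full
        horizon, or starts after ``start_date + 1``.
    WeatherGapError
        If an interior gap longer than ``max_gap`` days is encountered.
    """
    start = pd.Timestamp(start_date).date() if not isinstance(start_date, dt.date) \
        else start_date
    first = start + dt.timedelta(days=1)
    horizon_end = start + dt.timedelta(days=int(max_horizon))
    avail_end = min(horizon_end, weather.last_date)
    if avail_end < first:
        raise MissingWeatherError(
            f"site {weather.site_id}: no weather after start date {start}"
        )
    dates, rates = _rates(weather, first, avail_end, model, max_gap)
    cum = np.cumsum(rates)
    reached = cum >= 1.0 - COMPLETION_EPS
    if reached.any():
        idx = int(np.argmax(reached))
        s = idx + 1
        traj = pd.DataFrame(
            {"date": dates[: s], "dr": rates[: s], "cumulative": cum[: s]}
        )
        return SimulationResult(
            start_date=start,
            completed=True,
            s=s,
            end_date=start + dt.timedelta(days=s),
            trajectory=traj,
        )
    if avail_end < horizon_end:
        raise MissingWeatherError(
            f"site {weather.site_id}: weather ends {weather.last_date}, before "
            f"the phase starting {start} completed or the {max_horizon}-day "
            "horizon elapsed"
        )
    traj = pd.DataFrame({"date": dates, "dr": rates, "cumulative": cum})
    return SimulationResult(
        start_date=start, completed=False, s=None, end_date=None, trajectory=traj
    )


def reverse_budbreak(
    end_date: dt.date,
    weather: DailyWeather,
    model: DRModel,
    max_lookback: int = DEFAULT_HORIZON,
    max_gap: int = 3,
) -> dt.date:
    """Reconstruct the latest start date consistent with an observed end date.

    Returns the latest date ``s`` such that the rates accumulated over
    ``s + 1 .. end_date`` reach 1, i.e. such that a phase started on ``s``
    would have completed no later than ``end_date``.  Applied to a forward
    simulation's end date this recovers the forward start exactly whenever
    the rate on the day after the start exceeds the forward run's overshoot
    (its cumulative sum's excess over 1 at completion); otherwise the
    estimate may fall a day or two later, because dropping leading
    low-rate days still leaves enough accumulated development.

    The lookback window is truncated at the first available weather date if
    the series starts later than ``end_date - max_lookback``.

    Raises
    ------
    NoSolutionError
        If the rates summed over the whole (possibly truncated) lookback
        window never reach 1.
    """
    end = end_date
    earliest = end - dt.timedelta(days=int(max_lookback))
    first = earliest + dt.timedelta(days=1)
    if weather.first_date > first:
        logger.debug(
            "reverse lookback truncated at %s (requested %s) for site %s",
            weather.first_date, first, weather.site_id,
        )
        first = weather.first_date
    if end > weather.last_date or first > end:
        raise MissingWeatherError(
            f"site {weather.site_id}: weather does not cover the lookback "
            f"window ending {end}"
        )
    dates, rates = _rates(weather, first, end, model, max_gap)
    # tail[i] = sum of rates from day i to the end day inclusive; a candidate
    # start s = dates[i] - 1 day is feasible iff tail[i] >= 1.
    tail = np.cumsum(rates[::-1])[::-1]
    feasible = tail >= 1.0 - COMPLETION_EPS
    if not feasible.any():
        raise NoSolutionError(
            f"rates accumulated over {first}..{end} never reach 1; "
            "no start date within the lookback window"
        )
    i = int(np.flatnonzero(feasible)[-1])
    return (dates[i] - pd.Timedelta(days=1)).date()
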