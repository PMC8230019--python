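"""Synthetic weather and phenology with known ground truth.

The generators emulate the structure of the multi-site Italian olive survey
that the calibrations were built on: seven sites spanning latitudes
37.4-43.7 N, seventeen varieties (three common to every site), years
1997-1999, a sinusoidal annual temperature cycle with daily noise, event
dates produced by forward summing-rates simulation under known DR models,
whole-day survey jitter, and incomplete event coverage.  Every downstream
module can therefore be exercised against a known truth without any
external dataset.

Defaults (study conditions):

* budbreak (BBCH 01) day of year drawn uniformly in [30, 120];
* event chain 01 -> 61 -> 65, with the published (01, 61) linear
  calibration as the true budbreak-to-flowering model and a short invented
  (61, 65) model (about 7 days at 17 degC);
* survey date jitter sigma_obs = 3.5 days (half the 7-day survey interval),
  rounded to whole days, independent per event, redrawn if it would produce
  a non-positive phase length;
* per-event missingness p = 0.2, so a two-event phase retains about
  0.8^2 * 108 ~ 69 of the 7 sites x 36 site-variety pairs x 3 years
  combinations, matching the survey's per-phase sample sizes.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BBCHEvent,
    DailyWeather,
    DRModel,
    PhenologicalObservation,
    daylength_for_dates,
)
from .calibrate import PhaseRecord, bundled_calibration
from .simulate import simulate_phase

logger = logging.getLogger("olivephen")

__all__ = [
    "SyntheticSiteSpec",
    "SyntheticTruth",
    "default_site_specs",
    "default_truth",
    "generate_weather",
    "generate_observations",
    "synthetic_survey",
    "integer_consistent_records",
]


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Parameters of one synthetic site's climate and survey design.

    The daily mean temperature follows
    ``T(doy) = t_mean + amplitude * sin(2*pi*(doy - phase_shift)/365) + eps``
    with ``eps ~ Normal(0, sigma_t)``; ``phase_shift = 109`` puts the warmest
    day near DOY 200 (mid July).
    """

    site_id: str
    latitude: float
    t_mean: float
    amplitude: float = 8.5
    phase_shift: float = 109.0
    sigma_t: float = 2.0
    years: tuple[int, ...] = (1997, 1998, 1999)
    varieties: tuple[str, ...] = ("V01", "V02", "V03")

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.sigma_t < 0:
            raise ValueError("amplitude and sigma_t must be >= 0")


def _default_t_mean(latitude: float) -> float:
    # Annual mean cooling ~0.6 degC per degree of latitude around 15 degC at 40.5 N.
    return 15.0 + 0.6 * (40.5 - latitude)


def default_site_specs(**overrides) -> list[SyntheticSiteSpec]:
    """Seven sites mirroring the survey's latitudinal span and variety layout.

    Three varieties (V01-V03) are common to all sites; fourteen more are
    site-specific, for seventeen in total distributed 7/5/4/5/5/5/5.
    """
    layout = [
        ("IT-N1", 43.66, ("V01", "V02", "V03", "V04", "V05", "V06", "V07")),
        ("IT-S1", 39.38, ("V01", "V02", "V03", "V08", "V09")),
        ("IT-E1", 41.03, ("V01", "V02", "V03", "V10")),
        ("IT-S2", 37.41, ("V01", "V02", "V03", "V11", "V12")),
        ("IT-S3", 37.60, ("V01", "V03", "V13", "V14", "V15")),
        ("IT-S4", 39.36, ("V01", "V02", "V03", "V16", "V14")),
        ("IT-N2", 42.99, ("V01", "V02", "V03", "V04", "V17")),
    ]
    return [
        SyntheticSiteSpec(
            site_id=sid,
            latitude=lat,
            t_mean=_default_t_mean(lat),
            varieties=varieties,
            **overrides,
        )
        for sid, lat, varieties in layout
    ]


def _default_truth_models() -> dict[tuple[int, int], DRModel]:
    return {
        (1, 61): bundled_calibration(1, 61),
        # Short flowering phase: ~7 days at 17 degC, base temperature ~7 degC.
        (61, 65): DRModel(kind="linear", a=-0.10, b=0.0143),
    }


@dataclass
class SyntheticTruth:
    """Ground truth of the synthetic phenology: chain, models and noise."""

    chain: tuple[int, ...] = (1, 61, 65)
    models: dict[tuple[int, int], DRModel] = field(default_factory=_default_truth_models)
    sigma_obs: float = 3.5
    start_doy_range: tuple[int, int] = (30, 120)
    p_missing: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be >= 0")
        if not 0.0 <= self.p_missing < 1.0:
            raise ValueError("p_missing must lie in [0, 1)")
        for pair in zip(self.chain[:-1], self.chain[1:]):
            if pair not in self.models:
                raise ValueError(f"no true model for consecutive phase {pair}")


def generate_weather(spec: SyntheticSiteSpec, seed) -> DailyWeather:
    """Seeded daily temperature series for every calendar day of the spec's years."""
    rng = np.random.default_rng(seed)
    frames = [
        pd.date_range(dt.date(y, 1, 1), dt.date(y, 12, 31), freq="D")
        for y in spec.years
    ]
    dates = frames[0]
    for f in frames[1:]:
        dates = dates.append(f)
    doy = dates.dayofyear.to_numpy(dtype=float)
    temps = (
        spec.t_mean
        + spec.amplitude * np.sin(2.0 * np.pi * (doy - spec.phase_shift) / 365.0)
        + rng.normal(0.0, spec.sigma_t, size=len(dates))
    )
    return DailyWeather(spec.site_id, spec.latitude, pd.Series(temps, index=dates))


_MAX_JITTER_TRIES = 100


def _jitter_dates(
    true_dates: list[dt.date], sigma: float, year: int, rng: np.random.Generator
) -> list[dt.date] | None:
    """Whole-day jitter per event; redrawn until all phase lengths stay >= 1
    and every date stays within the record's calendar year."""
    if sigma == 0:
        return list(true_dates)
    for _ in range(_MAX_JITTER_TRIES):
        offsets = np.rint(rng.normal(0.0, sigma, size=len(true_dates))).astype(int)
        jittered = [d + dt.timedelta(days=int(o)) for d, o in zip(true_dates, offsets)]
        if all(b > a for a, b in zip(jittered, jittered[1:])) and all(
            d.year == year for d in jittered
        ):
            return jittered
    return None


def generate_observations(
    truth: SyntheticTruth,
    sites: list[SyntheticSiteSpec],
    weather: dict[str, DailyWeather],
    seed: int,
) -> list[PhenologicalObservation]:
    """Forward-simulate the event chain for every (site, variety, year).

    A budbreak date is drawn uniformly over the truth's DOY range, each
    consecutive phase end is obtained with the summing-rates simulator under
    the true model, survey jitter is applied, and each event is then emitted
    independently with probability ``1 - p_missing``.  Records whose
    simulation does not complete or whose jitter cannot be made consistent
    are skipped with a warning.
    """
    observations: list[PhenologicalObservation] = []
    events = [BBCHEvent.from_code(c) for c in truth.chain]
    lo, hi = truth.start_doy_range
    for si, spec in enumerate(sites):
        site_weather = weather[spec.site_id]
        for vi, variety in enumerate(spec.varieties):
            for year in spec.years:
                rng = np.random.default_rng([seed, si, vi, year])
                start_doy = int(rng.integers(lo, hi + 1))
                start = dt.date(year, 1, 1) + dt.timedelta(days=start_doy - 1)
                true_dates = [start]
                ok = True
                for pair in zip(truth.chain[:-1], truth.chain[1:]):
                    result = simulate_phase(
                        true_dates[-1], site_weather, truth.models[pair]
                    )
                    if not result.completed:
                        logger.warning(
                            "synthetic record skipped (%s, %s, %d): phase %s "
                            "did not complete", spec.site_id, variety, year, pair,
                        )
                        ok = False
                        break
                    true_dates.append(result.end_date)
                if not ok:
                    continue
                jittered = _jitter_dates(true_dates, truth.sigma_obs, year, rng)
                if jittered is None:
                    logger.warning(
                        "synthetic record skipped (%s, %s, %d): jitter never "
                        "consistent", spec.site_id, variety, year,
                    )
                    continue
                keep = rng.random(len(events)) >= truth.p_missing
                for event, date, kept in zip(events, jittered, keep):
                    if kept:
                        observations.append(
                            PhenologicalObservation(
                                site_id=spec.site_id,
                                latitude=spec.latitude,
                                variety=variety,
                                year=year,
                                event=event,
                                date=date,
                            )
                        )
    return observations


def synthetic_survey(
    seed: int,
    sigma_obs: float = 3.5,
    p_missing: float = 0.2,
    sites: list[SyntheticSiteSpec] | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[list[PhenologicalObservation], dict[str, DailyWeather], SyntheticTruth]:
    """One complete synthetic survey: observations, per-site weather and truth."""
    if sites is None:
        sites = default_site_specs()
    if truth is None:
        truth = SyntheticTruth(sigma_obs=sigma_obs, p_missing=p_missing)
    weather = {
        spec.site_id: generate_weather(spec, [seed, 1000 + i])
        for i, spec in enumerate(sites)
    }
    observations = generate_observations(truth, sites, weather, seed)
    return observations, weather, truth


def default_truth(**kwargs) -> SyntheticTruth:
    return SyntheticTruth(**kwargs)


def integer_consistent_records(
    model: DRModel,
    s_values,
    from_code: int = 1,
    to_code: int = 61,
    latitude: float = 40.0,
    start_date: dt.date = dt.date(1997, 3, 1),
) -> tuple[list[PhaseRecord], dict[str, DailyWeather]]:
    """Noise-free records whose integer lengths are exactly consistent with
    a linear DR model.

    For each requested integer length ``S`` the temperature ``T`` solving
    ``a + b*T = 1/S`` is used as a constant daily series at a dedicated
    synthetic site, so that ``DR_obs = 1/S`` lies exactly on the model and
    the summing-rates simulator completes at exactly ``S`` days.  This is the
    noiseless limit of the generate -> derive -> fit pipeline: OLS recovers
    the generating coefficients to machine precision and forward simulation
    round-trips every record.
    """
    records: list[PhaseRecord] = []
    weather: dict[str, DailyWeather] = {}
    from_event = BBCHEvent.from_code(from_code)
    to_event = BBCHEvent.from_code(to_code)
    for i, s in enumerate(s_values):
        s = int(s)
        if s < 1:
            raise ValueError(f"phase length {s} < 1 day")
        t = (1.0 / s - model.a) / model.b
        site_id = f"synth-{i:03d}"
        dates = pd.date_range(
            start_date - dt.timedelta(days=1),
            start_date + dt.timedelta(days=s + 400),
            freq="D",
        )
        weather[site_id] = DailyWeather(
            site_id, latitude, pd.Series(np.full(len(dates), t), index=dates)
        )
        window = pd.date_range(
            start_date + dt.timedelta(days=1), start_date + dt.timedelta(days=s)
        )
        records.append(
            PhaseRecord(
                from_event=from_event,
                to_event=to_event,
                site_id=site_id,
                variety="V01",
                year=start_date.year,
                start_date=start_date,
                s_obs=s,
                t_mean=t,
                p_mean=float(daylength_for_dates(latitude, window).mean()),
            )
        )
    return records, weather
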