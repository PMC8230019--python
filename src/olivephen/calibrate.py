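"""Phase-record construction, filtering and DR-model calibration.

A *phase* is the interval between two distinct BBCH events observed in the
same (site, variety, year).  From dated observations and daily weather this
module derives one record per observed phase instance — length ``S_obs``
[days], the mean temperature and daylength experienced during the phase, and
the observed developmental rate ``DR_obs = 1/S_obs`` — then fits DR functions
to record collections by ordinary least squares.

The means are taken over days ``start + 1 .. end``, the same days that carry
rate in the summing-rates simulator, keeping calibration and simulation
self-consistent.

The final published calibrations for the six cross-validated
budbreak/inflorescence-to-flowering phases are bundled
(:func:`bundled_calibration`).
"""

from __future__ import annotations

import datetime as dt
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    BBCHEvent,
    DailyWeather,
    DataFormatError,
    DRModel,
    FitError,
    MissingWeatherError,
    PhenologicalObservation,
    UnknownPhaseError,
    WeatherGapError,
    critical_thresholds,
    daylength_for_dates,
)

logger = logging.getLogger("olivephen")

__all__ = [
    "PhaseRecord",
    "PhaseCatalogue",
    "CalibrationResult",
    "derive_phase_records",
    "filter_phases",
    "fit_dr",
    "bundled_calibration",
    "bundled_table",
    "BUNDLED_PHASES",
    "lower_median_date",
    "reduce_plant_observations",
]


@dataclass(frozen=True)
class PhaseRecord:
    """One observed phase instance at a (site, variety, year).

    ``start_date`` is kept so that a held-out record can later be re-simulated
    from its own observed start during validation.
    """

    from_event: BBCHEvent
    to_event: BBCHEvent
    site_id: str
    variety: str
    year: int
    start_date: dt.date
    s_obs: int
    t_mean: float
    p_mean: float

    def __post_init__(self) -> None:
        if self.from_event.code >= self.to_event.code:
            raise ValueError(
                f"phase must run forward on the BBCH scale: "
                f"{self.from_event.code} >= {self.to_event.code}"
            )
        if self.s_obs < 1:
            raise ValueError(f"phase length {self.s_obs} < 1 day")

    @property
    def dr_obs(self) -> float:
        """Observed developmental rate, exactly 1/S_obs [d^-1]."""
        return 1.0 / self.s_obs

    @property
    def phase(self) -> tuple[int, int]:
        return (self.from_event.code, self.to_event.code)


@dataclass
class PhaseCatalogue:
    """Phase records grouped by (from_code, to_code), with group summaries."""

    groups: dict[tuple[int, int], list[PhaseRecord]] = field(default_factory=dict)
    n_rejected: int = 0

    def add(self, record: PhaseRecord) -> None:
        self.groups.setdefault(record.phase, []).append(record)

    def phases(self) -> list[tuple[int, int]]:
        return sorted(self.groups)

    def records(self, phase: tuple[int, int]) -> list[PhaseRecord]:
        return self.groups[phase]

    def n_sites(self, phase: tuple[int, int]) -> int:
        return len({r.site_id for r in self.groups[phase]})

    def __len__(self) -> int:
        return len(self.groups)

    def summary(self) -> pd.DataFrame:
        """Per-phase sample description: site/record counts, mean and SD of S."""
        rows = []
        for phase in self.phases():
            lengths = np.array([r.s_obs for r in self.groups[phase]], dtype=float)
            rows.append(
                {
                    "from_bbch": phase[0],
                    "to_bbch": phase[1],
                    "n_sites": self.n_sites(phase),
                    "n_records": len(lengths),
                    "s_mean": float(lengths.mean()),
                    "s_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["from_bbch", "to_bbch", "n_sites", "n_records", "s_mean", "s_sd"],
        )


def derive_phase_records(
    observations: list[PhenologicalObservation],
    weather: dict[str, DailyWeather],
    max_gap: int = 3,
) -> PhaseCatalogue:
    """Build phase records from all pairwise event combinations.

    For every (site, variety, year) and every pair of observed events with
    ``from.code < to.code``: ``S_obs`` is the day difference between the two
    dates, and temperature/daylength are averaged over the ``S_obs`` days
    following the start date.  Records whose end precedes (or equals) the
    start, or whose weather span is missing or too gappy, are rejected with a
    logged warning and counted in ``catalogue.n_rejected``.
    """
    catalogue = PhaseCatalogue()
    keyfn = lambda o: (o.site_id, o.variety, o.year)
    for key, group_iter in itertools.groupby(sorted(observations, key=keyfn), keyfn):
        group = list(group_iter)
        dates: dict[int, PhenologicalObservation] = {}
        for obs in group:
            if obs.event.code in dates:
                raise DataFormatError(
                    f"duplicate event BBCH {obs.event.code:02d} for {key}; reduce "
                    "per-plant dates first (see reduce_plant_observations)"
                )
            dates[obs.event.code] = obs
        for c1, c2 in itertools.combinations(sorted(dates), 2):
            start_obs, end_obs = dates[c1], dates[c2]
            s_obs = (end_obs.date - start_obs.date).days
            if s_obs <= 0:
                logger.warning(
                    "rejected phase %02d->%02d for %s: end %s not after start %s",
                    c1, c2, key, end_obs.date, start_obs.date,
                )
                catalogue.n_rejected += 1
                continue
            site_weather = weather.get(start_obs.site_id)
            if site_weather is None:
                logger.warning("rejected phase %02d->%02d for %s: no weather", c1, c2, key)
                catalogue.n_rejected += 1
                continue
            first = start_obs.date + dt.timedelta(days=1)
            try:
                temps = site_weather.daily(first, end_obs.date, max_gap=max_gap)
            except (MissingWeatherError, WeatherGapError) as exc:
                logger.warning(
                    "rejected phase %02d->%02d for %s: %s", c1, c2, key, exc
                )
                catalogue.n_rejected += 1
                continue
            p_mean = float(daylength_for_dates(site_weather.latitude, temps.index).mean())
            catalogue.add(
                PhaseRecord(
                    from_event=start_obs.event,
                    to_event=end_obs.event,
                    site_id=start_obs.site_id,
                    variety=start_obs.variety,
                    year=start_obs.year,
                    start_date=start_obs.date,
                    s_obs=s_obs,
                    t_mean=float(temps.mean()),
                    p_mean=p_mean,
                )
            )
    return catalogue


def filter_phases(catalogue: PhaseCatalogue, min_sites: int = 5) -> PhaseCatalogue:
    """Keep only phases with records from at least ``min_sites`` distinct sites.

    The default of 5 guarantees environmental heterogeneity in each phase's
    sample, mirroring the calibration survey's screening rule.
    """
    kept = PhaseCatalogue(n_rejected=catalogue.n_rejected)
    for phase in catalogue.phases():
        if catalogue.n_sites(phase) >= min_sites:
            kept.groups[phase] = list(catalogue.groups[phase])
    return kept


# ---------------------------------------------------------------------------
# Per-plant reduction helper
# ---------------------------------------------------------------------------

def lower_median_date(dates: list[dt.date]) -> dt.date:
    """Median of dates; for an even count, the lower of the two middle dates
    (deterministic, no averaging of calendar dates)."""
    if not dates:
        raise ValueError("no dates to reduce")
    ordered = sorted(dates)
    return ordered[(len(ordered) - 1) // 2]


def reduce_plant_observations(
    frame: pd.DataFrame, plant_col: str = "plant"
) -> pd.DataFrame:
    """Reduce per-plant survey rows to one date per (site, variety, year, bbch).

    Input columns: ``site_id, latitude, variety, year, bbch, date`` plus a
    plant identifier column; the output drops the plant column and carries the
    lower-median date of each group.
    """
    key = ["site_id", "latitude", "variety", "year", "bbch"]
    missing = [c for c in key + [plant_col, "date"] if c not in frame.columns]
    if missing:
        raise DataFormatError(f"missing columns for plant reduction: {missing}")
    reduced = (
        frame.groupby(key, as_index=False)["date"]
        .agg(lambda s: lower_median_date(list(s)))
    )
    return reduced


# ---------------------------------------------------------------------------
# OLS calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """A fitted DR function for one phase with its regression statistics.

    ``r2`` is the squared Pearson correlation between fitted and observed
    rates (identical to the classical coefficient of determination for an
    OLS fit with intercept); ``p_value`` is the regression F-test p-value.
    ``valid_for_simulation`` is False for a fitted upward parabola, whose
    upper temperature cut-off is meaningless.
    """

    phase: tuple[int, int]
    model: DRModel
    r2: float
    p_value: float
    n_sites: int
    n_records: int
    valid_for_simulation: bool = True

    def thresholds(self):
        return critical_thresholds(self.model)


def _design_matrix(kind: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    if kind == "linear":
        return t[:, None]
    if kind == "multiple":
        return np.column_stack([t, p])
    return np.column_stack([t, t * t])  # polynomial


def fit_dr(records: list[PhaseRecord], kind: str) -> CalibrationResult:
    """Fit a DR function of the given kind to phase records by OLS.

    Requires at least ``k + 1`` records (k = 2 coefficients for linear, 3
    otherwise) and non-degenerate predictors; raises :class:`FitError`
    otherwise.  A polynomial fit with ``c >= 0`` is returned flagged
    ``valid_for_simulation=False`` with a logged warning rather than raised.
    """
    if not records:
        raise FitError("no records to fit")
    phases = {r.phase for r in records}
    if len(phases) > 1:
        raise FitError(f"records mix phases {sorted(phases)}")
    k = 2 if kind == "linear" else 3
    if len(records) < k + 1:
        raise FitError(f"{kind} fit needs at least {k + 1} records, got {len(records)}")
    y = np.array([r.dr_obs for r in records], dtype=float)
    t = np.array([r.t_mean for r in records], dtype=float)
    p = np.array([r.p_mean for r in records], dtype=float)
    x = _design_matrix(kind, t, p)
    exog = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise FitError(f"degenerate predictors for {kind} fit (rank deficiency)")
    res = sm.OLS(y, exog).fit()
    coefs = res.params
    a, b = float(coefs[0]), float(coefs[1])
    c = float(coefs[2]) if kind != "linear" else None
    model = DRModel(
        kind=kind, a=a, b=b, c=c,
        t_ref=float(t.mean()) if kind == "multiple" else None,
        p_ref=float(p.mean()) if kind == "multiple" else None,
    )
    valid = True
    if kind == "polynomial" and c is not None and c >= 0:
        valid = False
        logger.warning(
            "polynomial fit for phase %s has c = %.3g >= 0 (upward parabola); "
            "model rejected for simulation", sorted(phases)[0], c,
        )
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = np.nan
    else:
        r2 = float(stats.pearsonr(fitted, y)[0] ** 2)
    return CalibrationResult(
        phase=sorted(phases)[0],
        model=model,
        r2=r2,
        p_value=float(res.f_pvalue),
        n_sites=len({r.site_id for r in records}),
        n_records=len(records),
        valid_for_simulation=valid,
    )


# ---------------------------------------------------------------------------
# Bundled final calibrations
# ---------------------------------------------------------------------------

# Published final linear calibrations for the six cross-validated phases:
# phase -> (a [d^-1], b [degC^-1 d^-1], published T0 [degC], r2, p_value).
# For (1, 65) and (51, 65) the published T0 differs from -a/b computed from
# the published (rounded) coefficients by 0.1 degC; both values are exposed
# via bundled_table().
_FINAL_LINEAR: dict[tuple[int, int], tuple[float, float, float, float, float]] = {
    (1, 61): (-0.0180, 0.0025, 7.2, 0.85, 1.8e-21),
    (7, 61): (-0.0253, 0.0031, 8.2, 0.79, 1.1e-25),
    (51, 61): (-0.0817, 0.0075, 10.9, 0.62, 5.9e-19),
    (1, 65): (-0.0132, 0.0020, 6.7, 0.89, 1.2e-25),
    (7, 65): (-0.0187, 0.0024, 7.8, 0.81, 1.7e-27),
    (51, 65): (-0.0540, 0.0050, 10.7, 0.74, 2.9e-26),
}

BUNDLED_PHASES: tuple[tuple[int, int], ...] = tuple(sorted(_FINAL_LINEAR))


def bundled_calibration(from_code: int, to_code: int) -> DRModel:
    """The shipped final linear calibration for one cross-validated phase.

    Supported phases run from budbreak (BBCH 01 and 07) or inflorescence
    swelling (BBCH 51) to the beginning of flowering (61) or full flowering
    (65).
    """
    key = (int(from_code), int(to_code))
    if key not in _FINAL_LINEAR:
        raise UnknownPhaseError(
            f"no bundled calibration for phase {key[0]:02d}->{key[1]:02d}; "
            f"supported phases: "
            + ", ".join(f"{f:02d}->{t:02d}" for f, t in BUNDLED_PHASES)
        )
    a, b, _, _, _ = _FINAL_LINEAR[key]
    return DRModel(kind="linear", a=a, b=b)


def bundled_table() -> pd.DataFrame:
    """All bundled calibrations with published and derived base temperatures."""
    rows = []
    for (f, t), (a, b, t0_pub, r2, p) in sorted(_FINAL_LINEAR.items()):
        rows.append(
            {
                "from_bbch": f,
                "to_bbch": t,
                "a": a,
                "b": b,
                "t0_published": t0_pub,
                "t0_derived": -a / b,
                "r2": r2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
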