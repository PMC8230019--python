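"""Delimited-text readers/writers and run configuration.

Formats
-------
weather CSV
    header ``site_id, latitude, date, tmean_c``; one row per site-day,
    ISO-8601 dates, strictly one latitude per site.
observations CSV
    header ``site_id, latitude, variety, year, bbch, date``; the BBCH code
    must belong to the supported 19-event catalogue and the date must fall
    in the stated year.
calibrations / CV reports / simulation output
    JSON; calibration entries carry ``phase, kind, a, b, c, thresholds, r2,
    p_value, n_sites, n_records``.

Errors in input tables are reported with the 1-based physical line number
(header is line 1).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    BBCH_CATALOGUE,
    BBCHEvent,
    DailyWeather,
    DataFormatError,
    DRModel,
    InvalidModelError,
    PhenologicalObservation,
    ThresholdUndefinedError,
)
from .calibrate import CalibrationResult
from .evaluate import CVReport

logger = logging.getLogger("olivephen")

__all__ = [
    "RunConfig",
    "read_weather",
    "write_weather",
    "read_observations",
    "write_observations",
    "write_calibrations",
    "read_calibrations",
    "write_cv_reports",
]

WEATHER_COLUMNS = ["site_id", "latitude", "date", "tmean_c"]
OBSERVATION_COLUMNS = ["site_id", "latitude", "variety", "year", "bbch", "date"]


@dataclasses.dataclass
class RunConfig:
    """Defaults shared by the CLI commands; a YAML config file may override
    any field and CLI flags override the file."""

    kind: str = "linear"
    k: int = 5
    n: int = 10
    seed: int = 0
    min_sites: int = 5
    r2_min: float = 0.8
    rmse_max: float = 7.0
    max_horizon: int = 366
    max_lookback: int = 366
    max_gap: int = 3

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for name in ("r2_min", "rmse_max", "max_horizon", "max_lookback"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")


def _parse_dates(df: pd.DataFrame, path) -> pd.Series:
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna())[0]) + 2  # +1 header, +1 one-based
        raise DataFormatError(f"{path}: unparseable date {df['date'].iloc[line - 2]!r} "
                              f"on line {line}")
    return parsed


def _parse_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    parsed = pd.to_numeric(df[col], errors="coerce")
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna())[0]) + 2
        raise DataFormatError(
            f"{path}: unparseable {col} {df[col].iloc[line - 2]!r} on line {line}"
        )
    return parsed


def read_weather(path: str | Path) -> dict[str, DailyWeather]:
    """Read a weather CSV into per-site :class:`DailyWeather` objects."""
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, WEATHER_COLUMNS, path)
    if df.empty:
        return {}
    df = df.assign(
        date=_parse_dates(df, path),
        latitude=_parse_numeric(df, "latitude", path),
        tmean_c=_parse_numeric(df, "tmean_c", path),
    )
    dup = df.duplicated(subset=["site_id", "date"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        row = df.iloc[line - 2]
        raise DataFormatError(
            f"{path}: duplicate (site, date) = ({row.site_id}, "
            f"{row.date.date()}) on line {line}"
        )
    out: dict[str, DailyWeather] = {}
    for site_id, group in df.groupby("site_id", sort=True):
        lats = group["latitude"].unique()
        if len(lats) > 1:
            raise DataFormatError(
                f"{path}: site {site_id} has conflicting latitudes {sorted(lats)}"
            )
        series = pd.Series(
            group["tmean_c"].to_numpy(), index=pd.DatetimeIndex(group["date"])
        ).sort_index()
        out[str(site_id)] = DailyWeather(str(site_id), float(lats[0]), series)
    return out


def write_weather(weather: dict[str, DailyWeather], path: str | Path) -> None:
    frames = []
    for site_id in sorted(weather):
        w = weather[site_id]
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "latitude": w.latitude,
                    "date": w.series.index.strftime("%Y-%m-%d"),
                    "tmean_c": np.round(w.series.to_numpy(), 3),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[PhenologicalObservation]:
    """Read an observations CSV, validating BBCH codes and year consistency."""
    df = pd.read_csv(path, dtype={"site_id": str, "variety": str})
    _require_columns(df, OBSERVATION_COLUMNS, path)
    if df.empty:
        return []
    df = df.assign(
        date=_parse_dates(df, path),
        latitude=_parse_numeric(df, "latitude", path),
        year=_parse_numeric(df, "year", path).astype(int),
        bbch=_parse_numeric(df, "bbch", path).astype(int),
    )
    observations = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        if row.bbch not in BBCH_CATALOGUE:
            raise DataFormatError(
                f"{path}: unknown BBCH code {row.bbch} on line {line}; supported "
                f"codes: {sorted(BBCH_CATALOGUE)}"
            )
        if row.date.year != row.year:
            raise DataFormatError(
                f"{path}: date {row.date.date()} does not fall in year "
                f"{row.year} on line {line}"
            )
        observations.append(
            PhenologicalObservation(
                site_id=str(row.site_id),
                latitude=float(row.latitude),
                variety=str(row.variety),
                year=int(row.year),
                event=BBCHEvent.from_code(row.bbch),
                date=row.date.date(),
            )
        )
    return observations


def write_observations(
    observations: list[PhenologicalObservation], path: str | Path
) -> None:
    rows = [
        {
            "site_id": o.site_id,
            "latitude": o.latitude,
            "variety": o.variety,
            "year": o.year,
            "bbch": o.event.code,
            "date": o.date.isoformat(),
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _thresholds_dict(model: DRModel) -> dict | None:
    try:
        th = model.thresholds()
    except (InvalidModelError, ThresholdUndefinedError):
        return None
    return dict(th._asdict())


def calibration_to_dict(result: CalibrationResult) -> dict:
    m = result.model
    return {
        "phase": list(result.phase),
        "kind": m.kind,
        "a": m.a,
        "b": m.b,
        "c": m.c,
        "t_ref": m.t_ref,
        "p_ref": m.p_ref,
        "thresholds": _thresholds_dict(m),
        "r2": result.r2,
        "p_value": result.p_value,
        "n_sites": result.n_sites,
        "n_records": result.n_records,
        "valid_for_simulation": result.valid_for_simulation,
    }


def write_calibrations(results: list[CalibrationResult], path: str | Path) -> None:
    payload = [calibration_to_dict(r) for r in results]
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def _model_from_dict(entry: dict) -> DRModel:
    return DRModel(
        kind=entry["kind"],
        a=float(entry["a"]),
        b=float(entry["b"]),
        c=None if entry.get("c") is None else float(entry["c"]),
        t_ref=None if entry.get("t_ref") is None else float(entry["t_ref"]),
        p_ref=None if entry.get("p_ref") is None else float(entry["p_ref"]),
    )


def read_calibrations(path: str | Path) -> list[tuple[tuple[int, int] | None, DRModel]]:
    """Read a calibration JSON file: a single model object or a list of
    calibration entries; returns (phase or None, model) pairs."""
    raw = json.loads(Path(path).read_text())
    entries = raw if isinstance(raw, list) else [raw]
    out = []
    for entry in entries:
        phase = entry.get("phase")
        out.append((tuple(int(c) for c in phase) if phase else None,
                    _model_from_dict(entry)))
    return out


def cv_report_to_dict(report: CVReport) -> dict:
    return {
        "phase": list(report.phase),
        "kind": report.kind,
        "r2": report.r2,
        "rmse": report.rmse,
        "mbe": report.mbe,
        "s_mean": report.s_mean,
        "s_sd": report.s_sd,
        "n_sites": report.n_sites,
        "n_records": report.n_records,
        "K": report.k,
        "N": report.n,
        "seed": report.seed,
        "n_fold_runs": report.n_fold_runs,
        "n_skipped_records": report.n_skipped_records,
    }


def write_cv_reports(reports: list[CVReport], path: str | Path,
                     selected: list[CVReport] | None = None) -> None:
    payload = []
    selected_phases = {(r.phase, r.kind) for r in (selected or [])}
    for rep in reports:
        entry = cv_report_to_dict(rep)
        if selected is not None:
            entry["cross_validated"] = (rep.phase, rep.kind) in selected_phases
        payload.append(entry)
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
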