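"""Repeated K-fold cross-validation of DR models at the phase level.

For each of N repeats the phase records are shuffled and split into K folds.
Each fold in turn is held out: a DR function is fitted on the remaining
K−1 folds, every held-out record's phase length is re-simulated with the
summing-rates method from the record's own observed start date and its site
weather, and r², RMSE and MBE are computed on that fold's simulated vs
observed lengths.  The report is the ensemble mean over all K·N fold runs.

Phases whose ensemble metrics clear ``r2 > 0.8`` and ``RMSE < 7`` days are
deemed cross-validated; the RMSE gate reflects the uncertainty of weekly
field surveys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DailyWeather,
    EvaluationError,
    FitError,
    InvalidModelError,
    MissingWeatherError,
    ThresholdUndefinedError,
    WeatherGapError,
)
from .calibrate import PhaseRecord, fit_dr
from .simulate import DEFAULT_HORIZON, simulate_phase

logger = logging.getLogger("olivephen")

__all__ = ["CVReport", "compute_metrics", "kfold_cross_validate", "select_cross_validated"]


@dataclass
class CVReport:
    """Ensemble cross-validation metrics for one phase and model kind.

    ``r2``, ``rmse`` [days] and ``mbe`` [days] are means over the K·N fold
    runs actually evaluated (``n_fold_runs``); for the ``multiple`` kind the
    per-run r² is adjusted for its two predictors.
    """

    phase: tuple[int, int]
    kind: str
    r2: float
    rmse: float
    mbe: float
    k: int
    n: int
    seed: int
    n_sites: int
    n_records: int
    s_mean: float
    s_sd: float
    n_fold_runs: int
    n_skipped_records: int = 0


def compute_metrics(simulated, observed) -> tuple[float, float, float]:
    """r², RMSE and MBE of simulated vs observed phase lengths [days].

    r² is the squared Pearson correlation of the two sequences; when the
    observed (or simulated) lengths have zero variance it is undefined and
    reported as NaN.  RMSE is the root mean squared difference and MBE the
    mean difference (simulated − observed).
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValueError(f"length mismatch: {sim.shape} vs {obs.shape}")
    if len(sim) < 2:
        raise ValueError("need at least two prediction/observation pairs")
    diff = sim - obs
    rmse = float(np.sqrt(np.mean(diff**2)))
    mbe = float(np.mean(diff))
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        r2 = np.nan
    else:
        r2 = float(stats.pearsonr(sim, obs)[0] ** 2)
    return r2, rmse, mbe


def _adjusted_r2(r2: float, n: int, n_predictors: int) -> float:
    dof = n - n_predictors - 1
    if dof <= 0 or np.isnan(r2):
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def kfold_cross_validate(
    records: list[PhaseRecord],
    weather: dict[str, DailyWeather],
    kind: str,
    k: int = 5,
    n: int = 10,
    seed: int = 0,
    max_horizon: int = DEFAULT_HORIZON,
    pool_per_repeat: bool = False,
) -> CVReport:
    """Repeated K-fold cross-validation of one phase's DR model.

    Defaults K=5 folds and N=10 repeats.  Repeat ``i`` derives its own RNG
    stream from ``(seed, i)`` so reports are reproducible across platforms.
    Training folds too small to fit, fits unusable for simulation, and
    held-out records whose simulation does not complete are skipped with a
    warning; if nothing evaluable remains an :class:`EvaluationError` is
    raised.

    With ``pool_per_repeat=True`` the predictions of all K folds of a repeat
    are pooled before computing metrics (one metric set per repeat instead of
    per fold run).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise EvaluationError(f"need at least k={k} records, got {len(records)}")
    records = list(records)
    idx = np.arange(len(records))
    run_metrics: list[tuple[float, float, float]] = []
    n_skipped = 0
    for rep in range(n):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(idx)
        folds = np.array_split(perm, k)
        pooled_sim: list[float] = []
        pooled_obs: list[float] = []
        for fold in folds:
            fold_set = set(fold.tolist())
            val = [records[i] for i in fold]
            train = [records[i] for i in perm if i not in fold_set]
            try:
                cal = fit_dr(train, kind)
            except FitError as exc:
                logger.warning("fold skipped (repeat %d): %s", rep, exc)
                continue
            if not cal.valid_for_simulation:
                logger.warning(
                    "fold skipped (repeat %d): fitted %s model unusable for "
                    "simulation", rep, kind,
                )
                continue
            try:
                cal.thresholds()
            except (InvalidModelError, ThresholdUndefinedError) as exc:
                logger.warning("fold skipped (repeat %d): %s", rep, exc)
                continue
            sim_lengths: list[float] = []
            obs_lengths: list[float] = []
            for rec in val:
                try:
                    result = simulate_phase(
                        rec.start_date, weather[rec.site_id], cal.model,
                        max_horizon=max_horizon,
                    )
                except (MissingWeatherError, WeatherGapError, KeyError) as exc:
                    logger.warning("record skipped: %s", exc)
                    n_skipped += 1
                    continue
                if not result.completed:
                    logger.warning(
                        "record skipped: simulation from %s did not complete "
                        "within %d days", rec.start_date, max_horizon,
                    )
                    n_skipped += 1
                    continue
                sim_lengths.append(float(result.s))
                obs_lengths.append(float(rec.s_obs))
            if pool_per_repeat:
                pooled_sim.extend(sim_lengths)
                pooled_obs.extend(obs_lengths)
                continue
            if len(sim_lengths) < 2:
                logger.warning("fold skipped (repeat %d): <2 evaluable records", rep)
                continue
            r2, rmse, mbe = compute_metrics(sim_lengths, obs_lengths)
            if kind == "multiple":
                r2 = _adjusted_r2(r2, len(sim_lengths), 2)
            run_metrics.append((r2, rmse, mbe))
        if pool_per_repeat:
            if len(pooled_sim) < 2:
                logger.warning("repeat %d skipped: <2 evaluable records", rep)
                continue
            r2, rmse, mbe = compute_metrics(pooled_sim, pooled_obs)
            if kind == "multiple":
                r2 = _adjusted_r2(r2, len(pooled_sim), 2)
            run_metrics.append((r2, rmse, mbe))
    if not run_metrics:
        raise EvaluationError("all folds were skipped; nothing to evaluate")
    arr = np.array(run_metrics, dtype=float)
    lengths = np.array([r.s_obs for r in records], dtype=float)
    phase = records[0].phase
    r2_vals = arr[:, 0]
    r2_mean = float(np.nanmean(r2_vals)) if np.isfinite(r2_vals).any() else float("nan")
    return CVReport(
        phase=phase,
        kind=kind,
        r2=r2_mean,
        rmse=float(np.mean(arr[:, 1])),
        mbe=float(np.mean(arr[:, 2])),
        k=k,
        n=n,
        seed=seed,
        n_sites=len({r.site_id for r in records}),
        n_records=len(records),
        s_mean=float(lengths.mean()),
        s_sd=float(lengths.std(ddof=1)) if len(lengths) > 1 else float("nan"),
        n_fold_runs=len(run_metrics),
        n_skipped_records=n_skipped,
    )


def select_cross_validated(
    reports: list[CVReport], r2_min: float = 0.8, rmse_max: float = 7.0
) -> list[CVReport]:
    """Keep reports with ``r2 > r2_min`` and ``rmse < rmse_max`` (both strict)."""
    return [
        rep
        for rep in reports
        if not np.isnan(rep.r2) and rep.r2 > r2_min and rep.rmse < rmse_max
    ]
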