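"""Phase-record derivation, filtering, OLS fits and bundled calibrations."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

import olivephen as op
from olivephen.core import DataFormatError, FitError, UnknownPhaseError
from olivephen.calibrate import lower_median_date, reduce_plant_observations
from conftest import make_constant_weather


def _obs(site, variety, year, code, date, latitude=40.0):
    return op.PhenologicalObservation(
        site_id=site, latitude=latitude, variety=variety, year=year,
        event=op.BBCHEvent.from_code(code), date=date,
    )


class TestDerivePhaseRecords:
    def test_all_nineteen_events_give_171_phases(self):
        codes = sorted(op.BBCH_CATALOGUE)
        base = dt.date(1997, 2, 1)
        observations = [
            _obs("s1", "v1", 1997, code, base + dt.timedelta(days=10 * i))
            for i, code in enumerate(codes)
        ]
        weather = {"s1": make_constant_weather(15.0, site_id="s1", days=400)}
        catalogue = op.derive_phase_records(observations, weather)
        assert len(catalogue) == 171
        assert sum(len(catalogue.records(p)) for p in catalogue.phases()) == 171
        assert len(codes) * (len(codes) - 1) // 2 == 171

    def test_two_events_give_one_phase(self):
        observations = [
            _obs("s1", "v1", 1997, 1, dt.date(1997, 3, 1)),
            _obs("s1", "v1", 1997, 61, dt.date(1997, 3, 31)),
        ]
        weather = {"s1": make_constant_weather(15.0, site_id="s1")}
        catalogue = op.derive_phase_records(observations, weather)
        assert catalogue.phases() == [(1, 61)]
        record = catalogue.records((1, 61))[0]
        assert record.s_obs == 30
        assert record.dr_obs == 1.0 / 30

    def test_record_count_for_fully_observed_chain(self):
        # E events fully observed -> E*(E-1)/2 records
        codes = [1, 7, 51, 61, 65]
        observations = [
            _obs("s1", "v1", 1997, code, dt.date(1997, 2, 1) + dt.timedelta(days=20 * i))
            for i, code in enumerate(codes)
        ]
        weather = {"s1": make_constant_weather(15.0, site_id="s1")}
        catalogue = op.derive_phase_records(observations, weather)
        assert sum(len(catalogue.records(p)) for p in catalogue.phases()) == 10

    def test_reversed_dates_rejected_not_inverted(self):
        observations = [
            _obs("s1", "v1", 1997, 1, dt.date(1997, 5, 1)),
            _obs("s1", "v1", 1997, 61, dt.date(1997, 3, 1)),  # before budbreak
        ]
        weather = {"s1": make_constant_weather(15.0, site_id="s1")}
        catalogue = op.derive_phase_records(observations, weather)
        assert len(catalogue) == 0
        assert catalogue.n_rejected == 1

    def test_missing_weather_rejects_record(self):
        observations = [
            _obs("s1", "v1", 1997, 1, dt.date(1997, 3, 1)),
            _obs("s1", "v1", 1997, 61, dt.date(1997, 3, 31)),
        ]
        catalogue = op.derive_phase_records(observations, {})
        assert len(catalogue) == 0
        assert catalogue.n_rejected == 1

    def test_duplicate_event_raises(self):
        observations = [
            _obs("s1", "v1", 1997, 1, dt.date(1997, 3, 1)),
            _obs("s1", "v1", 1997, 1, dt.date(1997, 3, 3)),
        ]
        weather = {"s1": make_constant_weather(15.0, site_id="s1")}
        with pytest.raises(DataFormatError):
            op.derive_phase_records(observations, weather)

    def test_means_cover_days_after_start(self):
        # Temperature ramps daily; the mean must span start+1 .. end.
        start = dt.date(1997, 3, 1)
        dates = pd.date_range(start, periods=40, freq="D")
        temps = pd.Series(np.arange(40, dtype=float), index=dates)
        weather = {"s1": op.DailyWeather("s1", 40.0, temps)}
        observations = [
            _obs("s1", "v1", 1997, 1, start),
            _obs("s1", "v1", 1997, 61, start + dt.timedelta(days=10)),
        ]
        record = op.derive_phase_records(observations, weather).records((1, 61))[0]
        assert record.t_mean == pytest.approx(np.mean(np.arange(1, 11)))


class TestFilterPhases:
    def _catalogue_with_sites(self, n_sites):
        observations = []
        weather = {}
        for i in range(n_sites):
            sid = f"s{i}"
            observations += [
                _obs(sid, "v1", 1997, 1, dt.date(1997, 3, 1)),
                _obs(sid, "v1", 1997, 61, dt.date(1997, 4, 20)),
            ]
            weather[sid] = make_constant_weather(15.0, site_id=sid)
        return op.derive_phase_records(observations, weather)

    def test_four_sites_removed_five_retained(self):
        assert len(op.filter_phases(self._catalogue_with_sites(4))) == 0
        assert len(op.filter_phases(self._catalogue_with_sites(5))) == 1

    def test_empty_catalogue(self):
        assert len(op.filter_phases(op.PhaseCatalogue())) == 0


class TestFitDR:
    def test_exact_recovery_on_noiseless_linear_data(self):
        model = op.DRModel(kind="linear", a=-0.0180, b=0.0025)
        records, _ = op.integer_consistent_records(model, range(30, 80, 5))
        result = op.fit_dr(records, "linear")
        assert result.model.a == pytest.approx(model.a, rel=1e-10)
        assert result.model.b == pytest.approx(model.b, rel=1e-10)
        assert result.r2 == pytest.approx(1.0)
        assert result.p_value < 1e-10

    def test_zero_predictor_variance_raises(self):
        model = op.DRModel(kind="linear", a=-0.0180, b=0.0025)
        records, _ = op.integer_consistent_records(model, [40, 40, 40, 40])
        with pytest.raises(FitError):
            op.fit_dr(records, "linear")

    def test_too_few_records_raises(self):
        model = op.DRModel(kind="linear", a=-0.0180, b=0.0025)
        records, _ = op.integer_consistent_records(model, [40, 50])
        with pytest.raises(FitError):
            op.fit_dr(records, "linear")

    def test_upward_parabola_flagged_not_raised(self):
        # Convex (U-shaped) DR-vs-T data force c > 0; the fit must be flagged
        # unusable for simulation.
        records = []
        for i, (t, s) in enumerate([(10, 50), (15, 77), (20, 91), (25, 91),
                                    (30, 77), (35, 50)]):
            records.append(op.PhaseRecord(
                from_event=op.BBCHEvent.from_code(1),
                to_event=op.BBCHEvent.from_code(61),
                site_id=f"s{i}", variety="v", year=1997,
                start_date=dt.date(1997, 3, 1), s_obs=s, t_mean=float(t),
                p_mean=12.0,
            ))
        result = op.fit_dr(records, "polynomial")
        assert result.model.c > 0
        assert not result.valid_for_simulation

    def test_noisy_slope_within_two_standard_errors(self):
        """Monte-Carlo coverage: the OLS slope lands within +-2 SE of truth in
        about 95% of replicates (and its mean is unbiased)."""
        rng = np.random.default_rng(2024)
        a_true, b_true = -0.0180, 0.0025
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            t = rng.uniform(10, 22, size=70)
            y = a_true + b_true * t + rng.normal(0, 0.002, size=70)
            x = np.column_stack([np.ones_like(t), t])
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            sigma2 = resid @ resid / (len(y) - 2)
            cov = sigma2 * np.linalg.inv(x.T @ x)
            if abs(coef[1] - b_true) < 2 * np.sqrt(cov[1, 1]):
                hits += 1
        assert hits / n_rep >= 0.90

    def test_multiple_kind_carries_training_means(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(12):
            t = float(rng.uniform(10, 22))
            p = float(rng.uniform(10, 15))
            s = int(np.clip(round(1.0 / (0.001 + 0.0012 * t + 0.001 * p)), 20, 200))
            records.append(op.PhaseRecord(
                from_event=op.BBCHEvent.from_code(1),
                to_event=op.BBCHEvent.from_code(61),
                site_id=f"s{i}", variety="v", year=1997,
                start_date=dt.date(1997, 3, 1), s_obs=s, t_mean=t, p_mean=p,
            ))
        result = op.fit_dr(records, "multiple")
        assert result.model.t_ref == pytest.approx(np.mean([r.t_mean for r in records]))
        assert result.model.p_ref == pytest.approx(np.mean([r.p_mean for r in records]))
        th = result.thresholds()
        assert np.isfinite(th.t0m) and np.isfinite(th.p0m)


class TestBundledCalibrations:
    @pytest.mark.parametrize(
        "phase, a, b, t0",
        [
            ((1, 61), -0.0180, 0.0025, 7.2),
            ((7, 65), -0.0187, 0.0024, 7.8),
        ],
    )
    def test_published_coefficients(self, phase, a, b, t0):
        model = op.bundled_calibration(*phase)
        assert model.a == a and model.b == b
        assert round(op.critical_thresholds(model).t0, 1) == t0

    def test_unknown_phase_lists_supported_pairs(self):
        with pytest.raises(UnknownPhaseError, match="01->61"):
            op.bundled_calibration(11, 61)

    def test_table_reports_both_base_temperatures(self):
        table = op.bundled_table()
        assert set(["t0_published", "t0_derived"]).issubset(table.columns)
        assert len(table) == 6
        # the two phases whose published T0 disagrees with -a/b by 0.1 degC
        row = table.set_index(["from_bbch", "to_bbch"])
        assert row.loc[(1, 65), "t0_published"] == 6.7
        assert round(row.loc[(1, 65), "t0_derived"], 1) == 6.6
        assert row.loc[(51, 65), "t0_published"] == 10.7
        assert round(row.loc[(51, 65), "t0_derived"], 1) == 10.8


class TestPlantReduction:
    def test_lower_median_even_count(self):
        dates = [dt.date(1997, 3, d) for d in (1, 3, 7, 20)]
        assert lower_median_date(dates) == dt.date(1997, 3, 3)

    def test_lower_median_odd_count(self):
        dates = [dt.date(1997, 3, d) for d in (7, 1, 3)]
        assert lower_median_date(dates) == dt.date(1997, 3, 3)

    def test_reduce_dataframe(self):
        frame = pd.DataFrame({
            "site_id": ["s1"] * 4,
            "latitude": [40.0] * 4,
            "variety": ["v1"] * 4,
            "year": [1997] * 4,
            "bbch": [61] * 4,
            "plant": [1, 2, 3, 4],
            "date": [dt.date(1997, 5, d) for d in (10, 12, 14, 20)],
        })
        reduced = reduce_plant_observations(frame)
        assert len(reduced) == 1
        assert reduced["date"].iloc[0] == dt.date(1997, 5, 12)
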