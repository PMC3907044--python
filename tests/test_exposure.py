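import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trafficsem import exposure
from trafficsem.exposure import (
    DegenerateDesignError,
    apparent_temperature,
    build_exposure_design,
    moving_average,
    residualize_atemp,
    seasonal_terms,
    station_average,
)


class TestApparentTemperature:
    def test_zero_inputs_leave_constant(self):
        assert apparent_temperature(0.0, 0.0) == pytest.approx(-2.653, abs=1e-12)

    def test_hand_evaluated(self):
        assert apparent_temperature(10.0, 10.0) == pytest.approx(8.817, abs=1e-12)

    def test_dewpoint_enters_squared(self):
        assert apparent_temperature(20.0, -10.0) == pytest.approx(18.757, abs=1e-12)
        assert apparent_temperature(20.0, 10.0) == apparent_temperature(20.0, -10.0)

    def test_vectorised(self):
        out = apparent_temperature([0.0, 10.0], [0.0, 10.0])
        np.testing.assert_allclose(out, [-2.653, 8.817], atol=1e-12)

    @pytest.mark.parametrize("bad", [(np.nan, 0.0), (0.0, np.inf), (np.inf, np.nan)])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            apparent_temperature(*bad)

    @given(
        at=st.floats(-40, 45),
        delta=st.floats(0.01, 10),
        dpt=st.floats(-40, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ambient_temperature(self, at, delta, dpt):
        assert apparent_temperature(at + delta, dpt) > apparent_temperature(at, dpt)


class TestSeasonalTerms:
    def test_theta_zero(self):
        s, c = seasonal_terms(0.0)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_quarter_period(self):
        s, c = seasonal_terms(91.31)
        assert s == pytest.approx(1.0, abs=1e-4)
        assert c == pytest.approx(0.0, abs=1e-4)

    def test_half_period(self):
        s, c = seasonal_terms(182.62)
        assert s == pytest.approx(0.0, abs=1e-4)
        assert c == pytest.approx(-1.0, abs=1e-4)

    def test_january_first_is_day_zero(self):
        s, c = seasonal_terms(pd.Timestamp("2003-01-01 14:00"))
        assert (s, c) == pytest.approx((0.0, 1.0), abs=1e-12)

    @given(theta=st.floats(0, 366))
    @settings(max_examples=100, deadline=None)
    def test_unit_circle(self, theta):
        s, c = seasonal_terms(theta)
        assert s * s + c * c == pytest.approx(1.0, abs=1e-12)

    def test_date_array(self):
        dates = pd.to_datetime(["2003-01-01", "2003-07-02"])
        s, c = seasonal_terms(dates)
        assert s.shape == (2,)


def _series(values_by_station, variable="bc", t0="2005-06-01 00:00"):
    rows = []
    for station, vals in values_by_station.items():
        ts0 = pd.Timestamp(t0)
        for i, v in enumerate(vals):
            rows.append(
                {
                    "station": station,
                    "timestamp": ts0 + pd.Timedelta(hours=i),
                    "variable": variable,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestStationAverage:
    def test_two_point_mean(self):
        series = _series({"a": [0.4], "b": [0.6]})
        assert station_average(series, "bc", "2005-06-01 00:00") == pytest.approx(0.5)

    def test_single_station_identity(self):
        series = _series({"a": [0.73]})
        assert station_average(series, "bc", "2005-06-01 00:00") == pytest.approx(0.73)

    def test_missing_station_excluded(self):
        series = _series({"a": [0.4], "b": [np.nan], "c": [0.8]})
        assert station_average(series, "bc", "2005-06-01 00:00") == pytest.approx(0.6)

    def test_no_station_reporting_propagates_missing(self):
        series = _series({"a": [0.4]})
        assert np.isnan(station_average(series, "bc", "2005-06-01 03:00"))
        assert np.isnan(station_average(series, "co", "2005-06-01 00:00"))


class TestMovingAverage:
    def test_constant_series(self):
        series = _series({"a": [3.5] * 100})
        got = moving_average(series, "bc", "2005-06-04 10:30", 24)
        assert got == pytest.approx(3.5, abs=1e-12)

    def test_mean_of_1_to_24(self):
        # hours ending at the visit hour hold 1..24
        series = _series({"a": list(range(1, 25))})
        visit = pd.Timestamp("2005-06-01 23:00")  # hour 23 holds value 24
        got = moving_average(series, "bc", visit, 24)
        assert got == pytest.approx(12.5, abs=1e-12)

    def test_below_completeness_threshold_missing(self):
        vals = [1.0] * 24
        for i in range(14):  # keep only 10 of 24 hours
            vals[i] = np.nan
        series = _series({"a": vals})
        got = moving_average(series, "bc", "2005-06-01 23:00", 24, completeness=0.75)
        assert np.isnan(got)

    def test_window_before_series_start_missing(self):
        series = _series({"a": [1.0] * 10})
        got = moving_average(series, "bc", "2005-05-01 00:00", 24)
        assert np.isnan(got)

    def test_nonstandard_window_warns(self):
        series = _series({"a": [1.0] * 20})
        with pytest.warns(UserWarning, match="outside the standard set"):
            moving_average(series, "bc", "2005-06-01 12:00", 12)

    def test_matches_brute_force_loop(self, rng):
        n = 400
        vals = rng.normal(1.0, 0.3, n)
        vals[rng.random(n) < 0.1] = np.nan
        series = _series({"a": vals})
        table = exposure.station_average_table(series)
        t0 = pd.Timestamp("2005-06-01 00:00")
        for _ in range(50):
            offset = int(rng.integers(80, n))
            minutes = int(rng.integers(0, 60))
            visit = t0 + pd.Timedelta(hours=offset, minutes=minutes)
            w = int(rng.choice([4, 24, 48, 72]))
            got = moving_average(series, "bc", visit, w, table=table)
            end = visit.floor("h")
            hours = [end - pd.Timedelta(hours=h) for h in range(w)]
            present = [
                table["bc"].get(h) for h in hours if pd.notna(table["bc"].get(h))
            ]
            if len(present) / w < 0.75:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(np.mean(present), rel=1e-12)


class TestResidualizeAtemp:
    def test_exact_seasonal_fit_gives_zero_residuals(self, rng):
        theta = rng.uniform(0, 365, 50)
        s, c = seasonal_terms(theta)
        atemp = 4.0 + 2.0 * s - 3.0 * c
        resid, resid2 = residualize_atemp(atemp, s, c)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)
        np.testing.assert_allclose(resid2, 0.0, atol=1e-10)

    def test_recovers_noise_up_to_projection(self, rng):
        theta = rng.uniform(0, 365, 200)
        s, c = seasonal_terms(theta)
        eps = rng.normal(0, 1.5, 200)
        atemp = 4.0 + 2.0 * s - 3.0 * c + eps
        resid, _ = residualize_atemp(atemp, s, c)
        # independent normal-equations solve
        D = np.column_stack([np.ones(200), s, c])
        proj = D @ np.linalg.solve(D.T @ D, D.T @ eps)
        np.testing.assert_allclose(resid, eps - proj, atol=1e-8)

    def test_square_column(self, rng):
        theta = rng.uniform(0, 365, 30)
        s, c = seasonal_terms(theta)
        atemp = rng.normal(10, 5, 30)
        resid, resid2 = residualize_atemp(atemp, s, c)
        np.testing.assert_allclose(resid2, resid**2, atol=1e-14)

    def test_orthogonality_and_zero_mean(self, rng):
        theta = rng.uniform(0, 365, 120)
        s, c = seasonal_terms(theta)
        atemp = rng.normal(10, 5, 120)
        resid, _ = residualize_atemp(atemp, s, c)
        n = len(resid)
        assert abs(resid.sum()) < 1e-8 * n
        assert abs(resid @ s) < 1e-8 * n
        assert abs(resid @ c) < 1e-8 * n

    def test_idempotent(self, rng):
        theta = rng.uniform(0, 365, 80)
        s, c = seasonal_terms(theta)
        atemp = rng.normal(10, 5, 80)
        resid, _ = residualize_atemp(atemp, s, c)
        again, _ = residualize_atemp(resid, s, c)
        np.testing.assert_allclose(again, resid, atol=1e-10)

    def test_degenerate_design_rejected(self):
        s, c = seasonal_terms(np.full(10, 42.0))
        with pytest.raises(DegenerateDesignError):
            residualize_atemp(np.arange(10.0), s, c)

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValueError):
            residualize_atemp(np.array([1.0, 2.0]), np.zeros(2), np.ones(2))


class TestBuildExposureDesign:
    def test_empty_visits_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            build_exposure_design(small_dataset.hourly, small_dataset.visits.iloc[:0])

    def test_complete_data_zero_exclusions(self, small_dataset):
        out = build_exposure_design(
            small_dataset.hourly, small_dataset.visits, windows=(24,)
        )
        assert out.exclusions[24]["n_excluded"] == 0
        assert len(out[24]) == len(small_dataset.visits)

    def test_matches_generator_window_truth(self, small_dataset):
        out = build_exposure_design(small_dataset.hourly, small_dataset.visits)
        truth = small_dataset.hourly_window_means
        for w, df in out.designs.items():
            for pol in ("bc", "co"):
                t = truth[(truth["window"] == w) & (truth["pollutant"] == pol)]
                merged = df.merge(
                    t[["visit_id", "value"]], on="visit_id", how="inner"
                )
                np.testing.assert_allclose(
                    merged[pol].to_numpy(), merged["value"].to_numpy(), rtol=1e-10
                )

    def test_gap_excludes_only_short_window(self, small_dataset):
        hourly = small_dataset.hourly.copy()
        visits = small_dataset.visits.iloc[:50].copy()
        victim = visits.iloc[10]
        end = pd.Timestamp(victim["visit_time"]).floor("h")
        gap = [end, end - pd.Timedelta(hours=1)]  # 2 of 4 hours lost
        mask = hourly["timestamp"].isin(gap) & (hourly["variable"] == "bc")
        hourly.loc[mask, "value"] = np.nan
        out = build_exposure_design(hourly, visits, windows=(4, 24))
        assert victim["visit_id"] not in set(out[4]["visit_id"])
        assert victim["visit_id"] in set(out[24]["visit_id"])
        assert out.exclusions[4]["n_excluded"] >= 1

    def test_seasonal_residual_columns_are_orthogonal(self, small_dataset):
        out = build_exposure_design(
            small_dataset.hourly, small_dataset.visits, windows=(24,)
        )
        df = out[24]
        n = len(df)
        assert abs(df["resid_atemp"] @ df["sine"]) < 1e-8 * n
        assert abs(df["resid_atemp"] @ df["cosine"]) < 1e-8 * n
        np.testing.assert_allclose(
            df["resid_atemp_sq"], df["resid_atemp"] ** 2, atol=1e-12
        )
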