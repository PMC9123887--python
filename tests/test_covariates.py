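"""Moon phase, tide features, daylength, environmental joins and screens."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import whistlegam as wg
from whistlegam.covariates import SYNODIC_DAYS, _REFERENCE_NEW_MOON
from whistlegam.errors import CoverageError, ValidationError


class TestMoonPhase:
    def test_reference_new_moon_is_zero(self):
        assert wg.moon_phase(_REFERENCE_NEW_MOON) == pytest.approx(0.0, abs=0.01)

    def test_half_synodic_month_is_full_moon(self):
        t = _REFERENCE_NEW_MOON + timedelta(days=SYNODIC_DAYS / 2)
        assert wg.moon_phase(t) == pytest.approx(0.5, abs=0.01)

    def test_periodic_and_bounded_over_study_span(self):
        rng = np.random.default_rng(0)
        t0 = datetime(2017, 6, 1)
        for _ in range(50):
            t = t0 + timedelta(hours=float(rng.uniform(0, 2 * 365 * 24)))
            m = wg.moon_phase(t)
            assert 0.0 <= m < 1.0
            m2 = wg.moon_phase(t + timedelta(days=SYNODIC_DAYS))
            assert min(abs(m2 - m), 1 - abs(m2 - m)) < 0.002


class TestTideFeatures:
    def _series(self, fn, start=datetime(2018, 1, 1), hours=6, step_min=1):
        idx = pd.date_range(start, start + timedelta(hours=hours), freq=f"{step_min}min")
        tau = (idx - start).total_seconds() / 3600.0
        return pd.Series(fn(np.asarray(tau)), index=idx)

    def test_constant_series(self):
        s = self._series(lambda t: np.full_like(t, 1.3))
        tf = wg.tide_features(s, datetime(2018, 1, 1, 5))
        assert tf.tide_m == pytest.approx(1.3)
        assert tf.flow_m == pytest.approx(0.0, abs=1e-12)
        assert tf.dtide == pytest.approx(0.0, abs=1e-9)

    def test_sinusoid_matches_analytic_second_derivative(self):
        # slow oscillation (48-h period) so the trailing-3-h cubic fit is in
        # its convergence regime; the endpoint curvature then tracks -ω² sin(ωt)
        om = 2 * np.pi / 48.0
        s = self._series(lambda t: np.sin(om * t), hours=10)
        t_eval = datetime(2018, 1, 1, 8)
        tf = wg.tide_features(s, t_eval)
        tau = 8.0
        assert tf.tide_m == pytest.approx(np.sin(om * tau), abs=1e-6)
        assert tf.flow_m == pytest.approx(np.sin(om * tau) - np.sin(om * (tau - 1)), abs=1e-6)
        assert tf.dtide == pytest.approx(-om * om * np.sin(om * tau), rel=0.05)

    def test_rising_series_has_positive_flow(self):
        s = self._series(lambda t: 0.2 * t)
        tf = wg.tide_features(s, datetime(2018, 1, 1, 4))
        assert tf.flow_m == pytest.approx(0.2, abs=1e-9)

    def test_gap_raises_coverage_error(self):
        s = self._series(lambda t: np.sin(t))
        s = s[(s.index < datetime(2018, 1, 1, 3)) | (s.index > datetime(2018, 1, 1, 4))]
        with pytest.raises(CoverageError):
            wg.tide_features(s, datetime(2018, 1, 1, 5))

    def test_insufficient_span_raises(self):
        s = self._series(lambda t: np.sin(t), hours=2)
        with pytest.raises(CoverageError):
            wg.tide_features(s, datetime(2018, 1, 1, 2))


class TestDaylength:
    def test_equator_equinox_near_civil_12_8(self):
        # civil twilight adds roughly 0.4 h on each side of the 12-h day
        assert wg.daylength(date(2018, 3, 20), 0.0) == pytest.approx(12.8, abs=0.2)

    def test_subtropical_seasonality(self):
        june = wg.daylength(date(2018, 6, 21), 24.16)
        dec = wg.daylength(date(2018, 12, 21), 24.16)
        assert june > dec
        for d in (date(2018, 1, 1), date(2018, 6, 21), date(2018, 12, 21)):
            assert 0.0 < wg.daylength(d, 24.16) < 24.0

    def test_polar_latitudes_unsupported(self):
        with pytest.raises(ValidationError):
            wg.daylength(date(2018, 6, 21), 70.0)


class TestAttachEnvironment:
    def _record(self, day):
        return wg.HourlyRecord(datetime(2018, 5, day, 10), "D1", 1, 60)

    def test_same_day_join_and_delta(self):
        days = [date(2018, 5, d) for d in range(1, 11)]
        rng = np.random.default_rng(3)
        sst = pd.DataFrame({"date": days, "value": rng.uniform(20, 30, 10)})
        bay = pd.DataFrame({"date": days, "value": rng.uniform(20, 30, 10)})
        recs = [self._record(d) for d in range(1, 11)]
        wg.attach_environment(recs, sst, bay)
        for r, s, b in zip(recs, sst["value"], bay["value"]):
            assert r.covariates["sst"] == pytest.approx(s)
            assert r.covariates["delta_sst"] == pytest.approx(s - b)

    def test_missing_day_flagged_not_imputed(self):
        sst = pd.DataFrame({"date": [date(2018, 5, 1)], "value": [25.0]})
        recs = [self._record(2)]
        with pytest.warns(UserWarning):
            wg.attach_environment(recs, sst, sst)
        assert np.isnan(recs[0].covariates["sst"])
        assert recs[0].covariates["chl_missing"]


class TestSpearmanScreen:
    def test_identical_columns_drop_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        res = wg.spearman_screen(t)
        assert res.retained == ["a", "c"]
        assert res.dropped[0][0] == "b" and res.dropped[0][2] == pytest.approx(1.0)

    def test_constructed_high_rank_correlation_drops(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        noisy = stats.rankdata(x) + rng.normal(0, 30, size=300)
        t = pd.DataFrame({"x": x, "y": noisy})
        rho = stats.spearmanr(x, noisy).statistic
        assert abs(rho) > 0.7  # construction check
        assert wg.spearman_screen(t).retained == ["x"]

    def test_independent_columns_not_dropped(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.uniform(size=(200, 5)), columns=list("abcde"))
        res = wg.spearman_screen(t)
        assert res.dropped == []

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        t1 = pd.DataFrame({"x": x, "y": 0.9 * x + 0.1 * rng.normal(size=100)})
        t2 = t1.assign(x=np.exp(t1["x"]))
        r1 = wg.spearman_screen(t1)
        r2 = wg.spearman_screen(t2)
        assert r1.retained == r2.retained
        assert np.allclose(r1.spearman_rho.to_numpy(), r2.spearman_rho.to_numpy())

    def test_constant_column_never_triggers_drop(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        res = wg.spearman_screen(t)
        assert set(res.retained) == {"a", "b"}


class TestKMO:
    @staticmethod
    def _kmo_bruteforce(X):
        """Independent route: partial correlations via explicit pairwise regression."""
        m = X.shape[1]
        R = np.corrcoef(X, rowvar=False)
        Q = np.eye(m)
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                others = [k for k in range(m) if k not in (i, j)]
                if others:
                    Zo = X[:, others]
                    Zo = np.column_stack([np.ones(len(X)), Zo])
                    ri = X[:, i] - Zo @ np.linalg.lstsq(Zo, X[:, i], rcond=None)[0]
                    rj = X[:, j] - Zo @ np.linalg.lstsq(Zo, X[:, j], rcond=None)[0]
                    Q[i, j] = np.corrcoef(ri, rj)[0, 1]
                else:
                    Q[i, j] = R[i, j]
        mask = ~np.eye(m, dtype=bool)
        return float((R[mask] ** 2).sum() / ((R[mask] ** 2).sum() + (Q[mask] ** 2).sum()))

    def test_matches_bruteforce_partial_correlations(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 3] += 0.4 * X[:, 2]
        overall, per = wg.kmo(pd.DataFrame(X, columns=list("abcd")))
        assert overall == pytest.approx(self._kmo_bruteforce(X), abs=1e-10)
        assert ((per >= 0) & (per <= 1)).all()

    def test_single_factor_structure_is_adequate(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=400)
        X = np.column_stack([z + 0.4 * rng.normal(size=400) for _ in range(3)])
        overall, _ = wg.kmo(pd.DataFrame(X, columns=list("abc")))
        assert overall > 0.6

    def test_singular_matrix_rejected(self):
        x = np.arange(10.0)
        t = pd.DataFrame({"a": x, "b": 2 * x, "c": np.random.default_rng(0).normal(size=10)})
        with pytest.raises(ValidationError):
            wg.kmo(t)


class TestRoundTripWithGenerator:
    def test_recomputed_covariates_match_generator(self, study):
        """Attached moon/tide/daylength agree with the generator's analytic values."""
        schedule, forcings, _, records = study
        tide_model = wg.TideModel()
        rng = np.random.default_rng(0)
        for r in [records[i] for i in rng.choice(len(records), 40, replace=False)]:
            mid = r.hour_start + timedelta(minutes=30)
            assert r.covariates["moon"] == pytest.approx(wg.moon_phase(mid), abs=0.002)
            assert r.covariates["tide"] == pytest.approx(
                float(tide_model.height(mid)[0]), abs=1e-6
            )
            assert r.covariates["daylength"] == pytest.approx(
                wg.daylength(r.hour_start.date(), forcings.lat), abs=1e-9
            )
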