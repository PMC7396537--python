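import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budburst.covariates import (Standardizer, day_length, fit_frost_curve,
                                 frost_indicator, gap_fill, gdd_accumulate,
                                 standardize)


def make_weather(tmean, site="s", year=2016, spread=2.0):
    tmean = np.asarray(tmean, dtype=float)
    return pd.DataFrame({
        "site": site, "year": year, "doy": np.arange(1, len(tmean) + 1),
        "tmin": tmean - spread, "tmean": tmean, "tmax": tmean + spread,
    })


class TestGDD:
    def test_constant_temperature_accumulates_linearly(self):
        w = make_weather(np.full(30, 10.0))
        g = gdd_accumulate(w, which="mean")
        assert g["gdd_mean"].iloc[-1] == pytest.approx(300.0)

    def test_subzero_temperatures_contribute_nothing(self):
        w = make_weather(np.full(20, -5.0))
        g = gdd_accumulate(w, which="mean")
        assert (g["gdd_mean"] == 0).all()

    def test_daily_truncation_hand_example(self):
        w = make_weather([2.0, -3.0, 5.0])
        g = gdd_accumulate(w, which="mean")
        assert g["gdd_mean"].tolist() == [2.0, 2.0, 7.0]

    def test_gap_raises_with_missing_doys(self):
        w = make_weather(np.full(10, 5.0))
        w = w[w["doy"] != 4]
        with pytest.raises(ValueError, match="missing DOYs.*4"):
            gdd_accumulate(w)

    def test_max_series_dominates_mean_series(self, rng):
        w = make_weather(rng.normal(8, 6, size=120), spread=3.0)
        gm = gdd_accumulate(w, which="mean")["gdd_mean"]
        gx = gdd_accumulate(w, which="max")["gdd_max"]
        assert (gx >= gm).all()
        assert (np.diff(gm) >= 0).all()


class TestFrost:
    def test_strict_zero_coding(self):
        w = make_weather([0.0, 0.0], spread=0.0)
        w["tmin"] = [-0.1, 0.0]
        assert frost_indicator(w).tolist() == [1, 0]

    def test_elementwise_rule(self):
        w = make_weather(np.zeros(4), spread=0.0)
        w["tmin"] = [-5.0, 3.0, 0.0, -1.0]
        assert frost_indicator(w).tolist() == [1, 0, 0, 1]

    def test_null_slope_when_outcome_independent_of_doy(self, rng):
        doy = np.tile(np.arange(1, 201), 2)
        y = rng.random(400) < 0.5
        m = fit_frost_curve(y.astype(int), doy)
        assert abs(m.beta1) < 2 * m.se1
        assert m.predict(100) == pytest.approx(0.5, abs=0.1)

    def test_recovers_generating_parameters(self, rng):
        b0, b1 = 40.0, -0.25
        doy = rng.integers(100, 220, size=4000)
        p = 1 / (1 + np.exp(-(b0 + b1 * doy)))
        y = (rng.random(4000) < p).astype(int)
        m = fit_frost_curve(y, doy)
        assert m.converged
        assert abs(m.beta0 - b0) < 2 * m.se0
        assert abs(m.beta1 - b1) < 2 * m.se1

    def test_all_frosty_is_degenerate_not_fatal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_frost_curve(np.ones(50), np.arange(50))
        assert m.degenerate
        with pytest.warns(UserWarning):
            assert m.predict(25) > 0.999


def _oracle_day_length(lat, doy):
    """Independent solar-position oracle (Meeus low-precision formulae:
    mean longitude plus equation of center, same nominal year)."""
    n = doy + 17 * 365.25   # days since J2000.0 for the nominal year
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    delta = math.asin(math.sin(math.radians(23.439)) * math.sin(lam))
    phi = math.radians(lat)
    h0 = math.radians(-0.833)
    cosw = (math.sin(h0) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta))
    cosw = min(1.0, max(-1.0, cosw))
    return 2.0 * math.degrees(math.acos(cosw)) / 15.0


class TestDayLength:
    def test_equator_near_twelve_hours_all_year(self):
        hours = day_length(0.0, np.arange(1, 366))
        assert np.all(np.abs(hours - 12.0) < 0.2)

    def test_temperate_site_mid_may(self):
        # the study's temperate plantation latitude in mid-May
        assert day_length(47.29, 140) == pytest.approx(15.37, abs=0.15)

    def test_near_equinox_at_boreal_latitude(self):
        assert day_length(48.29, 80) == pytest.approx(12.1, abs=0.3)

    def test_matches_independent_oracle_within_two_minutes(self, rng):
        for _ in range(1000):
            lat = float(rng.uniform(-60, 60))
            doy = int(rng.integers(1, 366))
            assert abs(day_length(lat, doy) - _oracle_day_length(lat, doy)) < 2 / 60
        assert abs(day_length(60.0, 172) - _oracle_day_length(60.0, 172)) < 2 / 60

    def test_polar_latitudes_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            day_length(70.0, 180)


def _logger_frame(reference, logger, days, noise=None, slope=1.0, intercept=0.0):
    ref = reference[reference["doy"].isin(days)]
    out = ref.copy()
    out["logger"] = logger
    for c in ("tmin", "tmean", "tmax"):
        vals = intercept + slope * ref[c].to_numpy()
        if noise is not None:
            vals = vals + noise
        out[c] = vals
    return out


class TestGapFill:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.reference = make_weather(rng.normal(10, 5, 80))

    def test_identity_logger_reproduces_reference(self):
        obs = _logger_frame(self.reference, "L1", range(10, 70))
        filled, models = gap_fill(obs, self.reference)
        tm = [m for m in models if m.variable == "tmean"][0]
        assert tm.slope == pytest.approx(1.0, abs=1e-8)
        assert tm.adj_r2 == pytest.approx(1.0, abs=1e-8)
        missing = ~self.reference["doy"].isin(range(10, 70))
        pd.testing.assert_series_equal(
            filled.loc[missing.to_numpy(), "tmean"].reset_index(drop=True),
            self.reference.loc[missing.to_numpy(), "tmean"].reset_index(drop=True),
            check_names=False,
        )

    def test_recovers_generating_regression(self, rng):
        noise = rng.normal(0, 0.5, 60)
        obs = _logger_frame(self.reference, "L1", range(1, 61), noise=noise,
                            slope=0.9, intercept=2.0)
        _, models = gap_fill(obs, self.reference)
        tm = [m for m in models if m.variable == "tmean"][0]
        se = 0.5 / np.sqrt(np.sum(
            (self.reference["tmean"][:60] - self.reference["tmean"][:60].mean())**2))
        assert abs(tm.slope - 0.9) < 2 * max(se, 0.02)

    def test_observed_days_never_altered(self):
        obs = _logger_frame(self.reference, "L1", range(5, 75), noise=None,
                            slope=1.1, intercept=-1.0)
        filled, _ = gap_fill(obs, self.reference)
        merged = filled.merge(obs, on=["site", "year", "doy"], suffixes=("", "_obs"))
        assert np.allclose(merged["tmean"], merged["tmean_obs"])

    def test_no_overlap_logger_excluded_with_warning(self):
        good = _logger_frame(self.reference, "L1", range(5, 75))
        lonely = _logger_frame(self.reference, "L2", range(5, 7))
        with pytest.warns(UserWarning, match="overlap"):
            filled, models = gap_fill(pd.concat([good, lonely]), self.reference)
        assert any(not m.used for m in models)
        assert not filled[["tmin", "tmean", "tmax"]].isna().any().any()


class TestStandardize:
    def test_closed_form(self):
        z, params = standardize([1.0, 2.0, 3.0])
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)
        assert params.mean == 2.0

    def test_stored_params_center(self):
        _, params = standardize([1.0, 2.0, 3.0])
        z, _ = standardize([2.0], params)
        assert z[0] == 0.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize([4.0, 4.0, 4.0], name="tmin")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40, unique=True))
    def test_round_trip(self, values):
        s = Standardizer().fit(pd.DataFrame({"v": values}), ["v"])
        z = s.transform(values, "v")
        back = s.inverse_transform(z, "v")
        assert np.allclose(back, values, atol=1e-10 * max(1.0, np.abs(values).max()))
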