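"""Forcing-model unit and property tests: daylength, rates, predictions,
RMSE objectives, and calibration determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frostring import phenology
from frostring.climate import PhenoObservation, ValidationError
from frostring.phenology import (
    M1Parameters,
    calibrate,
    cross_validate,
    daylength,
    forcing_rate,
    model_rmse,
    null_model_rmse,
    predict_leafout,
)

from conftest import make_year_climate, sinusoid_climate

PUBLISHED = M1Parameters(t0=3, Tb=0.29, k=4.76, Fcrit=1248.0)


class TestDaylength:
    def test_equator_near_12h_all_year(self):
        for doy in (1, 80, 172, 266, 355):
            assert daylength(0.0, doy) == pytest.approx(12.0, abs=0.25)

    def test_northern_summer_longer_than_winter(self):
        assert daylength(47.4, 172) > daylength(47.4, 355)

    def test_matches_independent_formula(self):
        # independent re-derivation: declination via the same revolution
        # angle, hour angle solved directly in degrees
        lat, doy, p = 47.4, 130, 0.8333
        theta = 0.2163108 + 2 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186)))
        decl = np.degrees(np.arcsin(0.39795 * np.cos(theta)))
        cos_h = (
            np.sin(np.radians(p)) + np.sin(np.radians(lat)) * np.sin(np.radians(decl))
        ) / (np.cos(np.radians(lat)) * np.cos(np.radians(decl)))
        expected = 24 - (24 / 180) * np.degrees(np.arccos(cos_h))
        assert daylength(lat, doy) == pytest.approx(expected, abs=0.01)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValidationError):
            daylength(70.0, 100)

    def test_bounded_in_0_24(self):
        for lat in (-60, -30, 0, 30, 60, 66.4):
            vals = daylength(lat, np.arange(1, 366))
            assert np.all((vals > 0) & (vals < 24))


class TestForcingRate:
    def test_zero_at_or_below_base(self):
        assert forcing_rate(0.2, 12.0, 0.29, 4.76) == 0.0
        assert forcing_rate(0.29, 12.0, 0.29, 4.76) == 0.0

    def test_unit_photoperiod_factor(self):
        assert forcing_rate(5.29, 10.0, 0.29, 4.76) == pytest.approx(5.0)

    def test_direct_arithmetic(self):
        assert forcing_rate(10.29, 12.0, 0.29, 4.76) == pytest.approx(23.82, abs=0.01)

    @given(
        ti=st.floats(-20, 35),
        li=st.floats(6, 20),
        tb=st.floats(0.01, 10),
        k=st.floats(0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, ti, li, tb, k):
        assert forcing_rate(ti, li, tb, k) >= 0.0


def _brute_force_leafout(climate, year, params):
    """Day-by-day accumulation oracle, independent of the implementation."""
    total = 0.0
    sub = climate.year_frame(year)
    for doy in range(1, int(sub.index.max()) + 1):
        if doy < params.t0:
            continue
        ti = float(sub.loc[doy, "tmean"])
        li = daylength(climate.latitude, doy)
        if ti > params.Tb:
            total += (li / 10.0) ** params.k * (ti - params.Tb)
        if total >= params.Fcrit:
            return doy
    return None


class TestPredictLeafout:
    def test_linear_accumulation_case(self):
        clim = make_year_climate("X", 2000, base=1.29)  # tmean = Tb + 1
        # fix photoperiod factor to 1 by k=0
        params = M1Parameters(t0=1, Tb=0.29, k=0.0, Fcrit=30.0)
        assert predict_leafout(clim, 2000, params) == 30

    def test_never_emerges_below_base(self):
        clim = make_year_climate("X", 2000, base=-5.0)
        params = M1Parameters(t0=1, Tb=0.29, k=4.76, Fcrit=30.0)
        assert predict_leafout(clim, 2000, params) is None

    def test_matches_brute_force_oracle_published_params(self):
        clim = sinusoid_climate(years=range(2000, 2003))
        for year in (2000, 2001, 2002):
            assert predict_leafout(clim, year, PUBLISHED) == _brute_force_leafout(
                clim, year, PUBLISHED
            )

    def test_warming_never_delays(self):
        clim = sinusoid_climate(years=range(2000, 2001))
        warmer = sinusoid_climate(mean=9.0, years=range(2000, 2001))
        d0 = predict_leafout(clim, 2000, PUBLISHED)
        d1 = predict_leafout(warmer, 2000, PUBLISHED)
        assert d1 <= d0

    @given(fcrit=st.floats(100, 3000))
    @settings(max_examples=25, deadline=None)
    def test_higher_threshold_never_advances(self, fcrit):
        clim = sinusoid_climate(years=range(2000, 2001))
        lo = predict_leafout(clim, 2000, M1Parameters(3, 0.29, 4.76, fcrit))
        hi = predict_leafout(clim, 2000, M1Parameters(3, 0.29, 4.76, fcrit + 200))
        if hi is not None:
            assert lo is not None and lo <= hi

    def test_k_zero_equals_plain_gdd(self):
        clim = sinusoid_climate(years=range(2000, 2001))
        params = M1Parameters(t0=1, Tb=2.0, k=0.0, Fcrit=300.0)
        # independent GDD implementation
        tmean = clim.doy_array(2000, "tmean")
        gdd = np.cumsum(np.maximum(tmean - 2.0, 0.0))
        expected = int(np.argmax(gdd >= 300.0)) + 1
        assert predict_leafout(clim, 2000, params) == expected


class TestRMSE:
    def test_perfect_predictions_zero(self):
        clim = make_year_climate("A", 2000, base=1.29)
        params = M1Parameters(t0=1, Tb=0.29, k=0.0, Fcrit=30.0)
        obs = [PhenoObservation("A", 2000, 30)]
        assert model_rmse(params, {"A": clim}, obs) == 0.0

    def test_hand_computed_two_errors(self):
        # predictions 30; observations 27 and 34 -> errors +3 / -4
        clims = {
            "A": make_year_climate("A", 2000, base=1.29),
            "B": make_year_climate("B", 2000, base=1.29),
        }
        params = M1Parameters(t0=1, Tb=0.29, k=0.0, Fcrit=30.0)
        obs = [PhenoObservation("A", 2000, 27), PhenoObservation("B", 2000, 34)]
        assert model_rmse(params, clims, obs) == pytest.approx(3.5355, abs=1e-4)

    def test_empty_observations_error(self):
        with pytest.raises(ValidationError):
            model_rmse(PUBLISHED, {}, [])

    def test_null_model_cases(self):
        a = [PhenoObservation("A", 2000, 128), PhenoObservation("A", 2001, 132)]
        assert null_model_rmse(a, [PhenoObservation("A", 2002, 130)]) == 0.0
        assert null_model_rmse(a, [PhenoObservation("A", 2002, 135)]) == 5.0
        # RMSE of train about its own mean = population SD
        assert null_model_rmse(a, a) == pytest.approx(np.std([128, 132]))
        with pytest.raises(ValidationError):
            null_model_rmse([], a)


def _small_dataset(n_sites=4, n_years=12, noise=0.0, seed=5):
    from frostring import synthetic

    climates, obs = {}, []
    for s in range(n_sites):
        cfg = synthetic.SyntheticConfig(
            seed=seed + s,
            n_years=n_years,
            start_year=2000,
            site_id=f"S{s}",
            mean_annual_temp=4.0 + 0.8 * s,
        )
        climates[f"S{s}"] = synthetic.generate_climate(cfg)
        o, _ = synthetic.generate_phenology(
            climates[f"S{s}"], synthetic.TRUE_BEECH_PARAMS, noise, seed=seed + 100 + s
        )
        obs.extend(o)
    return climates, obs


class TestCalibration:
    def test_seed_determinism(self):
        climates, obs = _small_dataset()
        a = calibrate(climates, obs, max_calls=300, seed=7)
        b = calibrate(climates, obs, max_calls=300, seed=7)
        assert a.params == b.params and a.train_rmse == b.train_rmse

    def test_single_observation_flags_degenerate(self):
        climates, obs = _small_dataset()
        fit = calibrate(climates, obs[:1], max_calls=200, seed=1)
        assert fit.degenerate

    def test_bounds_must_respect_constraints(self):
        climates, obs = _small_dataset()
        with pytest.raises(phenology.ConfigurationError):
            calibrate(climates, obs, bounds=[(-5, 90), (0.01, 10), (0, 10), (1, 5000)])
        with pytest.raises(phenology.ConfigurationError):
            calibrate(climates, obs, bounds=[(1, 90), (-1, 10), (0, 10), (1, 5000)])

    def test_result_json_roundtrip(self, tmp_path):
        climates, obs = _small_dataset()
        fit = calibrate(climates, obs, max_calls=200, seed=1)
        fit.to_json(tmp_path / "fit.json", bounds=phenology.DEFAULT_BOUNDS)
        back = phenology.CalibrationResult.from_json(tmp_path / "fit.json")
        assert back.params == fit.params and back.train_rmse == fit.train_rmse


class TestCrossValidation:
    def test_order_invariance_with_fixed_seed(self):
        climates, obs = _small_dataset()
        a = cross_validate(climates, obs, n_folds=4, seed=3, max_calls=200)
        b = cross_validate(climates, list(reversed(obs)), n_folds=4, seed=3, max_calls=200)
        assert a == b

    def test_too_many_folds_rejected(self):
        climates, obs = _small_dataset(n_sites=1, n_years=3)
        with pytest.raises(ValidationError):
            cross_validate(climates, obs, n_folds=50, seed=0)
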