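"""Generator contracts: determinism, injected structure, noise calibration."""

import numpy as np
import pytest
from scipy import stats

from frostring.climate import ValidationError
from frostring.phenology import M1Parameters, predict_leafout
from frostring.synthetic import (
    TRUE_BEECH_PARAMS,
    SyntheticConfig,
    generate_climate,
    generate_phenology,
    generate_ring_series,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_years": 0},
            {"ar1_coefficient": 1.0},
            {"frost_multiplier": 0.0},
            {"noise_sd": -1.0},
            {"frost_events": [(1900, 100, 5.0)]},  # outside coverage
            {"frost_events": [(1950, 400, 5.0)]},  # bad doy
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticConfig(**{"n_years": 30, "start_year": 1940, **kwargs})


class TestClimate:
    def test_zero_noise_is_exact_sinusoid(self):
        cfg = SyntheticConfig(
            n_years=1, start_year=2001, noise_sd=0.0, ar1_coefficient=0.0, seed=1
        )
        clim = generate_climate(cfg)
        doy = clim.data["doy"].to_numpy()
        expected_mean = cfg.mean_annual_temp - cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - 15) / 365.25
        )
        np.testing.assert_allclose(clim.data["tmean"], expected_mean, atol=1e-12)
        np.testing.assert_allclose(
            clim.data["tmin"], expected_mean - cfg.diurnal_range / 2, atol=1e-12
        )

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_years=5, seed=9)
        a, b = generate_climate(cfg), generate_climate(cfg)
        assert a.data.equals(b.data)

    def test_frost_event_is_exact_difference(self):
        base = SyntheticConfig(n_years=3, start_year=2000, seed=4)
        with_event = SyntheticConfig(
            n_years=3, start_year=2000, seed=4, frost_events=[(2001, 133, 8.0)]
        )
        a, b = generate_climate(base), generate_climate(with_event)
        ya, yb = a.year_frame(2001), b.year_frame(2001)
        assert yb.loc[133, "tmin"] == pytest.approx(ya.loc[133, "tmin"] - 8.0)
        # tmean/tmax untouched, all other days untouched
        assert yb["tmean"].equals(ya["tmean"])
        mask = ya.index != 133
        np.testing.assert_array_equal(ya.loc[mask, "tmin"], yb.loc[mask, "tmin"])

    def test_ar1_autocorrelation_recovered(self):
        cfg = SyntheticConfig(n_years=30, ar1_coefficient=0.7, seed=2)
        clim = generate_climate(cfg)
        doy = clim.data["doy"].to_numpy()
        seasonal = cfg.mean_annual_temp - cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - 15) / 365.25
        )
        resid = clim.data["tmean"].to_numpy() - seasonal
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert r1 == pytest.approx(0.7, abs=0.1)

    def test_leap_days_present(self):
        cfg = SyntheticConfig(n_years=1, start_year=2004, seed=0)
        clim = generate_climate(cfg)
        assert len(clim.data) == 366


class TestPhenology:
    def test_zero_noise_equals_predictions(self):
        cfg = SyntheticConfig(n_years=5, start_year=2000, seed=3)
        clim = generate_climate(cfg)
        obs, skipped = generate_phenology(clim, TRUE_BEECH_PARAMS, 0.0, seed=1)
        for o in obs:
            assert o.leafout_doy == predict_leafout(clim, o.year, TRUE_BEECH_PARAMS)
        assert not skipped

    def test_cold_climate_reports_non_emerging(self):
        cfg = SyntheticConfig(
            n_years=2, start_year=2000, mean_annual_temp=-20.0, noise_sd=0.0,
            ar1_coefficient=0.0, seed=1,
        )
        clim = generate_climate(cfg)
        obs, skipped = generate_phenology(clim, TRUE_BEECH_PARAMS, 0.0, seed=1)
        assert obs == [] and skipped == [2000, 2001]

    def test_noise_sd_recovered(self):
        cfg = SyntheticConfig(n_years=60, start_year=1950, seed=8)
        clim = generate_climate(cfg)
        obs, _ = generate_phenology(clim, TRUE_BEECH_PARAMS, 5.0, seed=21)
        errs = [
            o.leafout_doy - predict_leafout(clim, o.year, TRUE_BEECH_PARAMS) for o in obs
        ]
        assert 3.5 <= np.std(errs, ddof=1) <= 6.5


class TestRingSeries:
    def test_widths_positive_and_deterministic(self):
        cfg = SyntheticConfig(n_years=40, start_year=1960, seed=6)
        clim = generate_climate(cfg)
        a = generate_ring_series(clim, [1975], cfg, "frost_sensitive")
        b = generate_ring_series(clim, [1975], cfg, "frost_sensitive")
        assert len(a) == 2 * cfg.n_trees_per_species
        for s, t in zip(a, b):
            assert np.all(s.widths > 0)
            np.testing.assert_array_equal(s.widths, t.widths)

    def test_frost_year_outside_coverage(self):
        cfg = SyntheticConfig(n_years=10, start_year=1990, seed=1)
        clim = generate_climate(cfg)
        with pytest.raises(ValidationError):
            generate_ring_series(clim, [1950], cfg, "frost_sensitive")

    def test_deterministic_skeleton_without_noise_or_signal(self):
        cfg = SyntheticConfig(
            n_years=20, start_year=1990, seed=1, ring_noise_sd=0.0, core_noise_sd=0.0,
            climate_signal_beta=0.0, frost_multiplier=0.5,
        )
        clim = generate_climate(cfg)
        series = generate_ring_series(clim, [2000], cfg, "frost_sensitive")
        w0, decay = cfg.ring_age_trend
        expected = w0 * np.exp(-decay * np.arange(20))
        expected[2000 - 1990] *= 0.5
        for s in series:
            np.testing.assert_allclose(s.widths, expected, atol=1e-12)

    def test_multiplier_one_species_indistinguishable(self):
        cfg = SyntheticConfig(n_years=40, start_year=1960, seed=12, frost_multiplier=1.0)
        clim = generate_climate(cfg)
        frost = [1975]
        sens = generate_ring_series(clim, frost, cfg, "frost_sensitive")
        ref = generate_ring_series(clim, frost, cfg, "reference", seed_offset=500)
        year_idx = 1975 - 1960

        def tree_logs(series):
            # cores of one tree share its noise: average to tree level so
            # the two-sample test sees independent draws (n=12 per species)
            by_tree = {}
            for s in series:
                by_tree.setdefault(s.series_id[:-1], []).append(
                    np.log(s.widths[year_idx])
                )
            return [np.mean(v) for v in by_tree.values()]

        assert stats.ttest_ind(tree_logs(sens), tree_logs(ref)).pvalue > 0.01

    def test_frost_multiplier_shifts_log_width_by_ln_m(self):
        cfg = SyntheticConfig(n_years=60, start_year=1950, seed=13, frost_multiplier=0.4)
        clim = generate_climate(cfg)
        frost = [1975]
        sens = generate_ring_series(clim, frost, cfg, "frost_sensitive")
        ref = generate_ring_series(clim, frost, cfg, "reference", seed_offset=500)
        i = 1975 - 1950
        gap = np.mean(np.log([s.widths[i] for s in sens])) - np.mean(
            np.log([s.widths[i] for s in ref])
        )
        # expectation ln(0.4); tolerance ~ 3 * sd/sqrt(n_trees*2 cores)
        assert gap == pytest.approx(np.log(0.4), abs=0.25)

    def test_reference_species_ignores_frost_years(self):
        cfg = SyntheticConfig(n_years=20, start_year=1990, seed=2)
        clim = generate_climate(cfg)
        a = generate_ring_series(clim, [2000], cfg, "reference")
        b = generate_ring_series(clim, [], cfg, "reference")
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.widths, t.widths)
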