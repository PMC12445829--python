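"""Tucson I/O, spline detrending, core averaging, biweight chronology."""

import numpy as np
import pytest

from frostring.climate import ValidationError
from frostring.rings import (
    Chronology,
    RingSeries,
    RWISeries,
    average_cores,
    biweight_chronology,
    biweight_mean,
    chronology_stats,
    fit_growth_spline,
    read_rwl,
    spline_detrend,
    write_rwl,
)


def _series(seed=0, n=90, start=1931, sid="TST01A"):
    rng = np.random.default_rng(seed)
    years = np.arange(start, start + n)
    widths = 3.0 * np.exp(-0.01 * np.arange(n)) * np.exp(rng.normal(0, 0.2, n))
    return RingSeries(sid, "S", "frost_sensitive", years, widths)


class TestRWL:
    def test_round_trip_identity(self, tmp_path):
        series = [_series(s, sid=f"TST{s:02d}A") for s in range(3)]
        path = tmp_path / "t.rwl"
        write_rwl(series, path, precision=0.001)
        back = {s.series_id: s for s in read_rwl(path)}
        for s in series:
            b = back[s.series_id]
            assert np.array_equal(b.years, s.years)
            np.testing.assert_allclose(b.widths, s.widths, atol=0.0006)

    def test_hand_written_decadal_fixture_scale(self, tmp_path):
        # two decades, 0.01 mm precision (999 stop marker)
        text = (
            "CORE1   1995   250   240   230   220   210\n"
            "CORE1   2000   200   190   180   170   999\n"
        )
        path = tmp_path / "h.rwl"
        path.write_text(text)
        (s,) = read_rwl(path)
        assert list(s.years) == list(range(1995, 2004))
        np.testing.assert_allclose(
            s.widths, [2.5, 2.4, 2.3, 2.2, 2.1, 2.0, 1.9, 1.8, 1.7]
        )

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.rwl"
        path.write_text("")
        assert read_rwl(path) == []

    def test_data_value_999_not_a_stop_marker(self, tmp_path):
        # 0.999 mm ring inside a 0.001-precision series must survive
        s = _series(n=12, sid="NARROW1A")
        s.widths[5] = 0.999
        path = tmp_path / "n.rwl"
        write_rwl([s], path, precision=0.001)
        (back,) = read_rwl(path)
        assert len(back.widths) == 12
        assert back.widths[5] == pytest.approx(0.999)

    def test_malformed_line_reported_with_number(self, tmp_path):
        path = tmp_path / "bad.rwl"
        path.write_text("CORE1   1990   abc   999\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_rwl(path)


class TestSplineDetrend:
    def test_constant_series_indices_one(self):
        s = RingSeries("C1A", "S", "x", np.arange(1950, 2000), np.full(50, 2.5))
        rwi = spline_detrend(s)
        np.testing.assert_allclose(rwi.indices, 1.0, atol=1e-9)

    def test_ratio_scale_invariance(self):
        s = _series(3)
        doubled = RingSeries(s.series_id, s.site_id, s.species, s.years, 2 * s.widths)
        np.testing.assert_allclose(
            spline_detrend(s).indices, spline_detrend(doubled).indices, atol=1e-10
        )

    def test_fifty_percent_frequency_response_at_cutoff(self):
        # FFT oracle: fitted curve retains 50% +/- 5% of a 30-yr sinusoid
        n = 300
        years = np.arange(1700, 1700 + n)
        signal = 2.0 + np.sin(2 * np.pi * np.arange(n) / 30.0)
        fitted = fit_growth_spline(years, signal, cutoff_years=30.0)
        interior = slice(60, n - 60)
        amp = np.sqrt(2.0) * np.std(fitted[interior] - 2.0)
        assert amp == pytest.approx(0.5, abs=0.05)

    def test_mean_of_indices_near_one(self):
        rwi = spline_detrend(_series(7))
        assert abs(np.mean(rwi.indices) - 1.0) < 0.15

    def test_short_series_rejected(self):
        s = RingSeries("C1A", "S", "x", np.arange(2000, 2009), np.ones(9))
        with pytest.raises(ValidationError):
            spline_detrend(s)


class TestAverageCores:
    def test_identical_cores_pass_through(self):
        a = RWISeries("T01A", "S", "x", np.arange(2000, 2020), np.ones(20))
        b = RWISeries("T01B", "S", "x", np.arange(2000, 2020), np.ones(20))
        (tree,) = average_cores([a, b])
        assert tree.series_id == "T01"
        np.testing.assert_allclose(tree.indices, 1.0)

    def test_mean_of_two_cores(self):
        a = RWISeries("T01A", "S", "x", np.array([2000]), np.array([1.2]))
        b = RWISeries("T01B", "S", "x", np.array([2000]), np.array([0.8]))
        (tree,) = average_cores([a, b])
        assert tree.indices[0] == pytest.approx(1.0)

    def test_single_core_year_passes_through_and_flags(self):
        a = RWISeries("T01A", "S", "x", np.arange(2000, 2003), np.array([1.1, 1.2, 1.3]))
        b = RWISeries("T01B", "S", "x", np.arange(2001, 2003), np.array([1.0, 1.1]))
        (tree,) = average_cores([a, b])
        assert tree.indices[0] == pytest.approx(1.1)
        assert "single-core years present" in tree.notes


def _biweight_oracle(x, c=9.0, iters=200):
    """Independent fixed-point iteration of the Tukey biweight location."""
    x = np.asarray(x, dtype=float)
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    if mad == 0:
        return m
    for _ in range(iters):
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        m = np.sum(w * x) / np.sum(w)
    return m


class TestBiweight:
    def test_all_equal(self):
        assert biweight_mean(np.full(7, 1.3)) == 1.3

    def test_symmetric(self):
        assert biweight_mean(np.array([0.9, 1.0, 1.1])) == pytest.approx(1.0)

    def test_downweights_outlier(self):
        x = np.array([1.0] * 11 + [5.0])
        m = biweight_mean(x)
        assert abs(m - 1.0) < 0.02
        assert abs(m - np.mean(x)) > 0.3

    def test_matches_iterative_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(1.0, 0.3, size=15)
            x[0] += rng.choice([-3, 3])
            assert biweight_mean(x, tol=1e-12) == pytest.approx(
                _biweight_oracle(x), abs=1e-6
            )

    def test_close_to_mean_without_outliers(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(1.0, 0.1, size=30)
            assert abs(biweight_mean(x) - np.mean(x)) < 0.01


class TestChronology:
    def test_depth_recorded(self):
        a = RWISeries("T01", "S", "x", np.arange(2000, 2010), np.ones(10))
        b = RWISeries("T02", "S", "x", np.arange(2005, 2010), np.full(5, 2.0))
        chron = biweight_chronology([a, b])
        assert list(chron.sample_depth[:5]) == [1] * 5
        assert list(chron.sample_depth[5:]) == [2] * 5

    def test_stats_identical_series(self):
        series = [
            RWISeries(f"T{i}", "S", "x", np.arange(1980, 2010), 1 + 0.1 * np.sin(np.arange(30)))
            for i in range(3)
        ]
        st = chronology_stats(series)
        assert st.mean_interseries_correlation == pytest.approx(1.0)
        assert st.expressed_population_signal == pytest.approx(1.0)

    def test_eps_closed_form_from_rbar(self):
        rng = np.random.default_rng(9)
        common = rng.normal(0, 1, 90)
        series = [
            RWISeries(f"T{i}", "S", "x", np.arange(1931, 2021), 1 + 0.1 * common + rng.normal(0, 0.1, 90))
            for i in range(12)
        ]
        st = chronology_stats(series)
        r, n = st.mean_interseries_correlation, 12
        assert st.expressed_population_signal == pytest.approx(n * r / (n * r + 1 - r))

    def test_white_noise_low_rbar_and_eps(self):
        rng = np.random.default_rng(3)
        series = [
            RWISeries(f"T{i}", "S", "x", np.arange(1931, 2021), 1 + rng.normal(0, 0.2, 90))
            for i in range(12)
        ]
        st = chronology_stats(series)
        assert abs(st.mean_interseries_correlation) < 0.15
        assert st.expressed_population_signal < 0.85

    def test_no_overlap_error(self):
        a = RWISeries("T01", "S", "x", np.arange(1900, 1930), np.ones(30))
        b = RWISeries("T02", "S", "x", np.arange(1990, 2020), np.ones(30))
        with pytest.raises(ValidationError):
            chronology_stats([a, b])
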