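"""Shared fixtures: worked-example frost records and the synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from frostring import pipeline
from frostring.climate import ClimateSeries

# Worked-example site records: for each tree-ring-identified frost year, the
# minimum temperature found in the vulnerability window (degC), and the
# predicted leaf-out DOY, for a high- and a low-elevation mountain site.
HIGH_SITE_ROWS = [
    # (year, window_tmin, leafout_doy)
    (1940, -2.4, 141),
    (1946, -2.0, 128),
    (1975, -0.8, 140),
    (1977, +1.2, 143),
    (1991, -1.2, 149),
    (1995, -3.6, 138),
    (2012, -2.8, 132),
    (2016, -2.0, 141),
    (2017, +0.4, 136),
    (2020, -2.0, 124),
]
LOW_SITE_ROWS = [
    (1940, -0.8, 130),
    (1977, +0.8, 134),
    (1978, +0.0, 138),
    (1987, -1.6, 130),
    (2011, +0.4, 116),
    (2012, -1.6, 125),
]

# Tree-ring-identified frost-year lists for the same two sites.
HIGH_SITE_FROST_YEARS = [1940, 1946, 1975, 1977, 1991, 1995, 2012, 2016, 2017, 2020]
LOW_SITE_FROST_YEARS = [1940, 1977, 1978, 1987, 2011, 2012]


def make_year_climate(
    site_id: str,
    year: int,
    dip_doy: int | None = None,
    dip_tmin: float | None = None,
    base: float = 10.0,
    latitude: float = 47.4,
) -> ClimateSeries:
    """One calendar year of flat mild climate with an optional tmin dip."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(dates)
    tmean = np.full(n, base)
    tmin = tmean - 5.0
    tmax = tmean + 5.0
    if dip_doy is not None:
        tmin[dip_doy - 1] = dip_tmin
    df = pd.DataFrame(
        {"date": dates, "tmin": tmin, "tmean": tmean, "tmax": tmax, "precip": 0.0}
    )
    return ClimateSeries(site_id=site_id, latitude=latitude, elevation=1000.0, data=df)


def sinusoid_climate(
    site_id: str = "SIN",
    years: range = range(2000, 2001),
    mean: float = 8.0,
    amplitude: float = 10.0,
    latitude: float = 47.4,
) -> ClimateSeries:
    """Deterministic seasonal sinusoid (coldest mid-January), no noise."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    tmean = mean - amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    df = pd.DataFrame(
        {"date": dates, "tmin": tmean - 4, "tmean": tmean, "tmax": tmean + 4, "precip": 0.0}
    )
    return ClimateSeries(site_id=site_id, latitude=latitude, elevation=1200.0, data=df)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One synthetic two-site study generated and pushed through the full
    pipeline (seed 0); reused by pipeline and acceptance tests."""
    root = tmp_path_factory.mktemp("study")
    files = pipeline.make_fixtures(root / "fixtures", seed=0)
    config = pipeline.fixture_pipeline_config(files, root / "results", seed=0)
    manifest = pipeline.run_pipeline(config)
    return {
        "files": files,
        "config": config,
        "manifest": manifest,
        "out_dir": root / "results",
    }
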