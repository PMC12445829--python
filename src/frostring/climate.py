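"""Daily climate series and leaf-out observation containers.

The whole pipeline runs off two simple tabular inputs: a per-site daily
climate table (tmin / tmean / tmax in degrees Celsius, precipitation in mm)
and a per-site-year leaf-out observation table (day of year of ~50% leaf
unfolding, BBCH ~13).  Both are stored as pandas DataFrames wrapped in thin
dataclasses that carry site metadata and enforce the invariants the
downstream computations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "PhenoObservation",
    "read_climate_csv",
    "write_climate_csv",
    "read_phenology_csv",
    "write_phenology_csv",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ClimateSeries:
    """Daily climate record for one site.

    Parameters
    ----------
    site_id:
        Site identifier used to join climate with observations and rings.
    latitude:
        Site latitude in decimal degrees (needed for daylength).
    elevation:
        Elevation in m a.s.l. (metadata only; no lapse-rate physics here).
    data:
        DataFrame with columns ``date`` (datetime64), ``tmin``, ``tmean``,
        ``tmax`` (degrees C) and ``precip`` (mm), one row per calendar day,
        strictly increasing dates.
    """

    site_id: str
    latitude: float
    elevation: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"date", "tmin", "tmean", "tmax", "precip"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"climate table missing columns: {sorted(missing)}")
        df = self.data.reset_index(drop=True).copy()
        df["date"] = pd.to_datetime(df["date"])
        if len(df) > 1 and not df["date"].is_monotonic_increasing:
            raise ValidationError("climate dates must be strictly increasing")
        if len(df) > 1 and df["date"].duplicated().any():
            raise ValidationError("duplicate dates in climate series")
        bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
        if bool(bad.any()):
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"tmin <= tmean <= tmax violated on {df['date'].iloc[i].date()}"
            )
        df["year"] = df["date"].dt.year
        df["doy"] = df["date"].dt.dayofyear
        object.__setattr__(self, "data", df)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].to_numpy())

    def year_frame(self, year: int) -> pd.DataFrame:
        """Return the daily rows for one calendar year, indexed by DOY."""
        sub = self.data[self.data["year"] == year]
        return sub.set_index("doy")

    def doy_array(self, year: int, column: str, through_doy: int | None = None) -> np.ndarray:
        """Daily values for ``year`` as a dense DOY-indexed array.

        Raises a data-gap error when days 1..through_doy are not contiguous.
        """
        sub = self.year_frame(year)
        if sub.empty:
            raise ValidationError(f"site {self.site_id}: no climate for year {year}")
        doys = sub.index.to_numpy()
        n = int(doys.max())
        if through_doy is not None:
            n = min(n, through_doy)
        expected = np.arange(1, n + 1)
        have = doys[doys <= n]
        if len(have) != n or not np.array_equal(have, expected):
            raise ValidationError(
                f"site {self.site_id}, year {year}: gap in daily climate (need DOY 1..{n})"
            )
        return sub[column].to_numpy()[:n].astype(float)


@dataclass(frozen=True)
class PhenoObservation:
    """One site-year leaf-out observation (day of year)."""

    site_id: str
    year: int
    leafout_doy: int

    def __post_init__(self) -> None:
        if not 1 <= self.leafout_doy <= 366:
            raise ValidationError(
                f"leafout_doy {self.leafout_doy} outside [1, 366] "
                f"({self.site_id}, {self.year})"
            )


# ---------------------------------------------------------------------------
# CSV interchange formats
# ---------------------------------------------------------------------------

def write_climate_csv(series: ClimateSeries, path: str | Path) -> None:
    """Write one site's climate as CSV: site_id,date,tmin,tmean,tmax,precip."""
    out = series.data[["date", "tmin", "tmean", "tmax", "precip"]].copy()
    out.insert(0, "site_id", series.site_id)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    header = f"# latitude={series.latitude} elevation={series.elevation}\n"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, index=False, float_format="%.3f")


def read_climate_csv(path: str | Path) -> ClimateSeries:
    """Read a climate CSV written by :func:`write_climate_csv`."""
    latitude = np.nan
    elevation = np.nan
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(tok.split("=") for tok in first[1:].split())
        latitude = float(meta.get("latitude", "nan"))
        elevation = float(meta.get("elevation", "nan"))
        df = pd.read_csv(path, skiprows=1)
    else:
        df = pd.read_csv(path)
    site_ids = df["site_id"].unique()
    if len(site_ids) != 1:
        raise ValidationError(f"expected one site per climate file, got {list(site_ids)}")
    return ClimateSeries(
        site_id=str(site_ids[0]),
        latitude=latitude,
        elevation=elevation,
        data=df.drop(columns=["site_id"]),
    )


def write_phenology_csv(observations: Iterable[PhenoObservation], path: str | Path) -> None:
    rows = [(o.site_id, o.year, o.leafout_doy) for o in observations]
    pd.DataFrame(rows, columns=["site_id", "year", "leafout_doy"]).to_csv(path, index=False)


def read_phenology_csv(path: str | Path) -> list[PhenoObservation]:
    df = pd.read_csv(path)
    return [
        PhenoObservation(str(r.site_id), int(r.year), int(r.leafout_doy))
        for r in df.itertuples()
    ]


def observations_by_site(
    observations: Iterable[PhenoObservation],
) -> Mapping[str, list[PhenoObservation]]:
    out: dict[str, list[PhenoObservation]] = {}
    for o in observations:
        out.setdefault(o.site_id, []).append(o)
    return out
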