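"""Growth-climate response: daywise correlation grids and epoch analysis.

``daywise_correlations`` screens Pearson correlations between a chronology
and a daily climate variable aggregated over every (start DOY, window
length) combination — the standard moving-season dendroclimatology grid.
``superposed_epoch`` measures the mean chronology departure at lags 0..+L
around event years against a bootstrap null of randomly drawn pseudo-event
sets, testing for immediate and legacy growth effects of extreme events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateSeries, ValidationError
from .rings import Chronology

__all__ = [
    "DaywiseCorrelationGrid",
    "SEAResult",
    "daywise_correlations",
    "superposed_epoch",
]


@dataclass
class DaywiseCorrelationGrid:
    variable: str
    entries: pd.DataFrame  # columns: start_doy, window_length, r, p, n_years

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.entries[self.entries["p"] < alpha]

    def cell(self, start_doy: int, window_length: int) -> tuple[float, float, int]:
        row = self.entries[
            (self.entries["start_doy"] == start_doy)
            & (self.entries["window_length"] == window_length)
        ]
        if row.empty:
            raise KeyError((start_doy, window_length))
        r = row.iloc[0]
        return float(r["r"]), float(r["p"]), int(r["n_years"])


@dataclass
class SEAResult:
    lags: list[int]
    mean_anomaly: np.ndarray
    boot_quantiles: np.ndarray  # shape (n_lags, 2): 2.5% / 97.5%
    significant: np.ndarray
    n_events: int
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "anomaly": self.mean_anomaly,
                "lo": self.boot_quantiles[:, 0],
                "hi": self.boot_quantiles[:, 1],
                "significant": self.significant,
            }
        )


def _yearly_daily_matrix(
    climate: ClimateSeries, variable: str, years: np.ndarray, max_doy: int = 366
) -> np.ndarray:
    mat = np.full((len(years), max_doy), np.nan)
    for i, year in enumerate(years):
        sub = climate.year_frame(int(year))
        vals = sub[variable]
        mat[i, sub.index.to_numpy() - 1] = vals.to_numpy()
    return mat


def daywise_correlations(
    chronology: Chronology,
    climate: ClimateSeries,
    variable: str,
    start_doys: Sequence[int] = range(1, 271),
    window_lengths: Sequence[int] = range(15, 91, 5),
    aggregation: str | None = None,
) -> DaywiseCorrelationGrid:
    """Pearson r between the chronology and seasonal climate aggregates.

    For each (start, length) cell the daily variable is aggregated per year
    over DOY [start, start+length-1] — mean for temperatures, sum for
    precipitation, unless ``aggregation`` overrides — and correlated with
    the chronology across the overlapping years.  Cells whose window runs
    past DOY 365 or whose aggregate has zero variance are skipped.
    """
    if aggregation is None:
        aggregation = "sum" if variable == "precip" else "mean"
    if aggregation not in ("mean", "sum"):
        raise ValidationError("aggregation must be 'mean' or 'sum'")
    years = np.array(sorted(set(chronology.years) & set(climate.years.tolist())))
    if len(years) < 20:
        raise ValidationError(f"chronology-climate overlap {len(years)} yr < 20")
    chron_vals = np.array([chronology.at(int(y)) for y in years])

    daily = _yearly_daily_matrix(climate, variable, years)
    # prefix sums along DOY make every window aggregate O(1)
    filled = np.nan_to_num(daily, nan=0.0)
    csum = np.concatenate([np.zeros((len(years), 1)), np.cumsum(filled, axis=1)], axis=1)
    ccnt = np.concatenate(
        [np.zeros((len(years), 1)), np.cumsum(~np.isnan(daily), axis=1)], axis=1
    )

    rows = []
    n = len(years)
    cz = (chron_vals - chron_vals.mean()) / chron_vals.std()
    for length in window_lengths:
        for start in start_doys:
            end = start + length - 1
            if end > 365:
                continue
            counts = ccnt[:, end] - ccnt[:, start - 1]
            if np.any(counts < length):
                continue  # incomplete daily coverage in some year
            agg = csum[:, end] - csum[:, start - 1]
            if aggregation == "mean":
                agg = agg / length
            sd = agg.std()
            if sd == 0:
                continue
            az = (agg - agg.mean()) / sd
            r = float(np.dot(az, cz) / n)
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append((start, length, r, p, n))
    return DaywiseCorrelationGrid(
        variable=variable,
        entries=pd.DataFrame(
            rows, columns=["start_doy", "window_length", "r", "p", "n_years"]
        ),
    )


def superposed_epoch(
    chronology: Chronology,
    event_years: Sequence[int],
    lags: Sequence[int] = range(0, 5),
    n_boot: int = 999,
    seed: int = 0,
) -> SEAResult:
    """Superposed epoch analysis with a bootstrap null.

    The anomaly at lag L is the mean over events of the chronology value at
    event year + L, expressed as the departure from the chronology mean over
    all eligible years.  The null distribution draws ``n_boot`` pseudo-event
    sets of the same size uniformly (with replacement) from the years with
    full lag coverage; a lag is significant when the observed anomaly falls
    outside the null's central 95% interval.  ``boot_quantiles`` stores the
    interval of (observed - null draws), so "significant" is equivalent to
    zero lying outside that interval.
    """
    if n_boot < 199:
        raise ValidationError("n_boot must be >= 199")
    lags = list(lags)
    year_to_idx = {int(y): i for i, y in enumerate(chronology.years)}
    eligible = [
        int(y) for y in chronology.years if all(int(y) + L in year_to_idx for L in lags)
    ]
    if len(eligible) == 0:
        raise ValidationError("no years with full lag coverage")
    events = []
    for y in sorted(set(int(y) for y in event_years)):
        if y in year_to_idx and all(y + L in year_to_idx for L in lags):
            events.append(y)
    dropped = sorted(set(int(y) for y in event_years) - set(events))
    if dropped:
        import logging

        logging.getLogger(__name__).warning("SEA: dropped events without lag coverage: %s", dropped)
    if len(events) < 2:
        raise ValidationError("SEA needs >= 2 events with full lag coverage")

    values = chronology.values
    base = float(np.mean(values[[year_to_idx[y] for y in eligible]]))

    def lag_means(year_set: np.ndarray) -> np.ndarray:
        idx = np.array([[year_to_idx[int(y) + L] for L in lags] for y in year_set])
        return values[idx].mean(axis=0) - base

    observed = lag_means(np.array(events))

    rng = np.random.default_rng(seed)
    eligible_arr = np.array(eligible)
    null = np.empty((n_boot, len(lags)))
    for b in range(n_boot):
        pseudo = rng.choice(eligible_arr, size=len(events), replace=True)
        null[b] = lag_means(pseudo)

    lo, hi = np.quantile(null, [0.025, 0.975], axis=0)
    significant = (observed < lo) | (observed > hi)
    shifted = observed[None, :] - null
    boot_q = np.quantile(shifted, [0.025, 0.975], axis=0).T
    return SEAResult(
        lags=lags,
        mean_anomaly=observed,
        boot_quantiles=boot_q,
        significant=significant,
        n_events=len(events),
        n_boot=n_boot,
        seed=seed,
    )
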