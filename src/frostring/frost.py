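"""Frost risk from climate and predicted phenology.

A "false spring" is flagged when a frost at or below a threshold (default
-1.0 degrees C, an inclusive threshold chosen because screened 2-m air
temperature can overestimate bud tissue temperature under radiative
cooling) falls in the vulnerability window from 5 days before to 14 days
after the predicted leaf-out date.  The safety margin is leaf-out DOY minus
last-spring-frost DOY: positive means the last frost preceded leaf-out.

Temporal trends in leaf-out, last frost and margin use the Theil-Sen slope
(median of pairwise slopes, robust to outliers) with a rank-based 95% CI
and a two-sided Mann-Kendall test with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateSeries, ValidationError

__all__ = [
    "FrostEvent",
    "SafetyMarginRecord",
    "TrendResult",
    "last_spring_frost",
    "frost_in_window",
    "safety_margin",
    "theil_sen_trend",
    "mann_kendall",
    "risk_summary",
    "site_safety_margins",
]

DEFAULT_FROST_THRESHOLD = -1.0  # degrees C, inclusive (<=)
DEFAULT_WINDOW = (-5, 14)       # days relative to leaf-out, inclusive
SPRING_SEARCH_WINDOW = (1, 181)  # DOY range searched for the last spring frost


@dataclass(frozen=True)
class FrostEvent:
    year: int
    doy: int
    tmin: float
    daily_amplitude: float  # tmax - tmin on that day, degrees C


@dataclass
class SafetyMarginRecord:
    site_id: str
    year: int
    leafout_doy: int | None
    last_frost_doy: int | None
    margin_days: int | None
    window_frost: bool
    window_events: list[FrostEvent] = field(default_factory=list)


@dataclass
class TrendResult:
    """Theil-Sen slope (per decade) with 95% CI and Mann-Kendall test."""

    slope: float
    ci95: tuple[float, float]
    mk_p: float
    kendall_tau: float
    n: int


def last_spring_frost(
    climate: ClimateSeries,
    year: int,
    threshold: float = DEFAULT_FROST_THRESHOLD,
    search_window: tuple[int, int] = SPRING_SEARCH_WINDOW,
) -> int | None:
    """Largest DOY in ``search_window`` with tmin <= threshold, else None."""
    lo, hi = search_window
    tmin = climate.doy_array(year, "tmin", through_doy=hi)
    if len(tmin) < hi:
        raise ValidationError(
            f"site {climate.site_id}, year {year}: climate does not cover DOY {hi}"
        )
    doys = np.arange(1, len(tmin) + 1)
    mask = (doys >= lo) & (tmin <= threshold)
    if not mask.any():
        return None
    return int(doys[mask].max())


def frost_in_window(
    climate: ClimateSeries,
    year: int,
    leafout_doy: int | None,
    threshold: float = DEFAULT_FROST_THRESHOLD,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[bool | None, list[FrostEvent]]:
    """Frosts <= threshold within [leafout+window[0], leafout+window[1]].

    Bounds and threshold are inclusive.  Returns (None, []) when the
    leaf-out date is absent.
    """
    if leafout_doy is None:
        return None, []
    lo = max(1, leafout_doy + window[0])
    hi = leafout_doy + window[1]
    sub = climate.year_frame(year)
    days = sub.loc[(sub.index >= lo) & (sub.index <= hi)]
    if len(days) < hi - lo + 1:
        raise ValidationError(
            f"site {climate.site_id}, year {year}: window DOY {lo}..{hi} not covered"
        )
    hits = days[days["tmin"] <= threshold]
    events = [
        FrostEvent(
            year=year,
            doy=int(doy),
            tmin=float(row["tmin"]),
            daily_amplitude=float(row["tmax"] - row["tmin"]),
        )
        for doy, row in hits.iterrows()
    ]
    return bool(events), events


def safety_margin(leafout_doy: int | None, last_frost_doy: int | None) -> int | None:
    """Signed margin in days: leaf-out DOY minus last-frost DOY.

    Positive = the last frost preceded leaf-out (safe); negative = a frost
    struck after leaf-out.  Absent when either date is absent.
    """
    if leafout_doy is None or last_frost_doy is None:
        return None
    return int(leafout_doy) - int(last_frost_doy)


def site_safety_margins(
    climate: ClimateSeries,
    leafout_by_year: dict[int, int | None],
    threshold: float = DEFAULT_FROST_THRESHOLD,
    window: tuple[int, int] = DEFAULT_WINDOW,
    search_window: tuple[int, int] = SPRING_SEARCH_WINDOW,
) -> list[SafetyMarginRecord]:
    """Per-year frost/margin records for one site given predicted leaf-out."""
    records = []
    for year in sorted(leafout_by_year):
        leafout = leafout_by_year[year]
        last_frost = last_spring_frost(climate, year, threshold, search_window)
        flagged, events = frost_in_window(climate, year, leafout, threshold, window)
        records.append(
            SafetyMarginRecord(
                site_id=climate.site_id,
                year=year,
                leafout_doy=leafout,
                last_frost_doy=last_frost,
                margin_days=safety_margin(leafout, last_frost),
                window_frost=bool(flagged) if flagged is not None else False,
                window_events=events,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Trend statistics
# ---------------------------------------------------------------------------

def mann_kendall(values: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Kendall trend test with tie correction.

    Returns (p_value, S_statistic).  Uses the normal approximation with the
    standard tie-corrected variance and a continuity correction of 1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = float(np.sum(np.triu(diff_sign, k=1)))
    _, counts = np.unique(x, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var_s <= 0:
        return 1.0, s
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(p, 1.0)), s


def theil_sen_trend(
    years: Sequence[float], values: Sequence[float]
) -> TrendResult:
    """Theil-Sen slope of ``values`` against ``years``, scaled to per decade.

    Missing values (NaN / None) are dropped; n after dropping must be >= 3.
    """
    yr = np.asarray(years, dtype=float)
    vals = np.asarray([np.nan if v is None else v for v in values], dtype=float)
    keep = ~np.isnan(vals) & ~np.isnan(yr)
    yr, vals = yr[keep], vals[keep]
    if len(vals) < 3:
        raise ValidationError("trend requires at least 3 non-missing points")
    if np.ptp(vals) == 0:
        return TrendResult(slope=0.0, ci95=(0.0, 0.0), mk_p=1.0, kendall_tau=0.0, n=len(vals))
    slope, _, lo, hi = stats.theilslopes(vals, yr, alpha=0.95)
    tau = stats.kendalltau(yr, vals).statistic
    p, _ = mann_kendall(vals[np.argsort(yr)])
    return TrendResult(
        slope=float(slope * 10.0),
        ci95=(float(lo * 10.0), float(hi * 10.0)),
        mk_p=p,
        kendall_tau=float(tau),
        n=len(vals),
    )


# ---------------------------------------------------------------------------
# Site-level summary
# ---------------------------------------------------------------------------

def moving_average(values: Sequence[float], window: int = 10, min_valid: int = 6) -> np.ndarray:
    """Centered moving average requiring >= ``min_valid`` non-missing values."""
    vals = np.asarray([np.nan if v is None else v for v in values], dtype=float)
    out = np.full(len(vals), np.nan)
    half = window // 2
    for i in range(len(vals)):
        lo, hi = max(0, i - half), min(len(vals), i + window - half)
        win = vals[lo:hi]
        if np.sum(~np.isnan(win)) >= min_valid:
            out[i] = np.nanmean(win)
    return out


def risk_summary(
    records: Sequence[SafetyMarginRecord],
    sub_periods: Sequence[tuple[int, int]] = (),
) -> pd.DataFrame:
    """Per-site frost-risk summary.

    Columns: number and percentage of years with a window frost, mean and
    standard error of the safety margin, and counts of negative-margin years
    in each requested (start, end) sub-period.
    """
    if not records:
        raise ValidationError("risk_summary needs at least one record")
    rows = []
    by_site: dict[str, list[SafetyMarginRecord]] = {}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    for site, recs in sorted(by_site.items()):
        n = len(recs)
        n_flagged = sum(r.window_frost for r in recs)
        margins = np.array(
            [r.margin_days for r in recs if r.margin_days is not None], dtype=float
        )
        mean = float(np.mean(margins)) if len(margins) else np.nan
        se = float(np.std(margins, ddof=1) / np.sqrt(len(margins))) if len(margins) > 1 else 0.0
        row = {
            "site_id": site,
            "n_years": n,
            "n_window_frost": n_flagged,
            "pct_window_frost": round(100.0 * n_flagged / n, 1),
            "margin_mean": mean,
            "margin_se": se,
        }
        for start, end in sub_periods:
            neg = sum(
                1
                for r in recs
                if r.margin_days is not None and start <= r.year <= end and r.margin_days < 0
            )
            row[f"n_negative_{start}_{end}"] = neg
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[SafetyMarginRecord]) -> pd.DataFrame:
    """Flatten margin records for CSV export."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "year": [r.year for r in records],
            "leafout_doy": [r.leafout_doy for r in records],
            "last_frost_doy": [r.last_frost_doy for r in records],
            "margin_days": [r.margin_days for r in records],
            "window_frost": [r.window_frost for r in records],
            "n_window_events": [len(r.window_events) for r in records],
        }
    )
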