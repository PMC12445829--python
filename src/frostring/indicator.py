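"""Host / non-host residual indicator of damaging late spring frosts.

A frost-sensitive deciduous species (e.g. European beech) loses its entire
first leaf cohort to a late spring frost and diverts reserves into reflushing
at the expense of radial growth, while an evergreen reference species
(e.g. Norway spruce) keeps photosynthesising on older needles.  Subtracting
the reference species' site chronology from each individual sensitive-tree
RWI series cancels the climate signal the two species share (droughts, warm
summers) and leaves frost-specific growth collapses as strong negative
excursions.  Each residual series is standardised to z-scores; a year is
called a frost year when a supermajority of trees (default >= 60%) drop
below z = -1 (moderate damage; z < -1.5 severe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import ValidationError
from .frost import SafetyMarginRecord
from .rings import Chronology, RWISeries

__all__ = [
    "ResidualSeries",
    "FrostYearCall",
    "ConcordanceRecord",
    "residual_series",
    "build_site_residual_chronology",
    "flag_frost_years",
    "concordance_table",
    "period_counts",
]

log = logging.getLogger(__name__)

MODERATE_Z = -1.0
SEVERE_Z = -1.5
TREE_FRACTION = 0.60
MIN_TREES_PER_YEAR = 3


@dataclass
class ResidualSeries:
    """Standardised (z-score) residual of one sensitive tree vs reference."""

    tree_id: str
    site_id: str
    years: np.ndarray
    z_values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.z_values = np.asarray(self.z_values, dtype=float)


@dataclass
class FrostYearCall:
    site_id: str
    year: int
    n_trees: int
    frac_moderate: float
    frac_severe: float
    flagged: bool
    severity: str  # none | moderate | severe


@dataclass
class ConcordanceRecord:
    site_id: str
    year: int
    treering_flagged: bool
    climate_pheno_flagged: bool
    window_tmin: float | None
    leafout_doy: int | None
    out_of_window_candidates: list = field(default_factory=list)


def residual_series(
    tree_rwi: RWISeries, reference_chronology: Chronology, min_overlap: int = 20
) -> ResidualSeries:
    """Tree RWI minus the reference chronology, standardised to z-scores.

    z-scores use the mean and SD of the raw residual over the tree's full
    overlap with the chronology.  A zero-SD residual (degenerate, e.g. tree
    identical to the chronology) yields all-zero z-values with a warning.
    """
    ref_years = set(int(y) for y in reference_chronology.years)
    mask = np.array([int(y) in ref_years for y in tree_rwi.years])
    years = tree_rwi.years[mask]
    if len(years) < min_overlap:
        raise ValidationError(
            f"{tree_rwi.series_id}: overlap with reference chronology "
            f"({len(years)} yr) below {min_overlap}"
        )
    ref_vals = np.array([reference_chronology.at(int(y)) for y in years])
    resid = tree_rwi.indices[mask] - ref_vals
    sd = float(np.std(resid))
    if sd == 0.0:
        log.warning("%s: zero-variance residual, z set to 0", tree_rwi.series_id)
        z = np.zeros_like(resid)
    else:
        z = (resid - float(np.mean(resid))) / sd
    return ResidualSeries(
        tree_id=tree_rwi.series_id, site_id=tree_rwi.site_id, years=years, z_values=z
    )


def build_site_residual_chronology(residuals: Sequence[ResidualSeries]) -> Chronology:
    """Plain per-year mean of the individual z-score series."""
    if not residuals:
        raise ValidationError("need at least one residual series")
    start = min(int(r.years[0]) for r in residuals)
    end = max(int(r.years[-1]) for r in residuals)
    years = np.arange(start, end + 1)
    stack = np.full((len(residuals), len(years)), np.nan)
    for i, r in enumerate(residuals):
        stack[i, r.years - start] = r.z_values
    depth = np.sum(~np.isnan(stack), axis=0)
    keep = depth >= 1
    values = np.full(len(years), np.nan)
    values[keep] = np.nanmean(stack[:, keep], axis=0)
    return Chronology(
        site_id=residuals[0].site_id,
        species="residual",
        years=years[keep],
        values=values[keep],
        sample_depth=depth[keep],
    )


def flag_frost_years(
    residuals: Sequence[ResidualSeries],
    moderate_z: float = MODERATE_Z,
    severe_z: float = SEVERE_Z,
    tree_fraction: float = TREE_FRACTION,
    min_trees: int = MIN_TREES_PER_YEAR,
) -> list[FrostYearCall]:
    """Call frost years from the fraction of trees below the z thresholds.

    A year is flagged when the fraction of contributing trees with
    z < ``moderate_z`` reaches ``tree_fraction``; severity is "severe" when
    the fraction below ``severe_z`` also reaches it.  Years with fewer than
    ``min_trees`` contributing trees are not evaluated.
    """
    if not residuals:
        return []
    start = min(int(r.years[0]) for r in residuals)
    end = max(int(r.years[-1]) for r in residuals)
    years = np.arange(start, end + 1)
    stack = np.full((len(residuals), len(years)), np.nan)
    for i, r in enumerate(residuals):
        stack[i, r.years - start] = r.z_values
    calls = []
    site = residuals[0].site_id
    for j, year in enumerate(years):
        col = stack[:, j]
        have = ~np.isnan(col)
        n = int(have.sum())
        if n < min_trees:
            continue
        frac_mod = float(np.sum(col[have] < moderate_z)) / n
        frac_sev = float(np.sum(col[have] < severe_z)) / n
        flagged = frac_mod >= tree_fraction
        severity = "none"
        if flagged:
            severity = "severe" if frac_sev >= tree_fraction else "moderate"
        calls.append(
            FrostYearCall(
                site_id=site,
                year=int(year),
                n_trees=n,
                frac_moderate=frac_mod,
                frac_severe=frac_sev,
                flagged=flagged,
                severity=severity,
            )
        )
    return calls


def concordance_table(
    calls: Sequence[FrostYearCall],
    margins: Sequence[SafetyMarginRecord],
) -> tuple[list[ConcordanceRecord], Mapping[str, float]]:
    """Cross-check tree-ring frost calls against climate/phenology flags.

    For every tree-ring-flagged year, records whether a window frost
    (tmin <= threshold within the vulnerability window) was independently
    flagged from climate and predicted leaf-out; the summary maps site id to
    the concordant fraction.  For discordant years, the candidate frosts
    found outside the window (the record's last-frost information) are kept
    for inspection.
    """
    margin_by_key = {(m.site_id, m.year): m for m in margins}
    records: list[ConcordanceRecord] = []
    per_site: dict[str, list[bool]] = {}
    for call in calls:
        if not call.flagged:
            continue
        m = margin_by_key.get((call.site_id, call.year))
        climate_flag = bool(m.window_frost) if m is not None else False
        window_tmin = None
        leafout = None
        out_candidates: list = []
        if m is not None:
            leafout = m.leafout_doy
            if m.window_events:
                window_tmin = min(e.tmin for e in m.window_events)
            if not climate_flag and m.last_frost_doy is not None:
                out_candidates.append(("last_frost_doy", m.last_frost_doy))
        records.append(
            ConcordanceRecord(
                site_id=call.site_id,
                year=call.year,
                treering_flagged=True,
                climate_pheno_flagged=climate_flag,
                window_tmin=window_tmin,
                leafout_doy=leafout,
                out_of_window_candidates=out_candidates,
            )
        )
        per_site.setdefault(call.site_id, []).append(climate_flag)
    summary = {
        site: float(np.mean(flags)) for site, flags in per_site.items() if flags
    }
    return records, summary


def period_counts(
    calls: Sequence[FrostYearCall], periods: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """Flagged-year counts and mean return intervals per (start, end) period."""
    rows = []
    flagged_years: dict[str, list[int]] = {}
    for c in calls:
        if c.flagged:
            flagged_years.setdefault(c.site_id, []).append(c.year)
    sites = sorted(flagged_years) or [""]
    for start, end in periods:
        if end < start:
            raise ValidationError(f"invalid period {start}..{end}")
        length = end - start + 1
        for site in sites:
            years = flagged_years.get(site, [])
            n = sum(1 for y in years if start <= y <= end)
            rows.append(
                {
                    "site_id": site,
                    "period_start": start,
                    "period_end": end,
                    "n_flagged": n,
                    "return_interval_years": length / n if n else float("inf"),
                }
            )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[FrostYearCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [c.site_id for c in calls],
            "year": [c.year for c in calls],
            "n_trees": [c.n_trees for c in calls],
            "frac_moderate": [c.frac_moderate for c in calls],
            "frac_severe": [c.frac_severe for c in calls],
            "flagged": [c.flagged for c in calls],
            "severity": [c.severity for c in calls],
        }
    )
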