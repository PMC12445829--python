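"""Ring-width ingestion, detrending, and robust site chronologies.

Raw ring widths (mm/yr) are read from Tucson/RWL decadal files, detrended
per core by dividing by a cubic smoothing spline whose frequency response is
50% at a 30-yr wavelength (the standard age/size-trend removal that keeps
interannual climate signal while discarding low-frequency growth trends).
The resulting dimensionless ring-width indices (RWI, mean ~1) are averaged
per tree over its cores, then combined per site and species with Tukey's
biweight robust mean into a chronology with recorded sample depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .climate import ValidationError

__all__ = [
    "RingSeries",
    "RWISeries",
    "Chronology",
    "ChronologyStats",
    "read_rwl",
    "write_rwl",
    "spline_detrend",
    "spline_lambda",
    "average_cores",
    "biweight_mean",
    "biweight_chronology",
    "chronology_stats",
]

log = logging.getLogger(__name__)

#: Default 50% frequency-response cutoff wavelength for detrending (years).
DEFAULT_CUTOFF_YEARS = 30.0

#: Tukey biweight tuning constant (conventional value for chronologies).
BIWEIGHT_C = 9.0


@dataclass
class RingSeries:
    """Raw widths (mm) for one core over a contiguous span of years."""

    series_id: str
    site_id: str
    species: str
    years: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.years) != len(self.widths):
            raise ValidationError(f"{self.series_id}: years/widths length mismatch")
        if len(self.years) and not np.array_equal(
            self.years, np.arange(self.years[0], self.years[0] + len(self.years))
        ):
            raise ValidationError(f"{self.series_id}: years must be contiguous")
        if np.any(self.widths <= 0):
            raise ValidationError(f"{self.series_id}: widths must be > 0")


@dataclass
class RWISeries:
    """Detrended indices (dimensionless, ~1) for one core or tree."""

    series_id: str
    site_id: str
    species: str
    years: np.ndarray
    indices: np.ndarray
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.indices = np.asarray(self.indices, dtype=float)


@dataclass
class Chronology:
    """Robust site-level mean index series with per-year sample depth."""

    site_id: str
    species: str
    years: np.ndarray
    values: np.ndarray
    sample_depth: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=int)

    def at(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            return float("nan")
        return float(self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "value": self.values, "sample_depth": self.sample_depth}
        )


@dataclass
class ChronologyStats:
    mean_interseries_correlation: float  # rbar
    expressed_population_signal: float   # EPS
    first_order_autocorrelation: float
    mean_sensitivity: float
    n_trees: int
    span: tuple[int, int]


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

def read_rwl(
    path: str | Path, site_id: str = "", species: str = ""
) -> list[RingSeries]:
    """Read a Tucson decadal ring-width file.

    Stop marker 999 means 0.01 mm precision, -9999 means 0.001 mm.  Lines
    that do not parse are reported with their line number; duplicate series
    ids raise an error.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, float]]] = {}
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                errors.append(f"line {lineno}: malformed record")
                continue
            try:
                decade_year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError:
                errors.append(f"line {lineno}: non-numeric field")
                continue
            for offset, v in enumerate(values):
                raw.setdefault(sid, []).append((decade_year + offset, float(v)))
    if errors:
        raise ValidationError(f"{path.name}: " + "; ".join(errors))
    if not raw:
        log.warning("%s: empty RWL file", path.name)
        return []
    series = []
    for sid, pairs in raw.items():
        # the stop marker is the final value of a series: -9999 means
        # 0.001 mm precision, 999 means 0.01 mm (999 elsewhere is data)
        values = [p[1] for p in pairs]
        if -9999.0 in values[:-1]:
            i = values.index(-9999.0)
            errors.append(f"{sid}: data after -9999 stop marker (position {i})")
            continue
        if values and values[-1] == -9999.0:
            scale = 0.001
            pairs = pairs[:-1]
        elif values and values[-1] == 999.0:
            scale = 0.01
            pairs = pairs[:-1]
        else:
            scale = 0.01
        years = np.array([p[0] for p in pairs])
        widths = np.array([p[1] for p in pairs]) * scale
        series.append(
            RingSeries(
                series_id=sid,
                site_id=site_id or path.stem,
                species=species,
                years=years,
                widths=widths,
            )
        )
    if errors:
        raise ValidationError(f"{path.name}: " + "; ".join(errors))
    return series


def write_rwl(series: Iterable[RingSeries], path: str | Path, precision: float = 0.001) -> None:
    """Write series in Tucson decadal layout.

    ``precision`` 0.001 mm uses the -9999 stop marker, 0.01 mm uses 999.
    """
    if precision not in (0.01, 0.001):
        raise ValidationError("precision must be 0.01 or 0.001 mm")
    stop = "-9999" if precision == 0.001 else "999"
    lines = []
    for s in series:
        values = {int(y): int(round(w / precision)) for y, w in zip(s.years, s.widths)}
        first, last = int(s.years[0]), int(s.years[-1])
        year = first
        while year <= last:
            decade_end = (year // 10) * 10 + 9
            row_years = range(year, min(decade_end, last) + 1)
            fields = [f"{s.series_id:<8}{year:>4}"]
            fields += [f"{values[y]:>6}" for y in row_years]
            if last in row_years:
                fields.append(f"{stop:>6}")
            lines.append("".join(fields))
            year = decade_end + 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------

def spline_lambda(cutoff_years: float, frequency_response: float = 0.5) -> float:
    """Penalty parameter of a cubic smoothing spline whose transfer function
    ``H(f) = 1 / (1 + lam * (2*pi*f)^4)`` equals ``frequency_response`` at
    wavelength ``cutoff_years`` (unit sample spacing)."""
    if not 0 < frequency_response < 1:
        raise ValidationError("frequency_response must be in (0, 1)")
    omega = 2.0 * np.pi / cutoff_years
    return (1.0 / frequency_response - 1.0) / omega**4


def fit_growth_spline(
    years: np.ndarray,
    widths: np.ndarray,
    cutoff_years: float = DEFAULT_CUTOFF_YEARS,
    frequency_response: float = 0.5,
) -> np.ndarray:
    """Smoothed growth curve used as the detrending standard."""
    x = np.asarray(years, dtype=float)
    lam = spline_lambda(cutoff_years, frequency_response)
    spline = make_smoothing_spline(x, np.asarray(widths, dtype=float), lam=lam)
    return np.asarray(spline(x))


def spline_detrend(
    series: RingSeries,
    cutoff_years: float = DEFAULT_CUTOFF_YEARS,
    frequency_response: float = 0.5,
) -> RWISeries:
    """Ratio-detrend one core: RWI = width / fitted spline.

    If the fitted spline dips to <= 0 anywhere (possible with very suppressed
    segments), the series falls back to a linear fit, and to the series mean
    if the line is also non-positive; the fallback is recorded in the result
    notes and logged.
    """
    if len(series.years) < 10:
        raise ValidationError(f"{series.series_id}: need >= 10 years to detrend")
    notes: list[str] = []
    fitted = fit_growth_spline(series.years, series.widths, cutoff_years, frequency_response)
    if np.any(fitted <= 0):
        x = series.years.astype(float)
        coef = np.polyfit(x, series.widths, 1)
        fitted = np.polyval(coef, x)
        notes.append("spline fallback: linear")
        if np.any(fitted <= 0):
            fitted = np.full_like(fitted, float(np.mean(series.widths)))
            notes.append("spline fallback: mean")
        log.warning("%s: non-positive spline fit, fallback %s", series.series_id, notes[-1])
    return RWISeries(
        series_id=series.series_id,
        site_id=series.site_id,
        species=series.species,
        years=series.years.copy(),
        indices=series.widths / fitted,
        notes=notes,
    )


def default_tree_id(series_id: str) -> str:
    """Default core-to-tree mapping: strip the trailing core letter."""
    return series_id[:-1] if series_id and series_id[-1].isalpha() else series_id


def average_cores(
    core_indices: Sequence[RWISeries],
    tree_id: Callable[[str], str] = default_tree_id,
) -> list[RWISeries]:
    """Average the (typically two) core RWI series of each tree per year.

    Years covered by only one core pass that core's value through, with a
    note in the tree series metadata.
    """
    by_tree: dict[str, list[RWISeries]] = {}
    for s in core_indices:
        by_tree.setdefault(tree_id(s.series_id), []).append(s)
    trees = []
    for tid, cores in sorted(by_tree.items()):
        start = min(int(c.years[0]) for c in cores)
        end = max(int(c.years[-1]) for c in cores)
        years = np.arange(start, end + 1)
        stack = np.full((len(cores), len(years)), np.nan)
        for i, c in enumerate(cores):
            stack[i, c.years - start] = c.indices
        counts = np.sum(~np.isnan(stack), axis=0)
        mean = np.full(len(years), np.nan)
        has = counts > 0
        mean[has] = np.nanmean(stack[:, has], axis=0)
        notes = []
        if len(cores) > 1 and np.any((counts > 0) & (counts < len(cores))):
            notes.append("single-core years present")
        keep = has
        trees.append(
            RWISeries(
                series_id=tid,
                site_id=cores[0].site_id,
                species=cores[0].species,
                years=years[keep],
                indices=mean[keep],
                notes=notes,
            )
        )
    return trees


# ---------------------------------------------------------------------------
# Robust chronology
# ---------------------------------------------------------------------------

def biweight_mean(
    values: np.ndarray, c: float = BIWEIGHT_C, tol: float = 1e-8, max_iter: int = 50
) -> float:
    """Tukey's biweight robust location estimate.

    Starts at the median with MAD scale; iterates the weighted mean with
    weights ``(1 - u^2)^2`` for ``|u| < 1``, ``u = (x - m) / (c * MAD)``,
    until the location moves < tol or ``max_iter`` is hit.  Falls back to
    the median when MAD is zero.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return float("nan")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    for _ in range(max_iter):
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        new_m = float(np.sum(w * x) / np.sum(w))
        if abs(new_m - m) < tol:
            return new_m
        m = new_m
    return m


def _stack_series(series: Sequence[RWISeries]) -> tuple[np.ndarray, np.ndarray]:
    start = min(int(s.years[0]) for s in series)
    end = max(int(s.years[-1]) for s in series)
    years = np.arange(start, end + 1)
    stack = np.full((len(series), len(years)), np.nan)
    for i, s in enumerate(series):
        stack[i, s.years - start] = s.indices
    return years, stack


def biweight_chronology(
    tree_indices: Sequence[RWISeries], min_depth_warn: int = 6
) -> Chronology:
    """Biweight robust mean across trees per year, with sample depth.

    Years where no tree has data are dropped; years with depth below
    ``min_depth_warn`` are logged.
    """
    if not tree_indices:
        raise ValidationError("chronology needs at least one series")
    years, stack = _stack_series(tree_indices)
    depth = np.sum(~np.isnan(stack), axis=0)
    values = np.array([biweight_mean(stack[:, j]) for j in range(len(years))])
    keep = depth >= 1
    shallow = int(np.sum((depth >= 1) & (depth < min_depth_warn)))
    if shallow:
        log.info(
            "%s/%s chronology: %d years with sample depth < %d",
            tree_indices[0].site_id, tree_indices[0].species, shallow, min_depth_warn,
        )
    return Chronology(
        site_id=tree_indices[0].site_id,
        species=tree_indices[0].species,
        years=years[keep],
        values=values[keep],
        sample_depth=depth[keep],
    )


def chronology_stats(
    tree_indices: Sequence[RWISeries], min_overlap: int = 20
) -> ChronologyStats:
    """Classical chronology quality statistics.

    rbar is the mean pairwise Pearson correlation over pairs with at least
    ``min_overlap`` common years; EPS = n*rbar / (n*rbar + 1 - rbar).
    First-order autocorrelation and mean sensitivity are averaged over the
    individual tree series.
    """
    if len(tree_indices) < 2:
        raise ValidationError("chronology stats need >= 2 series")
    years, stack = _stack_series(tree_indices)
    cors = []
    for i in range(len(tree_indices)):
        for j in range(i + 1, len(tree_indices)):
            both = ~np.isnan(stack[i]) & ~np.isnan(stack[j])
            if both.sum() >= min_overlap:
                a, b = stack[i, both], stack[j, both]
                if np.std(a) > 0 and np.std(b) > 0:
                    cors.append(np.corrcoef(a, b)[0, 1])
    if not cors:
        raise ValidationError(f"no series pair overlaps >= {min_overlap} years")
    rbar = float(np.mean(cors))
    n = len(tree_indices)
    eps = n * rbar / (n * rbar + 1 - rbar) if n * rbar + 1 - rbar != 0 else float("nan")

    ar1s, senses = [], []
    for s in tree_indices:
        v = s.indices
        if len(v) > 2 and np.std(v) > 0:
            ar1s.append(np.corrcoef(v[:-1], v[1:])[0, 1])
        denom = (v[1:] + v[:-1]) / 2.0
        ok = denom != 0
        senses.append(np.mean(np.abs(np.diff(v))[ok] / denom[ok]))
    return ChronologyStats(
        mean_interseries_correlation=rbar,
        expressed_population_signal=float(eps),
        first_order_autocorrelation=float(np.mean(ar1s)) if ar1s else float("nan"),
        mean_sensitivity=float(np.mean(senses)),
        n_trees=n,
        span=(int(years[0]), int(years[-1])),
    )
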