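"""Synthetic climate, phenology, and ring-width generator with known truth.

Emulates a two-site mountain study design: daily temperature as a seasonal
sinusoid (coldest in mid-January) with AR(1) day-to-day anomalies, spring
cold snaps injected into tmin only (radiative-cooling nights leave the daily
mean and maximum untouched), leaf-out observations produced by the forcing
model itself plus observation noise, and lognormal ring-width series built
from a negative-exponential age trend, a summer climate signal shared
between species, and a multiplicative growth collapse applied to the
frost-sensitive species in injected frost years.  Every generator is fully
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .climate import ClimateSeries, PhenoObservation, ValidationError
from .phenology import M1Parameters, daylength, forcing_rate, predict_leafout
from .rings import RingSeries

__all__ = [
    "SyntheticConfig",
    "generate_climate",
    "generate_phenology",
    "generate_ring_series",
    "climate_summer_index",
]

#: Forcing-model parameters used as generator truth: start 3 January, base
#: temperature 0.29 C, photoperiod exponent 4.76, threshold 1248 units —
#: the published optimum for European beech at high-elevation Swiss sites.
TRUE_BEECH_PARAMS = M1Parameters(t0=3, Tb=0.29, k=4.76, Fcrit=1248.0)

#: DOY window of the shared summer climate index (mean tmax) that drives
#: ring growth in both species.
SUMMER_INDEX_WINDOW = (160, 220)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic two-species site.

    Defaults mirror the emulated high-elevation Jura site: mean annual
    temperature 4.7 C with a seasonal half-amplitude of 8.5 C (January mean
    ~ -4 C, July ~ +13 C), ~90 analysis years, 12 trees per species with two
    cores each, and a frost-year growth multiplier of 0.4 (an extreme-year
    RWI of ~0.4; the damage magnitude is a modelling choice).
    """

    n_years: int = 92
    start_year: int = 1930
    site_id: str = "SYN"
    site_latitude: float = 47.4
    site_elevation: float = 1365.0
    mean_annual_temp: float = 4.7
    seasonal_amplitude: float = 8.5
    diurnal_range: float = 8.0
    ar1_coefficient: float = 0.7
    noise_sd: float = 3.0
    frost_events: list[tuple[int, int, float]] = field(default_factory=list)
    true_m1_params: M1Parameters = TRUE_BEECH_PARAMS
    pheno_noise_sd: float = 7.5
    n_trees_per_species: int = 12
    ring_age_trend: tuple[float, float] = (3.0, 0.01)  # initial mm, decay /yr
    climate_signal_beta: float = 0.3
    frost_multiplier: float = 0.4
    ring_noise_sd: float = 0.2
    core_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValidationError("ar1_coefficient must be in [0, 1)")
        if not 0.0 < self.frost_multiplier <= 1.0:
            raise ValidationError("frost_multiplier must be in (0, 1]")
        for name in ("noise_sd", "pheno_noise_sd", "ring_noise_sd", "core_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        last = self.start_year + self.n_years - 1
        for year, doy, depth in self.frost_events:
            if not self.start_year <= year <= last:
                raise ValidationError(
                    f"frost_event year {year} outside [{self.start_year}, {last}]"
                )
            if not 1 <= doy <= 365:
                raise ValidationError(f"frost_event doy {doy} outside [1, 365]")
            if depth < 0:
                raise ValidationError("frost_event depth must be >= 0")


def generate_climate(config: SyntheticConfig) -> ClimateSeries:
    """Daily tmin/tmean/tmax/precip for ``n_years`` calendar years.

    tmean(d) = mean - amplitude * cos(2*pi*(doy - 15)/365.25) + AR(1) noise,
    so the coldest day falls mid-January.  tmin/tmax sit a half diurnal
    range below/above tmean; each injected frost event additionally pushes
    tmin on its (year, doy) down by the stated depth.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )
    doy = dates.dayofyear.to_numpy()
    seasonal = config.mean_annual_temp - config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 15) / 365.25
    )
    n = len(dates)
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1_coefficient**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.noise_sd)
        for i in range(1, n):
            noise[i] = config.ar1_coefficient * noise[i - 1] + eps[i]
    else:
        noise = np.zeros(n)
    tmean = seasonal + noise
    tmin = tmean - config.diurnal_range / 2.0
    tmax = tmean + config.diurnal_range / 2.0

    years = dates.year.to_numpy()
    for ev_year, ev_doy, depth in config.frost_events:
        mask = (years == ev_year) & (doy == ev_doy)
        tmin[mask] -= depth

    precip = rng.gamma(shape=0.6, scale=7.0, size=n) * (rng.random(n) < 0.45)
    df = pd.DataFrame(
        {"date": dates, "tmin": tmin, "tmean": tmean, "tmax": tmax, "precip": precip}
    )
    return ClimateSeries(
        site_id=config.site_id,
        latitude=config.site_latitude,
        elevation=config.site_elevation,
        data=df,
    )


def generate_phenology(
    climate: ClimateSeries,
    true_params: M1Parameters,
    pheno_noise_sd: float,
    seed: int,
) -> tuple[list[PhenoObservation], list[int]]:
    """Leaf-out observations = model prediction + rounded Gaussian noise.

    Returns (observations, non_emerging_years); years where the forcing
    threshold is never reached produce no observation and are reported in
    the second element.
    """
    rng = np.random.default_rng(seed)
    observations: list[PhenoObservation] = []
    non_emerging: list[int] = []
    for year in climate.years:
        pred = predict_leafout(climate, int(year), true_params)
        if pred is None:
            non_emerging.append(int(year))
            continue
        obs = pred
        if pheno_noise_sd > 0:
            obs = int(round(pred + rng.normal(0.0, pheno_noise_sd)))
        obs = int(np.clip(obs, 1, 366))
        observations.append(PhenoObservation(climate.site_id, int(year), obs))
    return observations, non_emerging


def climate_summer_index(climate: ClimateSeries) -> pd.Series:
    """Standardised mean summer tmax (DOY 160-220) per year — the shared
    growth signal both species respond to."""
    lo, hi = SUMMER_INDEX_WINDOW
    df = climate.data
    sel = df[(df["doy"] >= lo) & (df["doy"] <= hi)]
    raw = sel.groupby("year")["tmax"].mean()
    return (raw - raw.mean()) / raw.std()


def generate_ring_series(
    climate: ClimateSeries,
    frost_years: Sequence[int],
    config: SyntheticConfig,
    species: str,
    common_stress_years: Sequence[int] = (),
    common_stress_multiplier: float = 1.0,
    seed_offset: int = 0,
) -> list[RingSeries]:
    """Two cores per tree of lognormal ring widths with known structure.

    width(tree, year) = age_trend * exp(beta * climate_index + tree noise)
    * m, where m multiplies in ``frost_years`` for the frost-sensitive
    species only.  ``common_stress_years`` apply ``common_stress_multiplier``
    to BOTH species (e.g. a shared drought), supporting specificity checks
    of the residual indicator.  Cores add independent lognormal noise to the
    tree series.
    """
    if species not in ("frost_sensitive", "reference"):
        raise ValidationError("species must be 'frost_sensitive' or 'reference'")
    cover = set(int(y) for y in climate.years)
    bad = [y for y in frost_years if int(y) not in cover]
    if bad:
        raise ValidationError(f"frost years outside climate coverage: {bad}")

    index = climate_summer_index(climate)
    years = np.array(sorted(cover))
    z = index.reindex(years).to_numpy()
    w0, decay = config.ring_age_trend
    age = np.arange(len(years), dtype=float)
    age_trend = w0 * np.exp(-decay * age)

    multiplier = np.ones(len(years))
    if species == "frost_sensitive":
        for y in frost_years:
            multiplier[years == int(y)] *= config.frost_multiplier
    for y in common_stress_years:
        multiplier[years == int(y)] *= common_stress_multiplier

    rng = np.random.default_rng(config.seed + 1000 + seed_offset)
    prefix = "FS" if species == "frost_sensitive" else "RF"
    out: list[RingSeries] = []
    for t in range(config.n_trees_per_species):
        tree_noise = rng.normal(0.0, config.ring_noise_sd, size=len(years))
        tree_widths = age_trend * np.exp(config.climate_signal_beta * z + tree_noise) * multiplier
        for core in "AB":
            core_noise = rng.normal(0.0, config.core_noise_sd, size=len(years))
            widths = tree_widths * np.exp(core_noise)
            out.append(
                RingSeries(
                    series_id=f"{prefix}{t + 1:02d}{core}",
                    site_id=climate.site_id,
                    species=species,
                    years=years,
                    widths=widths,
                )
            )
    return out


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed (replicate experiments)."""
    return replace(config, seed=seed)
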