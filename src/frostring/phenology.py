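"""Photoperiod-modulated thermal-forcing model of spring leaf-out.

The model accumulates daily forcing units from a start day ``t0``:

    R_i = (L_i / 10)^k * max(T_i - Tb, 0)
    S(d) = sum_{i=t0}^{d} R_i

where ``T_i`` is daily mean temperature (degrees C), ``L_i`` the daylength in
hours, ``Tb`` a base temperature and ``k`` a photoperiod response exponent.
Leaf-out is predicted on the first day ``d >= t0`` with ``S(d) >= Fcrit``.
With ``k = 0`` this reduces to a plain growing-degree-day model.

Calibration minimises the RMSE between predicted and observed leaf-out day of
year over all site-years, using a seeded derivative-free global optimiser
(simulated annealing by default) inside a parameter box that keeps ``t0`` on
or after 1 January and ``Tb`` strictly positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .climate import ClimateSeries, PhenoObservation, ValidationError

__all__ = [
    "M1Parameters",
    "CalibrationResult",
    "daylength",
    "forcing_rate",
    "predict_leafout",
    "model_rmse",
    "null_model_rmse",
    "calibrate",
    "cross_validate",
    "DEFAULT_BOUNDS",
]

#: Day of year used in place of a prediction when the forcing threshold is
#: never reached within the year.  Keeps the calibration objective bounded
#: and steers the optimiser away from non-emerging parameter regions.
NON_EMERGENCE_PENALTY_DOY = 250

#: Default calibration box: t0 in days since 1 Jan, Tb in degrees C, k
#: unitless, Fcrit in forcing units.  Encloses published optima for European
#: beech and related temperate broadleaves.
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (1.0, 90.0),
    (1e-6, 10.0),
    (0.0, 10.0),
    (1.0, 5000.0),
)

#: Solar elevation angle (degrees below horizon) defining day start/end in
#: the daylength formula; 0.8333 degrees is the standard refraction-corrected
#: sunrise/sunset definition.  A single swappable constant so alternative
#: conventions (e.g. 6 degrees for civil twilight) can be substituted.
TWILIGHT_ANGLE_DEG = 0.8333


class ConfigurationError(ValueError):
    """Raised when calibration bounds violate the model's constraints."""


@dataclass(frozen=True)
class M1Parameters:
    """Calibrated state of the forcing model.

    t0: start day of forcing accumulation (DOY, >= 1).
    Tb: base temperature for accumulation (degrees C, > 0).
    k: photoperiod response exponent (unitless, >= 0).
    Fcrit: forcing threshold triggering leaf-out (forcing units, > 0).
    """

    t0: int
    Tb: float
    k: float
    Fcrit: float

    def __post_init__(self) -> None:
        if self.t0 < 1:
            raise ConfigurationError("t0 must be on or after 1 January (t0 >= 1)")
        if self.Tb <= 0:
            raise ConfigurationError("base temperature Tb must be > 0 degrees C")
        if self.Fcrit <= 0:
            raise ConfigurationError("Fcrit must be positive")


@dataclass
class CalibrationResult:
    params: M1Parameters
    train_rmse: float
    null_rmse: float
    n_site_years: int
    optimizer_calls: int
    seed: int
    degenerate: bool = False

    def to_json(self, path: str | Path, bounds: Sequence[Sequence[float]] | None = None) -> None:
        payload = {
            "params": asdict(self.params),
            "train_rmse": self.train_rmse,
            "null_rmse": self.null_rmse,
            "n_site_years": self.n_site_years,
            "optimizer_calls": self.optimizer_calls,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }
        if bounds is not None:
            payload["bounds"] = [list(b) for b in bounds]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(
            params=M1Parameters(**d["params"]),
            train_rmse=d["train_rmse"],
            null_rmse=d["null_rmse"],
            n_site_years=d["n_site_years"],
            optimizer_calls=d["optimizer_calls"],
            seed=d["seed"],
            degenerate=d.get("degenerate", False),
        )


# ---------------------------------------------------------------------------
# Daylength (Forsythe et al. 1995 "CBM" model)
# ---------------------------------------------------------------------------

def daylength(latitude: float, doy, twilight_angle: float = TWILIGHT_ANGLE_DEG):
    """Hours of daylight at ``latitude`` on day-of-year ``doy``.

    Uses the CBM model of Forsythe et al. (1995): solar declination from the
    revolution angle, day defined by the sun's centre reaching
    ``twilight_angle`` degrees below the horizon (civil definition by
    default).  Accepts scalar or array ``doy``.
    """
    if abs(latitude) > 66.5:
        raise ValidationError(
            f"latitude {latitude} outside supported temperate range (|lat| <= 66.5)"
        )
    doy = np.asarray(doy, dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    lat = math.radians(latitude)
    p = math.radians(twilight_angle)
    cos_hour = (np.sin(p) + np.sin(lat) * np.sin(phi)) / (np.cos(lat) * np.cos(phi))
    cos_hour = np.clip(cos_hour, -1.0, 1.0)
    hours = 24.0 - (24.0 / np.pi) * np.arccos(cos_hour)
    # near the edge of the supported band the midsummer sun never crosses
    # the twilight horizon; keep the value strictly inside (0, 24)
    hours = np.clip(hours, 1e-6, 24.0 - 1e-6)
    return float(hours) if hours.ndim == 0 else hours


def forcing_rate(ti, li, tb: float, k: float):
    """Daily forcing units: ``(Li/10)^k * (Ti - Tb)`` when Ti > Tb, else 0."""
    ti = np.asarray(ti, dtype=float)
    li = np.asarray(li, dtype=float)
    rate = np.power(li / 10.0, k) * np.maximum(ti - tb, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def predict_leafout(
    climate: ClimateSeries, year: int, params: M1Parameters
) -> int | None:
    """Predicted leaf-out DOY for one site-year, or None if the forcing
    threshold is never reached by year end.

    Accumulates daily forcing from ``params.t0`` using daily mean temperature
    and site daylength; returns the first DOY whose cumulative forcing meets
    ``Fcrit``.
    """
    tmean = climate.doy_array(year, "tmean")
    n = len(tmean)
    if n < 200:
        raise ValidationError(
            f"site {climate.site_id}, year {year}: climate must cover at least DOY 200"
        )
    doys = np.arange(1, n + 1)
    li = daylength(climate.latitude, doys)
    rates = forcing_rate(tmean, li, params.Tb, params.k)
    rates[: params.t0 - 1] = 0.0
    s = np.cumsum(rates)
    reached = s >= params.Fcrit
    if not reached.any():
        return None
    return int(np.argmax(reached)) + 1


# ---------------------------------------------------------------------------
# Vectorised forcing table (one row per site-year) for fast calibration
# ---------------------------------------------------------------------------

class ForcingTable:
    """Dense (site-year x DOY) temperature matrix with per-site daylength.

    Precomputed once per dataset so each objective evaluation is a handful of
    vectorised array operations.  Predictions use DOY 1..365; a threshold not
    reached by day 365 counts as non-emerging.
    """

    MAX_DOY = 365

    def __init__(
        self,
        climate_by_site: Mapping[str, ClimateSeries],
        observations: Sequence[PhenoObservation],
    ) -> None:
        if not observations:
            raise ValidationError("empty observation set")
        obs = sorted(observations, key=lambda o: (o.site_id, o.year))
        site_ids = sorted({o.site_id for o in obs})
        missing = [s for s in site_ids if s not in climate_by_site]
        if missing:
            raise ValidationError(f"no climate for sites: {missing}")

        self.keys = [(o.site_id, o.year) for o in obs]
        self.obs_doy = np.array([o.leafout_doy for o in obs], dtype=float)
        site_index = {s: i for i, s in enumerate(site_ids)}
        self.row_site = np.array([site_index[o.site_id] for o in obs])

        self.temps = np.empty((len(obs), self.MAX_DOY))
        for r, o in enumerate(obs):
            self.temps[r] = climate_by_site[o.site_id].doy_array(
                o.year, "tmean", through_doy=self.MAX_DOY
            )[: self.MAX_DOY]

        doys = np.arange(1, self.MAX_DOY + 1)
        self.log_photoperiod = np.stack(
            [np.log(daylength(climate_by_site[s].latitude, doys) / 10.0) for s in site_ids]
        )

    def __len__(self) -> int:
        return len(self.keys)

    def predict(self, params: M1Parameters) -> np.ndarray:
        """Predicted DOY per row; NaN where the model never emerges."""
        photo = np.exp(params.k * self.log_photoperiod)[self.row_site]
        rates = photo * np.maximum(self.temps - params.Tb, 0.0)
        rates[:, : params.t0 - 1] = 0.0
        s = np.cumsum(rates, axis=1)
        reached = s >= params.Fcrit
        idx = reached.argmax(axis=1)
        emerged = reached[np.arange(len(idx)), idx]
        pred = (idx + 1).astype(float)
        pred[~emerged] = np.nan
        return pred

    def rmse(self, params: M1Parameters, rows: np.ndarray | None = None) -> float:
        pred = self.predict(params)
        pred = np.where(np.isnan(pred), float(NON_EMERGENCE_PENALTY_DOY), pred)
        err = pred - self.obs_doy
        if rows is not None:
            err = err[rows]
        return float(np.sqrt(np.mean(err**2)))


def _vector_to_params(x: Sequence[float]) -> M1Parameters:
    return M1Parameters(
        t0=max(1, int(round(x[0]))), Tb=float(x[1]), k=float(x[2]), Fcrit=float(x[3])
    )


def model_rmse(
    params: M1Parameters,
    climate_by_site: Mapping[str, ClimateSeries],
    observations: Sequence[PhenoObservation],
    penalty_doy: int = NON_EMERGENCE_PENALTY_DOY,
) -> float:
    """RMSE (days) between predicted and observed leaf-out over site-years.

    Site-years where the model never reaches the threshold contribute a
    prediction at ``penalty_doy`` so the objective stays bounded.
    """
    if not observations:
        raise ValidationError("empty observation set")
    sq = []
    for o in observations:
        pred = predict_leafout(climate_by_site[o.site_id], o.year, params)
        if pred is None:
            pred = penalty_doy
        sq.append((pred - o.leafout_doy) ** 2)
    return float(np.sqrt(np.mean(sq)))


def null_model_rmse(
    train: Sequence[PhenoObservation], test: Sequence[PhenoObservation]
) -> float:
    """RMSE of ``test`` against the mean training leaf-out date."""
    if not train:
        raise ValidationError("null model requires a non-empty training set")
    mean_doy = float(np.mean([o.leafout_doy for o in train]))
    errs = np.array([o.leafout_doy - mean_doy for o in test])
    return float(np.sqrt(np.mean(errs**2)))


def calibrate(
    climate_by_site: Mapping[str, ClimateSeries],
    observations: Sequence[PhenoObservation],
    bounds: Sequence[Sequence[float]] = DEFAULT_BOUNDS,
    initial_temperature: float = 10_000.0,
    max_calls: int = 40_000,
    seed: int = 0,
) -> CalibrationResult:
    """Fit the forcing model by seeded simulated annealing within ``bounds``.

    The contract is "global minimiser of the leaf-out RMSE within the box";
    scipy's dual annealing (generalised simulated annealing, local search
    disabled because the integer-day objective is piecewise constant) is the
    default engine.  Deterministic for a given seed.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    if len(bounds) != 4:
        raise ConfigurationError("bounds must box (t0, Tb, k, Fcrit)")
    if bounds[0][0] < 1:
        raise ConfigurationError("t0 lower bound must be >= 1 (forcing from 1 January)")
    if bounds[1][0] <= 0:
        raise ConfigurationError("Tb lower bound must be > 0 degrees C")

    table = ForcingTable(climate_by_site, observations)

    calls = 0

    def objective(x: np.ndarray) -> float:
        nonlocal calls
        calls += 1
        return table.rmse(_vector_to_params(x))

    result = optimize.dual_annealing(
        objective,
        bounds=bounds,
        maxfun=max_calls,
        initial_temp=initial_temperature,
        no_local_search=True,
        rng=int(seed),
    )
    params = _vector_to_params(result.x)
    train_rmse = table.rmse(params)
    null_rmse = null_model_rmse(observations, observations)
    return CalibrationResult(
        params=params,
        train_rmse=train_rmse,
        null_rmse=null_rmse,
        n_site_years=len(table),
        optimizer_calls=calls,
        seed=seed,
        degenerate=len(table) < 10,
    )


def cross_validate(
    climate_by_site: Mapping[str, ClimateSeries],
    observations: Sequence[PhenoObservation],
    n_folds: int = 10,
    seed: int = 0,
    max_calls: int = 2_000,
    bounds: Sequence[Sequence[float]] = DEFAULT_BOUNDS,
) -> float:
    """Mean held-out RMSE (days) over a seeded k-fold split of site-years.

    Folds partition site-years after sorting by (site, year), so the result
    is invariant to the input ordering of the observations.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    obs = sorted(observations, key=lambda o: (o.site_id, o.year))
    if n_folds > len(obs):
        raise ValidationError(f"n_folds={n_folds} exceeds {len(obs)} site-years")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    fold_of = np.empty(len(obs), dtype=int)
    fold_of[order] = np.arange(len(obs)) % n_folds

    fold_rmses = []
    for fold in range(n_folds):
        train = [o for o, f in zip(obs, fold_of) if f != fold]
        test = [o for o, f in zip(obs, fold_of) if f == fold]
        fit = calibrate(
            climate_by_site,
            train,
            bounds=bounds,
            max_calls=max_calls,
            seed=seed + fold,
        )
        fold_rmses.append(model_rmse(fit.params, climate_by_site, test))
    return float(np.mean(fold_rmses))


def cross_validate_null(
    observations: Sequence[PhenoObservation], n_folds: int = 10, seed: int = 0
) -> float:
    """Held-out RMSE of the fixed-mean-date null model under the same folds."""
    obs = sorted(observations, key=lambda o: (o.site_id, o.year))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    fold_of = np.empty(len(obs), dtype=int)
    fold_of[order] = np.arange(len(obs)) % n_folds
    rmses = []
    for fold in range(n_folds):
        train = [o for o, f in zip(obs, fold_of) if f != fold]
        test = [o for o, f in zip(obs, fold_of) if f == fold]
        rmses.append(null_model_rmse(train, test))
    return float(np.mean(rmses))
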