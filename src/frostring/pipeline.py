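"""End-to-end orchestration: config -> calibrate -> risk -> rings -> calls.

Each stage consumes and produces plain files (CSV / JSON / RWL), so any
stage can be re-run in isolation; a run manifest records seeds, stage
timings and SHA-256 hashes of every input.  ``make_fixtures`` writes a
complete two-site, two-species synthetic emulation of a mountain LSF study
(12 trees x 2 cores per species per site over ~90 years, with frost events
injected at the high site) in exactly the formats the real pipeline reads.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import frost, indicator, phenology, response, rings, synthetic
from .climate import (
    ClimateSeries,
    ValidationError,
    observations_by_site,
    read_climate_csv,
    read_phenology_csv,
    write_climate_csv,
    write_phenology_csv,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SiteConfig", "run_pipeline", "make_fixtures"]


@dataclass
class SiteConfig:
    site_id: str
    climate_csv: str
    rwl_frost_sensitive: str
    rwl_reference: str
    exclude_series: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    sites: list[SiteConfig]
    phenology_csv: str
    out_dir: str
    frost_threshold: float = frost.DEFAULT_FROST_THRESHOLD
    window: tuple[int, int] = frost.DEFAULT_WINDOW
    moderate_z: float = indicator.MODERATE_Z
    severe_z: float = indicator.SEVERE_Z
    tree_fraction: float = indicator.TREE_FRACTION
    spline_cutoff_years: float = rings.DEFAULT_CUTOFF_YEARS
    sea_lags: tuple[int, int] = (0, 4)
    sea_n_boot: int = 999
    calibration_max_calls: int = 4000
    seed: int = 0
    periods: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -10.0 <= self.frost_threshold <= 0.0:
            raise ValidationError("frost_threshold must lie in [-10, 0] degrees C")
        for site in self.sites:
            for p in (site.climate_csv, site.rwl_frost_sensitive, site.rwl_reference):
                if not Path(p).exists():
                    raise ValidationError(f"site {site.site_id}: missing input {p}")
        if not Path(self.phenology_csv).exists():
            raise ValidationError(f"missing phenology input {self.phenology_csv}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sites = [SiteConfig(**s) for s in raw.pop("sites")]
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "sea_lags" in raw:
            raw["sea_lags"] = tuple(raw["sea_lags"])
        if "periods" in raw:
            raw["periods"] = [tuple(p) for p in raw["periods"]]
        return cls(sites=sites, **raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the run manifest (also written as manifest.json).  Deterministic
    for fixed inputs and seed; any stage failure raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "warnings": [],
    }
    for site in config.sites:
        for p in (site.climate_csv, site.rwl_frost_sensitive, site.rwl_reference):
            manifest["inputs"][p] = _sha256(p)
    manifest["inputs"][config.phenology_csv] = _sha256(config.phenology_csv)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            return result

        return wrap

    climates: dict[str, ClimateSeries] = {}

    def load_climate():
        for site in config.sites:
            climates[site.site_id] = read_climate_csv(site.climate_csv)

    stage("climate")(load_climate)

    observations = stage("phenology-load")(lambda: read_phenology_csv(config.phenology_csv))

    def do_calibrate():
        fit = phenology.calibrate(
            climates,
            observations,
            max_calls=config.calibration_max_calls,
            seed=config.seed,
        )
        fit.to_json(out / "calibration.json", bounds=phenology.DEFAULT_BOUNDS)
        return fit

    fit = stage("calibrate")(do_calibrate)

    def do_risk():
        records = []
        trend_out = {}
        for site_id, climate in climates.items():
            leafout = {
                int(y): phenology.predict_leafout(climate, int(y), fit.params)
                for y in climate.years
            }
            recs = frost.site_safety_margins(
                climate, leafout, config.frost_threshold, config.window
            )
            records.extend(recs)
            years = [r.year for r in recs]
            for label, vals in (
                ("leafout", [r.leafout_doy for r in recs]),
                ("last_frost", [r.last_frost_doy for r in recs]),
                ("margin", [r.margin_days for r in recs]),
            ):
                try:
                    t = frost.theil_sen_trend(years, vals)
                    trend_out[f"{site_id}.{label}"] = {
                        "slope_per_decade": t.slope,
                        "ci95": list(t.ci95),
                        "mk_p": t.mk_p,
                        "kendall_tau": t.kendall_tau,
                        "n": t.n,
                    }
                except ValidationError as exc:
                    manifest["warnings"].append(f"trend {site_id}.{label}: {exc}")
        frost.records_to_frame(records).to_csv(out / "safety_margins.csv", index=False)
        (out / "trends.json").write_text(json.dumps(trend_out, indent=2))
        return records

    margin_records = stage("risk")(do_risk)

    site_chronologies: dict[str, dict[str, rings.Chronology]] = {}
    site_residuals: dict[str, list[indicator.ResidualSeries]] = {}

    def do_rings():
        for site in config.sites:
            site_chronologies[site.site_id] = {}
            sens_cores = rings.read_rwl(
                site.rwl_frost_sensitive, site_id=site.site_id, species="frost_sensitive"
            )
            ref_cores = rings.read_rwl(
                site.rwl_reference, site_id=site.site_id, species="reference"
            )
            excluded = set(site.exclude_series)
            trees = {}
            for label, cores in (("frost_sensitive", sens_cores), ("reference", ref_cores)):
                kept = [c for c in cores if rings.default_tree_id(c.series_id) not in excluded]
                n_drop = len(cores) - len(kept)
                if n_drop:
                    manifest["warnings"].append(
                        f"{site.site_id}/{label}: excluded {n_drop} core series"
                    )
                rwi = [
                    rings.spline_detrend(c, cutoff_years=config.spline_cutoff_years)
                    for c in kept
                ]
                tree_series = rings.average_cores(rwi)
                trees[label] = tree_series
                chron = rings.biweight_chronology(tree_series)
                site_chronologies[site.site_id][label] = chron
                chron.to_frame().to_csv(
                    out / f"chronology_{site.site_id}_{label}.csv", index=False
                )
            site_residuals[site.site_id] = [
                indicator.residual_series(t, site_chronologies[site.site_id]["reference"])
                for t in trees["frost_sensitive"]
            ]

    stage("rings")(do_rings)

    def do_detect():
        all_calls = []
        for site in config.sites:
            residuals = site_residuals[site.site_id]
            chron = indicator.build_site_residual_chronology(residuals)
            chron.to_frame().to_csv(
                out / f"chronology_{site.site_id}_residual.csv", index=False
            )
            site_chronologies[site.site_id]["residual"] = chron
            all_calls.extend(
                indicator.flag_frost_years(
                    residuals,
                    moderate_z=config.moderate_z,
                    severe_z=config.severe_z,
                    tree_fraction=config.tree_fraction,
                )
            )
        indicator.calls_to_frame(all_calls).to_csv(out / "frost_year_calls.csv", index=False)
        records, summary = indicator.concordance_table(all_calls, margin_records)
        rows = [
            {
                "site_id": r.site_id,
                "year": r.year,
                "climate_pheno_flagged": r.climate_pheno_flagged,
                "window_tmin": r.window_tmin,
                "leafout_doy": r.leafout_doy,
            }
            for r in records
        ]
        (out / "concordance.json").write_text(
            json.dumps({"records": rows, "summary": summary}, indent=2)
        )
        if config.periods:
            indicator.period_counts(all_calls, config.periods).to_csv(
                out / "period_counts.csv", index=False
            )
        return all_calls

    calls = stage("detect")(do_detect)

    def do_respond():
        lags = range(config.sea_lags[0], config.sea_lags[1] + 1)
        sea_rows = []
        for site in config.sites:
            flagged = [c.year for c in calls if c.site_id == site.site_id and c.flagged]
            for label in ("frost_sensitive", "reference"):
                chron = site_chronologies[site.site_id][label]
                if len(flagged) >= 2:
                    try:
                        sea = response.superposed_epoch(
                            chron, flagged, lags=lags,
                            n_boot=config.sea_n_boot, seed=config.seed,
                        )
                        df = sea.to_frame()
                        df.insert(0, "species", label)
                        df.insert(0, "site_id", site.site_id)
                        sea_rows.append(df)
                    except ValidationError as exc:
                        manifest["warnings"].append(f"SEA {site.site_id}/{label}: {exc}")
            grid = response.daywise_correlations(
                site_chronologies[site.site_id]["residual"],
                climates[site.site_id],
                "tmin",
                start_doys=range(1, 271, 5),
                window_lengths=range(15, 91, 15),
            )
            grid.entries.assign(site_id=site.site_id, variable="tmin").to_csv(
                out / f"daywise_tmin_{site.site_id}.csv", index=False
            )
        if sea_rows:
            import pandas as pd

            pd.concat(sea_rows).to_csv(out / "sea.csv", index=False)

    stage("respond")(do_respond)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Fixture generation (synthetic two-site study)
# ---------------------------------------------------------------------------

def make_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    n_years: int = 92,
    start_year: int = 1930,
    high_frost_years: Sequence[int] = (1946, 1977, 1995, 2012, 2020),
    low_frost_years: Sequence[int] = (1977, 2012),
) -> dict[str, Any]:
    """Write a two-site synthetic study: climate CSVs, phenology CSV, RWLs.

    Frost events are injected 3 days after each year's model-predicted
    leaf-out (inside the vulnerability window) and drive both a tmin dip in
    the climate and a growth collapse in the frost-sensitive species, so the
    climate/phenology flags and the ring indicator have a common known
    truth.  Returns the file map plus the injected frost-year lists.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Any] = {"sites": {}}
    site_specs = {
        "high": dict(mean_annual_temp=4.7, elevation=1365.0, frost_years=list(high_frost_years)),
        "low": dict(mean_annual_temp=6.3, elevation=1085.0, frost_years=list(low_frost_years)),
    }
    last_year = start_year + n_years - 1
    for i, (name, spec) in enumerate(site_specs.items()):
        frost_years = [y for y in spec["frost_years"] if start_year <= y <= last_year]
        base = synthetic.SyntheticConfig(
            n_years=n_years,
            start_year=start_year,
            site_id=name,
            mean_annual_temp=spec["mean_annual_temp"],
            site_elevation=spec["elevation"],
            seed=seed + i,
        )
        # place each frost event inside the vulnerability window of its year
        climate0 = synthetic.generate_climate(base)
        events = []
        for y in frost_years:
            pred = phenology.predict_leafout(climate0, y, base.true_m1_params)
            if pred is None:
                continue
            # deep dip: leaf-out follows warm spells, so the realized tmin
            # shortly after it is warm-biased and a shallow dip may not
            # reach the frost threshold
            events.append((y, min(365, pred + 3), 12.0))
        cfg = synthetic.SyntheticConfig(
            **{**base.__dict__, "frost_events": events}
        )
        climate = synthetic.generate_climate(cfg)
        cpath = out / f"climate_{name}.csv"
        write_climate_csv(climate, cpath)

        sens = synthetic.generate_ring_series(
            climate, frost_years, cfg, "frost_sensitive", seed_offset=0
        )
        ref = synthetic.generate_ring_series(
            climate, frost_years, cfg, "reference", seed_offset=500
        )
        spath = out / f"rings_{name}_frost_sensitive.rwl"
        rpath = out / f"rings_{name}_reference.rwl"
        rings.write_rwl(sens, spath)
        rings.write_rwl(ref, rpath)
        files["sites"][name] = {
            "climate_csv": str(cpath),
            "rwl_frost_sensitive": str(spath),
            "rwl_reference": str(rpath),
            "frost_years": frost_years,
        }

    # phenology observations from both sites
    all_obs = []
    for i, name in enumerate(site_specs):
        climate = read_climate_csv(files["sites"][name]["climate_csv"])
        obs, skipped = synthetic.generate_phenology(
            climate, synthetic.TRUE_BEECH_PARAMS, pheno_noise_sd=7.5, seed=seed + 10 + i
        )
        all_obs.extend(obs)
        if skipped:
            log.info("site %s: %d non-emerging years in phenology fixture", name, len(skipped))
    ppath = out / "phenology.csv"
    write_phenology_csv(all_obs, ppath)
    files["phenology_csv"] = str(ppath)
    return files


def fixture_pipeline_config(files: Mapping[str, Any], out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """PipelineConfig pointing at a ``make_fixtures`` file map."""
    sites = [
        SiteConfig(
            site_id=name,
            climate_csv=spec["climate_csv"],
            rwl_frost_sensitive=spec["rwl_frost_sensitive"],
            rwl_reference=spec["rwl_reference"],
        )
        for name, spec in files["sites"].items()
    ]
    return PipelineConfig(
        sites=sites,
        phenology_csv=files["phenology_csv"],
        out_dir=str(out_dir),
        seed=seed,
    )
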