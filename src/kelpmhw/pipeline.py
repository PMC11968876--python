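"""End-to-end stage graph: simulate -> mhw -> ensemble -> exposure -> protection -> report.

One configuration drives everything. Each stage reads its inputs from the
output directory, writes its products into a temporary directory that is
promoted atomically on success, and is recorded (with content hashes) in a
run manifest, so a rerun with identical config and seed reproduces
identical hashes for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import ensemble as ens
from . import exposure as expo
from . import mhw as mhwmod
from . import protection as prot
from . import synthetic as synth
from .geo import read_geojson, write_geojson

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "mhw", "ensemble", "exposure", "protection", "report")
STAGE_DEPS = {
    "simulate": (),
    "mhw": ("simulate",),
    "ensemble": ("simulate",),
    "exposure": ("mhw", "ensemble"),
    "protection": ("simulate",),
    "report": ("exposure", "protection"),
}

#: Files each stage must leave behind (relative to the output directory).
STAGE_OUTPUTS = {
    "simulate": ["inputs/observed_sst.nc", "inputs/kelp.geojson", "inputs/mpas.geojson",
                 "inputs/model_manifest.csv"],
    "mhw": ["mhw/observed_events.csv", "mhw/observed_annual.csv"],
    "ensemble": ["ensemble/model_annual.csv"],
    "exposure": ["exposure/exposure_summary.csv", "exposure/ratios.csv",
                 "exposure/latitudinal.csv"],
    "protection": ["protection/protection_records.csv",
                   "protection/protection_summary.csv"],
    "report": ["threat_vs_protection.csv", "run_manifest.json"],
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (fail-fast validated)."""

    seed: int = 0
    out_dir: str = "runs/default"
    # synthetic world
    bbox: tuple[float, float, float, float] = (-122.5, 33.0, -119.5, 37.0)
    n_kelp_pixels: int = 80
    n_mpas: int = 8
    n_countries: int = 2
    n_ecoregions: int = 4
    mean_sst: float = 15.0
    seasonal_amplitude: float = 4.0
    ar1_phi: float = 0.7
    noise_sd: float = 0.5
    # ensemble
    n_models: int = 3
    scenarios: tuple[str, ...] = ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5")
    scenario_trends: dict = field(default_factory=lambda: dict(synth.DEFAULT_SCENARIO_TRENDS))
    model_grid_spacing: float = 1.0
    # years / periods
    hist_years: tuple[int, int] = (1983, 2014)
    scen_years: tuple[int, int] = (2015, 2100)
    observed_years: tuple[int, int] = (1983, 2020)
    periods: dict = field(default_factory=lambda: dict(expo.DEFAULT_PERIODS))
    # MHW parameters
    baseline: tuple[int, int] = mhwmod.DEFAULT_BASELINE
    window_half_width: int = mhwmod.DEFAULT_WINDOW_HALF_WIDTH
    smooth_window: int = mhwmod.DEFAULT_SMOOTH_WINDOW
    min_duration: int = mhwmod.DEFAULT_MIN_DURATION
    max_gap: int = mhwmod.DEFAULT_MAX_GAP
    # bias correction / IDW
    bias_mode: str = "monthly"
    reference_period: tuple[int, int] = ens.DEFAULT_REFERENCE_PERIOD
    idw_power: float = 2.0
    # protection
    targets: tuple[float, ...] = prot.DEFAULT_TARGETS
    effective_categories: tuple[str, ...] = ("high",)
    threat_scenario: str = "SSP2-4.5"
    threat_period: str = "mid"
    sequential: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(synth.SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        if not (self.hist_years[0] <= self.baseline[0] <= self.baseline[1] <= self.hist_years[1]):
            raise ValueError("climatology baseline must lie within the historical years")
        for name, (a, b) in self.periods.items():
            if b < a:
                raise ValueError(f"period {name} has decreasing years")
        if self.bias_mode not in ("monthly", "doy", "annual"):
            raise ValueError(f"unknown bias-correction mode {self.bias_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("bbox", "hist_years", "scen_years", "observed_years", "baseline",
                    "reference_period", "scenarios", "targets", "effective_categories"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "periods" in raw:
            raw["periods"] = {k: tuple(v) for k, v in raw["periods"].items()}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cell_id(lat: float, lon: float) -> str:
    return f"c{lat:+08.3f}{lon:+09.3f}"


class _StageWriter:
    """Write a stage's outputs to a temp dir, promote atomically on success."""

    def __init__(self, out_dir: Path, subdir: str):
        self.final = out_dir / subdir if subdir else out_dir
        self.tmp = Path(tempfile.mkdtemp(prefix=".stage-", dir=out_dir))

    def path(self, name: str) -> Path:
        p = self.tmp / Path(name).name
        return p

    def promote(self) -> None:
        self.final.mkdir(parents=True, exist_ok=True)
        for p in sorted(self.tmp.iterdir()):
            shutil.move(str(p), str(self.final / p.name))
        self.tmp.rmdir()

    def abort(self) -> None:
        shutil.rmtree(self.tmp, ignore_errors=True)


def _require(out_dir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        for rel in STAGE_OUTPUTS[dep]:
            if not (out_dir / rel).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs {rel} — run stage '{dep}' first"
                )


# --- stages ---------------------------------------------------------------


def _kelp_cells(config: RunConfig, kelp_records: list[dict]) -> pd.DataFrame:
    """Analysis-grid (0.25 deg) cells holding kelp, with region attribution."""
    grid = ens.AnalysisGrid.quarter_degree(
        (config.bbox[1], config.bbox[3]), (config.bbox[0], config.bbox[2])
    )
    rows = []
    for rec in kelp_records:
        c = rec["geometry"].centroid
        i = int(np.clip(np.searchsorted(grid.lat + 0.125, c.y), 0, grid.lat.size - 1))
        j = int(np.clip(np.searchsorted(grid.lon + 0.125, c.x), 0, grid.lon.size - 1))
        rows.append(
            {
                "cell_id": _cell_id(grid.lat[i], grid.lon[j]),
                "lat": grid.lat[i],
                "lon": grid.lon[j],
                "ecoregion": rec["ecoregion"],
                "realm": rec["realm"],
                "country": rec["country"],
            }
        )
    df = pd.DataFrame(rows)
    # one row per cell; region by majority of member pixels
    agg = (
        df.groupby("cell_id")
        .agg(
            lat=("lat", "first"),
            lon=("lon", "first"),
            ecoregion=("ecoregion", lambda s: s.mode().iloc[0]),
            realm=("realm", lambda s: s.mode().iloc[0]),
            country=("country", lambda s: s.mode().iloc[0]),
        )
        .reset_index()
    )
    return agg


def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    """Generate all synthetic inputs: vector layers, observed SST, model runs."""
    w = _StageWriter(out_dir, "inputs")
    try:
        geom_cfg = synth.GeometrySimConfig(
            bbox=config.bbox,
            n_kelp_pixels=config.n_kelp_pixels,
            n_mpas=config.n_mpas,
            n_countries=config.n_countries,
            n_ecoregions=config.n_ecoregions,
            seed=config.seed,
        )
        layers = synth.simulate_geometries(geom_cfg)
        write_geojson(
            [
                {
                    "feature_id": f.feature_id,
                    "area_ha": f.area_ha,
                    "country": f.country,
                    "realm": f.realm,
                    "ecoregion": f.ecoregion,
                    "source": f.source,
                    "geometry": f.geometry,
                }
                for f in layers["kelp"]
            ],
            w.path("kelp.geojson"),
        )
        write_geojson(
            [
                {
                    "mpa_id": m.mpa_id,
                    "lfp_score": m.lfp_score,
                    "category": m.category,
                    "country": m.country,
                    "geometry": m.geometry,
                }
                for m in layers["mpas"]
            ],
            w.path("mpas.geojson"),
        )
        part = layers["regions"]
        region_records = []
        for level, mapping in (
            ("country", part.countries),
            ("realm", part.realms),
            ("ecoregion", part.ecoregions),
        ):
            for name, poly in mapping.items():
                region_records.append({"region_id": name, "level": level, "geometry": poly})
        write_geojson(region_records, w.path("regions.geojson"))
        write_geojson([{"name": "coastline", "geometry": layers["coastline"]}],
                      w.path("coastline.geojson"))
        json_links = {
            "realm_of_country": part.realm_of_country,
            "country_of_ecoregion": part.country_of_ecoregion,
        }
        w.path("region_links.json").write_text(json.dumps(json_links))

        # observed daily SST per kelp-bearing analysis cell
        kelp_records = [
            {
                "geometry": f.geometry,
                "ecoregion": f.ecoregion,
                "realm": f.realm,
                "country": f.country,
            }
            for f in layers["kelp"]
        ]
        cells = _kelp_cells(config, kelp_records)
        cells.to_csv(w.path("kelp_cells.csv"), index=False)

        y0, y1 = config.observed_years
        dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
        obs = np.empty((len(dates), len(cells)))
        for k, row in cells.reset_index().iterrows():
            cfg = synth.SSTSimConfig(
                mean_sst=config.mean_sst - 0.25 * (abs(row["lat"]) - abs(cells["lat"].mean())),
                seasonal_amplitude=config.seasonal_amplitude,
                trend=config.scenario_trends.get("historical", 0.01),
                ar1_phi=config.ar1_phi,
                noise_sd=config.noise_sd,
                seed=config.seed * 7919 + k,
            )
            obs[:, k] = synth.simulate_sst_series(cfg, y0, y1).sst
        ds = xr.Dataset(
            {"sst": (("time", "cell"), obs)},
            coords={
                "time": dates,
                "cell": cells["cell_id"].to_numpy(),
                "lat": ("cell", cells["lat"].to_numpy()),
                "lon": ("cell", cells["lon"].to_numpy()),
            },
            attrs={"units": "degC"},
        )
        ds.to_netcdf(w.path("observed_sst.nc"), engine="scipy")

        # gridded model ensemble at coarse spacing, with a land mask east of
        # the coastline so some kelp cells need IDW filling downstream
        lon0, lat0, lon1, lat1 = config.bbox
        sp = config.model_grid_spacing
        mlat = np.arange(lat0 + sp / 2, lat1, sp)
        mlon = np.arange(lon0 + sp / 2, lon1, sp)
        grid = xr.Dataset(coords={"lat": mlat, "lon": mlon})
        ens_cfg = synth.EnsembleSimConfig(
            base=synth.SSTSimConfig(
                mean_sst=config.mean_sst,
                seasonal_amplitude=config.seasonal_amplitude,
                ar1_phi=config.ar1_phi,
                noise_sd=config.noise_sd,
            ),
            n_models=config.n_models,
            scenario_trends=dict(config.scenario_trends),
            seed=config.seed,
        )
        runs = synth.simulate_ensemble(
            ens_cfg, grid, hist_years=config.hist_years,
            scen_years=config.scen_years, scenarios=config.scenarios,
        )
        coast = layers["coastline"]
        coast_lon_at = lambda la: np.interp(
            la, [p[1] for p in coast.coords], [p[0] for p in coast.coords]
        )
        # mask model cells clearly inland (centre more than half a model
        # cell east of the coastline) so some kelp cells lack model data
        # and exercise the IDW fill, as with real coarse ESM masks
        land = np.zeros((mlat.size, mlon.size), bool)
        for i, la in enumerate(mlat):
            land[i] = mlon > coast_lon_at(la) + 0.5 * sp
        manifest_rows = []
        for run in runs:
            masked = run.sst.where(~xr.DataArray(land, dims=("lat", "lon"),
                                                 coords={"lat": mlat, "lon": mlon}))
            fname = f"{run.model_id}_{run.scenario.replace('.', 'p')}.nc"
            masked.to_dataset(name="sst").to_netcdf(w.path(fname), engine="scipy")
            manifest_rows.append(
                {"model_id": run.model_id, "scenario": run.scenario,
                 "path": f"inputs/{fname}", "calendar": "standard"}
            )
        pd.DataFrame(manifest_rows).to_csv(w.path("model_manifest.csv"), index=False)
        w.promote()
    except Exception:
        w.abort()
        raise


def _observed_series(out_dir: Path) -> list[mhwmod.DailySSTSeries]:
    ds = xr.open_dataset(out_dir / "inputs" / "observed_sst.nc", engine="scipy")
    dates = pd.DatetimeIndex(ds["time"].values)
    return [
        mhwmod.DailySSTSeries(str(cell), dates, ds["sst"].sel(cell=cell).values)
        for cell in ds["cell"].values
    ]


def stage_mhw(config: RunConfig, out_dir: Path) -> None:
    """Observed branch: climatology, events, annual exposures per kelp cell."""
    _require(out_dir, "mhw")
    w = _StageWriter(out_dir, "mhw")
    try:
        events_frames, annual_frames = [], []
        for series in _observed_series(out_dir):
            clim = mhwmod.compute_climatology(
                series, config.baseline, config.window_half_width, config.smooth_window
            )
            events = mhwmod.detect_events(series, clim, config.min_duration, config.max_gap)
            events_frames.append(mhwmod.events_to_frame(events))
            annual_frames.append(
                mhwmod.annual_exposure_series(
                    series, clim, config.min_duration, config.max_gap, source="observed"
                )
            )
        pd.concat(events_frames, ignore_index=True).to_csv(
            w.path("observed_events.csv"), index=False
        )
        annual = pd.concat(annual_frames, ignore_index=True)
        annual["model_id"] = "observed"
        annual.to_csv(w.path("observed_annual.csv"), index=False)
        w.promote()
    except Exception:
        w.abort()
        raise


def stage_ensemble(config: RunConfig, out_dir: Path) -> None:
    """Model branch: regrid, bias-correct, fill, detect, annual exposures."""
    _require(out_dir, "ensemble")
    w = _StageWriter(out_dir, "ensemble")
    try:
        manifest = pd.read_csv(out_dir / "inputs" / "model_manifest.csv")
        cells = pd.read_csv(out_dir / "inputs" / "kelp_cells.csv")
        grid = ens.AnalysisGrid.quarter_degree(
            (config.bbox[1], config.bbox[3]), (config.bbox[0], config.bbox[2])
        )

        def load(model_id, scenario):
            row = manifest[(manifest.model_id == model_id) & (manifest.scenario == scenario)]
            ds = xr.open_dataset(out_dir / row["path"].iloc[0], engine="scipy")
            return ens.ESMRunData(model_id, scenario, ds["sst"])

        models = sorted(manifest["model_id"].unique())
        # regrid once per model/run, then bias-correct on the analysis grid
        hist_regr = {
            m: ens.ESMRunData(m, "historical",
                              ens.bilinear_regrid(load(m, "historical").sst, grid))
            for m in models
        }
        ens_clim = ens.ensemble_mean_climatology(
            list(hist_regr.values()), config.reference_period
        )

        targets = list(zip(cells["lat"], cells["lon"]))
        annual_frames = []
        for m in models:
            hist = hist_regr[m]
            hist_corr = ens.delta_bias_correct(
                hist, ens_clim, config.reference_period, mode=config.bias_mode
            )
            for scen in config.scenarios:
                run = load(m, scen)
                regr = ens.ESMRunData(m, scen, ens.bilinear_regrid(run.sst, grid))
                corr = ens.delta_bias_correct(
                    regr, ens_clim, config.reference_period,
                    model_historical=hist, mode=config.bias_mode,
                )
                # continuous 1983-2100 series per kelp cell: model-historical
                # baseline + corrected scenario, filled where the model grid
                # has no water
                full = xr.concat([hist_corr.sst, corr.sst], dim="time")
                # radius spans two *model* grid cells: that is the scale on
                # which the coarse source can genuinely lack ocean data
                filled, unfillable = ens.idw_fill(
                    full, targets, power=config.idw_power,
                    grid_spacing_deg=config.model_grid_spacing,
                )
                for (tlat, tlon), values in filled.items():
                    cid = cells.loc[
                        (cells.lat == tlat) & (cells.lon == tlon), "cell_id"
                    ].iloc[0]
                    series = mhwmod.DailySSTSeries(
                        cid, pd.DatetimeIndex(full["time"].values), values
                    )
                    clim = mhwmod.compute_climatology(
                        series, config.baseline, config.window_half_width,
                        config.smooth_window,
                    )
                    af = mhwmod.annual_exposure_series(
                        series, clim, config.min_duration, config.max_gap, source="model"
                    )
                    af["model_id"] = m
                    af["scenario"] = scen
                    annual_frames.append(af)
                if unfillable:
                    logger.warning("%s %s: %d kelp cells unfillable", m, scen, len(unfillable))
        pd.concat(annual_frames, ignore_index=True).to_csv(
            w.path("model_annual.csv"), index=False
        )
        w.promote()
    except Exception:
        w.abort()
        raise


def stage_exposure(config: RunConfig, out_dir: Path) -> None:
    """Aggregate annual exposures into summaries, ratios and profiles."""
    _require(out_dir, "exposure")
    w = _StageWriter(out_dir, "exposure")
    try:
        cells = pd.read_csv(out_dir / "inputs" / "kelp_cells.csv").set_index("cell_id")
        observed = pd.read_csv(out_dir / "mhw" / "observed_annual.csv")
        model = pd.read_csv(out_dir / "ensemble" / "model_annual.csv")

        contemporary = expo.pixel_period_table(
            observed, expo.PeriodSpec("contemporary", tuple(config.periods["contemporary"])),
            expected_source="observed",
        )
        projected = {}
        for scen in config.scenarios:
            sub = model[model["scenario"] == scen]
            for pname in ("near", "mid", "long"):
                projected[(scen, pname)] = expo.pixel_period_table(
                    sub, expo.PeriodSpec(pname, tuple(config.periods[pname])),
                    expected_source="model",
                )
        # like-for-like pixel populations: a cell unfillable in the model
        # branch (no model data in reach) is excluded from both branches
        common = set(contemporary["cell_id"])
        for table in projected.values():
            common &= set(table["cell_id"])
        contemporary = contemporary[contemporary["cell_id"].isin(common)]
        projected = {
            k: t[t["cell_id"].isin(common)] for k, t in projected.items()
        }

        summaries, latitudinal = [], []
        def summarise(table, scenario, period):
            t = table.join(cells, on="cell_id")
            for level in ("realm", "ecoregion"):
                summaries.append(
                    expo.regional_summary(
                        t.rename(columns={level: "region_id"}), scenario, period,
                        region_level=level,
                    )
                )
            t["region_id"] = "global"
            summaries.append(
                expo.regional_summary(t, scenario, period, region_level="global")
            )
            lp = expo.latitudinal_profile(t)
            lp["scenario"], lp["period"] = scenario, period
            latitudinal.append(lp)

        summarise(contemporary, "observed", "contemporary")
        for (scen, pname), table in sorted(projected.items()):
            summarise(table, scen, pname)

        pd.concat(summaries, ignore_index=True).to_csv(
            w.path("exposure_summary.csv"), index=False
        )
        expo.scenario_period_ratios(projected, contemporary).to_csv(
            w.path("ratios.csv"), index=False
        )
        pd.concat(latitudinal, ignore_index=True).to_csv(
            w.path("latitudinal.csv"), index=False
        )
        w.promote()
    except Exception:
        w.abort()
        raise


def _load_vector_layers(out_dir: Path):
    kelp = [
        prot.KelpFeature(
            feature_id=r["feature_id"], geometry=r["geometry"], area_ha=r["area_ha"],
            country=r["country"], realm=r["realm"], ecoregion=r["ecoregion"],
            source=r.get("source", "landsat"),
        )
        for r in read_geojson(out_dir / "inputs" / "kelp.geojson")
    ]
    mpas = [
        prot.MPAFeature(
            mpa_id=r["mpa_id"], geometry=r["geometry"], lfp_score=r["lfp_score"],
            category=r["category"], country=r["country"],
        )
        for r in read_geojson(out_dir / "inputs" / "mpas.geojson")
    ]
    return kelp, mpas


def stage_protection(config: RunConfig, out_dir: Path) -> None:
    """Intersect kelp with MPAs and account area by protection category."""
    _require(out_dir, "protection")
    w = _StageWriter(out_dir, "protection")
    try:
        kelp, mpas = _load_vector_layers(out_dir)
        records = prot.hierarchical_intersection(
            kelp, mpas, parallel=not config.sequential
        )
        pd.DataFrame(
            [
                {"feature_id": r.feature_id, "mpa_id": r.mpa_id,
                 "category": r.category, "area_ha": r.area_ha}
                for r in records
            ]
        ).to_csv(w.path("protection_records.csv"), index=False)
        areas = prot.feature_category_areas(records, kelp)
        summary = prot.protection_summary(
            areas, targets=tuple(config.targets),
            effective_categories=tuple(config.effective_categories),
        )
        summary.to_csv(w.path("protection_summary.csv"), index=False)
        w.promote()
    except Exception:
        w.abort()
        raise


def stage_report(config: RunConfig, out_dir: Path) -> None:
    """Join threat and protection; write the run manifest with hashes."""
    _require(out_dir, "report")
    w = _StageWriter(out_dir, "")
    try:
        exposure = pd.read_csv(out_dir / "exposure" / "exposure_summary.csv")
        protection = pd.read_csv(out_dir / "protection" / "protection_summary.csv")
        joined = prot.threat_vs_protection(
            exposure, protection, scenario=config.threat_scenario,
            period=config.threat_period,
        )
        joined.to_csv(w.path("threat_vs_protection.csv"), index=False)

        files = {}
        for stage, rels in STAGE_OUTPUTS.items():
            if stage == "report":
                continue
            for rel in rels:
                p = out_dir / rel
                if p.exists():
                    files[rel] = _sha256(p)
        files["threat_vs_protection.csv"] = _sha256(w.path("threat_vs_protection.csv"))
        manifest = {
            "config_schema": 1,
            "seed": config.seed,
            "config": {k: _jsonable(v) for k, v in vars(config).items()},
            "files": files,
        }
        w.path("run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        w.promote()
    except Exception:
        w.abort()
        raise


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "mhw": stage_mhw,
    "ensemble": stage_ensemble,
    "exposure": stage_exposure,
    "protection": stage_protection,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Run the requested stages in dependency order; returns the output dir."""
    requested = set(stages) if stages else set(STAGE_ORDER)
    unknown = requested - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGE_ORDER:
        if stage in requested:
            logger.info("running stage %s", stage)
            STAGE_FUNCS[stage](config, out_dir)
    return out_dir
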