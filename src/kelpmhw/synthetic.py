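"""Synthetic inputs for the kelp-exposure pipeline.

Generates every input the analysis consumes, with the statistical structure
the method assumes, so the full pipeline is testable without downloads:

* daily SST series/grids — sinusoidal seasonal cycle + linear warming trend
  (piecewise, with a scenario pivot year) + AR(1) noise, with optional
  injected heatwave blocks of known timing and anomaly;
* a multi-model ensemble — a shared base signal plus per-model additive
  biases, per-model noise realisations, and scenario-dependent trends that
  continue the historical run at the pivot year;
* vector layers — 30 m kelp "pixels" strung along a synthetic coastline,
  MPA polygons carrying Level-of-Fishing-Protection (LFP) scores 1-5, and a
  nested country/realm/ecoregion partition of the domain.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter
from shapely.geometry import LineString, Polygon, box

from .mhw import DailySSTSeries

SCENARIOS = ("historical", "SSP1-2.6", "SSP2-4.5", "SSP5-8.5")

#: Default scenario warming trends (degC / year). The magnitudes follow the
#: end-of-century warming levels the three SSP pathways approximate
#: (~1.8 / 2.7 / 4.4 degC by 2100) spread over 2015-2100, with a modest
#: historical trend.
DEFAULT_SCENARIO_TRENDS = {
    "historical": 0.010,
    "SSP1-2.6": 0.012,
    "SSP2-4.5": 0.021,
    "SSP5-8.5": 0.039,
}

DEFAULT_PIVOT_YEAR = 2015  # historical runs end 2014; scenarios start 2015


@dataclass
class SSTSimConfig:
    """Parameters of one cell's daily SST process."""

    mean_sst: float = 15.0
    seasonal_amplitude: float = 4.0
    trend: float = 0.0  # degC per year before the pivot
    post_pivot_trend: float | None = None  # degC per year after the pivot
    pivot_year: int = DEFAULT_PIVOT_YEAR
    ar1_phi: float = 0.7
    noise_sd: float = 0.5
    seasonal_peak_doy: int = 228  # mid-August peak, northern-hemisphere-like
    injected_events: list[tuple[str, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for _, duration, _ in self.injected_events:
            if duration < 1:
                raise ValueError("injected event duration must be >= 1 day")


@dataclass
class EnsembleSimConfig:
    """A CMIP6-style multi-model ensemble around a shared base signal."""

    base: SSTSimConfig = field(default_factory=SSTSimConfig)
    n_models: int = 11
    per_model_bias: list[float] | None = None
    scenario_trends: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_TRENDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("an ensemble needs at least 2 models")
        unknown = set(self.scenario_trends) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario ids: {sorted(unknown)}")
        if self.per_model_bias is None:
            # reproducible spread of model biases, mean ~0, sd 0.5 degC
            rng = np.random.default_rng(self.seed + 101)
            self.per_model_bias = list(rng.normal(0.0, 0.5, self.n_models))
        if len(self.per_model_bias) != self.n_models:
            raise ValueError("per_model_bias length must equal n_models")


@dataclass
class GeometrySimConfig:
    """Synthetic coastal geometry: kelp pixels, MPAs, nested regions."""

    bbox: tuple[float, float, float, float] = (-121.0, 33.0, -119.0, 38.0)
    n_kelp_pixels: int = 100
    kelp_pixel_size: float = 30.0  # metres, Landsat-like footprint
    n_mpas: int = 8
    lfp_weights: tuple[float, ...] = (0.25, 0.2, 0.2, 0.15, 0.2)
    n_countries: int = 2
    n_ecoregions: int = 4
    n_realms: int = 1
    mpa_size_km: tuple[float, float] = (2.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.bbox
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("degenerate bounding box")
        if min(self.n_kelp_pixels, self.n_mpas, self.n_countries, self.n_ecoregions) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_countries > 0 and self.n_ecoregions % self.n_countries:
            raise ValueError("n_ecoregions must be a multiple of n_countries")
        if abs(sum(self.lfp_weights) - 1.0) > 1e-9:
            raise ValueError("lfp_weights must sum to 1")


def _seasonal_trend_signal(config: SSTSimConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    t_years = (dates - dates[0]).days.to_numpy() / 365.25
    doy = np.asarray(dates.dayofyear)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_doy) / 365.25
    )
    post = config.trend if config.post_pivot_trend is None else config.post_pivot_trend
    pivot = pd.Timestamp(f"{config.pivot_year}-01-01")
    t_pivot = max((pivot - dates[0]).days, 0) / 365.25
    before = np.minimum(t_years, t_pivot)
    after = np.maximum(t_years - t_pivot, 0.0)
    return config.mean_sst + seasonal + config.trend * before + post * after


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi**2)
    eps = rng.normal(0.0, innov_sd, n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_sst_series(
    config: SSTSimConfig,
    start_year: int,
    end_year: int,
    cell_id: str = "cell",
) -> DailySSTSeries:
    """One cell's daily SST: seasonal cycle + trend + AR(1) noise + events.

    Injected events add exactly their stated anomaly on their stated days on
    top of the seasonal + trend + noise signal. Events outside the simulated
    date range are rejected.
    """
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    sst = _seasonal_trend_signal(config, dates)
    rng = np.random.default_rng(config.seed)
    sst = sst + _ar1_noise(rng, len(dates), config.ar1_phi, config.noise_sd)
    for start, duration, anomaly in config.injected_events:
        t0 = pd.Timestamp(start)
        t1 = t0 + pd.Timedelta(days=duration - 1)
        if t0 < dates[0] or t1 > dates[-1]:
            raise ValueError(
                f"injected event {start} (+{duration} d) lies outside "
                f"{dates[0].date()}..{dates[-1].date()}"
            )
        a = dates.searchsorted(t0)
        sst[a : a + duration] += anomaly
    return DailySSTSeries(cell_id, dates, sst)


def simulate_ensemble(
    config: EnsembleSimConfig,
    grid: xr.Dataset,
    hist_years: tuple[int, int] = (1983, 2014),
    scen_years: tuple[int, int] = (2015, 2100),
    scenarios: tuple[str, ...] = ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5"),
) -> list["ESMRunData"]:
    """Gridded daily SST runs for each model and scenario.

    Every model shares the base seasonal + historical-trend signal and a
    deterministic spatial pattern, then adds its own constant bias and its
    own AR(1) noise realisation. A model's scenario run continues its
    historical run at the pivot year with the scenario's trend, reusing the
    model seed so the pre-pivot segment is bit-identical to the historical
    run.
    """
    from .ensemble import ESMRunData  # local import to avoid a cycle

    if "lat" not in grid or "lon" not in grid:
        raise ValueError("grid must provide lat and lon coordinates")
    if grid["lat"].size == 0 or grid["lon"].size == 0:
        raise ValueError("grid is empty")
    unknown = [s for s in scenarios if s not in SCENARIOS]
    if unknown:
        raise ValueError(f"unknown scenario ids: {unknown}")

    lat = np.asarray(grid["lat"], dtype=float)
    lon = np.asarray(grid["lon"], dtype=float)
    spatial = (
        -0.25 * (np.abs(lat)[:, None] - np.abs(lat).mean())
        + 0.02 * (lon[None, :] - lon.mean())
    )  # (lat, lon)

    hist_trend = config.scenario_trends.get("historical", config.base.trend)
    runs: list[ESMRunData] = []
    full_dates = pd.date_range(f"{hist_years[0]}-01-01", f"{scen_years[1]}-12-31", freq="D")
    hist_mask = np.asarray(full_dates.year <= hist_years[1])
    scen_mask = np.asarray(full_dates.year >= scen_years[0])

    for m in range(config.n_models):
        model_id = f"model{m:02d}"
        bias = float(config.per_model_bias[m])
        model_rng_seed = config.seed * 1000 + m
        for scen in ("historical",) + tuple(scenarios):
            scen_trend = config.scenario_trends.get(scen, hist_trend)
            cfg = SSTSimConfig(
                mean_sst=config.base.mean_sst,
                seasonal_amplitude=config.base.seasonal_amplitude,
                trend=hist_trend,
                post_pivot_trend=scen_trend,
                pivot_year=scen_years[0],
                ar1_phi=config.base.ar1_phi,
                noise_sd=0.0,  # noise added per grid cell below
                seasonal_peak_doy=config.base.seasonal_peak_doy,
                seed=model_rng_seed,
            )
            base = _seasonal_trend_signal(cfg, full_dates)
            mask = hist_mask if scen == "historical" else scen_mask
            dates = full_dates[mask]
            sig = base[mask]
            # the noise realisation is generated over the full span from the
            # model's seed, then sliced, so a scenario run continues its
            # historical run's noise path exactly at the pivot
            rng = np.random.default_rng(model_rng_seed)
            noise = np.empty((len(full_dates), lat.size, lon.size))
            for i in range(lat.size):
                for j in range(lon.size):
                    noise[:, i, j] = _ar1_noise(
                        rng, len(full_dates), config.base.ar1_phi, config.base.noise_sd
                    )
            data = sig[:, None, None] + spatial[None, :, :] + bias + noise[mask]
            da = xr.DataArray(
                data,
                dims=("time", "lat", "lon"),
                coords={"time": dates, "lat": lat, "lon": lon},
                name="sst",
                attrs={"units": "degC"},
            )
            runs.append(ESMRunData(model_id=model_id, scenario=scen, sst=da))
    return runs


# --- geometries -----------------------------------------------------------

M_PER_DEG_LAT = 111_320.0


def _deg_lon(metres: float, lat: float) -> float:
    return metres / (M_PER_DEG_LAT * np.cos(np.radians(lat)))


def simulate_geometries(config: GeometrySimConfig) -> dict:
    """Kelp pixels, MPAs and a nested region partition for one domain.

    The coastline is a wiggly meridional polyline; kelp pixels are
    ``kelp_pixel_size`` squares placed 100-2000 m offshore of it; MPAs are
    coastal rectangles (2-15 km) that may overlap one another and extend
    beyond kelp. Countries are latitudinal slabs of the bounding box,
    ecoregions subdivide countries, and realms group countries, so every
    kelp pixel falls in exactly one region at each level.

    Returns a dict with keys ``kelp`` (list of KelpFeature), ``mpas`` (list
    of MPAFeature), ``regions`` (RegionPartition) and ``coastline``
    (shapely LineString).
    """
    from .protection import KelpFeature, MPAFeature, RegionPartition, categorize_lfp
    from .geo import spherical_area_ha

    rng = np.random.default_rng(config.seed)
    lon0, lat0, lon1, lat1 = config.bbox

    # coastline: north-south polyline through the middle with sinusoidal wiggle
    lat_pts = np.linspace(lat0, lat1, 200)
    mid = 0.5 * (lon0 + lon1)
    wiggle = 0.15 * (lon1 - lon0) * np.sin(np.linspace(0, 6 * np.pi, lat_pts.size))
    coast_lon = mid + wiggle
    coastline = LineString(np.column_stack([coast_lon, lat_pts]))

    # nested partition: countries = latitudinal slabs; ecoregions subdivide
    n_c = max(config.n_countries, 1)
    n_e = max(config.n_ecoregions, n_c)
    country_edges = np.linspace(lat0, lat1, n_c + 1)
    eco_per_country = n_e // n_c
    countries, realms, ecoregions = {}, {}, {}
    realm_of_country, country_of_eco = {}, {}
    realm_slabs: dict[str, list] = {}
    for i in range(n_c):
        cname = f"country{i}"
        cpoly = box(lon0, country_edges[i], lon1, country_edges[i + 1])
        countries[cname] = cpoly
        rname = f"realm{i % max(config.n_realms, 1)}"
        realm_of_country[cname] = rname
        realm_slabs.setdefault(rname, []).append(cpoly)
        eco_edges = np.linspace(country_edges[i], country_edges[i + 1], eco_per_country + 1)
        for j in range(eco_per_country):
            ename = f"eco{i * eco_per_country + j}"
            ecoregions[ename] = box(lon0, eco_edges[j], lon1, eco_edges[j + 1])
            country_of_eco[ename] = cname
    from shapely.ops import unary_union

    realms = {r: unary_union(polys) for r, polys in realm_slabs.items()}

    def locate(lat: float, mapping: dict) -> str:
        from shapely.geometry import Point

        p = Point(mid, lat)
        for name, poly in mapping.items():
            if poly.covers(p):
                return name
        return next(iter(mapping))

    kelp = []
    lat_kelp = rng.uniform(lat0 + 0.02, lat1 - 0.02, config.n_kelp_pixels)
    offshore = rng.uniform(100.0, 2000.0, config.n_kelp_pixels)
    for k in range(config.n_kelp_pixels):
        la = lat_kelp[k]
        clon = float(np.interp(la, lat_pts, coast_lon))
        lo = clon - _deg_lon(offshore[k], la)  # offshore = west of coast
        half_lon = _deg_lon(config.kelp_pixel_size / 2, la)
        half_lat = (config.kelp_pixel_size / 2) / M_PER_DEG_LAT
        poly = box(lo - half_lon, la - half_lat, lo + half_lon, la + half_lat)
        eco = locate(la, ecoregions)
        country = country_of_eco[eco]
        kelp.append(
            KelpFeature(
                feature_id=f"kelp{k:05d}",
                geometry=poly,
                area_ha=spherical_area_ha(poly),
                country=country,
                realm=realm_of_country[country],
                ecoregion=eco,
            )
        )

    mpas = []
    lat_mpa = rng.uniform(lat0, lat1, config.n_mpas)
    scores = rng.choice(np.arange(1, 6), size=config.n_mpas, p=config.lfp_weights)
    for m in range(config.n_mpas):
        la = float(lat_mpa[m])
        clon = float(np.interp(la, lat_pts, coast_lon))
        w_km, h_km = rng.uniform(*config.mpa_size_km, 2)
        w = _deg_lon(w_km * 1000, la)
        h = h_km * 1000 / M_PER_DEG_LAT
        # centred just offshore so MPAs straddle the kelp band
        cx = clon - _deg_lon(1000.0, la)
        poly = box(cx - w / 2, la - h / 2, cx + w / 2, la + h / 2)
        score = int(scores[m])
        mpas.append(
            MPAFeature(
                mpa_id=f"mpa{m:03d}",
                geometry=poly,
                lfp_score=score,
                category=categorize_lfp(score),
                country=locate(la, countries),
            )
        )

    partition = RegionPartition(
        countries=countries,
        realms=realms,
        ecoregions=ecoregions,
        realm_of_country=realm_of_country,
        country_of_ecoregion=country_of_eco,
    )
    return {"kelp": kelp, "mpas": mpas, "regions": partition, "coastline": coastline}
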