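"""Preparation of Earth-System-Model SST for heatwave analysis.

Three standard steps sit between raw model output and event detection:

* **delta bias correction** — an additive, per-calendar-month adjustment
  aligning each model's reference-period climatology with the historical
  ensemble-mean climatology; the same delta is applied to a model's
  scenario runs so projections blend smoothly onto the end of the
  historical run;
* **bilinear regridding** to the 0.25-degree analysis grid;
* **inverse-distance-weighted (IDW) fill** of kelp-bearing analysis cells
  that have no model value (coarse model land/sea masks), using
  great-circle distances to valued neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geo import haversine_m

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_PERIOD = (1983, 2014)
DEFAULT_IDW_POWER = 2.0

VALID_SCENARIOS = ("historical", "SSP1-2.6", "SSP2-4.5", "SSP5-8.5")


@dataclass
class ESMRunData:
    """One model's daily SST under one forcing scenario."""

    model_id: str
    scenario: str
    sst: xr.DataArray  # dims (time, lat, lon), degC

    def __post_init__(self) -> None:
        if self.scenario not in VALID_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if tuple(self.sst.dims) != ("time", "lat", "lon"):
            raise ValueError("sst must have dims (time, lat, lon)")


@dataclass
class AnalysisGrid:
    """Regular lat/lon analysis grid with a kelp-cell mask."""

    lat: np.ndarray  # cell-centre latitudes
    lon: np.ndarray  # cell-centre longitudes, in (-180, 180]
    kelp_mask: np.ndarray | None = None  # bool (lat, lon)

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        for name, c in (("lat", self.lat), ("lon", self.lon)):
            if c.size > 1 and not np.allclose(np.diff(c), np.diff(c)[0]):
                raise ValueError(f"{name} centres must be regularly spaced")
        if self.kelp_mask is not None:
            self.kelp_mask = np.asarray(self.kelp_mask, dtype=bool)
            if self.kelp_mask.shape != (self.lat.size, self.lon.size):
                raise ValueError("kelp_mask shape must match (lat, lon)")

    @property
    def spacing(self) -> float:
        return float(np.diff(self.lat)[0]) if self.lat.size > 1 else 0.25

    @classmethod
    def quarter_degree(cls, lat_bounds, lon_bounds, kelp_mask=None) -> "AnalysisGrid":
        lat = np.arange(lat_bounds[0] + 0.125, lat_bounds[1], 0.25)
        lon = np.arange(lon_bounds[0] + 0.125, lon_bounds[1], 0.25)
        return cls(lat, lon, kelp_mask)


def monthly_climatology(
    sst: xr.DataArray, reference_period: tuple[int, int]
) -> xr.DataArray:
    """Per-cell monthly mean over the reference years; dims (month, lat, lon)."""
    y0, y1 = reference_period
    years = sst["time"].dt.year
    sel = sst.sel(time=(years >= y0) & (years <= y1))
    if sel.sizes["time"] == 0:
        raise ValueError(f"run does not cover reference period {y0}-{y1}")
    have = np.unique(sel["time"].dt.year)
    missing = sorted(set(range(y0, y1 + 1)) - set(int(y) for y in have))
    if missing:
        raise ValueError(f"reference period years missing from run: {missing}")
    return sel.groupby("time.month").mean("time")


def ensemble_mean_climatology(
    historical_runs: list[ESMRunData], reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD
) -> xr.DataArray:
    """Monthly climatology of the historical ensemble mean."""
    hist = [r for r in historical_runs if r.scenario == "historical"]
    if not hist:
        raise ValueError("no historical runs supplied")
    clims = [monthly_climatology(r.sst, reference_period) for r in hist]
    return xr.concat(clims, dim="model").mean("model")


def delta_bias_correct(
    run: ESMRunData,
    historical_ensemble_mean: xr.DataArray,
    reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
    model_historical: ESMRunData | None = None,
    mode: str = "monthly",
) -> ESMRunData:
    """Additive delta-method bias correction toward the ensemble mean.

    Per cell and calendar month (or day-of-year / annually, per ``mode``)::

        corrected(t) = raw(t) - model_ref_clim + ensemble_mean_ref_clim

    The model's own reference climatology comes from its historical run
    (``model_historical``; the run itself when it is historical), so the
    delta applied to a scenario run equals the one applied to the model's
    historical run and the corrected series is continuous at the
    historical/scenario boundary up to the model's own variability.
    """
    if mode not in ("monthly", "doy", "annual"):
        raise ValueError("mode must be monthly, doy or annual")
    source = model_historical if model_historical is not None else run
    if model_historical is not None and model_historical.model_id != run.model_id:
        raise ValueError("model_historical must belong to the same model")
    if run.scenario != "historical" and model_historical is None:
        raise ValueError("scenario runs need their model's historical run for the delta")

    if mode == "monthly":
        grouper = "time.month"
        ens = historical_ensemble_mean
        if "month" not in ens.dims:
            raise ValueError("ensemble climatology must be monthly (dim 'month')")
    elif mode == "doy":
        grouper = "time.dayofyear"
        ens = historical_ensemble_mean
    else:
        grouper = None
        ens = historical_ensemble_mean.mean("month") if "month" in historical_ensemble_mean.dims else historical_ensemble_mean

    for dim in ("lat", "lon"):
        if not np.array_equal(np.asarray(run.sst[dim]), np.asarray(ens[dim])):
            raise ValueError(f"run and ensemble climatology differ on {dim}")

    y0, y1 = reference_period
    ref = source.sst.sel(time=(source.sst["time"].dt.year >= y0) & (source.sst["time"].dt.year <= y1))
    if ref.sizes["time"] == 0:
        raise ValueError(f"model historical run does not cover {y0}-{y1}")
    have = set(int(y) for y in np.unique(ref["time"].dt.year))
    missing = sorted(set(range(y0, y1 + 1)) - have)
    if missing:
        raise ValueError(f"reference period years missing from model run: {missing}")

    if mode == "annual":
        delta = ens - ref.mean("time")
        corrected = run.sst + delta
    else:
        model_clim = ref.groupby(grouper).mean("time")
        delta = ens - model_clim
        corrected = (run.sst.groupby(grouper) + delta).drop_vars(
            delta.dims[0], errors="ignore"
        )
    corrected = corrected.transpose("time", "lat", "lon")
    corrected.attrs.update(run.sst.attrs)
    return ESMRunData(model_id=run.model_id, scenario=run.scenario, sst=corrected)


def bilinear_regrid(field: xr.DataArray, target: AnalysisGrid) -> xr.DataArray:
    """Bilinear interpolation onto the analysis grid.

    Standard bilinear weights from the four surrounding source cell
    centres; exact for fields linear in lon and lat. Target centres
    outside the source grid's bounding box are returned as NaN; an error is
    raised if no target centre falls inside.
    """
    out = field.interp(
        lat=xr.DataArray(target.lat, dims="lat"),
        lon=xr.DataArray(target.lon, dims="lon"),
        method="linear",
    )
    if bool(out.isnull().all()):
        raise ValueError("target grid lies wholly outside the source grid")
    return out


def idw_fill(
    values: xr.DataArray,
    targets: list[tuple[float, float]],
    power: float = DEFAULT_IDW_POWER,
    max_radius_m: float | None = None,
    grid_spacing_deg: float | None = None,
) -> tuple[dict[tuple[float, float], np.ndarray], list[tuple[float, float]]]:
    """Inverse-distance-weighted fill of target cells from valued cells.

    ``values`` is a (time, lat, lon) or (lat, lon) field with NaN where no
    model data exist. For each target (lat, lon) the fill is
    ``sum(w_i v_i) / sum(w_i)`` with ``w_i = d_i**(-power)`` over valued
    cell centres within ``max_radius_m`` (default: twice the grid cell's
    great-circle span). A target coincident with a valued centre returns
    that value. Targets with no valued neighbour in radius are returned in
    the ``unfillable`` list rather than silently dropped.
    """
    lat = np.asarray(values["lat"], dtype=float)
    lon = np.asarray(values["lon"], dtype=float)
    if max_radius_m is None:
        spacing = grid_spacing_deg
        if spacing is None:
            spacing = float(np.diff(lat)[0]) if lat.size > 1 else 0.25
        max_radius_m = 2.0 * spacing * np.pi / 180.0 * 6_371_007.181

    field2d = values if values.ndim == 2 else values.isel(time=0)
    valid = np.asarray(~field2d.isnull())
    vi, vj = np.nonzero(valid)
    vlat, vlon = lat[vi], lon[vj]

    filled: dict[tuple[float, float], np.ndarray] = {}
    unfillable: list[tuple[float, float]] = []
    for tlat, tlon in targets:
        if vlat.size == 0:
            unfillable.append((tlat, tlon))
            continue
        d = haversine_m(tlat, tlon, vlat, vlon)
        near = d <= max_radius_m
        if not near.any():
            logger.warning("idw_fill: no valued neighbour within %.0f m of (%.3f, %.3f)",
                           max_radius_m, tlat, tlon)
            unfillable.append((tlat, tlon))
            continue
        dn = d[near]
        sel_i, sel_j = vi[near], vj[near]
        neighbour_vals = np.asarray(values)[..., sel_i, sel_j]  # (time?, n)
        exact = dn < 1e-6
        if exact.any():
            filled[(tlat, tlon)] = np.atleast_1d(neighbour_vals[..., np.argmax(exact)])
            continue
        w = dn ** (-power)
        filled[(tlat, tlon)] = np.atleast_1d(neighbour_vals @ w / w.sum())
        logger.info("idw_fill: filled (%.3f, %.3f) from %d neighbours", tlat, tlon, dn.size)
    return filled, unfillable
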