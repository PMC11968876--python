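"""Marine-heatwave detection and annual cumulative intensity.

A marine heatwave (MHW) is a period during which daily sea-surface
temperature exceeds the seasonally varying 90th-percentile threshold of a
fixed baseline climatology for at least five consecutive days; two
qualifying exceedance runs separated by a short below-threshold gap are
merged into one event. The exposure metric is the cumulative annual MHW
intensity: the sum, over all event days in a calendar year, of the SST
anomaly relative to the climatological seasonal mean, in degC-days.

The climatology follows the standard Hobday-style construction: for each
day-of-year, all baseline observations within a +/-5-day window (pooled
circularly across the year boundary and across baseline years) contribute
to the seasonal mean and the 90th percentile; both curves are then
circularly smoothed with a 31-day moving average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = (1983, 2012)
DEFAULT_WINDOW_HALF_WIDTH = 5
DEFAULT_SMOOTH_WINDOW = 31
DEFAULT_PERCENTILE = 90.0
DEFAULT_MIN_DURATION = 5
DEFAULT_MAX_GAP = 2

N_DOY = 366  # climatology indexed on a leap-year calendar


def leap_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a 366-day (leap) calendar.

    In non-leap years, dates after Feb 28 are shifted by one so that e.g.
    Mar 1 always maps to doy 61; slot 60 (Feb 29) is populated only in leap
    years and shares its pooled climatology window with Feb 28 / Mar 1.
    """
    doy = np.asarray(index.dayofyear)
    shift = (~np.asarray(index.is_leap_year)) & (doy > 59)
    return doy + shift.astype(np.int64)


@dataclass
class DailySSTSeries:
    """One cell's contiguous daily SST record (missing values as NaN)."""

    cell_id: str
    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst must have equal length")
        if len(self.dates) < 365:
            raise ValueError("series must span at least one full year")
        step = np.diff(self.dates.to_numpy()).astype("timedelta64[D]")
        if not (step == np.timedelta64(1, "D")).all():
            raise ValueError("dates must be strictly increasing with step 1 day")

    def __len__(self) -> int:
        return len(self.sst)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "sst": self.sst})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id: str = "cell") -> "DailySSTSeries":
        return cls(cell_id, pd.DatetimeIndex(pd.to_datetime(df["date"])), df["sst"].to_numpy())


@dataclass
class ClimatologyThreshold:
    """Day-of-year seasonal mean and 90th-percentile threshold.

    Both curves hold 366 entries (leap-year day-of-year indexing) and are
    circularly smoothed, so the value at doy 1 depends on the doy-366
    neighbourhood.
    """

    clim_mean: np.ndarray
    thresh90: np.ndarray
    baseline: tuple[int, int]
    percentile: float = DEFAULT_PERCENTILE
    window_half_width: int = DEFAULT_WINDOW_HALF_WIDTH
    smooth_window: int = DEFAULT_SMOOTH_WINDOW

    def __post_init__(self) -> None:
        self.clim_mean = np.asarray(self.clim_mean, dtype=float)
        self.thresh90 = np.asarray(self.thresh90, dtype=float)
        for name, curve in (("clim_mean", self.clim_mean), ("thresh90", self.thresh90)):
            if curve.shape != (N_DOY,):
                raise ValueError(f"{name} must have exactly {N_DOY} entries")
            if not np.isfinite(curve).all():
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class MHWEvent:
    """A single detected marine heatwave at one cell."""

    cell_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    intensity_cumulative: float
    intensity_max: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start must not follow end")
        if self.duration != (self.end - self.start).days + 1:
            raise ValueError("duration inconsistent with start/end")


@dataclass
class AnnualExposure:
    """Per-cell, per-year cumulative MHW intensity (degC-days).

    ``source`` tags provenance of the underlying SST: the observed product
    branch ("observed") or a model branch ("model"); projected-period
    aggregation requires model provenance so observed and modelled
    statistics are never mixed.
    """

    cell_id: str
    year: int
    cumulative_intensity: float
    source: str = "observed"

    def __post_init__(self) -> None:
        if self.cumulative_intensity < 0:
            raise ValueError("cumulative intensity must be >= 0")


def _circular_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _doy_matrix(series: DailySSTSeries, years: np.ndarray) -> np.ndarray:
    """(n_years, 366) matrix of SST keyed by leap-calendar day-of-year."""
    mat = np.full((len(years), N_DOY), np.nan)
    yr = series.dates.year.to_numpy()
    ld = leap_doy(series.dates)
    lookup = {y: i for i, y in enumerate(years)}
    sel = np.isin(yr, years)
    rows = np.array([lookup[y] for y in yr[sel]], dtype=np.int64)
    mat[rows, ld[sel] - 1] = series.sst[sel]
    return mat


def compute_climatology(
    series: DailySSTSeries,
    baseline: tuple[int, int] = DEFAULT_BASELINE,
    window_half_width: int = DEFAULT_WINDOW_HALF_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    percentile: float = DEFAULT_PERCENTILE,
) -> ClimatologyThreshold:
    """Fixed-baseline seasonal climatology and percentile threshold.

    For each day-of-year, all baseline observations within
    ``+/-window_half_width`` days (circular across the year boundary) are
    pooled across baseline years; the pooled mean and the ``percentile``-th
    percentile (linear interpolation between order statistics) form the raw
    curves, which are then circularly smoothed with a ``smooth_window``-day
    moving average.

    Raises ``ValueError`` if the series does not cover every baseline year
    (the missing years are named) or if some day-of-year pool is entirely
    missing.
    """
    y0, y1 = baseline
    if y1 < y0:
        raise ValueError("baseline must be an increasing year range")
    if window_half_width < 0:
        raise ValueError("window_half_width must be >= 0")
    want = np.arange(y0, y1 + 1)
    have = set(series.years)
    missing = [int(y) for y in want if y not in have]
    if missing:
        raise ValueError(f"series does not cover baseline years: {missing}")

    mat = _doy_matrix(series, want)
    offsets = np.arange(-window_half_width, window_half_width + 1)
    win_idx = (np.arange(N_DOY)[:, None] + offsets[None, :]) % N_DOY  # (366, w)
    pooled = mat[:, win_idx]  # (years, 366, w)
    pooled = np.moveaxis(pooled, 0, 1).reshape(N_DOY, -1)  # (366, years*w)

    n_missing = np.isnan(pooled).sum(axis=1)
    if (n_missing == pooled.shape[1]).any():
        bad = int(np.argmax(n_missing == pooled.shape[1])) + 1
        raise ValueError(f"all observations missing in climatology pool for day-of-year {bad}")
    # doy 60 (Feb 29) legitimately has mostly-empty year rows; exclude it
    # from the sparse-pool warning.
    frac_missing = n_missing / pooled.shape[1]
    sparse = np.flatnonzero(frac_missing > 0.5)
    sparse = sparse[sparse != 59]
    if sparse.size:
        warnings.warn(
            f"more than half of the climatology pool is missing for {sparse.size} "
            "day(s)-of-year",
            stacklevel=2,
        )

    # per-row mean and percentile over valid entries; a single sort (NaN
    # ordered last) replaces nanpercentile, which dominates otherwise
    n_valid = pooled.shape[1] - n_missing
    raw_mean = np.nansum(pooled, axis=1) / n_valid
    srt = np.sort(pooled, axis=1)
    pos = (percentile / 100.0) * (n_valid - 1)
    lo = np.floor(pos).astype(np.int64)
    hi = np.ceil(pos).astype(np.int64)
    frac = pos - lo
    rows = np.arange(N_DOY)
    raw_p = srt[rows, lo] * (1 - frac) + srt[rows, hi] * frac

    return ClimatologyThreshold(
        clim_mean=_circular_smooth(raw_mean, smooth_window),
        thresh90=_circular_smooth(raw_p, smooth_window),
        baseline=(y0, y1),
        percentile=percentile,
        window_half_width=window_half_width,
        smooth_window=smooth_window,
    )


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    series: DailySSTSeries,
    clim: ClimatologyThreshold,
    min_duration: int = DEFAULT_MIN_DURATION,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[MHWEvent]:
    """Detect marine heatwaves against a fixed climatology.

    Maximal runs of days with SST strictly above the seasonal threshold, of
    length >= ``min_duration``, are events; consecutive qualifying runs
    separated by <= ``max_gap`` below-threshold days merge into a single
    event spanning the gap. Missing days count as below threshold and break
    exceedance runs. ``intensity_cumulative`` sums (sst - clim_mean) over
    every day of the event span, gap days included.
    """
    ld = leap_doy(series.dates) - 1
    thresh = clim.thresh90[ld]
    mean = clim.clim_mean[ld]
    sst = series.sst
    above = np.greater(sst, thresh, where=~np.isnan(sst), out=np.zeros(len(sst), bool))

    runs = [(a, b) for a, b in _runs_of(above) if b - a >= min_duration]
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    anomaly = sst - mean
    events = []
    for a, b in merged:
        span = anomaly[a:b]
        events.append(
            MHWEvent(
                cell_id=series.cell_id,
                start=series.dates[a],
                end=series.dates[b - 1],
                duration=b - a,
                intensity_cumulative=float(np.nansum(span)),
                intensity_max=float(np.nanmax(span)),
            )
        )
    return events


def annual_cumulative_intensity(
    events: list[MHWEvent],
    series: DailySSTSeries,
    clim: ClimatologyThreshold,
    year: int,
    source: str = "observed",
) -> AnnualExposure:
    """Cumulative MHW intensity for one calendar year (degC-days).

    Sums (sst - clim_mean) over event days falling in ``year``; an event
    straddling Dec/Jan contributes each day to that day's calendar year.
    """
    years = series.dates.year
    if year < years.min() or year > years.max():
        raise ValueError(f"year {year} outside series span {years.min()}-{years.max()}")
    ld = leap_doy(series.dates) - 1
    anomaly = series.sst - clim.clim_mean[ld]
    in_event = np.zeros(len(series), dtype=bool)
    for ev in events:
        a = series.dates.searchsorted(ev.start)
        b = series.dates.searchsorted(ev.end, side="right")
        in_event[a:b] = True
    sel = in_event & np.asarray(years == year)
    total = float(np.nansum(anomaly[sel]))
    return AnnualExposure(series.cell_id, int(year), max(total, 0.0), source=source)


def annual_exposure_series(
    series: DailySSTSeries,
    clim: ClimatologyThreshold,
    min_duration: int = DEFAULT_MIN_DURATION,
    max_gap: int = DEFAULT_MAX_GAP,
    source: str = "observed",
) -> pd.DataFrame:
    """Detect events and tabulate annual cumulative intensity for all years.

    Returns a DataFrame with columns (cell_id, year, cumulative_intensity,
    source), one row per calendar year of the series, zeros included.
    """
    events = detect_events(series, clim, min_duration=min_duration, max_gap=max_gap)
    ld = leap_doy(series.dates) - 1
    anomaly = series.sst - clim.clim_mean[ld]
    in_event = np.zeros(len(series), dtype=bool)
    for ev in events:
        a = series.dates.searchsorted(ev.start)
        b = series.dates.searchsorted(ev.end, side="right")
        in_event[a:b] = True
    contrib = np.where(in_event & ~np.isnan(anomaly), anomaly, 0.0)
    years = np.asarray(series.dates.year)
    uniq, starts = np.unique(years, return_index=True)
    sums = np.add.reduceat(contrib, starts)
    return pd.DataFrame(
        {
            "cell_id": series.cell_id,
            "year": uniq.astype(int),
            "cumulative_intensity": np.clip(sums, 0.0, None),
            "source": source,
        }
    )


def events_to_frame(events: list[MHWEvent]) -> pd.DataFrame:
    """Tabulate events with the standard output columns."""
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "start": e.start,
                "end": e.end,
                "duration": e.duration,
                "intensity_cumulative": e.intensity_cumulative,
                "intensity_max": e.intensity_max,
            }
            for e in events
        ],
        columns=["cell_id", "start", "end", "duration", "intensity_cumulative", "intensity_max"],
    )
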