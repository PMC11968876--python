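"""Aggregation of per-cell annual MHW exposures into reported summaries.

The aggregation order is: per-model median of annual cumulative intensity
over a period's years -> median across ensemble models per cell -> mean
(with 5th/95th percentile band) across cells per region. Exposure ratios
divide a projected regional mean by the contemporary mean from the
observed branch. Percentiles use linear interpolation between order
statistics.

Contemporary values come from the observed SST product; projected values
from bias-corrected model runs with model-historical baselines. Exposure
records carry a ``source`` tag ("observed" / "model") so the two branches
are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The study's reporting periods (calendar-year inclusive ranges).
DEFAULT_PERIODS = {
    "contemporary": (2001, 2020),
    "near": (2021, 2040),
    "mid": (2041, 2060),
    "long": (2081, 2100),
}


@dataclass(frozen=True)
class PeriodSpec:
    """A named reporting period of inclusive calendar years."""

    name: str
    years: tuple[int, int]

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("period years must be increasing")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @classmethod
    def default(cls, name: str) -> "PeriodSpec":
        return cls(name, DEFAULT_PERIODS[name])


def period_pixel_value(annual: pd.DataFrame, period: PeriodSpec) -> float:
    """Median annual cumulative intensity over one period, one cell, one model.

    ``annual`` needs columns (year, cumulative_intensity); every period year
    must be present.
    """
    sub = annual[annual["year"].isin(period.year_list)]
    missing = sorted(set(period.year_list) - set(sub["year"].astype(int)))
    if missing:
        raise ValueError(f"period {period.name} years missing from annual series: {missing}")
    return float(sub["cumulative_intensity"].median())


def ensemble_median(per_model_values) -> float:
    """Median across ensemble models of one cell's period values."""
    vals = np.asarray(list(per_model_values), dtype=float)
    if vals.size == 0:
        raise ValueError("ensemble median needs at least one model value")
    return float(np.median(vals))


def regional_summary(
    cell_values: pd.DataFrame,
    scenario: str,
    period: str,
    region_col: str = "region_id",
    region_level: str = "region",
) -> pd.DataFrame:
    """Mean and 5th/95th-percentile band of cell values per region.

    ``cell_values`` needs columns (cell_id, value, <region_col>); every cell
    must map to exactly one region (NaN regions raise, naming the cells).
    """
    if cell_values[region_col].isna().any():
        bad = cell_values.loc[cell_values[region_col].isna(), "cell_id"].tolist()
        raise ValueError(f"cells not mapped to any region: {bad}")
    rows = []
    for region, grp in cell_values.groupby(region_col, sort=True):
        v = grp["value"].to_numpy(dtype=float)
        rows.append(
            {
                "region_id": region,
                "region_level": region_level,
                "scenario": scenario,
                "period": period,
                "mean": float(v.mean()),
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
                "n_pixels": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def latitudinal_profile(
    cell_values: pd.DataFrame, bin_width: float = 1.0
) -> pd.DataFrame:
    """Mean cell value per latitude bin.

    Bins are half-open ``[k, k+1)`` on ``floor(latitude)`` (southern bins
    are labelled by their floor, e.g. -55 covers [-55, -54)). Empty bins are
    absent from the output.
    """
    lat = cell_values["lat"].to_numpy(dtype=float)
    if not np.isfinite(lat).all():
        raise ValueError("latitudes must be finite")
    bins = np.floor(lat / bin_width) * bin_width
    out = (
        cell_values.assign(bin=bins)
        .groupby("bin")["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean"})
    )
    return out


def exposure_ratio(projected_mean: float, contemporary_mean: float) -> float:
    """Fold-change of a projected regional mean over the contemporary mean."""
    if contemporary_mean < 0 or projected_mean < 0:
        raise ValueError("means must be non-negative")
    if contemporary_mean == 0:
        raise ZeroDivisionError("contemporary mean is zero; ratio undefined")
    return projected_mean / contemporary_mean


def pixel_period_table(
    annual_exposures: pd.DataFrame,
    period: PeriodSpec,
    expected_source: str | None = None,
) -> pd.DataFrame:
    """Per-cell ensemble-median period values from a long exposure table.

    ``annual_exposures`` needs columns (cell_id, model_id, year,
    cumulative_intensity[, source]). For the observed branch pass a table
    with a single pseudo-model. Returns columns (cell_id, value).
    """
    if expected_source is not None and "source" in annual_exposures:
        src = set(annual_exposures["source"].unique())
        if src - {expected_source}:
            raise ValueError(
                f"exposure records from {sorted(src - {expected_source})} where "
                f"only {expected_source!r} provenance is allowed"
            )
    rows = []
    for cell, by_cell in annual_exposures.groupby("cell_id", sort=True):
        per_model = [
            period_pixel_value(grp, period) for _, grp in by_cell.groupby("model_id", sort=True)
        ]
        rows.append({"cell_id": cell, "value": ensemble_median(per_model)})
    return pd.DataFrame(rows)


def scenario_period_ratios(
    projected: dict[tuple[str, str], pd.DataFrame],
    contemporary: pd.DataFrame,
) -> pd.DataFrame:
    """Fold-change table across scenarios and periods.

    ``projected`` maps (scenario, period) to per-cell value tables;
    ``contemporary`` is the observed-branch per-cell table. Means are taken
    over all cells (the global pixel population) before dividing.
    """
    c_mean = float(contemporary["value"].mean())
    rows = []
    for (scenario, period), table in sorted(projected.items()):
        rows.append(
            {
                "scenario": scenario,
                "period": period,
                "ratio": exposure_ratio(float(table["value"].mean()), c_mean),
            }
        )
    return pd.DataFrame(rows)
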