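"""Independent reference implementations used to validate the package.

Everything here is deliberately naive — explicit day loops and all-pairs
polygon scans — and shares no code with the implementations it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_events(
    dates: pd.DatetimeIndex,
    sst: np.ndarray,
    clim_mean_by_doy: np.ndarray,
    thresh_by_doy: np.ndarray,
    min_duration: int = 5,
    max_gap: int = 2,
) -> list[dict]:
    """Naive day-loop MHW detection (366-entry leap-doy climatology curves)."""
    n = len(sst)
    doy = []
    for d in dates:
        x = d.dayofyear
        if not d.is_leap_year and x > 59:
            x += 1
        doy.append(x - 1)

    above = []
    for i in range(n):
        v = sst[i]
        above.append(bool(not np.isnan(v) and v > thresh_by_doy[doy[i]]))

    # maximal exceedance runs
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_duration]

    # merge qualifying runs across short gaps, repeatedly
    changed = True
    while changed:
        changed = False
        merged = []
        for r in runs:
            if merged and r[0] - merged[-1][1] - 1 <= max_gap:
                merged[-1][1] = r[1]
                changed = True
            else:
                merged.append(list(r))
        runs = merged

    events = []
    for a, b in runs:
        total, peak = 0.0, -np.inf
        for i in range(a, b + 1):
            if not np.isnan(sst[i]):
                anom = sst[i] - clim_mean_by_doy[doy[i]]
                total += anom
                peak = max(peak, anom)
        events.append(
            {
                "start": dates[a],
                "end": dates[b],
                "duration": b - a + 1,
                "intensity_cumulative": total,
                "intensity_max": peak,
            }
        )
    return events


def brute_force_annual(
    dates: pd.DatetimeIndex,
    sst: np.ndarray,
    clim_mean_by_doy: np.ndarray,
    events: list[dict],
) -> dict[int, float]:
    """Naive per-year sum of event-day anomalies."""
    out: dict[int, float] = {int(y): 0.0 for y in np.unique(dates.year)}
    for ev in events:
        day = ev["start"]
        while day <= ev["end"]:
            i = dates.get_loc(day)
            if not np.isnan(sst[i]):
                x = day.dayofyear
                if not day.is_leap_year and x > 59:
                    x += 1
                out[day.year] += sst[i] - clim_mean_by_doy[x - 1]
            day += pd.Timedelta(days=1)
    return out


def brute_force_intersection(kelp, mpas) -> list[tuple[str, str, float]]:
    """All-pairs kelp x MPA intersection on the unsplit layers.

    Returns (feature_id, mpa_id, area_ha) for every pair with positive
    spherical intersection area, plus (feature_id, "none", 0.0) for kelp
    touching no MPA.
    """
    from kelpmhw.geo import spherical_area_ha

    out = []
    for f in kelp:
        hit = False
        for m in mpas:
            inter = f.geometry.intersection(m.geometry)
            if inter.is_empty:
                continue
            area = spherical_area_ha(inter)
            if area > 0:
                out.append((f.feature_id, m.mpa_id, area))
                hit = True
        if not hit:
            out.append((f.feature_id, "none", 0.0))
    return out
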