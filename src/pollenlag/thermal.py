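"""Thermal time: daily averages, growing degree days, anomalies.

Growing degree days (GDD) accumulate from January 1 with base 5.5 °C: on
each day whose average temperature (midpoint of tmax and tmin) strictly
exceeds the base, the excess above the base is added. The alternative
"full" convention, which adds the whole daily average on exceedance days,
is available behind the ``convention`` flag; excess-above-base is the
standard degree-day definition and the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import PhenologySurvey

__all__ = [
    "GDD_BASE",
    "GddSeries",
    "daily_average",
    "cumulative_gdd",
    "gdd_anomaly",
    "long_term_mean_gdd",
    "attach_gdd_covariate",
]

GDD_BASE = 5.5  # °C

logger = logging.getLogger(__name__)


def daily_average(tmax, tmin):
    """Daily average temperature: midpoint of tmax and tmin (°C).

    Inverted inputs (tmin > tmax) raise — callers must fix their data, not
    rely on a silent swap.
    """
    tmax = np.asarray(tmax, float)
    tmin = np.asarray(tmin, float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax; inputs look swapped")
    out = (tmax + tmin) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class GddSeries:
    """Cumulative growing degree days for one station-year."""

    station: str
    year: int
    base: float
    values: pd.Series  # DatetimeIndex -> cumulative °C·day, nondecreasing

    def at(self, date) -> float:
        date = pd.Timestamp(date)
        if date not in self.values.index:
            raise KeyError(f"no GDD value for {self.station} on {date.date()}")
        return float(self.values.loc[date])

    def __len__(self):
        return len(self.values)


def _daily_contribution(tavg: np.ndarray, base: float, convention: str) -> np.ndarray:
    exceeds = tavg > base  # strict: exactly base contributes nothing
    if convention == "excess":
        return np.where(exceeds, tavg - base, 0.0)
    if convention == "full":
        return np.where(exceeds, tavg, 0.0)
    raise ValueError("convention must be 'excess' or 'full'")


def cumulative_gdd(weather: pd.DataFrame, base: float = GDD_BASE,
                   convention: str = "excess") -> list[GddSeries]:
    """Cumulative GDD per station-year, accumulating from January 1.

    Requires continuous daily coverage from January 1 to the last date of
    each station-year; any gap (or a late start) raises an error naming the
    missing dates.
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    if "tavg" not in weather.columns:
        weather["tavg"] = daily_average(weather["tmax"], weather["tmin"])
    out = []
    weather["year"] = weather["date"].dt.year
    for (st, yr), grp in weather.groupby(["station", "year"]):
        grp = grp.sort_values("date")
        full = pd.date_range(f"{yr}-01-01", grp["date"].max(), freq="D")
        missing = full.difference(grp["date"])
        if len(missing):
            shown = ", ".join(str(d.date()) for d in missing[:5])
            more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
            raise ValueError(f"GDD for {st} {yr} needs continuous coverage from "
                             f"Jan 1; missing {shown}{more}")
        grp = grp.set_index("date").reindex(full)
        contrib = _daily_contribution(grp["tavg"].to_numpy(), base, convention)
        cum = pd.Series(np.cumsum(contrib), index=full)
        out.append(GddSeries(station=st, year=int(yr), base=base, values=cum))
    return out


def long_term_mean_gdd(series: list[GddSeries], station: str) -> GddSeries:
    """Mean cumulative GDD by day-of-year across a station's years
    (a long-term reference trajectory)."""
    mine = [s for s in series if s.station == station]
    if not mine:
        raise ValueError(f"no GDD series for station {station!r}")
    frames = []
    for s in mine:
        v = s.values.copy()
        v.index = v.index.dayofyear
        frames.append(v)
    mean = pd.concat(frames, axis=1).mean(axis=1)
    mean.index.name = "doy"
    return GddSeries(station=station, year=0, base=mine[0].base, values=mean)


def gdd_anomaly(series: GddSeries, reference: GddSeries) -> pd.Series:
    """Pointwise difference of a station-year trajectory from a reference.

    Alignment is by day-of-year so a long-term mean reference (year 0) can be
    compared with any year. Station mismatch raises.
    """
    if series.station != reference.station:
        raise ValueError(f"station mismatch: {series.station} vs {reference.station}")
    s = series.values.copy()
    doy = (s.index.dayofyear if isinstance(s.index, pd.DatetimeIndex) else s.index)
    r = reference.values.copy()
    rdoy = (r.index.dayofyear if isinstance(r.index, pd.DatetimeIndex) else r.index)
    r.index = rdoy
    missing = set(doy) - set(rdoy)
    if missing:
        raise ValueError("reference does not cover the series' date range")
    anom = pd.Series(s.to_numpy() - r.loc[doy].to_numpy(), index=series.values.index)
    return anom


def attach_gdd_covariate(survey: PhenologySurvey, gdd: list[GddSeries],
                         station_map: dict, exclude: set | None = None) -> PhenologySurvey:
    """Add a ``gdd`` column giving each observation the thermal time at its
    visit date, via a site -> station map.

    Sites in ``exclude`` (stations judged unrepresentative of the site) are
    dropped with a logged count. Unmapped retained sites, or visit dates
    without a GDD value, raise.
    """
    exclude = exclude or set()
    df = survey.data
    dropped = df["site"].isin(list(exclude))
    if dropped.any():
        logger.info("attach_gdd_covariate: dropping %d observations from "
                    "excluded sites %s", int(dropped.sum()),
                    sorted(set(df.loc[dropped, "site"]))),
    df = df.loc[~dropped].copy()
    lookup = {(s.station, s.year): s for s in gdd}
    vals = np.empty(len(df))
    for k, (_, row) in enumerate(df.iterrows()):
        site = row["site"]
        if site not in station_map:
            raise KeyError(f"site {site!r} has no station mapping")
        key = (station_map[site], int(row["year"]))
        if key not in lookup:
            raise KeyError(f"no GDD series for station-year {key}")
        vals[k] = lookup[key].at(row["date"])
    df["gdd"] = vals
    return PhenologySurvey(df.reset_index(drop=True), sites=survey.sites)
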