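"""Synthetic surveys and weather with the structure the analysis assumes.

The survey generator draws each strobilus score from an ordinal logistic
(proportional-odds) process: at calendar day d the latent linear predictor is

    eta = beta_day * (d + site_effect + year_effect + tree_offset)

and P(score <= c) = expit(theta_c - eta). Site, year and tree effects enter
on the day scale (days are multiplied by beta_day), so a site_effect of
+12 means that site runs 12 days ahead of the reference: positive effects
mean earlier development. Tree offsets are drawn once per (site, tree) and
reused across years, which is what induces between-year rank correlation of
individuals; set ``tree_sd = 0`` for the null of no tree signal.

Defaults mirror a three-year, five-site Scottish pine survey: 20 trees per
site, the five most developed strobili scored per tree roughly every 10 days
through May–June, site offsets spanning 12 days with the westernmost site
earliest, and year offsets spanning about 11 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey import PhenologySurvey, day_from_may1

__all__ = [
    "SimulationParams",
    "TemperatureSimParams",
    "simulate_survey",
    "simulate_temperatures",
]

#: site effects in days, earlier = larger; order matches field observations
DEFAULT_SITES = (("AC", 0.0), ("LD", 3.0), ("RM", 5.0), ("BL", 8.0), ("BE", 12.0))
#: year effects in days (2015 coolest and latest, 2014 warmest and earliest)
DEFAULT_YEARS = ((2014, 0.0), (2015, -11.4), (2016, -3.2))
#: latent cutpoints, chosen so the seven stages unfold across May–June at
#: beta_day = 0.30 (stage-5 crossing near day 32 for a zero-effect site)
DEFAULT_THRESHOLDS = (2.4, 5.4, 7.8, 9.6, 11.4, 14.4)


@dataclass(frozen=True)
class SimulationParams:
    """Design and latent-process parameters of a synthetic survey."""

    sites: tuple = DEFAULT_SITES
    years: tuple = DEFAULT_YEARS
    beta_day: float = 0.30          # logit units per day
    thresholds: tuple = DEFAULT_THRESHOLDS
    tree_sd: float = 3.0            # SD of per-tree offset, days
    visit_interval: int = 10        # days between visits
    n_trees: int = 20
    n_replicates: int = 5
    season: tuple = ("05-01", "06-30")   # month-day of first and last visit
    site_years: Mapping[str, Sequence[int]] | None = None  # None = all years
    seed: int | None = None

    def __post_init__(self):
        th = np.asarray(self.thresholds, float)
        if np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.beta_day <= 0:
            raise ValueError("beta_day must be positive")
        if self.n_trees < 2:
            raise ValueError("need at least 2 trees per site")
        if self.visit_interval < 1:
            raise ValueError("visit_interval must be >= 1 day")


def _visit_days(params: SimulationParams) -> np.ndarray:
    start_m, start_d = map(int, params.season[0].split("-"))
    end_m, end_d = map(int, params.season[1].split("-"))
    first = pd.Timestamp(2001, start_m, start_d)
    last = pd.Timestamp(2001, end_m, end_d)
    origin = pd.Timestamp(2001, 5, 1)
    d0 = (first - origin).days + 1
    d1 = (last - origin).days + 1
    return np.arange(d0, d1 + 1, params.visit_interval)


def simulate_survey(params: SimulationParams | None = None,
                    seed: int | None = None) -> PhenologySurvey:
    """Draw a full survey from the latent ordinal development process.

    Identical seed (via ``params.seed`` or the ``seed`` argument, which takes
    precedence) yields an identical observation table. A warning is issued if
    the whole survey collapses into a single category (degenerate
    parametrisation).
    """
    params = params or SimulationParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    theta = np.asarray(params.thresholds, float)
    days = _visit_days(params)
    site_years = params.site_years or {}
    year_effect = dict(params.years)

    # per-(site, tree) latent offsets, drawn once and reused across years
    offsets = {
        (code, t): rng.normal(0.0, params.tree_sd) if params.tree_sd > 0 else 0.0
        for code, _ in params.sites for t in range(1, params.n_trees + 1)
    }

    rows = []
    for code, site_eff in params.sites:
        yrs = site_years.get(code, [y for y, _ in params.years])
        for yr in yrs:
            dates = pd.Timestamp(int(yr), 5, 1) + pd.to_timedelta(days - 1, unit="D")
            for t in range(1, params.n_trees + 1):
                eff_days = days + site_eff + year_effect[int(yr)] + offsets[(code, t)]
                eta = params.beta_day * eff_days
                cum = expit(theta[None, :] - eta[:, None])      # visits x 6
                u = rng.random((len(days), params.n_replicates))
                scores = 1 + (u[:, :, None] > cum[:, None, :]).sum(axis=2)
                for vi, dt in enumerate(dates):
                    for r in range(params.n_replicates):
                        rows.append((code, t, int(yr), dt, int(days[vi]),
                                     r + 1, int(scores[vi, r])))

    df = pd.DataFrame(rows, columns=["site", "tree", "year", "date", "day",
                                     "replicate", "score"])
    if df["score"].nunique() == 1:
        warnings.warn("degenerate simulation: all probability mass in one "
                      "category over the whole season", UserWarning)
    meta = pd.DataFrame({"site": [c for c, _ in params.sites],
                         "site_effect_days": [e for _, e in params.sites]})
    return PhenologySurvey(df, sites=meta)


@dataclass(frozen=True)
class TemperatureSimParams:
    """Sinusoidal seasonal temperature cycle plus daily noise.

    ``annual_mean``/``annual_amplitude`` set the clean daily average
    (coldest mid-January); ``diurnal_range`` splits it into tmax/tmin;
    ``year_anomaly`` maps (station, year) to an additive °C offset (the
    warm-spring scenario).
    """

    stations: tuple = ("BE", "RM", "AC")
    years: tuple = (2014, 2015, 2016)
    annual_mean: float = 8.0        # °C, Scottish lowland long-term mean
    annual_amplitude: float = 6.0   # °C, winter-summer half-range
    noise_sd: float = 1.5           # °C day-to-day weather noise
    diurnal_range: float = 6.0      # °C, tmax - tmin
    year_anomaly: Mapping = field(default_factory=dict)  # (station, year) -> °C
    station_offsets: Mapping = field(default_factory=dict)  # station -> °C
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")


def simulate_temperatures(params: TemperatureSimParams | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Daily tmax/tmin per station from Jan 1 to Jun 30 of each year.

    Deterministic under a fixed seed. Returns a weather DataFrame with
    columns station, date, tmax, tmin, tavg.
    """
    params = params or TemperatureSimParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    frames = []
    for st in params.stations:
        for yr in params.years:
            dates = pd.date_range(f"{yr}-01-01", f"{yr}-06-30", freq="D")
            doy = dates.dayofyear.to_numpy(dtype=float)
            clean = (params.annual_mean
                     - params.annual_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25))
            clean += params.station_offsets.get(st, 0.0)
            clean += params.year_anomaly.get((st, yr), 0.0)
            noise = rng.normal(0.0, params.noise_sd, len(dates)) if params.noise_sd > 0 else 0.0
            tavg = clean + noise
            frames.append(pd.DataFrame({
                "station": st, "date": dates,
                "tmax": tavg + params.diurnal_range / 2.0,
                "tmin": tavg - params.diurnal_range / 2.0,
                "tavg": tavg,
            }))
    return pd.concat(frames, ignore_index=True)
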