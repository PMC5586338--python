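"""Canned model pipelines over a survey.

Three standard fits:

* per-year: ``score ~ day + site`` separately per year, restricted to the
  sites visited that year (the workaround when uneven site-year coverage
  makes the site×year interaction rank deficient on the pooled data);
* between-year: ``score ~ day + site × year`` on the sites visited in every
  year (full-rank by construction), from which year-vs-year lags come;
* thermal: ``score ~ gdd + site × year`` after attaching the GDD covariate,
  excluding sites whose nearest weather station is unrepresentative.
"""

from __future__ import annotations

from .ordinal import ClmSpec, CumulativeLinkModel, CumulativeLinkResults
from .survey import PhenologySurvey
from .thermal import attach_gdd_covariate

__all__ = ["per_year_fits", "between_year_fit", "thermal_fit",
           "per_year_spec", "between_year_spec", "thermal_spec"]


def per_year_spec(year) -> ClmSpec:
    return ClmSpec(time_term="day", factors=("site",), subset={"year": [year]})


def between_year_spec(sites) -> ClmSpec:
    return ClmSpec(time_term="day", factors=("site", "year"), interaction=True,
                   subset={"site": list(sites)})


def thermal_spec(sites=None) -> ClmSpec:
    subset = {"site": list(sites)} if sites is not None else None
    return ClmSpec(time_term="gdd", factors=("site", "year"), interaction=True,
                   subset=subset)


def per_year_fits(survey: PhenologySurvey, **fit_options) -> dict[int, CumulativeLinkResults]:
    """Fit ``day + site`` per year on that year's sites."""
    out = {}
    for yr in survey.years:
        model = CumulativeLinkModel(survey, per_year_spec(yr))
        out[yr] = model.fit(**fit_options)
    return out


def between_year_fit(survey: PhenologySurvey, sites=None, **fit_options) -> CumulativeLinkResults:
    """Fit ``day + site×year`` on the sites visited in every year."""
    if sites is None:
        sites = survey.sites_in_all_years()
    model = CumulativeLinkModel(survey, between_year_spec(sites))
    return model.fit(**fit_options)


def thermal_fit(survey: PhenologySurvey, gdd, station_map: dict,
                exclude: set | None = None, interaction: bool = True,
                **fit_options) -> CumulativeLinkResults:
    """Attach GDD and fit ``gdd + site(×year)`` on the retained sites."""
    with_gdd = attach_gdd_covariate(survey, gdd, station_map, exclude=exclude)
    factors = ("site", "year") if len(with_gdd.years) > 1 else ("site",)
    inter = interaction and len(with_gdd.years) > 1
    spec = ClmSpec(time_term="gdd", factors=factors, interaction=inter)
    model = CumulativeLinkModel(with_gdd, spec)
    return model.fit(**fit_options)
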