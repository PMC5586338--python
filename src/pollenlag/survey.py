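"""Reading, validating and writing phenology surveys and weather tables.

A survey is a long table with one row per strobilus score: columns ``site``,
``tree``, ``date``, ``year``, ``replicate`` (1–5, the index of the scored
strobilus within a tree-visit) and ``score`` (ordinal stage 1–7). On read,
rows failing validation are rejected individually with a per-row reason and
the ``day`` covariate is computed as days since May 1, counting May 1 itself
as day 1 (June 30 is day 61).

Weather tables carry daily station records (station, date, tmax, tmin, °C);
the daily average used downstream is the midpoint of tmax and tmin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenologySurvey",
    "ValidationReport",
    "day_from_may1",
    "read_survey",
    "write_survey",
    "read_weather",
    "write_weather",
    "DEFAULT_COLUMN_MAP",
]

SCORE_MIN, SCORE_MAX = 1, 7
REPLICATE_MAX = 5
SURVEY_MONTHS = (5, 6)  # May–June observation window

DEFAULT_COLUMN_MAP = {
    "site": "site",
    "tree": "tree",
    "date": "date",
    "score": "score",
    "replicate": "replicate",
}


class SurveyFormatError(ValueError):
    """File-level problem: missing mandatory column, unreadable layout."""


@dataclass
class ValidationReport:
    """Per-row rejection reasons collected while validating a survey."""

    rejected: pd.DataFrame  # columns: row, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __repr__(self):
        return f"<ValidationReport {self.n_rejected} rejected rows>"


@dataclass
class PhenologySurvey:
    """A validated survey plus optional site metadata.

    ``data`` columns: site, tree, year, date, day, replicate, score.
    ``sites`` (optional): one row per site with latitude/longitude/altitude.
    """

    data: pd.DataFrame
    sites: pd.DataFrame | None = None
    validation: ValidationReport | None = field(default=None, repr=False)

    def __post_init__(self):
        required = {"site", "tree", "year", "date", "day", "replicate", "score"}
        missing = required - set(self.data.columns)
        if missing:
            raise SurveyFormatError(f"survey missing columns: {sorted(missing)}")

    @property
    def site_codes(self) -> list:
        return sorted(self.data["site"].unique())

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    def subset(self, sites=None, years=None) -> "PhenologySurvey":
        df = self.data
        if sites is not None:
            df = df[df["site"].isin(list(sites))]
        if years is not None:
            df = df[df["year"].isin(list(years))]
        return PhenologySurvey(df.reset_index(drop=True), self.sites)

    def sites_in_all_years(self) -> list:
        """Sites visited in every survey year (the between-year subset)."""
        cover = self.data.groupby("site")["year"].nunique()
        return sorted(cover[cover == len(self.years)].index)

    def __len__(self):
        return len(self.data)


def day_from_may1(dates: pd.Series, years: pd.Series | None = None) -> pd.Series:
    """Day covariate: days since May 1 of the observation year, inclusive.

    May 1 maps to 1 and each later calendar day adds exactly 1, so dates d
    and d+k map to values differing by k.
    """
    dates = pd.to_datetime(dates)
    yrs = dates.dt.year if years is None else years
    origin = pd.to_datetime(pd.DataFrame({"year": yrs, "month": 5, "day": 1}))
    return (dates - origin).dt.days + 1


def _melt_wide_scores(df: pd.DataFrame, score_columns: list[str]) -> pd.DataFrame:
    keep = [c for c in df.columns if c not in score_columns]
    long = df.melt(id_vars=keep, value_vars=score_columns,
                   var_name="_score_col", value_name="score")
    long["replicate"] = long["_score_col"].map(
        {c: i + 1 for i, c in enumerate(score_columns)})
    return long.drop(columns="_score_col")


def read_survey(path, column_map: dict | None = None,
                score_columns: list[str] | None = None,
                sep: str = ",") -> PhenologySurvey:
    """Read a survey file into a validated :class:`PhenologySurvey`.

    The column layout of deposited data files varies, so the reader accepts a
    ``column_map`` from canonical names (site, tree, date, score, replicate)
    to the file's headers, and ``score_columns`` for wide layouts with one
    column per scored strobilus (melted to long form, replicate = column
    order). Rows failing validation (score outside 1–7, unparsable or
    out-of-window date, duplicate key) are rejected and listed in
    ``survey.validation``.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path, sep=sep)

    if score_columns:
        missing = [c for c in score_columns if c not in raw.columns]
        if missing:
            raise SurveyFormatError(f"missing score columns: {missing}")
        raw = _melt_wide_scores(raw, score_columns)
        cmap = {**cmap, "score": "score", "replicate": "replicate"}

    mandatory = ["site", "tree", "date", "score"]
    for canon in mandatory:
        if cmap[canon] not in raw.columns:
            raise SurveyFormatError(
                f"missing mandatory column {cmap[canon]!r} (for {canon!r})")

    df = pd.DataFrame({
        "site": raw[cmap["site"]].astype(str),
        "tree": raw[cmap["tree"]],
        "date": raw[cmap["date"]],
        "score": raw[cmap["score"]],
    })
    if cmap["replicate"] in raw.columns:
        df["replicate"] = raw[cmap["replicate"]]
    else:
        df["replicate"] = df.groupby(["site", "tree", "date"]).cumcount() + 1

    return validate_survey(df)


def validate_survey(df: pd.DataFrame) -> PhenologySurvey:
    """Row-wise validation of a raw long-form survey table."""
    reasons: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)

    dates = pd.to_datetime(df["date"], errors="coerce")
    bad_date = dates.isna()
    for i in df.index[bad_date]:
        reasons.append((i, f"unparsable date: {df.loc[i, 'date']!r}"))
    keep &= ~bad_date

    score_num = pd.to_numeric(df["score"], errors="coerce")
    bad_score = (score_num.isna() | (score_num % 1 != 0)
                 | (score_num < SCORE_MIN) | (score_num > SCORE_MAX))
    for i in df.index[bad_score & keep]:
        reasons.append((i, f"score outside {SCORE_MIN}-{SCORE_MAX}: {df.loc[i, 'score']!r}"))
    keep &= ~bad_score

    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad_rep = rep.isna() | (rep < 1) | (rep > REPLICATE_MAX)
    for i in df.index[bad_rep & keep]:
        reasons.append((i, f"replicate outside 1-{REPLICATE_MAX}: {df.loc[i, 'replicate']!r}"))
    keep &= ~bad_rep

    in_window = dates.dt.month.isin(SURVEY_MONTHS)
    for i in df.index[~in_window & keep & ~bad_date]:
        reasons.append((i, f"date outside May-June survey window: {dates[i].date()}"))
    keep &= in_window | bad_date

    dup = df.duplicated(subset=["site", "tree", "date", "replicate"], keep="first")
    for i in df.index[dup & keep]:
        reasons.append((i, "duplicate (site, tree, date, replicate) key"))
    keep &= ~dup

    clean = df.loc[keep].copy()
    clean["date"] = dates.loc[keep]
    clean["score"] = score_num.loc[keep].astype(int)
    clean["replicate"] = rep.loc[keep].astype(int)
    clean["year"] = clean["date"].dt.year.astype(int)
    clean["day"] = day_from_may1(clean["date"], clean["year"]).astype(int)
    clean = clean[["site", "tree", "year", "date", "day", "replicate", "score"]]
    report = ValidationReport(pd.DataFrame(reasons, columns=["row", "reason"]))
    if report.n_rejected:
        warnings.warn(f"survey validation rejected {report.n_rejected} rows",
                      UserWarning, stacklevel=2)
    return PhenologySurvey(clean.reset_index(drop=True), validation=report)


def write_survey(survey: PhenologySurvey, path) -> None:
    """Write a survey as CSV with ISO-8601 dates; round-trips exactly."""
    out = survey.data.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# weather

def read_weather(path, sep: str = ",") -> pd.DataFrame:
    """Read daily station records; validate and report coverage gaps.

    Returns a DataFrame with columns station, date, tmax, tmin, tavg.
    Rows with tmin > tmax raise a ``ValueError`` naming the rows; missing
    days within each station-year raise a ``UserWarning`` listing the gaps.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"station", "date", "tmax", "tmin"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyFormatError(f"weather file missing columns: {sorted(missing)}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    inverted = df["tmin"] > df["tmax"]
    if inverted.any():
        rows = list(df.index[inverted])
        raise ValueError(f"tmin > tmax on rows {rows}")
    df["tavg"] = (df["tmax"] + df["tmin"]) / 2.0

    gaps = find_gaps(df)
    if gaps:
        n = sum(len(g) for g in gaps.values())
        detail = "; ".join(f"{k}: {[str(d.date()) for d in v]}" for k, v in gaps.items())
        warnings.warn(f"{n} gap(s) in weather coverage ({detail})",
                      UserWarning, stacklevel=2)
    return df.sort_values(["station", "date"]).reset_index(drop=True)


def find_gaps(weather: pd.DataFrame) -> dict:
    """Missing calendar days per (station, year), within the observed span."""
    gaps = {}
    weather = weather.assign(year=weather["date"].dt.year)
    for (st, yr), grp in weather.groupby(["station", "year"]):
        full = pd.date_range(grp["date"].min(), grp["date"].max(), freq="D")
        missing = full.difference(grp["date"])
        if len(missing):
            gaps[(st, yr)] = list(missing)
    return gaps


def write_weather(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in ["station", "date", "tmax", "tmin"] if c in out.columns]
    out[cols].to_csv(path, index=False)
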