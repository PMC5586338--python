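"""Within-site rank consistency of individual trees across years.

Do the same trees develop first every year? Per visit, each tree's five
strobilus scores are summed and the trees ranked (average ranks on ties);
the ranks are summed over the visits of a year and ranked again, giving one
final rank per tree per (site, year) — higher final rank means consistently
higher scores, i.e. an earlier developer. Between-year agreement of these
final rankings is measured by Spearman's rank correlation (tie-corrected,
with a t-approximation p-value, or an optional Monte-Carlo permutation
p-value), one coefficient per site per year pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "visit_score_sums",
    "annual_rank_sum",
    "spearman_rho",
    "RankConsistencyTable",
    "consistency_table",
    "consistency_frame",
]


def visit_score_sums(survey, site, year) -> pd.DataFrame:
    """Per-visit sum of each tree's strobilus scores at one site-year.

    Returns a visits × trees DataFrame (rows indexed by date). A tree not
    scored at a visit is NaN — flagged missing, never zero-filled.
    """
    df = getattr(survey, "data", survey)
    sub = df[(df["site"] == site) & (df["year"] == year)]
    if sub.empty:
        raise ValueError(f"no visits for site {site!r} in {year}")
    sums = (sub.groupby(["date", "tree"])["score"].sum()
               .unstack("tree"))
    return sums


def annual_rank_sum(visit_sums: pd.DataFrame) -> pd.Series:
    """Final within-site ranking of trees for one year.

    Trees are ranked within each visit (average ranks for ties), the ranks
    summed per tree across visits, and the sums ranked again. Trees missing
    every visit are dropped; a fully tied table returns a degenerate ranking
    with a warning.
    """
    if visit_sums.shape[1] < 2:
        raise ValueError("need at least 2 trees to rank")
    per_visit_ranks = visit_sums.rank(axis=1, method="average")
    rank_sums = per_visit_ranks.sum(axis=0, skipna=True)
    observed = per_visit_ranks.notna().any(axis=0)
    rank_sums = rank_sums[observed]
    final = rank_sums.rank(method="average")
    all_tied = bool((visit_sums.nunique(axis=1, dropna=True) <= 1).all())
    if all_tied and len(final) > 1:
        warnings.warn("all trees tied at every visit; degenerate ranking",
                      UserWarning, stacklevel=2)
    final.name = "final_rank"
    return final


def spearman_rho(x, y, method: str = "t", n_perm: int = 9999,
                 seed: int | None = None) -> tuple[float, float]:
    """Tie-corrected Spearman correlation of two rankings with a p-value.

    Pairs with a missing value on either side are dropped; fewer than 4
    complete pairs raise. ``method='t'`` uses the t-distribution
    approximation on n−2 degrees of freedom; ``method='permutation'`` uses a
    seeded Monte-Carlo permutation test (two-sided). Zero variance on either
    side yields (nan, nan) with a warning.
    """
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    both = x.notna() & y.notna()
    x, y = x[both].to_numpy(), y[both].to_numpy()
    if len(x) < 4:
        raise ValueError(f"need >= 4 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a ranking; rho undefined", UserWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    rho, p_t = stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p_t)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return float(rho), (count + 1) / (n_perm + 1)
    raise ValueError("method must be 't' or 'permutation'")


@dataclass
class RankConsistencyTable:
    """Per-site rank consistency: final rankings and between-year rho."""

    site: str
    per_year_rank: dict = field(default_factory=dict)   # year -> Series tree -> rank
    rho: dict = field(default_factory=dict)             # (yearA, yearB) -> rho
    p_value: dict = field(default_factory=dict)         # (yearA, yearB) -> p
    n_trees: dict = field(default_factory=dict)         # (yearA, yearB) -> n used


def consistency_table(survey, method: str = "t", seed: int | None = None) -> list[RankConsistencyTable]:
    """Rank-consistency analysis for every site with >= 2 survey years.

    Trees missing in either year of a pair are dropped pairwise. Sites seen
    in a single year are omitted (logged via warning at debug-free level).
    """
    df = getattr(survey, "data", survey)
    out = []
    for site in sorted(df["site"].unique()):
        years = sorted(df.loc[df["site"] == site, "year"].unique())
        if len(years) < 2:
            continue
        table = RankConsistencyTable(site=site)
        for yr in years:
            sums = visit_score_sums(survey, site, yr)
            table.per_year_rank[yr] = annual_rank_sum(sums)
        for ya, yb in itertools.combinations(years, 2):
            ra, rb = table.per_year_rank[ya], table.per_year_rank[yb]
            joined = pd.concat([ra, rb], axis=1, keys=["a", "b"]).dropna()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                rho, p = spearman_rho(joined["a"], joined["b"], method=method,
                                      seed=seed)
            table.rho[(ya, yb)] = rho
            table.rho[(yb, ya)] = rho
            table.p_value[(ya, yb)] = p
            table.p_value[(yb, ya)] = p
            table.n_trees[(ya, yb)] = len(joined)
            table.n_trees[(yb, ya)] = len(joined)
        out.append(table)
    return out


def consistency_frame(tables: list[RankConsistencyTable]) -> pd.DataFrame:
    """Tidy sites × year-pairs table of rho, p and n (one row per cell)."""
    rows = []
    for t in tables:
        for (ya, yb) in sorted({tuple(sorted(k)) for k in t.rho}):
            rows.append({"site": t.site, "year_a": ya, "year_b": yb,
                         "rho": t.rho[(ya, yb)], "p_value": t.p_value[(ya, yb)],
                         "n_trees": t.n_trees[(ya, yb)]})
    return pd.DataFrame(rows)
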