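"""Time lags between factor levels from cumulative link coefficients.

The lag between two sites (or years) is the difference in days at which half
of the strobili at one have reached the same stage as at the other:

    lag(i, j) = (beta_j - beta_i) / beta_day

with treatment-coded factor coefficients (reference level = 0) and the common
time slope beta_day. Within one fit the lags are antisymmetric and additive.

Uncertainty comes from a nonparametric cluster bootstrap: trees are resampled
with replacement within each site (scores within a tree are dependent, so the
tree is the exchangeable unit), the model is refitted per replicate, and the
2.5/97.5 percentiles give the CI. For significance testing the CI is widened
by a fixed penalty (default 3 days — roughly the span over which a single
tree sheds most of its pollen); a pair differs significantly only when the
penalized interval excludes zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ordinal import ClmSpec, CumulativeLinkModel, CumulativeLinkResults, _BETA_DAY_FLOOR

__all__ = [
    "TimeLagEstimate",
    "time_lag",
    "penalized_significance",
    "bootstrap_lag_ci",
    "pairwise_lag_table",
    "lag_table_frame",
]

DEFAULT_PENALTY_DAYS = 3.0
MAX_FAILED_FRACTION = 0.20


@dataclass
class TimeLagEstimate:
    """Pairwise lag in days with bootstrap and penalized intervals."""

    level_i: object
    level_j: object
    lag_days: float
    ci: tuple | None = None             # (lower, upper), percentile bootstrap
    penalized_ci: tuple | None = None
    significant: bool | None = None
    n_boot: int = 0
    n_failed: int = 0
    seed: int | None = None

    def reversed(self) -> "TimeLagEstimate":
        flip = lambda iv: (-iv[1], -iv[0]) if iv is not None else None
        return replace(self, level_i=self.level_j, level_j=self.level_i,
                       lag_days=-self.lag_days, ci=flip(self.ci),
                       penalized_ci=flip(self.penalized_ci))


def _lag_from_results(results: CumulativeLinkResults, factor, level_i, level_j) -> float:
    b_time = results.beta_time
    if abs(b_time) < _BETA_DAY_FLOOR:
        raise ValueError("time slope is numerically zero; lag undefined for a "
                         "flat time response")
    bi = results.factor_coef(factor, level_i)
    bj = results.factor_coef(factor, level_j)
    return (bj - bi) / b_time


def time_lag(results: CumulativeLinkResults, level_i, level_j,
             factor: str = "site") -> float:
    """Point-estimate lag in days between two levels of ``factor``.

    Positive when level_i reaches a given stage later than level_j, i.e.
    the returned value is Day[level_i] − Day[level_j] at the half-crossing.
    """
    return _lag_from_results(results, factor, level_i, level_j)


def penalized_significance(estimate: TimeLagEstimate,
                           penalty_days: float = DEFAULT_PENALTY_DAYS) -> TimeLagEstimate:
    """Widen the CI by ``penalty_days`` on each side; significant iff the
    penalized interval excludes zero."""
    if penalty_days < 0:
        raise ValueError("penalty must be >= 0 days")
    if estimate.ci is None:
        raise ValueError("estimate carries no confidence interval")
    lo, hi = estimate.ci
    pen = (lo - penalty_days, hi + penalty_days)
    sig = pen[0] > 0 or pen[1] < 0
    return replace(estimate, penalized_ci=pen, significant=sig)


# ---------------------------------------------------------------------------
# cluster bootstrap

def _tree_clusters(frame: pd.DataFrame):
    """Row positions (into the design arrays) per (site, tree)."""
    sites: dict = {}
    for (site, _tree), pos in frame.groupby(["site", "tree"], sort=True).indices.items():
        sites.setdefault(site, []).append(np.asarray(pos))
    return sites


def _bootstrap_lag_distributions(survey, spec: ClmSpec, pairs, factor: str,
                                 n_boot: int, seed) -> tuple[dict, float, int, CumulativeLinkResults]:
    """Fit once, then resample trees within site and refit ``n_boot`` times.

    Returns (pair -> array of replicate lags, point fit, n_failed, results).
    """
    model = CumulativeLinkModel(survey, spec)
    frame = getattr(survey, "data", survey)
    if spec.subset:
        from .ordinal import _apply_subset
        frame = _apply_subset(frame, spec.subset).reset_index(drop=True)
    else:
        frame = frame.reset_index(drop=True)
    results = model.fit()

    clusters = _tree_clusters(frame)
    for site, trees in clusters.items():
        if len(trees) < 2:
            raise ValueError(f"site {site!r} has fewer than 2 trees; cluster "
                             "bootstrap undefined")

    rng = np.random.default_rng(seed)
    y, X = model.design.y, model.design.X
    warm = results.params_raw
    dists = {p: [] for p in pairs}
    n_failed = 0
    site_trees = {s: list(t) for s, t in clusters.items()}
    for _ in range(n_boot):
        take = []
        for site in sorted(site_trees):
            trees = site_trees[site]
            picks = rng.integers(0, len(trees), size=len(trees))
            take.extend(trees[k] for k in picks)
        idx = np.concatenate(take)
        yb, Xb = y[idx], X[idx]
        try:
            if len(np.unique(yb)) < model.design.n_levels:
                raise ValueError("replicate lost response categories")
            bmodel = CumulativeLinkModel.__new__(CumulativeLinkModel)
            bmodel.spec = spec
            bmodel.data = None
            d = model.design
            bmodel.design = type(d)(y=yb, X=Xb, xnames=d.xnames, levels=d.levels,
                                    response_levels=d.response_levels, spec=spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bres = bmodel.fit(start_params=warm, compute_vcov=False)
            if not bres.converged:
                raise ValueError("replicate fit did not converge")
            for (li, lj) in pairs:
                dists[(li, lj)].append(_lag_from_results(bres, factor, li, lj))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_boot and n_failed > MAX_FAILED_FRACTION * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed; "
                           "results would be unreliable")
    return {p: np.asarray(v) for p, v in dists.items()}, n_failed, results


def bootstrap_lag_ci(survey, spec: ClmSpec, level_i, level_j,
                     n_boot: int = 1000, seed: int | None = None,
                     factor: str = "site",
                     penalty_days: float = DEFAULT_PENALTY_DAYS) -> TimeLagEstimate:
    """Cluster-bootstrap percentile CI for one pairwise lag.

    Trees are resampled with replacement within each site; replicates that
    fail to refit are dropped and counted (an error is raised beyond 20%).
    Reproducible under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a percentile CI")
    dists, n_failed, results = _bootstrap_lag_distributions(
        survey, spec, [(level_i, level_j)], factor, n_boot, seed)
    lag = _lag_from_results(results, factor, level_i, level_j)
    draws = dists[(level_i, level_j)]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    est = TimeLagEstimate(level_i, level_j, lag, ci=(float(lo), float(hi)),
                          n_boot=n_boot, n_failed=n_failed, seed=seed)
    return penalized_significance(est, penalty_days)


def pairwise_lag_table(survey, spec: ClmSpec, n_boot: int = 1000,
                       seed: int | None = None, factor: str = "site",
                       penalty_days: float = DEFAULT_PENALTY_DAYS,
                       levels=None) -> list[TimeLagEstimate]:
    """All unordered pairwise lags among the levels of ``factor``.

    One shared bootstrap run serves every pair (each replicate refit yields
    the full coefficient vector). Point estimates are exactly antisymmetric
    and additive because they come from a single fit.
    """
    model_levels = None
    if levels is None:
        probe = CumulativeLinkModel(survey, spec)
        model_levels = probe.design.levels[factor]
        levels = model_levels
    if len(levels) < 2:
        raise ValueError("need at least 2 levels to compare")
    pairs = list(itertools.combinations(levels, 2))
    dists, n_failed, results = _bootstrap_lag_distributions(
        survey, spec, pairs, factor, n_boot, seed)
    out = []
    for (li, lj) in pairs:
        lag = _lag_from_results(results, factor, li, lj)
        if n_boot:
            lo, hi = np.percentile(dists[(li, lj)], [2.5, 97.5])
            est = TimeLagEstimate(li, lj, lag, ci=(float(lo), float(hi)),
                                  n_boot=n_boot, n_failed=n_failed, seed=seed)
            est = penalized_significance(est, penalty_days)
        else:
            est = TimeLagEstimate(li, lj, lag)
        out.append(est)
    return out


def lag_table_frame(estimates: list[TimeLagEstimate]) -> pd.DataFrame:
    """Tidy table of lag estimates (one row per unordered pair)."""
    rows = []
    for e in estimates:
        rows.append({
            "level_i": e.level_i, "level_j": e.level_j, "lag_days": e.lag_days,
            "ci_lo": e.ci[0] if e.ci else np.nan,
            "ci_hi": e.ci[1] if e.ci else np.nan,
            "pen_lo": e.penalized_ci[0] if e.penalized_ci else np.nan,
            "pen_hi": e.penalized_ci[1] if e.penalized_ci else np.nan,
            "significant": e.significant, "n_boot": e.n_boot,
            "n_failed": e.n_failed,
        })
    return pd.DataFrame(rows)
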