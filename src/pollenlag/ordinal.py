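"""Cumulative link (proportional-odds) models for ordinal phenology scores.

The response is an ordinal developmental stage (by default the 1–7 strobilus
scale). The model places ordered thresholds ``theta_1 < ... < theta_{K-1}`` on
a latent logistic scale and a common linear predictor ``eta`` built from a
continuous time covariate (calendar day or growing degree days) and
treatment-coded categorical terms (site, year, optionally their interaction):

    P(Y <= j) = F(theta_j - eta),    F = logistic CDF.

Because the slope is shared across thresholds, differences between factor
levels are the same at every response level (the proportional-odds
assumption), which is what makes the coefficient-ratio time-lag statistic
well defined.

Fitting is by maximum likelihood with the thresholds reparametrised as
``theta_1`` plus log-increments (ordering holds by construction), an analytic
gradient, and BFGS. The covariance of the estimates is the inverse of the
observed information, obtained by central finite differences of the analytic
score at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "ClmSpec",
    "Design",
    "RankDeficiencyError",
    "build_design",
    "negative_log_likelihood",
    "CumulativeLinkModel",
    "CumulativeLinkResults",
    "fit_clm",
]

_BETA_DAY_FLOOR = 1e-8


class RankDeficiencyError(ValueError):
    """Design matrix has linearly dependent columns.

    Raised in particular when a Site×Year interaction is requested on a
    survey whose site-year coverage is unbalanced (cells never observed);
    the remedy is to drop the interaction or restrict to the sites observed
    in every year.
    """


@dataclass(frozen=True)
class ClmSpec:
    """Specification of a cumulative link model on a phenology survey.

    Parameters
    ----------
    time_term : str or None
        Column holding the continuous covariate ("day" or "gdd"); ``None``
        fits thresholds only (intercept-only model).
    factors : tuple of str
        Categorical main effects, drawn from {"site", "year"}.
    interaction : bool
        Include the site×year interaction (requires both main effects and a
        full-rank design; unbalanced site-year coverage raises
        :class:`RankDeficiencyError`).
    reference_levels : mapping, optional
        Baseline level per factor; defaults to the alphabetically /
        numerically first observed level.
    subset : mapping, optional
        Column -> collection of allowed values, applied before coding.
    response_levels : sequence, optional
        Ordered response levels; defaults to the observed sorted scores.
    """

    time_term: str | None = "day"
    factors: tuple[str, ...] = ("site",)
    interaction: bool = False
    reference_levels: Mapping[str, Any] | None = None
    subset: Mapping[str, Sequence[Any]] | None = None
    response_levels: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.interaction and not {"site", "year"} <= set(self.factors):
            raise ValueError("interaction requires both 'site' and 'year' factors")


@dataclass
class Design:
    """Response vector, model matrix, and level bookkeeping for one fit."""

    y: np.ndarray            # integer codes 0..K-1
    X: np.ndarray            # n x p, no intercept (thresholds absorb it)
    xnames: list[str]        # p column names: time term first, then factors
    levels: dict[str, list]  # factor -> observed levels, levels[0] = reference
    response_levels: list    # original ordinal labels, ascending
    spec: ClmSpec
    index: np.ndarray = field(default=None)  # row positions into the source frame

    @property
    def n_levels(self) -> int:
        return len(self.response_levels)


def _apply_subset(data: pd.DataFrame, subset: Mapping[str, Sequence[Any]] | None) -> pd.DataFrame:
    if not subset:
        return data
    mask = pd.Series(True, index=data.index)
    for col, allowed in subset.items():
        mask &= data[col].isin(list(allowed))
    return data.loc[mask]


def build_design(data, spec: ClmSpec) -> Design:
    """Build the treatment-coded design for a cumulative link model.

    ``data`` may be a :class:`~pollenlag.survey.PhenologySurvey` or a tidy
    DataFrame with columns ``score``, the time term, and the factor columns.
    Subsetting is applied before coding, so reference levels and coded columns
    reflect only the retained rows. Structurally confounded columns (e.g.
    site×year cells never observed) trigger :class:`RankDeficiencyError`
    naming the offending columns and advising to drop the interaction.
    """
    frame = getattr(data, "data", data)
    frame = _apply_subset(frame, spec.subset)
    if len(frame) == 0:
        raise ValueError("empty design: the subset matched no observations")

    if spec.response_levels is not None:
        levels_y = list(spec.response_levels)
        bad = set(frame["score"]) - set(levels_y)
        if bad:
            raise ValueError(f"scores {sorted(bad)} not in declared response levels")
    else:
        levels_y = [l.item() if hasattr(l, "item") else l
                    for l in sorted(frame["score"].unique())]
    if len(levels_y) < 2:
        raise ValueError("response needs at least 2 observed levels")
    code_of = {lvl: i for i, lvl in enumerate(levels_y)}
    y = frame["score"].map(code_of).to_numpy(dtype=np.int64)

    cols = []
    xnames = []
    if spec.time_term is not None:
        cols.append(frame[spec.time_term].to_numpy(dtype=float))
        xnames.append(spec.time_term)
    levels: dict[str, list] = {}
    indicators: dict[str, dict[Any, np.ndarray]] = {}
    refs = dict(spec.reference_levels or {})
    for fac in spec.factors:
        obs = sorted(frame[fac].unique())
        ref = refs.get(fac, obs[0])
        if ref not in obs:
            raise ValueError(f"reference level {ref!r} not observed for factor {fac!r}")
        ordered = [ref] + [l for l in obs if l != ref]
        levels[fac] = ordered
        vals = frame[fac].to_numpy()
        indicators[fac] = {l: (vals == l).astype(float) for l in ordered}
        for l in ordered[1:]:
            cols.append(indicators[fac][l])
            xnames.append(f"{fac}[{l}]")

    if spec.interaction:
        never_observed = []
        for s in levels["site"][1:]:
            for yr in levels["year"][1:]:
                col = indicators["site"][s] * indicators["year"][yr]
                name = f"site[{s}]:year[{yr}]"
                if col.sum() == 0:
                    never_observed.append(name)
                cols.append(col)
                xnames.append(name)
        if never_observed:
            raise RankDeficiencyError(
                "site×year interaction is rank deficient: cells never observed "
                f"({', '.join(never_observed)}); drop the interaction or restrict "
                "to sites visited in every year"
            )

    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    rank = np.linalg.matrix_rank(X) if X.shape[1] else 0
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            "drop the interaction or merge confounded levels"
        )
    idx = np.arange(len(frame))
    return Design(y=y, X=X, xnames=xnames, levels=levels,
                  response_levels=levels_y, spec=spec, index=idx)


# ---------------------------------------------------------------------------
# likelihood

def _nll_and_grad(theta: np.ndarray, beta: np.ndarray, y: np.ndarray,
                  X: np.ndarray, K: int):
    """Negative log-likelihood and its gradient in the direct (theta, beta)
    parametrisation. theta has K-1 strictly increasing entries."""
    eta = X @ beta
    n = y.shape[0]
    F_hi = np.ones(n)
    f_hi = np.zeros(n)
    hi = y < K - 1
    z = theta[y[hi]] - eta[hi]
    F_hi[hi] = expit(z)
    f_hi[hi] = F_hi[hi] * (1.0 - F_hi[hi])
    F_lo = np.zeros(n)
    f_lo = np.zeros(n)
    lo = y > 0
    z = theta[y[lo] - 1] - eta[lo]
    F_lo[lo] = expit(z)
    f_lo[lo] = F_lo[lo] * (1.0 - F_lo[lo])

    p = np.clip(F_hi - F_lo, 1e-300, None)
    nll = -np.log(p).sum()

    w = 1.0 / p
    g_theta = (-np.bincount(y[hi], weights=f_hi[hi] * w[hi], minlength=K - 1)
               + np.bincount(y[lo] - 1, weights=f_lo[lo] * w[lo], minlength=K - 1))
    g_beta = X.T @ (w * (f_hi - f_lo))
    return nll, g_theta, g_beta


def negative_log_likelihood(thresholds, beta, design: Design) -> float:
    """−Σ log[F(θ_x − η) − F(θ_{x−1} − η)] with θ_0 = −∞, θ_K = +∞.

    Raises ``ValueError`` for non-increasing thresholds.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if thresholds.shape[0] != design.n_levels - 1:
        raise ValueError("need K-1 thresholds for K response levels")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    nll, _, _ = _nll_and_grad(thresholds, beta, design.y, design.X, design.n_levels)
    return float(nll)


def _unpack(q: np.ndarray, K: int):
    """Transformed -> direct: q = (theta_1, log-increments, beta)."""
    theta = q[0] + np.concatenate(([0.0], np.cumsum(np.exp(q[1:K - 1]))))
    return theta, q[K - 1:]


def _pack(theta: np.ndarray, beta: np.ndarray):
    d = np.diff(theta)
    return np.concatenate(([theta[0]], np.log(d), beta))


class CumulativeLinkModel:
    """Proportional-odds cumulative logit model on an ordinal survey.

    Construct from a survey (or tidy DataFrame) and a :class:`ClmSpec`;
    :meth:`fit` returns a :class:`CumulativeLinkResults`.
    """

    def __init__(self, data, spec: ClmSpec | None = None, design: Design | None = None):
        self.spec = spec if spec is not None else ClmSpec()
        self.data = getattr(data, "data", data) if data is not None else None
        self.design = design if design is not None else build_design(data, self.spec)
        self._check_separation()

    @classmethod
    def from_survey(cls, survey, time_term: str = "day",
                    factors: Sequence[str] = ("site",), interaction: bool = False,
                    subset: Mapping[str, Sequence[Any]] | None = None,
                    **kwargs) -> "CumulativeLinkModel":
        spec = ClmSpec(time_term=time_term, factors=tuple(factors),
                       interaction=interaction, subset=subset, **kwargs)
        return cls(survey, spec)

    def _check_separation(self):
        d = self.design
        K = d.n_levels
        for fac, lvls in d.levels.items():
            pos = [i for i, nm in enumerate(d.xnames) if nm.startswith(f"{fac}[")]
            names = [d.xnames[i] for i in pos]
            for i, nm in zip(pos, names):
                mask = d.X[:, i] == 1.0
                if mask.any():
                    ys = d.y[mask]
                    if (ys == 0).all() or (ys == K - 1).all():
                        warnings.warn(
                            f"possible complete separation: level {nm} observed only "
                            "at an extreme category", UserWarning, stacklevel=3)

    # -- likelihood in transformed coordinates --------------------------------
    def _objective(self, q: np.ndarray):
        K = self.design.n_levels
        theta, beta = _unpack(q, K)
        nll, g_theta, g_beta = _nll_and_grad(theta, beta, self.design.y,
                                             self.design.X, K)
        # chain rule through theta = theta_1 + cumsum(exp(zeta))
        g = np.empty_like(q)
        g[0] = g_theta.sum()
        for j in range(1, K - 1):
            g[j] = np.exp(q[j]) * g_theta[j:].sum()
        g[K - 1:] = g_beta
        return nll, g

    def _start_params(self) -> np.ndarray:
        d = self.design
        K = d.n_levels
        n = d.y.shape[0]
        counts = np.bincount(d.y, minlength=K)
        cum = np.cumsum(counts)[:-1] / n
        cum = np.clip(cum, 1.0 / (n + 1.0), n / (n + 1.0))
        cum = np.maximum.accumulate(cum)
        theta0 = logit(cum)
        # enforce strict increase for the log-increment transform
        for j in range(1, K - 1):
            if theta0[j] <= theta0[j - 1]:
                theta0[j] = theta0[j - 1] + 1e-4
        return _pack(theta0, np.zeros(d.X.shape[1]))

    def fit(self, start_params: np.ndarray | None = None, maxiter: int = 500,
            gtol: float = 1e-8, compute_vcov: bool = True) -> "CumulativeLinkResults":
        """Maximise the likelihood; deterministic given data and options."""
        q0 = self._start_params() if start_params is None else np.asarray(start_params, float)
        res = minimize(self._objective, q0, jac=True, method="BFGS",
                       options={"gtol": gtol, "maxiter": maxiter})
        nit = int(res.nit)
        if not res.success:
            # BFGS can stop on precision loss with a stale Hessian estimate;
            # one restart from the current point usually finishes the job
            res2 = minimize(self._objective, res.x, jac=True, method="BFGS",
                            options={"gtol": gtol, "maxiter": maxiter})
            nit += int(res2.nit)
            if res2.fun <= res.fun:
                res = res2
        K = self.design.n_levels
        theta, beta = _unpack(res.x, K)
        # gradient judged relative to the objective's magnitude: a slope of
        # 1e-6 per unit on a log-likelihood of thousands is at the optimum
        gmax = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or gmax < 1e-6 * max(1.0, abs(float(res.fun)))
        if not converged:
            warnings.warn("cumulative link fit did not converge "
                          f"(|grad|max={np.max(np.abs(res.jac)):.3g})", UserWarning)
        vcov = self._observed_information_inverse(theta, beta) if compute_vcov else None
        return CumulativeLinkResults(self, theta, beta, vcov, -float(res.fun),
                                     converged, nit, res.x)

    def _observed_information_inverse(self, theta, beta):
        """Inverse observed information via central differences of the score
        in the direct (theta, beta) parametrisation."""
        d = self.design
        K = d.n_levels
        p0 = np.concatenate([theta, beta])
        m = p0.shape[0]

        def grad(p):
            th, be = p[:K - 1], p[K - 1:]
            _, gt, gb = _nll_and_grad(th, be, d.y, d.X, K)
            return np.concatenate([gt, gb])

        H = np.empty((m, m))
        h = 1e-5 * np.maximum(1.0, np.abs(p0))
        for j in range(m):
            e = np.zeros(m)
            e[j] = h[j]
            H[:, j] = (grad(p0 + e) - grad(p0 - e)) / (2.0 * h[j])
        H = 0.5 * (H + H.T)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; using pseudo-inverse",
                          UserWarning)
            return np.linalg.pinv(H)


class CumulativeLinkResults:
    """Fitted cumulative link model: estimates, uncertainty, predictions.

    Attributes
    ----------
    thresholds : ndarray
        Ordered cutpoints ``theta_1 < ... < theta_{K-1}`` (logit units).
    beta : pandas.Series
        Slope for the time term plus treatment-coded factor effects
        (reference levels are identically 0 and not listed).
    vcov : pandas.DataFrame
        Covariance of (thresholds, beta) from the observed information.
    llf : float
        Maximised log-likelihood.
    """

    def __init__(self, model: CumulativeLinkModel, thresholds, beta, vcov,
                 llf, converged, nit, params_raw):
        self.model = model
        self.design = model.design
        self.thresholds = np.asarray(thresholds, float)
        self.beta = pd.Series(np.asarray(beta, float), index=model.design.xnames)
        names = ([f"theta[{j + 1}]" for j in range(len(self.thresholds))]
                 + model.design.xnames)
        self.param_names = names
        self.vcov = (pd.DataFrame(vcov, index=names, columns=names)
                     if vcov is not None else None)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.nit = nit
        self.params_raw = params_raw
        self.nobs = model.design.y.shape[0]

    # -- accessors ------------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(np.concatenate([self.thresholds, self.beta.to_numpy()]),
                         index=self.param_names)

    @property
    def bse(self) -> pd.Series:
        if self.vcov is None:
            raise ValueError("fit was run with compute_vcov=False")
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=self.param_names)

    def factor_coef(self, factor: str, level) -> float:
        """Treatment-coded coefficient of ``level``; 0 for the reference."""
        lvls = self.design.levels[factor]
        if level not in lvls:
            raise KeyError(f"level {level!r} unknown to the fit for factor {factor!r}")
        if level == lvls[0]:
            return 0.0
        return float(self.beta[f"{factor}[{level}]"])

    @property
    def beta_time(self) -> float:
        term = self.design.spec.time_term
        if term is None:
            raise ValueError("model has no time term")
        return float(self.beta[term])

    # -- predictions ----------------------------------------------------------
    def _eta(self, time_value: float, levels: Mapping[str, Any]) -> float:
        eta = 0.0
        if self.design.spec.time_term is not None:
            eta = self.beta_time * float(time_value)
        for fac in self.design.levels:
            if fac not in levels:
                raise KeyError(f"factor {fac!r} requires a level for prediction")
            eta += self.factor_coef(fac, levels[fac])
        if self.design.spec.interaction:
            s, yr = levels["site"], levels["year"]
            name = f"site[{s}]:year[{yr}]"
            if name in self.beta.index:
                eta += float(self.beta[name])
        return eta

    def predict_exceedance(self, stage, time_value, **levels) -> float:
        """P(score >= stage) at one covariate point.

        ``stage`` is an original response label (e.g. 5 = peak pollen
        shedding); it must not be the lowest level (exceedance of the lowest
        level is trivially 1). Unknown factor levels raise ``KeyError``.
        """
        lvls = self.design.response_levels
        if stage not in lvls or stage == lvls[0]:
            raise ValueError(f"stage must be one of {lvls[1:]}")
        j = lvls.index(stage)
        eta = self._eta(time_value, levels)
        return float(1.0 - expit(self.thresholds[j - 1] - eta))

    def predict_categories(self, time_value, **levels) -> pd.Series:
        """Probability of each response category at one covariate point."""
        eta = self._eta(time_value, levels)
        cum = expit(self.thresholds - eta)
        probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
        return pd.Series(probs, index=self.design.response_levels)

    def exceedance_curve(self, stage, time_values, **levels) -> pd.Series:
        vals = [self.predict_exceedance(stage, t, **levels) for t in np.asarray(time_values)]
        return pd.Series(vals, index=np.asarray(time_values), name=f"P(score>={stage})")

    def plot_exceedance(self, stage, time_values, factor: str = "site", ax=None):
        """One exceedance curve per level of ``factor`` (other factors at
        their reference level)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        others = {f: lv[0] for f, lv in self.design.levels.items() if f != factor}
        for level in self.design.levels[factor]:
            curve = self.exceedance_curve(stage, time_values,
                                          **{factor: level, **others})
            ax.plot(curve.index, curve.to_numpy(), label=str(level))
        ax.set_xlabel(self.design.spec.time_term)
        ax.set_ylabel(f"P(score >= {stage})")
        ax.legend(title=factor)
        return ax

    def summary(self) -> str:
        lines = []
        d = self.design
        lines.append("Cumulative link model (logit)")
        lines.append(f"  response levels: {d.response_levels}   n_obs: {self.nobs}")
        lines.append(f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}"
                     f"   iterations: {self.nit}")
        lines.append("")
        header = f"{'parameter':<22}{'estimate':>12}{'std err':>12}"
        lines.append(header)
        lines.append("-" * len(header))
        se = self.bse if self.vcov is not None else None
        for name, val in self.params.items():
            s = f"{se[name]:>12.4f}" if se is not None else f"{'':>12}"
            lines.append(f"{name:<22}{val:>12.4f}{s}")
        for fac, lv in d.levels.items():
            lines.append(f"  reference {fac}: {lv[0]}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<CumulativeLinkResults llf={self.llf:.2f} nobs={self.nobs} "
                f"converged={self.converged}>")


def fit_clm(survey, spec: ClmSpec | None = None, **fit_options) -> CumulativeLinkResults:
    """Convenience wrapper: build the model from a survey and fit it."""
    return CumulativeLinkModel(survey, spec).fit(**fit_options)
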