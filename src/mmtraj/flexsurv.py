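"""Flexible parametric (Royston-Parmar) survival on the log cumulative
hazard scale, with delayed-entry episodes for time-updating covariates.

The model is

    ln H(t | x) = s(ln t; gamma) + x' beta,

where s is a restricted (natural) cubic spline in log time with ``spline_df``
basis terms beyond the intercept: interior knots sit at equally spaced
centiles of the uncensored log event times and boundary knots at their
extremes.  ``spline_df = 1`` reduces to a Weibull model.

Each counting-process episode (start, stop, event, x) contributes the
standard left-truncated log-likelihood term

    d * ln h(stop) + ln S(stop) - ln S(start),

with h(t) = H(t) * s'(ln t) / t, so a subject's covariates may change at
episode boundaries (e.g. a yearly-updated dominant disease cluster).  The
likelihood is maximised by quasi-Newton optimisation with an analytic
gradient; standard errors come from the inverse observed information.

Optionally, non-proportional (time-dependent) effects are obtained by
interacting selected covariate columns with a second, smaller spline in log
time (``tvc_df``), which adds covariate-specific deviations to s.

Age enters through its own restricted cubic spline when requested; ordinal
deprivation and rurality enter as indicator variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

Z_95 = 1.959963984540054


class SurvivalError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# restricted cubic splines


@dataclass(frozen=True)
class RCSpline:
    """Restricted cubic spline basis: linear tails beyond boundary knots.

    ``knots`` ascending, length m+1 (boundary + m-1 interior).  The basis has
    m columns: u itself plus m-1 cubic terms

        v_j(u) = z_j^3+ - lam_j z_0^3+ - (1 - lam_j) z_m^3+,

    z_i = (u - k_i), lam_j = (k_m - k_j)/(k_m - k_0), each scaled by
    (k_m - k_0)^-2 for numerical conditioning.
    """

    knots: tuple[float, ...]

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def basis(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        k = np.asarray(self.knots)
        cols = [u]
        if len(k) > 2:
            span2 = (k[-1] - k[0]) ** 2
            for j in range(1, len(k) - 1):
                lam = (k[-1] - k[j]) / (k[-1] - k[0])
                term = (
                    np.clip(u - k[j], 0, None) ** 3
                    - lam * np.clip(u - k[0], 0, None) ** 3
                    - (1 - lam) * np.clip(u - k[-1], 0, None) ** 3
                )
                cols.append(term / span2)
        return np.column_stack(cols)

    def deriv(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        k = np.asarray(self.knots)
        cols = [np.ones_like(u)]
        if len(k) > 2:
            span2 = (k[-1] - k[0]) ** 2
            for j in range(1, len(k) - 1):
                lam = (k[-1] - k[j]) / (k[-1] - k[0])
                term = 3 * (
                    np.clip(u - k[j], 0, None) ** 2
                    - lam * np.clip(u - k[0], 0, None) ** 2
                    - (1 - lam) * np.clip(u - k[-1], 0, None) ** 2
                )
                cols.append(term / span2)
        return np.column_stack(cols)


def spline_from_quantiles(x: np.ndarray, df: int) -> RCSpline:
    """Spline with df basis terms: boundary knots at the extremes of ``x``,
    df-1 interior knots at equally spaced centiles."""
    if df < 1:
        raise SurvivalError("spline df must be >= 1")
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    knots = np.unique(knots)
    if len(knots) < 2:
        raise SurvivalError("degenerate knot placement: too few distinct values")
    return RCSpline(tuple(knots))


# --------------------------------------------------------------------------
# covariate design


@dataclass
class _Term:
    kind: str  # "dummies" | "linear" | "spline"
    column: str
    levels: list = field(default_factory=list)
    spline: RCSpline | None = None
    center: float = 0.0
    names: list = field(default_factory=list)


@dataclass
class CovariateDesign:
    terms: list[_Term]

    @property
    def names(self) -> list[str]:
        return [n for t in self.terms for n in t.names]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        cols = []
        for t in self.terms:
            x = data[t.column]
            if t.kind == "dummies":
                for lev in t.levels[1:]:
                    cols.append((x == lev).to_numpy(dtype=float))
            elif t.kind == "linear":
                cols.append(x.to_numpy(dtype=float) - t.center)
            else:
                cols.append(
                    self._spline_cols(t, x.to_numpy(dtype=float))
                )
        if not cols:
            return np.empty((len(data), 0))
        return np.column_stack(
            [c if c.ndim == 1 else c for c in cols]
        )

    @staticmethod
    def _spline_cols(t: _Term, x: np.ndarray) -> np.ndarray:
        return t.spline.basis(x)


def build_design(
    data: pd.DataFrame,
    covariates: tuple[str, ...],
    age_spline_df: int = 3,
    categorical: tuple[str, ...] = ("sex", "rurality", "deprivation_quintile", "cluster"),
    spline_cols: tuple[str, ...] = ("age_at_index",),
) -> CovariateDesign:
    """Build an encoder for the requested covariate columns.

    Categorical columns become indicators against their lowest level;
    ``age_at_index`` becomes a restricted cubic spline with ``age_spline_df``
    terms (linear if 1); remaining numeric columns enter linearly, centred.
    """
    terms: list[_Term] = []
    for c in covariates:
        if c in categorical:
            levels = sorted(pd.unique(data[c]))
            t = _Term("dummies", c, levels=levels)
            t.names = [f"{c}[{lev}]" for lev in levels[1:]]
        elif c in spline_cols and age_spline_df > 1:
            sp = spline_from_quantiles(data[c].to_numpy(dtype=float), age_spline_df)
            t = _Term("spline", c, spline=sp)
            t.names = [f"{c}_s{j + 1}" for j in range(sp.df)]
        else:
            t = _Term("linear", c, center=float(np.mean(data[c])))
            t.names = [c]
        terms.append(t)
    return CovariateDesign(terms)


# --------------------------------------------------------------------------
# model


@dataclass
class FlexSurvFit:
    gamma: np.ndarray  # intercept + time-spline coefficients
    beta: np.ndarray  # covariate coefficients (incl. tvc interactions)
    cov: np.ndarray  # joint covariance, [gamma, beta] order
    time_spline: RCSpline
    design: CovariateDesign
    spline_df: int
    loglik: float
    bic: float
    n_events: int
    n_episodes: int
    term_names: list[str]
    tvc_design: CovariateDesign | None = None
    tvc_spline: RCSpline | None = None
    converged: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.gamma, self.beta])

    def coefficient_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        names = [f"ls{j}" for j in range(len(self.gamma))] + self.term_names
        est = self.params
        return pd.DataFrame(
            {
                "term": names,
                "coef": est,
                "se": se,
                "ci_low": est - Z_95 * se,
                "ci_high": est + Z_95 * se,
            }
        )

    # -- prediction ---------------------------------------------------------

    def _eta(self, data: pd.DataFrame, t: np.ndarray) -> np.ndarray:
        """Linear predictor ln H(t | x) for paired rows/times."""
        u = np.log(t)
        B = np.column_stack([np.ones_like(u), self.time_spline.basis(u)])
        eta = B @ self.gamma
        X = self.design.transform(data)
        n_x = X.shape[1]
        eta = eta + X @ self.beta[:n_x]
        if self.tvc_design is not None:
            Z = self.tvc_design.transform(data)
            Btv = self.tvc_spline.basis(u)
            inter = np.einsum("ij,ik->ijk", Z, Btv).reshape(len(u), -1)
            eta = eta + inter @ self.beta[n_x:]
        return eta

    def predict_survival(self, data: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """S(t | x) for every row of ``data`` at every time; shape (n, T)."""
        times = np.asarray(times, dtype=float)
        out = np.empty((len(data), len(times)))
        for j, t in enumerate(times):
            eta = self._eta(data, np.full(len(data), t))
            out[:, j] = np.exp(-np.exp(eta))
        return out


def _episode_arrays(episodes: pd.DataFrame):
    t1 = episodes["stop"].to_numpy(dtype=float)
    t0 = episodes["start"].to_numpy(dtype=float)
    d = episodes["event"].to_numpy(dtype=float)
    if (t1 <= t0).any():
        raise SurvivalError("episodes must have start < stop")
    if (t1 <= 0).any():
        raise SurvivalError("episode stop times must be positive")
    return t0, t1, d


def fit_flexible_parametric(
    episodes: pd.DataFrame,
    spline_df: int = 6,
    covariates: tuple[str, ...] = ("cluster",),
    age_spline_df: int = 3,
    tvc: tuple[str, ...] = (),
    tvc_df: int = 2,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> FlexSurvFit:
    """Fit the log-cumulative-hazard spline model to a counting-process table.

    ``episodes`` needs columns start, stop, event plus every requested
    covariate.  ``tvc`` names covariates whose effects may vary with time
    (interacted with a ``tvc_df``-term log-time spline); off by default.
    """
    t0, t1, d = _episode_arrays(episodes)
    n_events = int(d.sum())
    if n_events < 1:
        raise SurvivalError("no events in the episode table")

    u1 = np.log(t1)
    event_u = u1[d == 1]
    time_spline = spline_from_quantiles(event_u, spline_df)

    B1 = np.column_stack([np.ones_like(u1), time_spline.basis(u1)])
    D1 = np.column_stack([np.zeros_like(u1), time_spline.deriv(u1)])
    entry = t0 > 0
    u0 = np.log(t0[entry])
    B0 = np.column_stack([np.ones_like(u0), time_spline.basis(u0)])

    design = build_design(episodes, covariates, age_spline_df=age_spline_df)
    X = design.transform(episodes)
    term_names = list(design.names)

    tvc_design = None
    tvc_spline = None
    if tvc:
        tvc_design = build_design(episodes, tvc, age_spline_df=1)
        tvc_spline = spline_from_quantiles(event_u, tvc_df)
        Z = tvc_design.transform(episodes)
        Btv1 = tvc_spline.basis(u1)
        Dtv1 = tvc_spline.deriv(u1)
        inter1 = np.einsum("ij,ik->ijk", Z, Btv1).reshape(len(u1), -1)
        dinter1 = np.einsum("ij,ik->ijk", Z, Dtv1).reshape(len(u1), -1)
        Btv0 = tvc_spline.basis(u0)
        inter0 = np.einsum(
            "ij,ik->ijk", Z[entry], Btv0
        ).reshape(int(entry.sum()), inter1.shape[1])
        X1 = np.hstack([X, inter1])
        X0 = np.hstack([X[entry], inter0])
        term_names += [
            f"{n}:t_s{j + 1}"
            for n in tvc_design.names
            for j in range(tvc_spline.df)
        ]
    else:
        dinter1 = None
        X1 = X
        X0 = X[entry]

    n_g = B1.shape[1]
    n_b = X1.shape[1]

    # full "eta" design and its log-time derivative, per episode row
    Z1 = np.hstack([B1, X1])
    Zd1 = np.hstack([D1, np.zeros((len(u1), n_b))])
    if dinter1 is not None:
        Zd1[:, n_g + X.shape[1] :] = dinter1
    Z0 = np.hstack([B0, X0])
    ev = d == 1
    Z1e, Zd1e = Z1[ev], Zd1[ev]
    u1e = u1[ev]

    def negll_grad(theta: np.ndarray):
        sprime = Zd1e @ theta
        if np.any(sprime <= 0):
            # infeasible: fitted hazard negative at an event; steer back
            pen = np.sum(np.clip(-sprime, 0, None) + 1e-3)
            grad = -(Zd1e.T @ (sprime <= 0).astype(float))
            return 1e8 * (1 + pen), grad * 1e8
        eta1 = Z1 @ theta
        eta1 = np.clip(eta1, -500, 500)
        H1 = np.exp(eta1)
        eta0 = np.clip(Z0 @ theta, -500, 500)
        H0 = np.exp(eta0)
        ll = (
            np.sum(np.log(sprime) + eta1[ev] - u1e)
            - H1.sum()
            + H0.sum()
        )
        grad = (
            Zd1e.T @ (1.0 / sprime)
            + Z1e.sum(axis=0)
            - Z1.T @ H1
            + Z0.T @ H0
        )
        return -ll, -grad

    theta0 = np.zeros(n_g + n_b)
    persontime = float(np.sum(t1 - t0))
    theta0[0] = np.log(max(n_events, 1) / persontime)
    theta0[1] = 1.0  # exponential start: ln H = ln(rate) + ln t

    res = minimize(
        negll_grad,
        theta0,
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    theta = res.x
    gnorm = float(np.linalg.norm(res.jac))
    if not res.success and gnorm > 1e-2 * max(1.0, abs(res.fun)):
        raise SurvivalError(
            f"flexible parametric fit did not converge (gradient norm {gnorm:.3g})"
        )

    # monotone cumulative hazard over the observed time range, every pattern
    grid = np.linspace(u1.min(), u1.max(), 101)
    Dg = np.column_stack([np.zeros_like(grid), time_spline.deriv(grid)])
    s_base = Dg @ theta[:n_g]
    if tvc:
        # worst-case deviation over the observed tvc covariate patterns
        Dtv = tvc_spline.deriv(grid)
        uniq = np.unique(Z, axis=0)
        dev = uniq @ (
            Dtv @ theta[n_g + X.shape[1] :].reshape(Z.shape[1], -1).T
        ).T  # patterns x grid
        monotone = np.all(s_base[None, :] + dev > 0)
    else:
        monotone = np.all(s_base > 0)
    if not monotone:
        raise SurvivalError(
            "fitted cumulative hazard is non-monotone over the observed "
            "time range for some covariate pattern"
        )

    hess = _numeric_hessian(lambda th: negll_grad(th)[1], theta)
    cov = _safe_inverse(hess)
    ll = -res.fun
    n_par = len(theta)
    bic = -2.0 * ll + n_par * np.log(max(n_events, 1))

    return FlexSurvFit(
        gamma=theta[:n_g],
        beta=theta[n_g:],
        cov=cov,
        time_spline=time_spline,
        design=design,
        spline_df=spline_df,
        loglik=float(ll),
        bic=float(bic),
        n_events=n_events,
        n_episodes=len(episodes),
        term_names=term_names,
        tvc_design=tvc_design,
        tvc_spline=tvc_spline,
        converged=bool(res.success),
    )


def _numeric_hessian(grad_fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        step = h * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += step
        tm = theta.copy()
        tm[i] -= step
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def hazard_ratios(fit: FlexSurvFit, prefix: str = "cluster") -> pd.DataFrame:
    """Hazard ratios exp(beta) with Wald 95% CIs for one categorical term.

    The reference level appears with HR 1 and empty CI bounds.
    """
    table = fit.coefficient_table()
    n_g = len(fit.gamma)
    rows = [
        {"term": f"{prefix}[ref]", "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan}
    ]
    for _, r in table.iloc[n_g:].iterrows():
        if r["term"].startswith(f"{prefix}[") and ":" not in r["term"]:
            rows.append(
                {
                    "term": r["term"],
                    "hr": float(np.exp(r["coef"])),
                    "ci_low": float(np.exp(r["ci_low"])),
                    "ci_high": float(np.exp(r["ci_high"])),
                }
            )
    return pd.DataFrame(rows)


def standardized_survival(
    fit: FlexSurvFit,
    population: pd.DataFrame,
    cluster: int,
    times: np.ndarray,
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Regression-standardised survival for one cluster.

    Every subject in ``population`` has their cluster covariate set to
    ``cluster``; the average of the predicted survival curves estimates the
    marginal curve "had everyone followed this trajectory".  The 95% CI uses
    the delta method on the joint coefficient covariance.
    """
    if len(population) == 0:
        raise SurvivalError("empty standardisation population")
    pop = population.copy()
    pop[cluster_col] = cluster
    times = np.asarray(times, dtype=float)
    n = len(pop)

    X = fit.design.transform(pop)
    rows = []
    for t in times:
        u = np.log(np.full(n, t))
        B = np.column_stack([np.ones(n), fit.time_spline.basis(u)])
        Zfull = np.hstack([B, X])
        if fit.tvc_design is not None:
            Zt = fit.tvc_design.transform(pop)
            Btv = fit.tvc_spline.basis(u)
            inter = np.einsum("ij,ik->ijk", Zt, Btv).reshape(n, -1)
            Zfull = np.hstack([Zfull, inter])
        eta = np.clip(Zfull @ fit.params, -500, 500)
        Hi = np.exp(eta)
        Si = np.exp(-Hi)
        s_bar = float(Si.mean())
        g = -(Hi * Si)[:, None] * Zfull
        g_bar = g.mean(axis=0)
        var = float(g_bar @ fit.cov @ g_bar)
        se = np.sqrt(max(var, 0.0))
        rows.append(
            {
                "cluster": cluster,
                "t": float(t),
                "s": s_bar,
                "ci_low": max(s_bar - Z_95 * se, 0.0),
                "ci_high": min(s_bar + Z_95 * se, 1.0),
            }
        )
    return pd.DataFrame(rows)
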