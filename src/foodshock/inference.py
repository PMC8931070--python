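"""Regression analyses linking network position to simulated demand deficits.

Three estimators mirror the three outcome types produced by the shock grid:

* a left-censored-at-zero (Tobit) maximum-likelihood regression for the
  dyadic per-capita deficits, which are zero for most country pairs;
* an NB2 negative-binomial regression for threshold-exceedance counts;
* OLS for the continuous log rank-sum vulnerability score.

All three report heteroskedasticity-robust (HC1 sandwich) standard errors.
The Tobit likelihood is maximized in the Olsen reparametrization
(delta = beta/sigma, gamma = 1/sigma), in which the log-likelihood is
globally concave, then mapped back to (beta, sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from statsmodels.tools.numdiff import approx_hess

from .experiments import ExperimentGrid
from .network import DAYS_PER_YEAR, TradeNetwork

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised on degenerate designs or unfittable outcomes."""


@dataclass
class RegressionResult:
    """Coefficients, robust standard errors and fit statistics."""

    model: str
    params: pd.Series
    bse: pd.Series
    nobs: int
    stats: dict[str, float]
    exog_sd: pd.Series  # sample SD of each design column
    is_indicator: pd.Series  # True for 0/1 columns
    cov: np.ndarray | None = None

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "robust_se": self.bse, "t": self.tvalues}
        )


# --------------------------------------------------------------------------
# dyadic design table

#: per-country covariates entering the dyadic design, and how they are
#: transformed (Table conventions: clustering and pagerank scaled by 1000,
#: betweenness log(1 + x), strengths log(1 + x))
_NODE_COVS = (
    "in_degree",
    "out_degree",
    "log_in_strength",
    "log_out_strength",
    "hub",
    "log_betweenness",
    "pagerank_x1000",
    "clustering_x1000",
)


def _transformed_features(features: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=features.index)
    out["in_degree"] = features["in_degree"].astype(float)
    out["out_degree"] = features["out_degree"].astype(float)
    out["log_in_strength"] = np.log1p(features["in_strength"])
    out["log_out_strength"] = np.log1p(features["out_strength"])
    out["hub"] = features["hub"]
    out["log_betweenness"] = np.log1p(features["betweenness"])
    out["pagerank_x1000"] = features["pagerank"] * 1000.0
    out["clustering_x1000"] = features["clustering"] * 1000.0
    return out


def build_dyadic_table(
    grid: ExperimentGrid,
    features: pd.DataFrame,
    network: TradeNetwork,
    shock_transform: str = "log",
) -> pd.DataFrame:
    """One row per (origin, destination, alpha) with regression covariates.

    The dependent ``dd`` is the final deficit in kcal/person/day.  The
    shock covariate is the origin's shock expressed per destination capita
    per day, log-transformed by default (``shock_transform="level"`` keeps
    the level).  Distance regime indicators are computed on the baseline
    directed graph: ``domestic`` (i == j), ``indirect`` (finite directed
    distance >= 2) and ``no_direct_link`` (no directed path); the omitted
    baseline is a direct origin->destination edge.
    """
    if grid.network_hash != network.content_hash():
        raise FitError("grid was computed on a different network")
    if shock_transform not in ("log", "level"):
        raise ValueError("shock_transform must be 'log' or 'level'")

    codes = network.codes
    n = network.n
    g = network.to_networkx()
    dist = np.full((n, n), np.inf)
    for i, o in enumerate(codes):
        lengths = nx.single_source_shortest_path_length(g, o)
        for d, ln in lengths.items():
            dist[i, network.index(d)] = ln

    tf = _transformed_features(features.loc[codes])
    pcgdp = network.gdp / network.population
    pop = network.population

    frames = []
    for k, a in enumerate(grid.alphas):
        D = grid.dd[k]
        oi, dj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        oi = oi.ravel()
        dj = dj.ravel()
        shock_percap = grid.shock[oi] / (pop[dj] * DAYS_PER_YEAR)
        df = pd.DataFrame(
            {
                "origin": np.array(codes)[oi],
                "dest": np.array(codes)[dj],
                "alpha": a,
                "dd": D.ravel(),
                "log_pcgdp_dest": np.log(pcgdp[dj]),
                "shock": (
                    np.log1p(shock_percap)
                    if shock_transform == "log"
                    else shock_percap
                ),
                "c4_dest": features["c4"].values[dj],
                "domestic": (oi == dj).astype(float),
                "indirect": (
                    np.isfinite(dist[oi, dj]) & (dist[oi, dj] >= 2)
                ).astype(float),
                "no_direct_link": (~np.isfinite(dist[oi, dj])).astype(float),
            }
        )
        for cov in _NODE_COVS:
            df[f"orig_{cov}"] = tf[cov].values[oi]
            df[f"dest_{cov}"] = tf[cov].values[dj]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    # alpha dummies, first level omitted
    for a in grid.alphas[1:]:
        table[f"alpha_{a:g}"] = (table["alpha"] == a).astype(float)
    return table


def dyadic_covariates(grid: ExperimentGrid) -> list[str]:
    """Default covariate list for the dyadic censored regression."""
    cols = [
        "log_pcgdp_dest",
        "shock",
        "c4_dest",
        "domestic",
        "indirect",
        "no_direct_link",
    ]
    cols += [f"orig_{c}" for c in _NODE_COVS]
    cols += [f"dest_{c}" for c in _NODE_COVS]
    cols += [f"alpha_{a:g}" for a in grid.alphas[1:]]
    return cols


def count_covariates(grid: ExperimentGrid) -> list[str]:
    """Default covariate list for the vulnerability count / rank models."""
    return [
        "log_pcgdp",
        "in_degree",
        "out_degree",
        "log_in_strength",
        "log_out_strength",
        "c4",
        "clustering_x1000",
        "log_betweenness",
        "hub",
        "pagerank_x1000",
    ] + [f"alpha_{a:g}" for a in grid.alphas[1:]]


def build_country_table(
    per_country: pd.DataFrame,
    features: pd.DataFrame,
    network: TradeNetwork,
    response: str,
) -> pd.DataFrame:
    """Merge a per-(country, alpha) outcome with baseline node covariates.

    ``per_country`` must have columns (id, alpha, <response>).  Covariates
    are pre-shock network measures, so they do not vary with alpha; alpha
    enters as dummies.
    """
    tf = _transformed_features(features)
    tf["c4"] = features["c4"]
    tf["hub"] = features["hub"]
    pcgdp = pd.Series(
        network.gdp / network.population, index=network.codes
    )
    tf["log_pcgdp"] = np.log(pcgdp)
    df = per_country.merge(tf, left_on="id", right_index=True, how="left")
    alphas = sorted(df["alpha"].unique())
    for a in alphas[1:]:
        df[f"alpha_{a:g}"] = (df["alpha"] == a).astype(float)
    return df


# --------------------------------------------------------------------------
# design helpers


def prune_covariates(table: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Drop constant and collinear covariates, keeping first-come columns.

    Needed on small or highly regular networks where some regime indicator
    never switches on (e.g. no country pair at infinite distance when the
    graph has diameter 2).
    """
    keep: list[str] = []
    X = np.ones((len(table), 1))
    for c in covariates:
        col = table[c].to_numpy(dtype=float)[:, None]
        if np.std(col) == 0:
            continue
        cand = np.column_stack([X, col])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            keep.append(c)
            X = cand
    return keep


def _design(
    table: pd.DataFrame, covariates: list[str], add_const: bool = True
) -> tuple[np.ndarray, list[str]]:
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise FitError(f"covariates not in table: {missing}")
    X = table[covariates].to_numpy(dtype=float)
    names = list(covariates)
    if add_const:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["const"] + names
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.where(diag <= tol)[0]]
        raise FitError(f"singular design; collinear columns: {bad}")


def _sd_meta(
    table: pd.DataFrame, names: list[str]
) -> tuple[pd.Series, pd.Series]:
    sds, inds = {}, {}
    for nm in names:
        if nm == "const":
            sds[nm] = 0.0
            inds[nm] = True
            continue
        col = table[nm].to_numpy(dtype=float)
        sds[nm] = float(np.std(col, ddof=1))
        inds[nm] = bool(np.isin(np.unique(col), [0.0, 1.0]).all())
    return pd.Series(sds), pd.Series(inds)


# --------------------------------------------------------------------------
# Tobit


def _tobit_negll_olsen(theta, X, y, cens):
    """Negative log-likelihood in (delta, gamma); globally convex."""
    delta = theta[:-1]
    gamma = theta[-1]
    if gamma <= 0:  # infeasible line-search trial
        return np.inf
    xb = X @ delta
    ll = np.empty(len(y))
    ll[cens] = log_ndtr(-xb[cens])
    r = gamma * y[~cens] - xb[~cens]
    ll[~cens] = np.log(gamma) - _LOG_SQRT_2PI - 0.5 * r * r
    return -ll.sum()


def _tobit_negll_grad_olsen(theta, X, y, cens):
    delta = theta[:-1]
    gamma = theta[-1]
    if gamma <= 0:
        return np.zeros_like(theta)
    xb = X @ delta
    g_delta = np.zeros(len(delta))
    # censored rows: d/d delta log Phi(-x d) = -x * mills(-x d)
    u = -xb[cens]
    mills = np.exp(_log_norm_pdf(u) - log_ndtr(u))
    g_delta -= X[cens].T @ mills
    # uncensored rows
    r = gamma * y[~cens] - xb[~cens]
    g_delta += X[~cens].T @ r
    g_gamma = (~cens).sum() / gamma - r @ y[~cens]
    return -np.concatenate([g_delta, [g_gamma]])


def _log_norm_pdf(u):
    return -_LOG_SQRT_2PI - 0.5 * u * u


def _tobit_negll_hess_olsen(theta, X, y, cens):
    """Analytic Hessian of the negative log-likelihood in (delta, gamma)."""
    delta = theta[:-1]
    gamma = theta[-1]
    p = len(delta)
    xb = X @ delta
    H = np.zeros((p + 1, p + 1))
    # censored block: d2/ddelta2 log Phi(-x d) = m'(u) x x^T with
    # m(u) = phi/Phi and m'(u) = -u m - m^2  (negative)
    u = -xb[cens]
    m = np.exp(_log_norm_pdf(u) - log_ndtr(u))
    mprime = -u * m - m * m
    Xc = X[cens]
    H[:p, :p] += Xc.T @ (mprime[:, None] * Xc)
    # uncensored block: l = log(gamma) - r^2/2 with r = gamma y - x delta
    Xu = X[~cens]
    yu = y[~cens]
    H[:p, :p] -= Xu.T @ Xu
    H[:p, p] = H[p, :p] = Xu.T @ yu
    H[p, p] = -(~cens).sum() / gamma**2 - yu @ yu
    return -H


def _newton_maximize(negll, grad, hess, theta0, maxiter=200, gtol=1e-8):
    """Damped Newton descent on a convex objective with gamma > 0."""
    theta = theta0.copy()
    f = negll(theta)
    for _ in range(maxiter):
        g = grad(theta)
        if np.linalg.norm(g, ord=np.inf) < gtol * max(1.0, abs(f)):
            break
        H = hess(theta)
        try:
            direction = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            direction = -g
        if g @ direction > 0:  # not a descent direction (should not happen)
            direction = -g
        t = 1.0
        for _ in range(60):
            cand = theta + t * direction
            fc = negll(cand)
            if np.isfinite(fc) and fc <= f + 1e-4 * t * (g @ direction):
                theta, f = cand, fc
                break
            t *= 0.5
        else:
            break
    return theta, f


def _tobit_loglike_obs(beta, sigma, X, y, cens):
    xb = X @ beta
    ll = np.empty(len(y))
    ll[cens] = log_ndtr(-xb[cens] / sigma)
    r = (y[~cens] - xb[~cens]) / sigma
    ll[~cens] = -np.log(sigma) - _LOG_SQRT_2PI - 0.5 * r * r
    return ll


def _tobit_score_obs(beta, sigma, X, y, cens):
    """Per-observation scores in (beta, sigma)."""
    n, p = X.shape
    S = np.zeros((n, p + 1))
    xb = X @ beta
    u = -xb[cens] / sigma
    mills = np.exp(_log_norm_pdf(u) - log_ndtr(u))
    S[cens, :p] = -X[cens] * (mills / sigma)[:, None]
    S[cens, p] = mills * xb[cens] / sigma**2
    e = (y[~cens] - xb[~cens]) / sigma
    S[~cens, :p] = X[~cens] * (e / sigma)[:, None]
    S[~cens, p] = (e**2 - 1.0) / sigma
    return S


def tobit_fit(
    table: pd.DataFrame,
    covariates: list[str],
    response: str = "dd",
    add_const: bool = True,
) -> RegressionResult:
    """Left-censored-at-zero Gaussian MLE with HC1 sandwich errors.

    Rows with response == 0 contribute Phi(-x beta / sigma) to the
    likelihood, uncensored rows the Gaussian density.  Optimization runs in
    the concave Olsen parametrization from a least-squares start; with no
    censored rows the estimate coincides with OLS.  Refuses an all-censored
    outcome.  The reported pseudo R-squared is McFadden's 1 - ll/ll0
    against an intercept-only censored model.
    """
    y = table[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise FitError("response must be >= 0 for left censoring at zero")
    cens = y == 0
    if cens.all():
        raise FitError("all observations censored at zero; nothing to fit")
    X, names = _design(table, covariates, add_const)
    n, p = X.shape

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = max(np.std(resid), 1e-8)
    theta0 = np.concatenate([beta0 / sigma0, [1.0 / sigma0]])

    theta, _ = _newton_maximize(
        lambda t: _tobit_negll_olsen(t, X, y, cens),
        lambda t: _tobit_negll_grad_olsen(t, X, y, cens),
        lambda t: _tobit_negll_hess_olsen(t, X, y, cens),
        theta0,
    )
    gamma = theta[-1]
    if gamma <= 0:
        raise FitError("Tobit scale collapsed (gamma <= 0)")
    sigma = 1.0 / gamma
    beta = theta[:-1] * sigma

    # sandwich covariance in the (beta, sigma) parametrization
    S = _tobit_score_obs(beta, sigma, X, y, cens)
    theta_bs = np.concatenate([beta, [sigma]])
    H = approx_hess(
        theta_bs,
        lambda th: _tobit_loglike_obs(th[:-1], th[-1], X, y, cens).sum(),
    )
    Hinv = np.linalg.inv(-H)
    B = S.T @ S
    k = p + 1
    cov = Hinv @ B @ Hinv * (n / (n - k))
    bse = np.sqrt(np.diag(cov))

    ll = _tobit_loglike_obs(beta, sigma, X, y, cens).sum()
    ll0 = _tobit_null_loglike(y, cens)
    pseudo_r2 = 1.0 - ll / ll0 if ll0 != 0 else float("nan")

    idx = names + ["sigma"]
    sds, inds = _sd_meta(table, names)
    return RegressionResult(
        model="tobit",
        params=pd.Series(np.append(beta, sigma), index=idx),
        bse=pd.Series(bse, index=idx),
        nobs=n,
        stats={
            "loglike": float(ll),
            "loglike_null": float(ll0),
            "pseudo_r2": float(pseudo_r2),
            "n_censored": int(cens.sum()),
            "sigma": float(sigma),
        },
        exog_sd=sds,
        is_indicator=inds,
        cov=cov,
    )


def _tobit_null_loglike(y, cens):
    """Intercept-only censored-normal maximum log-likelihood."""
    X0 = np.ones((len(y), 1))

    def nll(theta):
        return _tobit_negll_olsen(theta, X0, y, cens)

    mu0 = y[~cens].mean()
    s0 = max(y[~cens].std(), 1e-8)
    res = optimize.minimize(
        nll,
        np.array([mu0 / s0, 1.0 / s0]),
        jac=lambda t: _tobit_negll_grad_olsen(t, X0, y, cens),
        method="BFGS",
        options={"maxiter": 1000},
    )
    return -res.fun


# --------------------------------------------------------------------------
# negative binomial and OLS


def negbin_fit(
    table: pd.DataFrame,
    covariates: list[str],
    response: str = "count",
    add_const: bool = True,
) -> RegressionResult:
    """NB2 count regression (variance mu + kappa mu^2) with HC1 errors.

    Falls back to Poisson (with a warning) when the estimated dispersion is
    at the zero boundary, where the NB2 information matrix degenerates.
    Refuses an all-zero count outcome.
    """
    y = table[response].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise FitError("response must be nonnegative integers")
    if (y == 0).all():
        raise FitError("all counts are zero; nothing to fit")
    X, names = _design(table, covariates, add_const)

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(
                cov_type="HC1", disp=0, maxiter=500, method="bfgs"
            )
            kappa = float(fit.params[-1])
        except Exception:
            fit, kappa = None, 0.0

    if fit is None or kappa < 1e-4 or not np.isfinite(fit.bse).all():
        warnings.warn(
            "dispersion at the Poisson boundary; refitting as Poisson",
            stacklevel=2,
        )
        pfit = sm.Poisson(y, X).fit(cov_type="HC1", disp=0, maxiter=500)
        params = pd.Series(pfit.params, index=names)
        bse = pd.Series(pfit.bse, index=names)
        stats = {
            "loglike": float(pfit.llf),
            "dispersion": 0.0,
            "family": 0.0,  # 0 = Poisson fallback
        }
        nobs = int(pfit.nobs)
    else:
        idx = names + ["dispersion"]
        params = pd.Series(fit.params, index=idx)
        bse = pd.Series(fit.bse, index=idx)
        stats = {
            "loglike": float(fit.llf),
            "dispersion": kappa,
            "family": 1.0,  # 1 = NB2
        }
        nobs = int(fit.nobs)

    sds, inds = _sd_meta(table, names)
    return RegressionResult(
        model="negbin",
        params=params,
        bse=bse,
        nobs=nobs,
        stats=stats,
        exog_sd=sds,
        is_indicator=inds,
    )


def ols_fit(
    table: pd.DataFrame,
    covariates: list[str],
    response: str,
    add_const: bool = True,
) -> RegressionResult:
    """Least squares with HC1 robust errors, R-squared and F statistic."""
    y = table[response].to_numpy(dtype=float)
    X, names = _design(table, covariates, add_const)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    sds, inds = _sd_meta(table, names)
    return RegressionResult(
        model="ols",
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        nobs=int(fit.nobs),
        stats={
            "r2": float(fit.rsquared),
            "f_stat": float(fit.fvalue),
            "loglike": float(fit.llf),
        },
        exog_sd=sds,
        is_indicator=inds,
    )


def standardize_coefficients(result: RegressionResult) -> pd.Series:
    """Per-SD display coefficients: slope times sample SD of its covariate.

    Indicator covariates (and the intercept) pass through unscaled;
    zero-variance non-indicator covariates are dropped with a note in the
    series attrs.  Rescaling a covariate rescales its SE identically, so
    t-statistics are unchanged.
    """
    out = {}
    dropped = []
    for nm in result.exog_sd.index:
        b = result.params[nm]
        if result.is_indicator[nm] or nm == "const":
            out[nm] = b
            continue
        sd = result.exog_sd[nm]
        if sd == 0:
            dropped.append(nm)
            continue
        out[nm] = b * sd
    s = pd.Series(out, name="std_coef")
    s.attrs["dropped_zero_variance"] = dropped
    return s
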