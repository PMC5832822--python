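"""Diversity-disturbance inference.

Variable selection and model fitting for the site-level relationship

    alpha_i ~ Normal(theta0 + theta1*U_i + theta2*U_i**theta3
                     + theta4*Rain_i + theta5*Alt_i, sigma**2)

where ``U`` is the short-lived-pioneer (Urticaceae) stem frequency in
percent, the disturbance indicator.  ``theta3 = 2`` gives the classical
quadratic hump; leaving ``theta3`` free and inferring it by MCMC tests the
robustness of the unimodal diversity-disturbance pattern.  Because alpha is
itself estimated by Monte-Carlo simulation of species composition, one
alpha realization per site is redrawn from the composition draws at every
MCMC iteration, so identification uncertainty propagates into the
posterior.

Also here: BIC-weighted Bayesian model averaging with posterior inclusion
probabilities, bidirectional stepwise AIC selection, empirical variograms
for residual spatial-autocorrelation checks, and Pearson correlation
reports.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "bma_pip",
    "stepwise_aic",
    "fit_idh_quadratic",
    "fit_idh_power",
    "peak_and_shape",
    "empirical_variogram",
    "pearson_cor",
    "BMAResult",
    "StepwiseResult",
    "QuadraticFit",
    "ModelPosterior",
    "MCMCSettings",
    "PeakSummary",
    "CorrelationResult",
]


# ---------------------------------------------------------------------------
# Bayesian model averaging


@dataclasses.dataclass
class BMAResult:
    """Posterior inclusion probabilities from full model enumeration."""

    pip: pd.Series                 # per predictor, in [0, 1]
    model_probs: pd.DataFrame      # columns: predictors (tuple), prob

    def top_models(self, k: int = 5) -> pd.DataFrame:
        return self.model_probs.nlargest(k, "prob").reset_index(drop=True)


def bma_pip(X: pd.DataFrame, y: np.ndarray,
            max_predictors: int = 20) -> BMAResult:
    """Enumerate every predictor subset, weight by exp(-BIC/2), normalize.

    The uniform model prior with BIC weights approximates posterior model
    probabilities; a predictor's PIP is the summed probability of the
    models containing it.  Limited to full enumeration (p <= 20 by
    default); larger candidate sets should be screened first.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= 3:
        raise ValueError("need more than 3 observations")
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors exceed the enumeration limit {max_predictors}; "
            "screen the candidate set first")
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    ridge_warned = False

    bics = np.empty(2 ** p)
    subsets = []
    for m, subset in enumerate(itertools.chain.from_iterable(
            itertools.combinations(range(p), k) for k in range(p + 1))):
        subsets.append(subset)
        D = np.column_stack([np.ones(n), Xv[:, list(subset)]])
        k = D.shape[1]
        beta, res, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < k:
            if not ridge_warned:
                warnings.warn("rank-deficient design; using a ridge fallback",
                              stacklevel=2)
                ridge_warned = True
            beta = np.linalg.solve(D.T @ D + 1e-8 * np.eye(k), D.T @ y)
        rss = float(np.sum((y - D @ beta) ** 2))
        rss = max(rss, 1e-300)
        bics[m] = n * np.log(rss / n) + (k + 1) * np.log(n)

    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    pip = pd.Series(0.0, index=cols)
    for subset, wm in zip(subsets, w):
        for j in subset:
            pip.iloc[j] += wm
    model_probs = pd.DataFrame({
        "predictors": [tuple(cols[j] for j in s) for s in subsets],
        "prob": w,
    })
    return BMAResult(pip=pip, model_probs=model_probs)


# ---------------------------------------------------------------------------
# Stepwise AIC


@dataclasses.dataclass
class StepwiseResult:
    terms: list
    aic: float
    adj_r2: float
    coefficients: pd.DataFrame      # estimate, std err, t, p per term
    anova: pd.DataFrame             # sequential F per term
    model: object                   # fitted statsmodels results


def _ols(data: pd.DataFrame, response: str, terms: Sequence[str]):
    X = sm.add_constant(data[list(terms)], has_constant="add") \
        if terms else pd.DataFrame({"const": np.ones(len(data))},
                                   index=data.index)
    return sm.OLS(data[response], X).fit()


def stepwise_aic(data: pd.DataFrame, response: str,
                 candidate_terms: Sequence[str],
                 hierarchy: Mapping[str, str] | None = None) -> StepwiseResult:
    """Bidirectional add/drop search to a local AIC minimum.

    ``hierarchy`` maps a quadratic term to its linear parent: the quadratic
    can only enter while the parent is in the model, and the parent cannot
    leave while its quadratic stays.  Ties are broken toward the smaller
    model.  The returned ``anova`` table holds sequential (type I) F tests
    in selection order.
    """
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    hierarchy = dict(hierarchy or {})
    current: list[str] = []
    current_fit = _ols(data, response, current)
    order: list[str] = []

    while True:
        moves = []  # (aic, prefer_drop_rank, terms, added_term)
        for t in candidate_terms:
            if t in current:
                continue
            parent = hierarchy.get(t)
            if parent is not None and parent not in current:
                continue
            trial = current + [t]
            moves.append((_ols(data, response, trial).aic, 1, trial, t))
        quad_of = {v: k for k, v in hierarchy.items()}
        for t in current:
            dep = quad_of.get(t)
            if dep is not None and dep in current:
                continue
            trial = [u for u in current if u != t]
            moves.append((_ols(data, response, trial).aic, 0, trial, None))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], len(m[2])))
        best_aic, _, best_terms, added = moves[0]
        if best_aic < current_fit.aic - 1e-10:
            current = best_terms
            current_fit = _ols(data, response, current)
            if added is not None:
                order.append(added)
            order = [t for t in order if t in current]
        else:
            break

    fit = current_fit
    coef = pd.DataFrame({
        "estimate": fit.params,
        "std_err": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    anova = _sequential_anova(data, response, order)
    adj_r2 = float(fit.rsquared_adj) if current else 0.0
    return StepwiseResult(terms=list(current), aic=float(fit.aic),
                          adj_r2=adj_r2, coefficients=coef, anova=anova,
                          model=fit)


def _sequential_anova(data: pd.DataFrame, response: str,
                      order: Sequence[str]) -> pd.DataFrame:
    """Type I (sequential) F tests, terms entered in the given order."""
    if not order:
        return pd.DataFrame(columns=["term", "ss", "F", "p"])
    n = len(data)
    full = _ols(data, response, order)
    mse = full.ssr / full.df_resid
    rows = []
    prev_rss = float(np.sum((data[response] - data[response].mean()) ** 2))
    for i, term in enumerate(order):
        rss = _ols(data, response, order[:i + 1]).ssr
        ss = prev_rss - rss
        F = ss / mse
        rows.append({"term": term, "ss": ss, "F": F,
                     "p": float(stats.f.sf(F, 1, full.df_resid))})
        prev_rss = rss
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quadratic diversity model


@dataclasses.dataclass
class QuadraticFit:
    """OLS fit of alpha on urti, urti^2, rainfall and elevation."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    adj_r2: float
    peak_u: float | None      # vertex -theta1/(2*theta2), percent
    model: object

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "std_err": self.bse,
                             "t": self.tvalues})


def fit_idh_quadratic(site_table: pd.DataFrame,
                      response: str = "alpha_mean") -> QuadraticFit:
    """Least-squares hump model: ``alpha ~ U + U^2 + rainfall + elevation``.

    ``U`` is the Urticaceae stem frequency in percent.  When the quadratic
    coefficient is negative the diversity peak sits at the vertex
    ``U* = -theta1 / (2 * theta2)``; otherwise the peak is undefined and
    reported as None.
    """
    if len(site_table) < 6:
        raise ValueError("need at least 6 sites")
    df = site_table.copy()
    df["urti_pct2"] = df["urti_pct"] ** 2
    terms = ["urti_pct", "urti_pct2", "rainfall_mm", "elevation_m"]
    fit = _ols(df, response, terms)
    t1 = fit.params["urti_pct"]
    t2 = fit.params["urti_pct2"]
    peak = float(-t1 / (2.0 * t2)) if t2 < 0 else None
    return QuadraticFit(params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
                        adj_r2=float(fit.rsquared_adj), peak_u=peak,
                        model=fit)


# ---------------------------------------------------------------------------
# Free-power Bayesian model


@dataclasses.dataclass
class MCMCSettings:
    chains: int = 4
    draws: int = 2000
    warmup: int = 2000
    seed: int = 0
    fix_power: float | None = None   # pin theta3 (e.g. 2.0) instead of sampling
    ess_floor: float = 100.0


@dataclasses.dataclass
class PowerPriors:
    """Weakly informative priors on the standardized-covariate scale."""

    coef_sd: float = 100.0           # Normal(0, coef_sd^2) on theta1..theta5
    intercept_sd: float = 100.0      # Normal(ybar, intercept_sd^2) on theta0
    power_bounds: tuple = (0.5, 5.0)  # Uniform on theta3
    sigma_scale: float = 50.0        # Half-Normal(0, sigma_scale^2) on sigma


@dataclasses.dataclass
class ModelPosterior:
    """MCMC samples of (theta0..theta5, sigma) in raw covariate units."""

    samples: pd.DataFrame            # columns: chain, draw, theta0..theta5, sigma
    accept_rate: float
    ess: dict
    converged: bool
    settings: MCMCSettings

    PARAM_NAMES = ("theta0", "theta1", "theta2", "theta3", "theta4",
                   "theta5", "sigma")

    def median(self) -> pd.Series:
        return self.samples[list(self.PARAM_NAMES)].median()

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        lo = (1.0 - level) / 2.0
        q = self.samples[list(self.PARAM_NAMES)].quantile([lo, 1.0 - lo]).T
        q.columns = ["lower", "upper"]
        return q


def _power_design(site_table: pd.DataFrame):
    u = site_table["urti_pct"].to_numpy(dtype=float)
    rain = site_table["rainfall_mm"].to_numpy(dtype=float)
    alt = site_table["elevation_m"].to_numpy(dtype=float)
    rain_mu, rain_sd = rain.mean(), rain.std(ddof=0)
    alt_mu, alt_sd = alt.mean(), alt.std(ddof=0)
    if rain_sd == 0 or alt_sd == 0:
        raise ValueError("rainfall/elevation must vary across sites")
    return u, (rain - rain_mu) / rain_sd, (alt - alt_mu) / alt_sd, \
        (rain_mu, rain_sd, alt_mu, alt_sd)


def fit_idh_power(site_table: pd.DataFrame,
                  alpha_draws: np.ndarray | None = None,
                  priors: PowerPriors | None = None,
                  settings: MCMCSettings | None = None,
                  response: str = "alpha_mean") -> ModelPosterior:
    """Posterior of the power-term diversity model by blocked Gibbs MCMC.

    Given the exponent ``theta3`` and ``sigma`` the model is linear, so the
    five regression coefficients get an exact conjugate multivariate-normal
    Gibbs draw each iteration; ``theta3`` and ``log sigma`` move by 1-D
    random-walk Metropolis steps whose scales adapt (Robbins-Monro, target
    44% acceptance) during warmup and freeze afterwards.  The power-term
    column is RMS-normalized internally (``u**theta3 / rms(u**theta3)``) so
    the sampled coefficient is only weakly coupled to the exponent; samples
    are mapped back to the raw ``theta2`` scale on output.  Rainfall and
    elevation are z-scored internally and reported back in raw per-mm /
    per-m units; ``U`` stays in percent.

    ``alpha_draws`` is an (n_draws, n_sites) matrix of per-site Fisher's
    alpha composition draws; at every iteration each site's response is
    redrawn from its column, propagating identification uncertainty into
    the posterior (with None the point response in ``site_table[response]``
    is used throughout).

    Convergence is flagged via the bulk effective sample size of every
    parameter (floor in ``settings.ess_floor``).
    """
    priors = priors or PowerPriors()
    settings = settings or MCMCSettings()
    u, rain_z, alt_z, (rain_mu, rain_sd, alt_mu, alt_sd) = \
        _power_design(site_table)
    n = len(u)
    y_point = site_table[response].to_numpy(dtype=float)
    if alpha_draws is not None:
        alpha_draws = np.asarray(alpha_draws, dtype=float)
        if alpha_draws.shape[1] != n:
            raise ValueError("alpha_draws must have one column per site")
    ybar = y_point.mean()
    fix_power = settings.fix_power
    lo3, hi3 = priors.power_bounds
    if fix_power is not None and not lo3 <= fix_power <= hi3:
        raise ValueError(f"fix_power={fix_power} outside prior bounds")

    prior_mean = np.array([ybar, 0.0, 0.0, 0.0, 0.0])
    prior_prec = np.diag(
        np.array([priors.intercept_sd] + [priors.coef_sd] * 4) ** -2.0)

    def basis(th3: float) -> tuple[np.ndarray, float]:
        pw = u ** th3
        r = np.sqrt(np.mean(pw * pw))
        return np.column_stack([np.ones(n), u, pw / r, rain_z, alt_z]), r

    def loglik(resid: np.ndarray, sigma: float) -> float:
        return -n * np.log(sigma) - 0.5 * np.dot(resid, resid) / sigma**2

    def marginal_loglik(X: np.ndarray, sigma: float, y: np.ndarray) -> float:
        """log p(y | theta3, sigma) with the linear block integrated out
        (Woodbury/determinant-lemma form, 5x5 linear algebra only)."""
        r = y - X @ prior_mean
        Xtr = X.T @ r
        A = prior_prec + X.T @ X / sigma**2
        cA = np.linalg.cholesky(A)
        w = np.linalg.solve(cA, Xtr)
        quad = np.dot(r, r) / sigma**2 - np.dot(w, w) / sigma**4
        logdet = 2.0 * n * np.log(sigma) + 2.0 * np.log(np.diag(cA)).sum()
        return -0.5 * (logdet + quad)

    all_chains = []
    accepts = 0
    total = 0
    root = np.random.SeedSequence([settings.seed, 6])
    for chain, ss in enumerate(root.spawn(settings.chains)):
        rng = np.random.default_rng(ss)
        th3 = fix_power if fix_power is not None else rng.uniform(1.5, 2.5)
        sigma = max(y_point.std(ddof=0), 1.0) * rng.uniform(0.5, 1.5)
        X, r3 = basis(th3)
        beta = np.zeros(5)
        beta[0] = ybar
        y = y_point
        s_th3, s_ls = 0.3, 0.3  # RW scales, adapted during warmup
        n_iter = settings.warmup + settings.draws
        out_rows = np.empty((settings.draws, 7))
        for it in range(n_iter):
            if alpha_draws is not None:
                y = alpha_draws[rng.integers(alpha_draws.shape[0], size=n),
                                np.arange(n)]
            # --- theta3: collapsed 1-D Metropolis (linear block
            #     marginalized out, so the exponent moves freely) ---------
            acc_t = False
            if fix_power is None:
                th3_p = th3 + s_th3 * rng.standard_normal()
                if lo3 < th3_p < hi3:
                    X_p, r3_p = basis(th3_p)
                    lp_cur = marginal_loglik(X, sigma, y)
                    lp_prop = marginal_loglik(X_p, sigma, y)
                    acc_t = np.log(rng.uniform()) < lp_prop - lp_cur
                    if acc_t:
                        th3, X, r3 = th3_p, X_p, r3_p
            # --- exact Gibbs draw of the linear block -------------------
            prec = X.T @ X / sigma**2 + prior_prec
            cf = np.linalg.cholesky(prec)
            m = np.linalg.solve(
                prec, X.T @ y / sigma**2 + prior_prec @ prior_mean)
            beta = m + np.linalg.solve(cf.T, rng.standard_normal(5))
            resid = y - X @ beta
            # --- log sigma: 1-D adaptive Metropolis ---------------------
            ls = np.log(sigma)
            ls_p = ls + s_ls * rng.standard_normal()
            sig_p = np.exp(ls_p)
            # Half-Normal(sigma_scale) prior plus the log-scale Jacobian
            cur = loglik(resid, sigma) - 0.5 * (sigma / priors.sigma_scale)**2 + ls
            prop = loglik(resid, sig_p) - 0.5 * (sig_p / priors.sigma_scale)**2 + ls_p
            acc_s = np.log(rng.uniform()) < prop - cur
            if acc_s:
                sigma = sig_p
            if it < settings.warmup:
                gain = 2.0 / (20.0 + it)
                s_ls *= np.exp(((1.0 if acc_s else 0.0) - 0.44) * gain)
                if fix_power is None:
                    s_th3 *= np.exp(((1.0 if acc_t else 0.0) - 0.44) * gain)
            else:
                j = it - settings.warmup
                out_rows[j] = (beta[0], beta[1], beta[2] / r3, th3,
                               beta[3], beta[4], sigma)
                if fix_power is None:
                    accepts += int(acc_t)
                    total += 1
                accepts += int(acc_s)
                total += 1
        df = pd.DataFrame(out_rows, columns=["b0", "theta1", "theta2",
                                             "theta3", "b4", "b5", "sigma"])
        df["chain"] = chain
        df["draw"] = np.arange(settings.draws)
        all_chains.append(df)

    out = pd.concat(all_chains, ignore_index=True)
    out["theta4"] = out["b4"] / rain_sd
    out["theta5"] = out["b5"] / alt_sd
    out["theta0"] = (out.pop("b0") - out.pop("b4") * rain_mu / rain_sd
                     - out.pop("b5") * alt_mu / alt_sd)
    out = out[["chain", "draw", "theta0", "theta1", "theta2", "theta3",
               "theta4", "theta5", "sigma"]]

    ess = _bulk_ess(out, settings.chains, settings.draws,
                    skip=("theta3",) if fix_power is not None else ())
    converged = all(v >= settings.ess_floor for v in ess.values())
    return ModelPosterior(samples=out, accept_rate=accepts / max(total, 1),
                          ess=ess, converged=converged, settings=settings)


def _bulk_ess(samples: pd.DataFrame, chains: int, draws: int,
              skip: tuple = ()) -> dict:
    import arviz as az
    ess = {}
    for name in ModelPosterior.PARAM_NAMES:
        if name in skip:
            continue
        arr = samples[name].to_numpy().reshape(chains, draws)
        ess[name] = float(az.ess(az.convert_to_dataset(arr)).x)
    return ess


# ---------------------------------------------------------------------------
# Peak location / unimodality


@dataclasses.dataclass
class PeakSummary:
    """Posterior of the disturbance level maximizing diversity."""

    u_star: np.ndarray        # argmax of the disturbance effect, percent
    gain: np.ndarray          # diversity gain at the argmax vs U = 0
    interior: np.ndarray      # True where the maximum is strictly interior

    @property
    def p_unimodal(self) -> float:
        return float(self.interior.mean())


def peak_and_shape(posterior: ModelPosterior | pd.DataFrame,
                   u_max: float = 6.5) -> PeakSummary:
    """Per-sample argmax of the disturbance effect on [0, u_max].

    The effect curve is ``g(U) = theta1*U + theta2*U**theta3``.  Samples
    with ``theta1 > 0, theta2 < 0, theta3 > 1`` have the interior critical
    point ``U* = (theta1 / (-theta2*theta3)) ** (1/(theta3-1))`` (the
    quadratic vertex when theta3 = 2); the argmax is taken over that
    candidate and the interval ends, and a sample counts as unimodal only
    when the winner is strictly interior.
    """
    df = posterior.samples if isinstance(posterior, ModelPosterior) else posterior
    t1 = df["theta1"].to_numpy(dtype=float)
    t2 = df["theta2"].to_numpy(dtype=float)
    t3 = df["theta3"].to_numpy(dtype=float)

    def g(Uv):
        return t1 * Uv + t2 * np.where(Uv > 0, Uv, 1.0) ** t3 * (Uv > 0)

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        valid = (t1 > 0) & (t2 < 0) & (t3 > 1)
        u_c = np.where(valid,
                       (t1 / np.where(valid, -t2 * t3, 1.0))
                       ** (1.0 / np.where(valid, t3 - 1.0, 1.0)),
                       np.nan)
    candidates = np.column_stack([
        np.zeros_like(t1),
        np.full_like(t1, u_max),
        np.where(valid & (u_c > 0) & (u_c < u_max), u_c, 0.0),
    ])
    vals = np.column_stack([g(candidates[:, j]) for j in range(3)])
    best = np.argmax(vals, axis=1)
    u_star = candidates[np.arange(len(t1)), best]
    interior = (best == 2) & (u_star > 0) & (u_star < u_max)
    gain = vals[np.arange(len(t1)), best] - vals[:, 0]
    return PeakSummary(u_star=u_star, gain=gain, interior=interior)


# ---------------------------------------------------------------------------
# Variogram & correlation


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        lag_bins: np.ndarray) -> pd.DataFrame:
    """Binned semivariance ``gamma(h) = mean of 0.5*(v_i - v_j)^2`` over
    point pairs with separation in each lag bin.

    Empty bins get NaN with a zero pair count.  A flat variogram at the
    field variance indicates no spatial autocorrelation.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 5:
        raise ValueError("need at least 5 points")
    if len(coords) != len(values):
        raise ValueError("coords and values must align")
    lag_bins = np.asarray(lag_bins, dtype=float)
    if len(lag_bins) < 2 or np.any(np.diff(lag_bins) <= 0):
        raise ValueError("lag_bins must be increasing edges")
    from scipy.spatial.distance import pdist
    h = pdist(coords)
    dv = pdist(values[:, None]) ** 2 * 0.5  # 0.5*(vi-vj)^2
    which = np.digitize(h, lag_bins) - 1
    rows = []
    for b in range(len(lag_bins) - 1):
        mask = which == b
        cnt = int(mask.sum())
        rows.append({
            "lag_lo": lag_bins[b], "lag_hi": lag_bins[b + 1],
            "lag_mid": 0.5 * (lag_bins[b] + lag_bins[b + 1]),
            "gamma": float(dv[mask].mean()) if cnt else np.nan,
            "n_pairs": cnt,
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float


def pearson_cor(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with ``t = r*sqrt(df/(1-r^2))``,
    ``df = n - 2``, and the two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = len(x) - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, t=np.inf if r > 0 else -np.inf,
                                 df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r=r, t=float(t), df=df,
                             p=float(2.0 * stats.t.sf(abs(t), df)))
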