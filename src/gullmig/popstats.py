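"""Population comparison of migration characteristics with GLMMs.

Each characteristic is modelled with breeding population as a fixed
effect and individual as a random intercept (some individuals
contribute several annual tracks).  Families follow the nature of the
response: Gaussian with identity link for migration distance, start and
end date, directness, migration speed, travel speed and travel:stopover
ratio; Poisson with log link for duration, total stopover days and
stopover length (one row per stopover site).

Estimation is maximum likelihood throughout (not REML) so that
likelihood-ratio tests on the fixed effect are valid: the Gaussian
random-intercept model has a closed-form marginal likelihood which is
optimized over the two variance components with the fixed effects
profiled out by GLS; the Poisson model integrates the random intercept
by Gauss-Hermite quadrature.  A random-intercept variance estimated at
(numerically) zero is a singular fit: the model is refit without the
random effect and flagged, and the LRT compares models with matching
random structure.

LRT p-values apply a Bartlett-style small-sample scaling
(n - p_full)/n to the statistic before the chi-square reference; the
reported statistic itself is the unscaled 2*(l_full - l_null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

log = logging.getLogger(__name__)

GAUSSIAN_RESPONSES = frozenset({
    "migration_distance_km", "start_doy", "end_doy", "directness",
    "migration_speed_km_day", "travel_speed_km_day",
    "travel_stopover_ratio_km_day"})
POISSON_RESPONSES = frozenset({
    "duration_days", "total_stopover_days", "stopover_length"})

SINGULAR_REL_TOL = 1e-6
_GH_NODES = 30


@dataclass(frozen=True)
class ModelSpec:
    response: str
    family: str = ""                 # inferred from the response if empty
    reference_level: str | None = None
    random_intercept: bool = True

    def resolved_family(self) -> str:
        if self.family:
            return self.family
        if self.response in GAUSSIAN_RESPONSES:
            return "gaussian"
        if self.response in POISSON_RESPONSES:
            return "poisson"
        raise ValueError(f"no default family for response {self.response!r}")


@dataclass
class PopulationFit:
    """One fitted GLMM (or GLM after a singular refit)."""

    family: str
    terms: list                      # coefficient names, intercept first
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    random_intercept_var: float
    resid_var: float                 # gaussian residual variance (nan: poisson)
    loglik: float
    n_obs: int
    n_fixed: int
    singular: bool
    has_random: bool
    # data retained for LRT / R2 / residual checks
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    # filled by compare_populations
    lrt_chi2: float = np.nan
    lrt_df: int = 0
    lrt_p: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan

    @property
    def eta(self) -> np.ndarray:
        """Fixed-effect linear predictor."""
        return self.X @ self.beta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "beta": self.beta,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


# ---------------------------------------------------------------- designs

def _design(df: pd.DataFrame, response: str, reference: str | None,
            with_population: bool = True):
    y = df[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in response {response!r}")
    pops = sorted(df["population"].unique())
    if with_population and len(pops) < 2:
        raise ValueError("need at least two populations to compare")
    if reference is not None:
        if reference not in pops:
            raise ValueError(f"reference level {reference!r} not present")
        pops = [reference] + [p for p in pops if p != reference]
    n = len(df)
    if with_population:
        X = np.zeros((n, len(pops)))
        X[:, 0] = 1.0
        for j, p in enumerate(pops[1:], start=1):
            X[:, j] = (df["population"] == p).to_numpy(dtype=float)
        terms = ["Intercept"] + list(pops[1:])
    else:
        X = np.ones((n, 1))
        terms = ["Intercept"]
    groups = pd.factorize(df["individual"])[0]
    return X, y, groups, terms


# ------------------------------------------------------- gaussian marginal ML

def _gaussian_ml(X, y, groups, with_random=True):
    """ML fit of y = X b + Z u + e, u ~ N(0, tau2) per group.

    Returns (beta, cov_beta, tau2, sigma2, loglik).
    """
    n, p = X.shape
    uniq = np.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in uniq]
    ni = np.array([len(i) for i in idx], dtype=float)

    def profile(log_s2, log_t2):
        s2, t2 = np.exp(log_s2), np.exp(log_t2)
        XtVX = X.T @ X / s2
        XtVy = X.T @ y / s2
        yVy = float(y @ y) / s2
        logdet = n * np.log(s2)
        for i, m in zip(idx, ni):
            c = t2 / (s2 * (s2 + m * t2))
            sx = X[i].sum(axis=0)
            sy = y[i].sum()
            XtVX -= c * np.outer(sx, sx)
            XtVy -= c * sx * sy
            yVy -= c * sy * sy
            logdet += np.log1p(m * t2 / s2)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return None
        quad = yVy - beta @ XtVy
        ll = -0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
        return beta, XtVX, ll

    if not with_random:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / n
        ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
        cov = s2 * np.linalg.inv(X.T @ X)
        return beta, cov, 0.0, s2, ll

    def nll(par):
        out = profile(par[0], par[1])
        return np.inf if out is None else -out[2]

    v0 = max(np.var(y), 1e-8)
    res = optimize.minimize(
        nll, x0=np.array([np.log(v0 * 0.7), np.log(v0 * 0.3)]),
        method="L-BFGS-B",
        bounds=[(np.log(v0) - 20.0, np.log(v0) + 10.0),
                (np.log(v0) - 25.0, np.log(v0) + 10.0)])
    log_s2, log_t2 = res.x
    beta, XtVX, ll = profile(log_s2, log_t2)
    cov = np.linalg.inv(XtVX)
    return beta, cov, float(np.exp(log_t2)), float(np.exp(log_s2)), float(ll)


# ------------------------------------------------------- poisson GH ML

def _poisson_glm(X, y):
    """Newton-Raphson ML for the fixed-effects Poisson log-link model."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.mean(y) + 0.5)
    for _ in range(100):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        g = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(X @ beta)
    ll = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    cov = np.linalg.inv((X * mu[:, None]).T @ X)
    return beta, cov, ll


def _poisson_gh_nll(par, X, y, idx, nodes, wts):
    p = X.shape[1]
    beta, s = par[:p], par[p]
    eta = np.clip(X @ beta, -30, 30)
    ll = 0.0
    z = np.sqrt(2.0) * nodes * s          # integration over N(0, s^2)
    for i in idx:
        # log integrand at each node for group i
        e = eta[i][:, None] + z[None, :]
        contrib = (y[i][:, None] * e - np.exp(np.clip(e, -30, 30))).sum(axis=0)
        m = contrib.max()
        ll += m + np.log(np.dot(wts, np.exp(contrib - m))) - 0.5 * np.log(np.pi)
    ll -= float(gammaln(y + 1.0).sum())
    return -ll


def _poisson_gh_ml(X, y, groups):
    n, p = X.shape
    uniq = np.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in uniq]
    nodes, wts = np.polynomial.hermite.hermgauss(_GH_NODES)
    beta0, _, _ = _poisson_glm(X, y)
    x0 = np.concatenate([beta0, [0.1]])
    bounds = [(None, None)] * p + [(0.0, 5.0)]
    res = optimize.minimize(_poisson_gh_nll, x0, args=(X, y, idx, nodes, wts),
                            method="L-BFGS-B", bounds=bounds)
    par = res.x
    ll = -float(res.fun)
    cov = _beta_cov_numeric(
        lambda b: -_poisson_gh_nll(np.concatenate([b, par[p:]]),
                                   X, y, idx, nodes, wts), par[:p])
    return par[:p], cov, float(par[p] ** 2), ll


def _beta_cov_numeric(loglik_fn, beta, h: float = 1e-4):
    """Observed-information covariance by central finite differences."""
    p = len(beta)
    H = np.zeros((p, p))
    f0 = loglik_fn(beta)
    for i in range(p):
        for j in range(i, p):
            bpp = beta.copy(); bpp[i] += h; bpp[j] += h
            bpm = beta.copy(); bpm[i] += h; bpm[j] -= h
            bmp = beta.copy(); bmp[i] -= h; bmp[j] += h
            bmm = beta.copy(); bmm[i] -= h; bmm[j] -= h
            H[i, j] = H[j, i] = (loglik_fn(bpp) - loglik_fn(bpm)
                                 - loglik_fn(bmp) + loglik_fn(bmm)) / (4 * h * h)
    return np.linalg.inv(-H)


# ---------------------------------------------------------------- public API

def fit_glmm(df: pd.DataFrame, spec: ModelSpec,
             _with_population: bool = True,
             _force_no_random: bool = False) -> PopulationFit:
    """Fit one characteristic's GLMM; detects and handles singular fits."""
    family = spec.resolved_family()
    X, y, groups, terms = _design(df, spec.response, spec.reference_level,
                                  with_population=_with_population)
    if family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson responses must be non-negative integers")

    want_random = spec.random_intercept and not _force_no_random
    singular = False
    if family == "gaussian":
        if want_random:
            beta, cov, tau2, s2, ll = _gaussian_ml(X, y, groups)
            if tau2 < SINGULAR_REL_TOL * max(s2, 1e-12):
                singular = True
        if not want_random or singular:
            beta, cov, tau2, s2, ll = _gaussian_ml(X, y, groups,
                                                   with_random=False)
            if singular:
                log.info("%s: singular random-intercept fit; refit without "
                         "random effect", spec.response)
        has_random = want_random and not singular
        resid_var = s2
    elif family == "poisson":
        if want_random:
            beta, cov, tau2, ll = _poisson_gh_ml(X, y, groups)
            if tau2 < 1e-6:
                singular = True
        if not want_random or singular:
            beta, cov, ll = _poisson_glm(X, y)
            tau2 = 0.0
            if singular:
                log.info("%s: singular random-intercept fit; refit without "
                         "random effect", spec.response)
        has_random = want_random and not singular
        resid_var = np.nan
    else:
        raise ValueError(f"unknown family {family!r}")

    se = np.sqrt(np.diag(cov))
    zq = stats.norm.ppf(0.975)
    return PopulationFit(
        family=family, terms=terms, beta=np.asarray(beta), se=se,
        ci_low=beta - zq * se, ci_high=beta + zq * se,
        random_intercept_var=float(tau2), resid_var=float(resid_var),
        loglik=float(ll), n_obs=len(y), n_fixed=X.shape[1],
        singular=singular, has_random=has_random,
        X=X, y=y, groups=groups)


def lrt(full: PopulationFit, null: PopulationFit):
    """Likelihood-ratio test of the population fixed effect.

    Returns ``(chi2, df, p)``; ``chi2`` is the raw 2*(l_full - l_null),
    the p-value uses the small-sample scaled statistic (see module
    docstring).
    """
    if full.family != null.family:
        raise ValueError("LRT requires the same family")
    if full.n_obs != null.n_obs:
        raise ValueError("LRT requires the same data")
    if null.n_fixed >= full.n_fixed:
        raise ValueError("null model must be nested in the full model")
    chi2 = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = full.n_fixed - null.n_fixed
    scale = (full.n_obs - full.n_fixed) / full.n_obs
    p = float(stats.chi2.sf(chi2 * scale, df))
    return float(chi2), int(df), p


def r2_nakagawa(fit: PopulationFit):
    """Marginal and conditional R2 for a mixed model.

    Marginal: fixed-effect variance over total; conditional adds the
    random-intercept variance.  Poisson (log link) uses the lognormal
    approximation ln(1 + 1/lambda) for the distribution-specific
    residual variance.  A singular fit reports conditional == marginal.
    """
    var_f = float(np.var(fit.eta))
    tau2 = fit.random_intercept_var
    if fit.family == "gaussian":
        var_d = fit.resid_var
    else:
        lam = float(np.exp(np.mean(fit.eta) + tau2 / 2.0))
        var_d = float(np.log1p(1.0 / lam))
    denom = var_f + tau2 + var_d
    if denom <= 0:
        return 0.0, 0.0
    r2m = var_f / denom
    r2c = (var_f + tau2) / denom
    if fit.singular or not fit.has_random:
        r2c = r2m
    return float(r2m), float(r2c)


def _blups(fit: PopulationFit) -> np.ndarray:
    """Per-group random-intercept predictions (zero when no random effect)."""
    n_groups = fit.groups.max() + 1
    b = np.zeros(n_groups)
    if not fit.has_random or fit.random_intercept_var <= 0:
        return b
    tau2 = fit.random_intercept_var
    eta = fit.eta
    if fit.family == "gaussian":
        s2 = fit.resid_var
        for g in range(n_groups):
            i = fit.groups == g
            m = i.sum()
            b[g] = tau2 * m / (s2 + tau2 * m) * np.mean(fit.y[i] - eta[i])
    else:
        for g in range(n_groups):
            i = fit.groups == g
            bg = 0.0
            for _ in range(50):  # Newton for the posterior mode
                mu = np.exp(np.clip(eta[i] + bg, -30, 30))
                g1 = np.sum(fit.y[i] - mu) - bg / tau2
                g2 = -np.sum(mu) - 1.0 / tau2
                step = g1 / g2
                bg -= step
                if abs(step) < 1e-10:
                    break
            b[g] = bg
    return b


@dataclass
class ResidualCheck:
    """Advisory randomized-quantile-residual uniformity check."""

    ks_stat: float
    p_value: float
    flagged: bool
    residuals: np.ndarray = field(repr=False, default=None)


def residual_check(fit: PopulationFit, seed: int = 0) -> ResidualCheck:
    """Randomized quantile residuals + KS uniformity test (advisory)."""
    if fit.X is None or len(fit.y) == 0:
        raise ValueError("empty model")
    rng = np.random.default_rng(seed)
    b = _blups(fit)[fit.groups]
    eta = fit.eta + b
    if fit.family == "gaussian":
        sd = np.sqrt(max(fit.resid_var, 1e-300))
        u = stats.norm.cdf((fit.y - eta) / sd)
    else:
        mu = np.exp(np.clip(eta, -30, 30))
        lo = stats.poisson.cdf(fit.y - 1, mu)
        hi = stats.poisson.cdf(fit.y, mu)
        u = lo + rng.uniform(size=len(fit.y)) * (hi - lo)
    u = np.clip(u, 1e-10, 1 - 1e-10)
    ks = stats.kstest(u, "uniform")
    return ResidualCheck(ks_stat=float(ks.statistic), p_value=float(ks.pvalue),
                         flagged=bool(ks.pvalue < 0.05),
                         residuals=stats.norm.ppf(u))


def compare_populations(df: pd.DataFrame, spec: ModelSpec) -> PopulationFit:
    """Full vs null (fixed effect removed) comparison for one response.

    The null model keeps the random structure the full model ended up
    with, so the two likelihoods are comparable.
    """
    full = fit_glmm(df, spec)
    null = fit_glmm(df, spec, _with_population=False,
                    _force_no_random=not full.has_random)
    chi2, dof, p = lrt(full, null)
    full.lrt_chi2, full.lrt_df, full.lrt_p = chi2, dof, p
    full.r2_marginal, full.r2_conditional = r2_nakagawa(full)
    return full


# ------------------------------------------------- simulation for calibration

def simulate_response_dataset(group_means, n_per_group, family: str,
                              rng: np.random.Generator,
                              sd_between: float = 0.0,
                              sd_resid: float = 1.0) -> pd.DataFrame:
    """Simulate a characteristic table for calibration studies.

    Mirrors the tracking design: within each population roughly a third
    of the individuals contribute two annual tracks, the rest one.
    ``sd_between`` is the individual random-intercept SD (response scale
    for gaussian, log scale for poisson).
    """
    rows = []
    for g, (pop, mean) in enumerate(group_means.items()):
        n = n_per_group[g] if np.ndim(n_per_group) else int(n_per_group)
        k2 = n // 3                      # individuals with two tracks
        sizes = [2] * k2 + [1] * (n - 2 * k2)
        for i, sz in enumerate(sizes):
            u = rng.normal(0.0, sd_between)
            for r in range(sz):
                if family == "gaussian":
                    val = mean + u + rng.normal(0.0, sd_resid)
                elif family == "poisson":
                    val = rng.poisson(np.exp(np.log(mean) + u))
                else:
                    raise ValueError(family)
                rows.append({"population": pop, "individual": f"{pop}_{i}",
                             "value": val})
    return pd.DataFrame(rows)
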