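"""Maximum-likelihood covariance fitting and goodness-of-fit indices.

Estimation minimises the ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - ln|S| - p

over the free parameters with a quasi-Newton method (L-BFGS-B, analytic
gradient), from equation-wise least-squares starting values.  The test
statistic is chi^2 = (n-1) * F_min with df = p(p+1)/2 - q.

Conventions (they differ between published SEM programs, so they are pinned
here): the sample covariance S uses the n-1 divisor; chi^2 uses the (n-1)
multiplier; the log-likelihood entering AIC/BIC uses the Wishart (n-1)
convention so -2lnL = chi^2 + a data-only constant, AIC = -2lnL + 2q and
BIC = -2lnL + q ln n; SRMR
standardizes residuals in the correlation metric and includes the diagonal;
the RMSEA 90% CI comes from inverting the noncentral chi^2 distribution at
the 5% and 95% bounds.  A fit is classified "good" when RMSEA < 0.05,
CFI > 0.97 and SRMR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathModel, implied_covariance, model_df

__all__ = ["SemFit", "fit_ml", "fit_indices", "fit_model", "r_squared", "is_good_fit"]


def is_good_fit(rmsea: float, cfi: float, srmr: float) -> bool:
    """Good-fit classification: RMSEA < 0.05, CFI > 0.97 and SRMR < 0.05."""
    return bool(rmsea < 0.05 and cfi > 0.97 and srmr < 0.05)

_PENALTY = 1e10


@dataclass
class SemFit:
    """Fitted structural model: estimates, test statistic and fit indices."""

    model: PathModel
    n: int
    sample_cov: np.ndarray
    estimates: dict
    se: dict
    F_min: float
    chi2: float
    df: int
    p_value: float
    converged: bool
    n_free: int
    # completed by fit_indices
    rmsea: float = np.nan
    rmsea_ci: tuple = (np.nan, np.nan)
    srmr: float = np.nan
    cfi: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    loglik: float = np.nan
    baseline_chi2: float = np.nan
    baseline_df: int = 0
    good_fit: bool = False
    r2: dict = field(default_factory=dict)

    @property
    def implied(self) -> np.ndarray:
        return implied_covariance(self.model, self.estimates)

    def standardized(self) -> dict:
        """Standardized estimates (post hoc, from model-implied SDs)."""
        sigma = self.implied
        sd = np.sqrt(np.diag(sigma))
        idx = self.model.index
        out = {}
        for e in self.model.edges:
            if e.free:
                out[e.name] = self.estimates[e.name] * sd[idx(e.src)] / sd[idx(e.dst)]
        for c in self.model.covariances:
            if c.free:
                i, j = idx(c.a), idx(c.b)
                out[c.name] = self.estimates[c.name] / (sd[i] * sd[j])
        return out

    def table(self) -> pd.DataFrame:
        std = self.standardized()
        rows = []
        for name in self.model.free_names:
            est = self.estimates[name]
            se = self.se.get(name, np.nan)
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "std_estimate": std.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _validate_sample_cov(S, model: PathModel, n: int) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    p = model.p
    if S.shape != (p, p):
        raise ValueError(f"sample covariance must be {p}x{p}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("sample covariance is not symmetric")
    if np.min(np.linalg.eigvalsh(S)) <= 0:
        raise ValueError("sample covariance is not positive definite")
    if n <= p:
        raise ValueError("need n > p observations")
    return 0.5 * (S + S.T)


def _start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Equation-wise least-squares starts computed from S.

    Path coefficients start at the OLS regression of each endogenous variable
    on all its parents; residual variances at the corresponding OLS residual
    variance; exogenous variances/covariances at their sample moments.
    """
    idx = model.index
    ols_coef: dict = {}
    resid_var: dict = {}
    for v in model.endogenous:
        par = model.parents(v)
        pi = [idx(s) for s in par]
        yi = idx(v)
        Sxx = S[np.ix_(pi, pi)]
        Sxy = S[pi, yi]
        b = np.linalg.solve(Sxx, Sxy)
        for s, bs in zip(par, b):
            ols_coef[f"{v}~{s}"] = float(bs)
        resid_var[v] = float(max(S[yi, yi] - Sxy @ b, 1e-3 * S[yi, yi]))
    theta0 = []
    for e in model.edges:
        if e.free:
            theta0.append(ols_coef.get(e.name, 0.0))
    endo = set(model.endogenous)
    for c in model.covariances:
        if not c.free:
            continue
        if c.a == c.b:
            theta0.append(resid_var[c.a] if c.a in endo else float(S[idx(c.a), idx(c.a)]))
        else:
            theta0.append(float(S[idx(c.a), idx(c.b)]))
    return np.asarray(theta0)


def _theta_to_params(model: PathModel, theta: np.ndarray) -> dict:
    return dict(zip(model.free_names, theta))


def _objective_and_grad(model: PathModel, S: np.ndarray):
    """Return f(theta) -> (F, dF/dtheta) for the ML discrepancy."""
    p = model.p
    sign, logdet_S = np.linalg.slogdet(S)
    idx = model.index
    free_edges = [e for e in model.edges if e.free]
    free_covs = [c for c in model.covariances if c.free]
    n_edge = len(free_edges)

    def fun(theta):
        params = _theta_to_params(model, theta)
        B, Psi = model.matrices(params)
        IB = np.eye(p) - B
        try:
            A = np.linalg.inv(IB)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta)
        sigma = A @ Psi @ A.T
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        sigma_inv = np.linalg.inv(sigma)
        F = logdet + np.trace(S @ sigma_inv) - logdet_S - p
        # gradient: dF/dtheta_k = tr(M dSigma/dtheta_k),
        # M = Sigma^{-1} (Sigma - S) Sigma^{-1}
        M = sigma_inv @ (sigma - S) @ sigma_inv
        G_edge = 2.0 * (A.T @ M @ sigma)       # entry [dst, src] per free edge
        G_psi = A.T @ M @ A                    # symmetric-unit derivative
        grad = np.empty_like(theta)
        for k, e in enumerate(free_edges):
            grad[k] = G_edge[idx(e.dst), idx(e.src)]
        for k, c in enumerate(free_covs):
            i, j = idx(c.a), idx(c.b)
            grad[n_edge + k] = G_psi[i, j] * (1.0 if i == j else 2.0)
        return float(F), grad

    return fun


def _hessian(fun, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    q = theta.size
    H = np.empty((q, q))
    for k in range(q):
        h = rel_step * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_ml(
    model: PathModel,
    sample_cov,
    n: int,
    compute_se: bool = True,
    max_iter: int = 500,
) -> SemFit:
    """Fit a path model to a sample covariance matrix by maximum likelihood.

    Returns estimates, chi^2 = (n-1) F_min, df and the chi^2 p-value.
    Non-convergence is reported via ``converged``, never silently.  Call
    :func:`fit_indices` (or :func:`fit_model` on raw data) for RMSEA, CFI,
    SRMR, AIC, BIC and R^2.
    """
    S = _validate_sample_cov(sample_cov, model, n)
    df = model_df(model)
    fun = _objective_and_grad(model, S)
    theta0 = _start_values(model, S)

    # variance parameters stay positive; paths and covariances unbounded
    bounds = []
    k = 0
    for e in model.edges:
        if e.free:
            bounds.append((None, None))
            k += 1
    floor = 1e-8 * float(np.max(np.diag(S)))
    for c in model.covariances:
        if c.free:
            bounds.append((floor, None) if c.a == c.b else (None, None))

    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    theta = res.x
    F_min = float(res.fun)
    converged = bool(res.success) and F_min < _PENALTY / 2
    chi2 = max((n - 1) * F_min, 0.0)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    se = {}
    if compute_se:
        H = _hessian(fun, theta) * (n - 1) / 2.0
        with np.errstate(invalid="ignore"):
            try:
                acov = np.linalg.inv(H)
                diag = np.diag(acov)
                se_vals = np.sqrt(np.where(diag > 0, diag, np.nan))
            except np.linalg.LinAlgError:
                se_vals = np.full(theta.size, np.nan)
        se = dict(zip(model.free_names, se_vals))

    return SemFit(
        model=model,
        n=n,
        sample_cov=S,
        estimates=_theta_to_params(model, theta),
        se=se,
        F_min=F_min,
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        converged=converged,
        n_free=model.n_free,
    )


def _baseline_stats(S: np.ndarray, n: int) -> tuple:
    """Independence-model fit (free variances, zero covariances), closed form.

    The ML solution fixes each variance at its sample value, so
    F_b = sum(ln s_ii) - ln|S| and df_b = p(p-1)/2.
    """
    p = S.shape[0]
    _, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    return max((n - 1) * F_b, 0.0), p * (p - 1) // 2


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple:
    """Noncentrality inversion for the RMSEA confidence interval."""
    if df == 0:
        return (0.0, 0.0)
    lo_q = (1.0 + level) / 2.0   # 0.95
    hi_q = (1.0 - level) / 2.0   # 0.05

    def _solve(target):
        # find lambda with ncx2.cdf(chi2, df, lambda) = target
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - target
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = _solve(lo_q)
    lam_hi = _solve(hi_q)
    denom = df * (n - 1)
    return (float(np.sqrt(lam_lo / denom)), float(np.sqrt(lam_hi / denom)))


def fit_indices(fit: SemFit) -> SemFit:
    """Complete a fit with RMSEA (+90% CI), CFI, SRMR, AIC, BIC and R^2.

    The baseline is the independence model on the same data (closed form).
    With df = 0 the truncation rules give RMSEA = 0 and CFI = 1.
    """
    S = fit.sample_cov
    n = fit.n
    p = fit.model.p
    chi2, df = fit.chi2, fit.df
    chi2_b, df_b = _baseline_stats(S, n)

    if df > 0:
        fit.rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        fit.rmsea_ci = _rmsea_ci(chi2, df, n)
    else:
        fit.rmsea = 0.0
        fit.rmsea_ci = (0.0, 0.0)

    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    fit.cfi = 1.0 if denom == 0 else float(1.0 - max(chi2 - df, 0.0) / denom)
    fit.baseline_chi2, fit.baseline_df = float(chi2_b), int(df_b)

    sigma = fit.implied
    sd = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    fit.srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    # Wishart-convention log-likelihood (n-1 multiplier, same S as chi^2), so
    # -2lnL = chi^2 + data-only constant and information-criterion
    # differences between nested models reduce to chi^2 differences exactly
    sigma_inv = np.linalg.inv(sigma)
    _, logdet = np.linalg.slogdet(sigma)
    fit.loglik = float(
        -0.5 * (n - 1) * (p * np.log(2 * np.pi) + logdet + np.trace(S @ sigma_inv))
    )
    q = fit.n_free
    fit.aic = float(-2 * fit.loglik + 2 * q)
    fit.bic = float(-2 * fit.loglik + q * np.log(n))

    fit.good_fit = is_good_fit(fit.rmsea, fit.cfi, fit.srmr)
    fit.r2 = {v: r_squared(fit, v) for v in fit.model.endogenous}
    return fit


def r_squared(fit: SemFit, variable: str) -> float:
    """Explained variance 1 - residual/total for an endogenous variable."""
    if variable not in fit.model.endogenous:
        raise ValueError(f"{variable!r} is not endogenous")
    psi_name = f"{variable}~~{variable}"
    psi = fit.estimates.get(psi_name)
    if psi is None:
        cov = next(c for c in fit.model.covariances if c.a == c.b == variable)
        psi = cov.value
    total = fit.implied[fit.model.index(variable), fit.model.index(variable)]
    return float(1.0 - psi / total)


def fit_model(model: PathModel, data: pd.DataFrame, compute_se: bool = True) -> SemFit:
    """Fit from a raw data table (complete-case) and complete all indices."""
    cols = list(model.variables)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data table lacks column(s) {missing}")
    frame = data[cols].dropna()
    S = np.cov(frame.to_numpy(float), rowvar=False, ddof=1)
    fit = fit_ml(model, S, n=len(frame), compute_se=compute_se)
    return fit_indices(fit)
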