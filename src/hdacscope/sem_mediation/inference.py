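"""Bootstrap inference, model comparison and Monte-Carlo power for path models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import fit_ml, fit_model
from .mediation import mediation_effects
from .model import PathModel, implied_covariance

__all__ = [
    "BootstrapResult",
    "bootstrap_inference",
    "compare_models",
    "monte_carlo_power",
    "PowerResult",
]

FIT_PARAMETER_ROWS = ("RMSEA", "SRMR", "CFI", "AIC", "BIC")
# lower is better for all rows except CFI
_HIGHER_BETTER = {"CFI"}


@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs and p-values for parameters and mediation."""

    table: pd.DataFrame           # parameter, estimate, ci_lo, ci_hi, p
    mediation: pd.DataFrame       # per (source, mediator, outcome) quantities
    n_boot: int
    n_failed: int
    flagged: bool                 # > 20% non-converged replicates


def bootstrap_inference(
    model: PathModel,
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    mediation_triples=(),
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Row-resampling bootstrap of a path-model fit.

    Percentile CIs at ``ci_level`` and two-sided p-values from the symmetric
    tail of the bootstrap distribution (fraction of replicates on the far
    side of zero, doubled).  Non-converged replicates are excluded and
    counted; more than 20% failures flags the result.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    frame = data[list(model.variables)].dropna().reset_index(drop=True)
    n = len(frame)
    rng = np.random.default_rng(seed)

    point = fit_model(model, frame, compute_se=False)
    names = list(model.free_names)
    draws = []
    med_draws = {t: [] for t in mediation_triples}
    n_failed = 0
    arr = frame.to_numpy(float)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        S = np.cov(arr[idx], rowvar=False, ddof=1)
        try:
            rep = fit_ml(model, S, n=n, compute_se=False)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not rep.converged:
            n_failed += 1
            continue
        draws.append([rep.estimates[k] for k in names])
        for t in mediation_triples:
            med_draws[t].append(mediation_effects(rep, *t))
    draws = np.asarray(draws)
    n_ok = draws.shape[0]
    if n_ok == 0:
        raise RuntimeError("no bootstrap replicate converged")
    alpha = 1.0 - ci_level
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def _tail_p(sample):
        sample = np.asarray(sample)
        frac_le = np.mean(sample <= 0)
        frac_ge = np.mean(sample >= 0)
        return float(min(1.0, 2.0 * min(frac_le, frac_ge)))

    rows = []
    for j, name in enumerate(names):
        col = draws[:, j]
        rows.append(
            {
                "parameter": name,
                "estimate": point.estimates[name],
                "ci_lo": float(np.percentile(col, lo_q)),
                "ci_hi": float(np.percentile(col, hi_q)),
                "p": _tail_p(col),
            }
        )
    med_rows = []
    for t in mediation_triples:
        point_med = mediation_effects(point, *t)
        for quantity in ("indirect", "direct", "total", "proportion_mediated"):
            col = np.asarray([getattr(m, quantity) for m in med_draws[t]])
            col = col[np.isfinite(col)]
            med_rows.append(
                {
                    "source": t[0],
                    "mediator": t[1],
                    "outcome": t[2],
                    "quantity": quantity,
                    "estimate": getattr(point_med, quantity),
                    "ci_lo": float(np.percentile(col, lo_q)) if col.size else np.nan,
                    "ci_hi": float(np.percentile(col, hi_q)) if col.size else np.nan,
                    "p": _tail_p(col) if col.size else np.nan,
                }
            )
    return BootstrapResult(
        table=pd.DataFrame(rows),
        mediation=pd.DataFrame(med_rows),
        n_boot=n_boot,
        n_failed=n_failed,
        flagged=n_failed > 0.2 * n_boot,
    )


def compare_models(models: dict, data: pd.DataFrame, compute_se: bool = False):
    """Fit several models to one data table and rank their goodness-of-fit.

    ``models`` maps model name -> PathModel; all models must cover the same
    variable set.  Returns ``(table, best, fits)`` where ``table`` has rows
    (RMSEA, SRMR, CFI, AIC, BIC) by model columns, ``best`` is a same-shaped
    boolean frame with exactly one best mark per row (lower is better except
    CFI) and ``fits`` the underlying SemFit objects.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    var_sets = {name: frozenset(m.variables) for name, m in models.items()}
    first = next(iter(var_sets.values()))
    mismatched = [name for name, s in var_sets.items() if s != first]
    if mismatched:
        raise ValueError(f"variable-set mismatch for model(s) {mismatched}")

    fits = {name: fit_model(m, data, compute_se=compute_se) for name, m in models.items()}
    table = pd.DataFrame(
        {
            name: [f.rmsea, f.srmr, f.cfi, f.aic, f.bic]
            for name, f in fits.items()
        },
        index=list(FIT_PARAMETER_ROWS),
    )
    best = pd.DataFrame(False, index=table.index, columns=table.columns)
    for row in table.index:
        vals = table.loc[row]
        winner = vals.idxmax() if row in _HIGHER_BETTER else vals.idxmin()
        best.loc[row, winner] = True
    return table, best, fits


@dataclass
class PowerResult:
    """Per-parameter Monte-Carlo rejection rates."""

    power: dict
    alpha: float
    n: int
    n_sims: int
    n_converged: int


def monte_carlo_power(
    model: PathModel,
    params: dict,
    n: int,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Power of the Wald z-test for every free parameter.

    Repeatedly simulates datasets of size ``n`` from the model at ``params``,
    refits, and counts rejections of H0: parameter = 0 at level ``alpha``.
    A zero coefficient therefore estimates the test's size.
    """
    sigma = implied_covariance(model, params)
    if np.min(np.linalg.eigvalsh(sigma)) <= 0:
        raise ValueError("implied covariance is not positive definite")
    chol = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    names = list(model.free_names)
    rejections = {k: 0 for k in names}
    n_converged = 0
    for _ in range(n_sims):
        X = rng.standard_normal((n, model.p)) @ chol.T
        S = np.cov(X, rowvar=False, ddof=1)
        try:
            rep = fit_ml(model, S, n=n, compute_se=True)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not rep.converged:
            continue
        n_converged += 1
        for k in names:
            se = rep.se.get(k, np.nan)
            if np.isfinite(se) and se > 0 and abs(rep.estimates[k] / se) > zcrit:
                rejections[k] += 1
    if n_converged == 0:
        raise RuntimeError("no simulation replicate converged")
    power = {k: rejections[k] / n_converged for k in names}
    return PowerResult(power=power, alpha=alpha, n=n, n_sims=n_sims, n_converged=n_converged)
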