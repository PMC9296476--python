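"""Closed-form path-analysis oracle for recursive structural models.

For a recursive system with uncorrelated disturbances and a saturated
exogenous block, the Gaussian likelihood factorises into the product of the
exogenous density and one conditional regression per endogenous variable.
The ML estimates are therefore available in closed form: each endogenous
variable's coefficients are the least-squares regression on its parents
(computed directly from the sample covariance), its residual variance the
corresponding residual moment, and the exogenous (co)variances their sample
values.  No iteration is involved, which makes this an independent check of
the quasi-Newton covariance-fitting engine.

Run as a script to (re)generate the frozen oracle fixtures:

    python tests/_sem_oracle.py
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

FIXTURE_PATH = Path(__file__).parent / "fixtures" / "sem_oracle.json"


def oracle_fit(variables, edges, S, n):
    """Closed-form ML fit of a recursive path model.

    Parameters
    ----------
    variables : ordered list of names.
    edges : list of (src, dst) free directed paths; the model must be
        recursive with uncorrelated disturbances.
    S : sample covariance (n-1 divisor).
    n : number of observations.

    Returns a dict of estimates and fit statistics using the same
    conventions as the engine (chi^2 with n-1, Wishart n-1 log-likelihood
    for AIC/BIC, SRMR with diagonal in the correlation metric).
    """
    variables = list(variables)
    S = np.asarray(S, dtype=float)
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    parents: dict = {v: [] for v in variables}
    for src, dst in edges:
        parents[dst].append(src)
    endo = [v for v in variables if parents[v]]
    exo = [v for v in variables if not parents[v]]

    estimates = {}
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    for y in endo:
        par = parents[y]
        pi = [idx[s] for s in par]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, idx[y]])
        for s, bs in zip(par, b):
            estimates[f"{y}~{s}"] = float(bs)
            B[idx[y], idx[s]] = bs
        psi = float(S[idx[y], idx[y]] - S[pi, idx[y]] @ b)
        estimates[f"{y}~~{y}"] = psi
        Psi[idx[y], idx[y]] = psi
    for i, a in enumerate(exo):
        estimates[f"{a}~~{a}"] = float(S[idx[a], idx[a]])
        Psi[idx[a], idx[a]] = S[idx[a], idx[a]]
        for b_ in exo[i + 1 :]:
            estimates[f"{a}~~{b_}"] = float(S[idx[a], idx[b_]])
            Psi[idx[a], idx[b_]] = Psi[idx[b_], idx[a]] = S[idx[a], idx[b_]]

    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ Psi @ A.T

    q = len(edges) + len(endo) + len(exo) * (len(exo) + 1) // 2
    df = p * (p + 1) // 2 - q

    sign, logdet_S = np.linalg.slogdet(S)
    sign2, logdet_sig = np.linalg.slogdet(sigma)
    F = float(logdet_sig + np.trace(S @ np.linalg.inv(sigma)) - logdet_S - p)
    chi2 = max((n - 1) * F, 0.0)

    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0

    sd = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    F_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = max((n - 1) * F_base, 0.0)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else float(1.0 - max(chi2 - df, 0.0) / denom)

    loglik = float(
        -0.5
        * (n - 1)
        * (p * np.log(2 * np.pi) + logdet_sig + np.trace(S @ np.linalg.inv(sigma)))
    )
    aic = float(-2 * loglik + 2 * q)
    bic = float(-2 * loglik + q * np.log(n))

    return {
        "estimates": estimates,
        "F": F,
        "chi2": chi2,
        "df": int(df),
        "rmsea": rmsea,
        "srmr": srmr,
        "cfi": cfi,
        "aic": aic,
        "bic": bic,
        "n_free": int(q),
    }


def _toy_cases():
    """Three fixed toy models with seeded sample covariance matrices."""
    rng = np.random.default_rng(20260923)

    def sample_cov(B, Psi, n):
        p = B.shape[0]
        A = np.linalg.inv(np.eye(p) - B)
        chol = np.linalg.cholesky(A @ Psi @ A.T)
        X = rng.standard_normal((n, p)) @ chol.T
        return np.cov(X, rowvar=False, ddof=1)

    cases = {}

    # 1. simple chain X -> M -> Y (df = 1)
    variables = ["X", "M", "Y"]
    edges = [["X", "M"], ["M", "Y"]]
    B = np.zeros((3, 3))
    B[1, 0] = 0.6
    B[2, 1] = 0.5
    Psi = np.diag([1.0, 0.64, 0.75])
    cases["chain"] = {
        "variables": variables,
        "edges": edges,
        "n": 150,
        "S": sample_cov(B, Psi, 150).tolist(),
    }

    # 2. two-route mediation A -> {T, H}, T -> H, {T, H} -> C (df = 1)
    variables = ["A", "T", "H", "C"]
    edges = [["A", "T"], ["A", "H"], ["T", "H"], ["H", "C"], ["T", "C"]]
    B = np.zeros((4, 4))
    B[1, 0] = 0.65
    B[2, 0] = -0.30
    B[2, 1] = -0.50
    B[3, 2] = 0.50
    B[3, 1] = -0.24
    Psi = np.diag([1.0, 0.58, 0.49, 0.49])
    cases["two_route"] = {
        "variables": variables,
        "edges": edges,
        "n": 200,
        "S": sample_cov(B, Psi, 200).tolist(),
    }

    # 3. correlated exogenous pair with two outcomes (df = 4)
    variables = ["X1", "X2", "M", "Y1", "Y2"]
    edges = [["X1", "M"], ["X2", "M"], ["M", "Y1"], ["M", "Y2"], ["X1", "Y2"]]
    B = np.zeros((5, 5))
    B[2, 0] = 0.5
    B[2, 1] = -0.4
    B[3, 2] = 0.7
    B[4, 2] = 0.3
    B[4, 0] = 0.2
    Psi = np.diag([1.0, 1.0, 0.6, 0.51, 0.8])
    Psi[0, 1] = Psi[1, 0] = 0.3
    cases["covariate"] = {
        "variables": variables,
        "edges": edges,
        "n": 120,
        "S": sample_cov(B, Psi, 120).tolist(),
    }
    return cases


def main():
    cases = _toy_cases()
    out = {}
    for name, case in cases.items():
        result = oracle_fit(case["variables"], case["edges"], np.array(case["S"]), case["n"])
        out[name] = {**case, "oracle": result}
    FIXTURE_PATH.parent.mkdir(exist_ok=True)
    FIXTURE_PATH.write_text(json.dumps(out, indent=1))
    print(f"wrote {FIXTURE_PATH}")
    for name, case in out.items():
        o = case["oracle"]
        print(name, "chi2", round(o["chi2"], 4), "df", o["df"], "rmsea", round(o["rmsea"], 4),
              "cfi", round(o["cfi"], 4), "srmr", round(o["srmr"], 4))


if __name__ == "__main__":
    main()
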