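"""Group-level voxel statistics and cohort regression models.

Voxel-wise operations take a list of subject maps sharing one grid and an
analysis mask; every statistic is computed inside the mask only and
out-of-mask voxels are NaN in the returned maps.  Multiple-comparison
correction is Benjamini-Hochberg over in-mask voxels.

ROC orientation: `voxelwise_auc(controls, patients)` reports the area under
the curve for discriminating patients by *reduced* uptake, i.e. AUC > 0.5
where the patient group is lower.  The orientation is fixed here because a
silently flipped AUC map is a classic bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import StatImage, check_same_grid

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "AnovaResult",
    "LongitudinalModelResult",
    "voxelwise_glm",
    "fdr_bh",
    "voxelwise_auc",
    "anova_tukey",
    "correlate",
    "fit_longitudinal_model",
]

#: two-sided p reported for numerically exact fits (zero residual)
P_MACHINE_FLOOR = 1e-300


def _collinear_columns(X: np.ndarray, names) -> list:
    """Names of columns involved in a rank deficiency (pivoted-QR diagnosis)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.where(diag < tol)[0]]
    return [names[i] for i in sorted(bad)]


@dataclass
class DesignMatrix:
    """Subject-by-predictor matrix with named columns and a contrast vector."""

    X: np.ndarray
    names: list
    contrast: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        n, k = self.X.shape
        if len(self.names) != k:
            raise ValueError("one name per column required")
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (k,):
            raise ValueError("contrast length must match the number of columns")
        if not any(np.allclose(self.X[:, j], self.X[0, j]) and self.X[0, j] != 0 for j in range(k)):
            raise ValueError("design must contain an intercept column")
        if np.linalg.matrix_rank(self.X) < k:
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                f"{_collinear_columns(self.X, self.names)}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, predictors, contrast_on: str):
        names = ["intercept"] + list(predictors)
        X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
        c = np.zeros(len(names))
        c[names.index(contrast_on)] = 1.0
        return cls(X, names, c)


@dataclass
class GlmResult:
    """Voxel-wise OLS output for one contrast."""

    t: StatImage
    p: StatImage
    beta: StatImage
    df: int
    n_exact_fit: int


def voxelwise_glm(images, design: DesignMatrix, mask=None) -> GlmResult:
    """Per-voxel ordinary least squares with a two-sided contrast test.

    ``images`` is a list of StatImage (one per design row) on a shared grid.
    Voxels with numerically zero residual variance report p at
    ``P_MACHINE_FLOOR`` and are counted in ``n_exact_fit``.
    """
    if len(images) != design.n:
        raise ValueError("one image per design row required")
    if design.n < design.k + 2:
        raise ValueError("need at least k+2 subjects")
    check_same_grid(*images)
    joint_mask = np.logical_and.reduce([im.mask for im in images])
    if mask is not None:
        joint_mask &= np.asarray(mask, bool)
    Y = np.stack([im.data[joint_mask] for im in images])  # (n, v)

    X = design.X
    c = design.contrast
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                              # (k, v)
    resid = Y - X @ beta
    dof = design.n - design.k
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / dof
    cvar = float(c @ XtX_inv @ c)
    cb = c @ beta
    scale = np.maximum(np.sum(Y**2, axis=0), 1.0)
    exact = rss <= 1e-12 * scale
    se = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    t = np.where(exact, np.sign(cb) * np.inf, t)
    p = np.where(exact, P_MACHINE_FLOOR, np.maximum(p, P_MACHINE_FLOOR))

    aff = images[0].affine

    def _vol(vals, tag):
        out = np.full(joint_mask.shape, np.nan)
        out[joint_mask] = vals
        return StatImage(out, aff, tag=tag, mask=joint_mask)

    return GlmResult(
        t=_vol(t, "t"),
        p=_vol(p, "p"),
        beta=_vol(cb, "beta"),
        df=dof,
        n_exact_fit=int(exact.sum()),
    )


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up over the supplied p-values.

    Accepts an array or a p-map StatImage (in-mask voxels only).  Returns
    ``(reject, threshold)`` where ``reject`` matches the input layout and
    ``threshold`` is the adaptive p cut-off (0.0 when nothing is rejected).
    """
    from statsmodels.stats.multitest import multipletests

    if isinstance(p_values, StatImage):
        flat = p_values.in_mask()
        if flat.size == 0:
            raise ValueError("empty p-value input")
        rej_flat, thr = fdr_bh(flat, q)
        out = np.zeros(p_values.data.shape, dtype=bool)
        out[p_values.mask] = rej_flat
        return out, thr
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    reject = reject.reshape(p.shape)
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def voxelwise_auc(images_controls, images_patients, mask=None) -> StatImage:
    """Voxel-wise ROC area discriminating patients from controls.

    AUC is the Mann-Whitney statistic U/(n_a*n_b) with ties counted 1/2,
    oriented as the probability that a control voxel value exceeds a patient
    value, so *reduced* uptake in patients yields AUC > 0.5.
    """
    if len(images_controls) < 2 or len(images_patients) < 2:
        raise ValueError("both groups need at least 2 subjects")
    check_same_grid(*(list(images_controls) + list(images_patients)))
    joint = np.logical_and.reduce([im.mask for im in list(images_controls) + list(images_patients)])
    if mask is not None:
        joint &= np.asarray(mask, bool)
    A = np.stack([im.data[joint] for im in images_controls])   # (na, v)
    B = np.stack([im.data[joint] for im in images_patients])   # (nb, v)
    na, nb = A.shape[0], B.shape[0]
    both = np.concatenate([A, B], axis=0)
    ranks = stats.rankdata(both, axis=0)      # average ranks handle ties
    ra = ranks[:na].sum(axis=0)
    auc = (ra - na * (na + 1) / 2.0) / (na * nb)
    out = np.full(joint.shape, np.nan)
    out[joint] = auc
    return StatImage(out, images_controls[0].affine, tag="AUC", mask=joint)


@dataclass
class AnovaResult:
    """One-way ANOVA omnibus test plus Tukey HSD pairwise table."""

    F: float
    p: float
    pairwise: pd.DataFrame
    degenerate: bool = False


def anova_tukey(values, group_labels, pairwise: bool = True) -> AnovaResult:
    """One-way ANOVA with Tukey's HSD (studentized range, Tukey-Kramer for
    unequal group sizes).

    Groups with fewer than 2 values raise.  If every observation is
    identical the omnibus F is undefined; the result is flagged degenerate
    with all pairwise p = 1.  ``pairwise=False`` skips the HSD table (the
    studentized-range CDF is comparatively expensive) and returns the
    omnibus test only.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names = [g for g in pd.unique(group_labels)]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = [values[group_labels == g] for g in names]
    for g, arr in zip(names, groups):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    if np.all(values == values[0]):
        pairwise = pd.DataFrame(
            [
                {"group_a": names[i], "group_b": names[j], "diff": 0.0, "p_adj": 1.0}
                for i, j in pairs
            ]
        )
        return AnovaResult(F=np.nan, p=np.nan, pairwise=pairwise, degenerate=True)

    F, p = stats.f_oneway(*groups)
    if not pairwise:
        return AnovaResult(F=float(F), p=float(p), pairwise=pd.DataFrame())
    hsd = stats.tukey_hsd(*groups)
    table = pd.DataFrame(
        [
            {
                "group_a": names[i],
                "group_b": names[j],
                "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p_adj": float(hsd.pvalue[i, j]),
            }
            for i, j in pairs
        ]
    )
    return AnovaResult(F=float(F), p=float(p), pairwise=table)


def correlate(x, y, method: str = "pearson"):
    """Correlation coefficient and two-sided p.

    ``method`` is ``pearson`` or ``spearman`` (average ranks for ties).
    Requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class LongitudinalModelResult:
    """Per-predictor estimates of a longitudinal outcome regression."""

    outcome: str
    table: pd.DataFrame   # columns: variable, beta, se, p
    n: int
    r_squared: float


def fit_longitudinal_model(
    cohort: pd.DataFrame, outcome: str, predictors
) -> LongitudinalModelResult:
    """OLS of a longitudinal change score on baseline biomarkers.

    Complete-case analysis; an intercept is always included.  The result
    table mirrors the (variable, beta, std. error, p) layout of a regression
    report.
    """
    import statsmodels.api as sm

    predictors = list(predictors)
    missing = [c for c in [outcome] + predictors if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in cohort table")
    frame = cohort[[outcome] + predictors].dropna()
    if len(frame) < len(predictors) + 2:
        raise ValueError("too few complete cases")
    X = frame[predictors].to_numpy(float)
    names = ["intercept"] + predictors
    Xc = np.column_stack([np.ones(len(frame)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            "predictors are collinear: " f"{_collinear_columns(Xc, names)}"
        )
    fit = sm.OLS(frame[outcome].to_numpy(float), Xc).fit()
    table = pd.DataFrame(
        {
            "variable": names,
            "beta": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
        }
    )
    return LongitudinalModelResult(
        outcome=outcome, table=table, n=len(frame), r_squared=float(fit.rsquared)
    )
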