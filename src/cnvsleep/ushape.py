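"""Quadratic (U-shape) association testing with a nested-model LRT.

Protocol: an exploratory covariate-adjusted spline smooth of outcome on
exposure, then linear and quadratic least-squares fits on the same rows,
compared by a likelihood-ratio test (2·Δloglik vs χ²(1)).  The exposure
value at the parabola's extremum — the vertex — is −B/(2A), where A is the
coefficient on the squared exposure and B the coefficient on the linear
term, both on the original exposure scale.

The same protocol serves outcome-on-sleep (cognition vs sleep duration)
and burden-on-sleep (Σ1/LOEUF vs sleep duration) analyses; the caller
chooses exposure and outcome.

The exposure is centered before squaring for numerical conditioning;
coefficients are reported back-transformed to the original scale, so the
vertex formula applies as printed above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

VERTEX_TOL = 1e-10


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    loglik: float
    adj_r2: float
    n: int


@dataclass
class QuadraticFit:
    A: float          # coefficient on exposure², original scale
    B: float          # coefficient on exposure, original scale
    intercept: float
    A_se: float
    A_p: float
    loglik: float
    adj_r2: float
    resid_var: float
    n: int
    covariate_names: list = field(default_factory=list)
    covariate_coefs: np.ndarray = field(default=None, repr=False)

    @property
    def vertex_defined(self) -> bool:
        return abs(self.A) > VERTEX_TOL

    @property
    def vertex(self) -> float:
        return vertex(self)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float
    preferred_model: str  # "linear" | "quadratic"


@dataclass
class SmoothFit:
    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray


def _design(
    x: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((len(x), 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"c{i}" for i in range(arr.shape[1])]


def _drop_collinear(X: np.ndarray, names: list[str], n_protected: int):
    """Greedily drop trailing covariate columns until full rank.

    The first ``n_protected`` columns (intercept and exposure terms) are
    never dropped.
    """
    keep = list(range(X.shape[1]))
    while np.linalg.matrix_rank(X[:, keep]) < len(keep):
        dropped = None
        for j in reversed(keep[n_protected:]):
            trial = [k for k in keep if k != j]
            if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
                dropped = j
                break
        if dropped is None:
            break
        warnings.warn(f"dropping collinear covariate {names[dropped]!r}", stacklevel=3)
        keep.remove(dropped)
    return X[:, keep], [names[k] for k in keep]


def fit_linear_quadratic(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[LinearFit, QuadraticFit, LrtResult]:
    """Covariate-adjusted linear and quadratic fits plus the nested LRT.

    Both models use the same rows (listwise deletion over x, y and all
    covariates).  ``preferred_model`` is "quadratic" iff the LRT p-value is
    below ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C, cnames = _design(x, covariates)
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    if len(x) < 3 + C.shape[1]:
        raise ValueError(f"too few complete rows ({len(x)}) for a quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("exposure has zero variance")

    xm = x.mean()
    xc = x - xm
    names = ["const", "x", "x2"] + cnames
    Xq = np.column_stack([np.ones_like(xc), xc, xc**2, C])
    Xq, names = _drop_collinear(Xq, names, n_protected=3)
    kept_cov = [n for n in names if n not in ("const", "x", "x2")]
    Xl = Xq[:, [0, 1] + list(range(3, Xq.shape[1]))]

    res_q = sm.OLS(y, Xq).fit()
    res_l = sm.OLS(y, Xl).fit()

    a1, a2 = res_q.params[1], res_q.params[2]
    # back-transform from centered exposure: a1·xc + a2·xc² =
    #   a2·x² + (a1 − 2·a2·xm)·x + const
    A = float(a2)
    B = float(a1 - 2.0 * a2 * xm)
    intercept_q = float(res_q.params[0] - a1 * xm + a2 * xm**2)

    quad = QuadraticFit(
        A=A,
        B=B,
        intercept=intercept_q,
        A_se=float(res_q.bse[2]),
        A_p=float(res_q.pvalues[2]),
        loglik=float(res_q.llf),
        adj_r2=float(res_q.rsquared_adj),
        resid_var=float(res_q.scale),
        n=int(res_q.nobs),
        covariate_names=kept_cov,
        covariate_coefs=res_q.params[3:],
    )
    lin = LinearFit(
        slope=float(res_l.params[1]),
        intercept=float(res_l.params[0] - res_l.params[1] * xm),
        slope_se=float(res_l.bse[1]),
        slope_p=float(res_l.pvalues[1]),
        loglik=float(res_l.llf),
        adj_r2=float(res_l.rsquared_adj),
        n=int(res_l.nobs),
    )
    stat = max(0.0, 2.0 * (res_q.llf - res_l.llf))
    p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    lrt = LrtResult(
        statistic=float(stat),
        df=1,
        p_value=p,
        preferred_model="quadratic" if p < alpha else "linear",
    )
    return lin, quad, lrt


def vertex(fit: QuadraticFit) -> float:
    """Exposure value −B/(2A) at the parabola's extremum.

    Raises when |A| is below tolerance — a vertex of a near-linear fit is
    not a number.
    """
    if abs(fit.A) <= VERTEX_TOL:
        raise ValueError("vertex undefined: |A| below tolerance")
    return -fit.B / (2.0 * fit.A)


def smooth_fit(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    df: int = 10,
    degree: int = 3,
    n_grid: int = 100,
) -> SmoothFit:
    """Exploratory covariate-adjusted B-spline smooth of y on x.

    An unpenalized cubic regression spline (``df`` basis functions) fit by
    least squares jointly with the covariates; the returned curve is the
    partial effect of x (covariates held at their means) on a uniform grid,
    with pointwise standard errors.  Exploratory only — no inference.
    """
    from statsmodels.gam.smooth_basis import BSplines

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C, _ = _design(x, covariates)
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    if len(x) < 50:
        raise ValueError(f"need n >= 50 for the smooth, got {len(x)}")

    bs = BSplines(x[:, None], df=[df], degree=[degree], include_intercept=False)
    X = np.column_stack([np.ones(len(x)), bs.basis, C])
    res = sm.OLS(y, X).fit()

    grid = np.linspace(x.min(), x.max(), n_grid)
    basis_g = bs.transform(grid[:, None])
    cmean = C.mean(axis=0) if C.shape[1] else np.empty(0)
    Xg = np.column_stack(
        [np.ones(n_grid), basis_g, np.tile(cmean, (n_grid, 1))]
    )
    fitted = Xg @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
    return SmoothFit(grid=grid, fitted=fitted, se=se)


def tidy(lin: LinearFit, quad: QuadraticFit, lrt: LrtResult) -> pd.DataFrame:
    """Model-comparison summary as a tidy one-row-per-term table."""
    rows = [
        {"model": "linear", "term": "x", "estimate": lin.slope, "se": lin.slope_se,
         "p": lin.slope_p},
        {"model": "quadratic", "term": "x2", "estimate": quad.A, "se": quad.A_se,
         "p": quad.A_p},
        {"model": "quadratic", "term": "x", "estimate": quad.B, "se": np.nan, "p": np.nan},
        {"model": "lrt", "term": "statistic", "estimate": lrt.statistic, "se": np.nan,
         "p": lrt.p_value},
    ]
    return pd.DataFrame(rows)
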