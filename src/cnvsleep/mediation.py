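"""Causal mediation of the burden → cognition effect through sleep deviation.

Product-of-coefficients decomposition for the linear–linear case:

    mediator model   M ~ a·X + covariates
    outcome model    Y ~ c'·X + b·M + covariates

    ACME (average causal mediation effect) = a·b
    ADE  (average direct effect)           = c'
    total effect                           = a·b + c'   (exact OLS identity)
    proportion mediated                    = ACME / total

Uncertainty comes from a nonparametric bootstrap: individuals are resampled
with replacement, both regressions are refit, and percentile intervals /
sign-crossing p-values are taken over the bootstrap draws.  Point estimates
are always the full-sample two-regression values; the bootstrap is used
only for uncertainty.

The default mediator for the sleep analyses is the absolute deviation of
self-reported sleep duration from the cohort mean, which linearizes the
U-shaped burden–sleep relationship so a linear mediation model is coherent;
plain duration can be passed instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOTAL_TOL = 1e-10

_STATS = ("a", "b", "acme", "ade", "total", "prop_mediated")


@dataclass
class MediationResult:
    a: float
    b: float
    acme: float
    ade: float
    total: float
    prop_mediated: float | None  # None when |total| <= tolerance
    ci: dict = field(default_factory=dict)        # stat -> (lo, hi), 2.5/97.5 percentile
    p_value: dict = field(default_factory=dict)   # stat -> two-sided bootstrap p
    n: int = 0
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in _STATS},
            "ci": {k: list(v) for k, v in self.ci.items()},
            "p_value": dict(self.p_value),
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def absolute_deviation(sleep) -> np.ndarray:
    """|sleep − cohort mean|, the linearized U-shape mediator (hours)."""
    arr = np.asarray(sleep, dtype=float)
    return np.abs(arr - np.nanmean(arr))


def _estimate(X_m, M, X_y, y) -> tuple[float, float, float]:
    """(a, b, ade) from the two regressions sharing covariates."""
    beta_m, *_ = np.linalg.lstsq(X_m, M, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X_y, y, rcond=None)
    return float(beta_m[1]), float(beta_y[2]), float(beta_y[1])


def mediate(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Two-regression mediation with nonparametric bootstrap uncertainty.

    Parameters
    ----------
    exposure, mediator, outcome : array-like
        Per-individual exposure (e.g. Σ1/LOEUF), mediator (e.g. absolute
        sleep deviation in hours) and outcome (e.g. cognition z).
    covariates : array-like or DataFrame, optional
        Adjustment covariates entering both models.
    n_boot : int
        Bootstrap resamples (>= 100).  Percentile 95% CIs; two-sided
        p-values are twice the fraction of bootstrap draws crossing zero,
        floored at 1/n_boot.
    seed : int, optional
        Seed for the resampling stream; fixed seed gives bit-reproducible
        output.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
    ok = (
        np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
        & np.all(np.isfinite(C), axis=1)
    )
    x, m, y, C = x[ok], m[ok], y[ok], C[ok]
    n = len(x)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if n < C.shape[1] + 3:
        raise ValueError(f"too few complete cases: {n}")
    if np.ptp(m) == 0:
        raise ValueError("mediator is constant")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant")

    ones = np.ones(n)
    X_m = np.column_stack([ones, x, C])
    X_y = np.column_stack([ones, x, m, C])
    a, b, ade = _estimate(X_m, m, X_y, y)
    if not all(np.isfinite(v) for v in (a, b, ade)):
        raise ValueError("non-finite fit")
    acme = a * b
    total = acme + ade
    prop = acme / total if abs(total) > TOTAL_TOL else None

    rng = np.random.default_rng(seed)
    draws = {k: np.full(n_boot, np.nan) for k in _STATS}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, bb, adeb = _estimate(X_m[idx], m[idx], X_y[idx], y[idx])
        acmeb = ab * bb
        totalb = acmeb + adeb
        draws["a"][i] = ab
        draws["b"][i] = bb
        draws["acme"][i] = acmeb
        draws["ade"][i] = adeb
        draws["total"][i] = totalb
        if abs(totalb) > TOTAL_TOL:
            draws["prop_mediated"][i] = acmeb / totalb

    ci = {}
    pvals = {}
    for k, v in draws.items():
        vv = v[np.isfinite(v)]
        if not len(vv):
            continue
        ci[k] = (float(np.percentile(vv, 2.5)), float(np.percentile(vv, 97.5)))
        crossing = min((vv > 0).mean(), (vv < 0).mean())
        pvals[k] = float(min(1.0, max(2.0 * crossing, 1.0 / n_boot)))

    return MediationResult(
        a=a, b=b, acme=acme, ade=ade, total=total, prop_mediated=prop,
        ci=ci, p_value=pvals, n=n, n_boot=n_boot, seed=seed,
    )


def proportion_mediated(result: MediationResult, as_percent: bool = False) -> float:
    """ACME / total effect; raises when the total effect is ~0."""
    if result.prop_mediated is None or abs(result.total) <= TOTAL_TOL:
        raise ValueError("proportion mediated undefined: |total effect| ~ 0")
    return result.prop_mediated * 100.0 if as_percent else result.prop_mediated


def mediate_burden_sleep_cognition(
    cohort: pd.DataFrame,
    burden: pd.DataFrame,
    cnv_type: str,
    covariates=("age", "sex", *[f"pc{i}" for i in range(1, 11)]),
    mediator: str = "abs_deviation",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Convenience wrapper: Σ1/LOEUF (DEL or DUP) → sleep deviation → cognition."""
    tag = cnv_type.lower()
    merged = cohort.merge(burden, on="individual_id", how="inner")
    x = merged[f"{tag}_sum_inv_loeuf"].to_numpy(float)
    sleep = merged["sleep_selfreport"].to_numpy(float)
    med = absolute_deviation(sleep) if mediator == "abs_deviation" else sleep
    return mediate(
        x, med, merged["cognition"].to_numpy(float),
        covariates=merged[list(covariates)], n_boot=n_boot, seed=seed,
    )


def worked_example(a: float, b: float, ade: float, n: int = 60, n_boot: int = 200,
                   seed: int = 0) -> MediationResult:
    """Deterministic dataset built so OLS returns exactly the given paths.

    Constructs (X, M, Y) with M = a·X + u, u exactly orthogonal to (1, X),
    and Y = b·M + ade·X with zero residual, so the two-regression estimates
    reproduce a, b and ade to machine precision regardless of sample size.
    """
    x = np.arange(n, dtype=float)
    x -= x.mean()
    u = np.tile([1.0, -1.0], n // 2 + 1)[:n]
    u -= u.mean()
    u -= (u @ x) / (x @ x) * x  # exact orthogonality to x
    m = a * x + u
    y = b * m + ade * x
    return mediate(x, m, y, n_boot=n_boot, seed=seed)
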