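"""Recurrent-CNV carrier association scans and LOEUF-stratified burden regressions.

Carrier calling uses 40% reciprocal overlap between a same-type call and the
locus critical interval — a conventional CNV-matching criterion, exposed as
a single parameter.  Loci are analyzed only when strictly more than 10
carriers are present in the analyzed sample.  Multiple testing is corrected
by Benjamini–Hochberg FDR within each phenotype, separately for deletion
and duplication loci.

The stratified regressions fit, per LOEUF category, CNV type and phenotype:

    Y_i ~ β0 + β1·(genes inside category) + β2·(genes outside category)
          + β3·age + β4·sex + 10 PCs

where the gene counts are the individual's deleted (or duplicated) genes
inside vs outside the category; β1 is the per-gene effect of the category,
adjusted for the rest of that individual's same-type gene content.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .burden import CATEGORY_NAMES, normalize_chrom

logger = logging.getLogger(__name__)

MIN_CARRIERS = 10  # strict: a locus needs MORE than this many carriers
RECIPROCAL_OVERLAP = 0.4

DEFAULT_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]


def carrier_status(
    calls: pd.DataFrame,
    loci: pd.DataFrame,
    individual_ids: Sequence[str],
    reciprocal_overlap: float = RECIPROCAL_OVERLAP,
) -> pd.DataFrame:
    """Boolean individuals × loci matrix of recurrent-CNV carrier status.

    An individual carries a locus when any same-type call overlaps the
    locus interval reciprocally by at least ``reciprocal_overlap`` of both
    the call and the locus length.
    """
    idx = pd.Index(individual_ids, name="individual_id")
    out = pd.DataFrame(False, index=idx, columns=list(loci["label"]))
    if not len(calls):
        return out
    cchrom = normalize_chrom(calls["chrom"]).to_numpy()
    cstart = calls["start"].to_numpy()
    cend = calls["end"].to_numpy()
    ctype = calls["cnv_type"].to_numpy()
    cind = calls["individual_id"].to_numpy()
    clen = (cend - cstart).astype(float)
    for _, locus in loci.iterrows():
        lchrom = normalize_chrom([locus["chrom"]]).iloc[0]
        ls, le = locus["start"], locus["end"]
        llen = float(le - ls)
        ov = np.minimum(cend, le) - np.maximum(cstart, ls)
        hit = (
            (ctype == locus["cnv_type"])
            & (cchrom == lchrom)
            & (ov >= reciprocal_overlap * llen)
            & (ov >= reciprocal_overlap * clen)
        )
        if hit.any():
            out.loc[np.unique(cind[hit]), locus["label"]] = True
    return out


@dataclass
class AssocResult:
    label: str
    phenotype: str
    cnv_type: str
    n: int
    n_carriers: int
    estimate: float
    se: float
    p: float
    converged: bool
    fdr_q: float = np.nan


def _fit_one(y: np.ndarray, X: np.ndarray, logistic: bool):
    if logistic:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                return np.nan, np.nan, np.nan, False
        converged = bool(res.mle_retvals.get("converged", True)) and np.all(
            np.isfinite(res.bse)
        )
        return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]), converged
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]), True


def scan_loci(
    cohort: pd.DataFrame,
    carriers: pd.DataFrame,
    loci: pd.DataFrame,
    phenotypes: Sequence[str],
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    logistic_phenotypes: Sequence[str] = ("probable_insomnia",),
    min_carriers: int = MIN_CARRIERS,
) -> pd.DataFrame:
    """Per-locus, per-phenotype carrier regressions with within-family BH-FDR.

    Continuous phenotypes use least squares; phenotypes listed in
    ``logistic_phenotypes`` use logistic regression.  FDR families are one
    per (phenotype, CNV type); non-converged logistic fits are flagged and
    excluded from their family.  Loci with ``<= min_carriers`` carriers in
    the analyzed rows are skipped entirely.
    """
    data = cohort.set_index("individual_id")
    carr = carriers.reindex(data.index).fillna(False)
    locus_type = dict(zip(loci["label"], loci["cnv_type"]))
    results: list[AssocResult] = []
    for phen in phenotypes:
        y_all = pd.to_numeric(data[phen], errors="coerce")
        C = data[list(covariates)].astype(float)
        base_ok = y_all.notna() & C.notna().all(axis=1)
        logistic = phen in logistic_phenotypes
        for label in carr.columns:
            g = carr[label].to_numpy()
            ok = base_ok.to_numpy()
            n_carriers = int(g[ok].sum())
            if n_carriers <= min_carriers:
                logger.info(
                    "scan_loci: %s × %s skipped (%d carriers, need >%d)",
                    label, phen, n_carriers, min_carriers,
                )
                continue
            X = np.column_stack(
                [np.ones(ok.sum()), g[ok].astype(float), C.to_numpy()[ok]]
            )
            est, se, p, conv = _fit_one(y_all.to_numpy()[ok], X, logistic)
            results.append(
                AssocResult(
                    label=label, phenotype=phen,
                    cnv_type=locus_type.get(label, "NA"),
                    n=int(ok.sum()), n_carriers=n_carriers,
                    estimate=est, se=se, p=p, converged=conv,
                )
            )
    df = pd.DataFrame([r.__dict__ for r in results])
    if not len(df):
        return df
    df["fdr_q"] = np.nan
    for (_, _), sub in df.groupby(["phenotype", "cnv_type"]):
        fam = sub[sub["converged"] & sub["p"].notna()]
        if len(fam):
            _, q, _, _ = multipletests(fam["p"].to_numpy(), method="fdr_bh")
            df.loc[fam.index, "fdr_q"] = q
    return df.reset_index(drop=True)


@dataclass
class StratifiedFit:
    category: str
    cnv_type: str
    phenotype: str
    beta1: float       # per-gene effect inside the category
    beta1_se: float
    beta1_p: float
    beta2: float       # per-gene effect outside the category
    n: int


def stratified_burden_regression(
    cohort: pd.DataFrame,
    burden: pd.DataFrame,
    category: str,
    cnv_type: str,
    phenotype: str,
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    logistic: bool = False,
) -> StratifiedFit | None:
    """One fit of the category-stratified gene-count regression.

    Returns None (with a warning) when the inside-category count has zero
    variance in the analyzed rows — β1 is then unidentifiable.
    """
    if category not in CATEGORY_NAMES:
        raise ValueError(f"unknown LOEUF category {category!r}")
    tag = cnv_type.lower()
    if tag not in ("del", "dup"):
        raise ValueError(f"cnv_type must be DEL or DUP, got {cnv_type!r}")
    merged = cohort.merge(burden, on="individual_id", how="inner")
    inside = merged[f"{tag}_n_{category}"].astype(float)
    outside = (merged[f"{tag}_n_genes"] - inside).astype(float)
    y = pd.to_numeric(merged[phenotype], errors="coerce")
    C = merged[list(covariates)].astype(float)
    ok = y.notna() & C.notna().all(axis=1)
    if inside[ok].nunique() <= 1:
        warnings.warn(
            f"stratified regression skipped: zero variance in {tag}_n_{category}",
            stacklevel=2,
        )
        return None
    X = np.column_stack(
        [np.ones(int(ok.sum())), inside[ok], outside[ok], C[ok].to_numpy()]
    )
    if logistic:
        res = sm.Logit(y[ok].to_numpy(), X).fit(disp=0)
    else:
        res = sm.OLS(y[ok].to_numpy(), X).fit()
    return StratifiedFit(
        category=category, cnv_type=cnv_type.upper(), phenotype=phenotype,
        beta1=float(res.params[1]), beta1_se=float(res.bse[1]),
        beta1_p=float(res.pvalues[1]), beta2=float(res.params[2]),
        n=int(ok.sum()),
    )


def stratified_scan(
    cohort: pd.DataFrame,
    burden: pd.DataFrame,
    phenotypes: Sequence[str],
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    logistic_phenotypes: Sequence[str] = ("probable_insomnia",),
) -> pd.DataFrame:
    """All (category × CNV type × phenotype) stratified regressions, tidy."""
    rows = []
    for phen in phenotypes:
        for cnv_type in ("DEL", "DUP"):
            for category in CATEGORY_NAMES:
                fit = stratified_burden_regression(
                    cohort, burden, category, cnv_type, phen,
                    covariates=covariates,
                    logistic=phen in logistic_phenotypes,
                )
                if fit is not None:
                    rows.append(fit.__dict__)
    return pd.DataFrame(rows)
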