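"""Phenotype exclusion rules, insomnia coding and covariate-adjusted z-scores.

Filters never drop rows: an out-of-range measure is set missing so the
record stays available for the other phenotypes (per-analysis sample sizes
then differ by phenotype, as in biobank practice).  All bounds are strict
inequalities: sleep durations of exactly 3 or 12 hours are kept, exactly 5
wear-days is kept, age exactly 65 is kept by the sensitivity subset.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLEEP_MIN_HOURS = 3.0
SLEEP_MAX_HOURS = 12.0
MIN_WEAR_DAYS = 5

INSOMNIA_CASES = ("sometimes", "usually")
INSOMNIA_CONTROL = "never_rarely"
INSOMNIA_REFUSED = "prefer_not_answer"


def _out_of_range(values: pd.Series) -> pd.Series:
    return values.notna() & ((values < SLEEP_MIN_HOURS) | (values > SLEEP_MAX_HOURS))


def filter_sleep_duration(cohort: pd.DataFrame, report: dict | None = None) -> pd.DataFrame:
    """Set self-reported and accelerometer durations <3 h or >12 h missing."""
    out = cohort.copy()
    for col in ("sleep_selfreport", "sleep_accel"):
        if col not in out.columns:
            continue
        bad = _out_of_range(out[col])
        out.loc[bad, col] = np.nan
        n_bad = int(bad.sum())
        logger.info("filter_sleep_duration: %d %s values set missing", n_bad, col)
        if report is not None:
            report[f"sleep_duration_removed_{col}"] = n_bad
    return out


def filter_accelerometer(cohort: pd.DataFrame, report: dict | None = None) -> pd.DataFrame:
    """Drop accelerometer measures for wear < 5 days or out-of-range duration."""
    out = cohort.copy()
    if "accel_wear_days" in out.columns:
        short_wear = out["accel_wear_days"].notna() & (out["accel_wear_days"] < MIN_WEAR_DAYS)
    else:
        short_wear = pd.Series(False, index=out.index)
    bad_duration = _out_of_range(out["sleep_accel"]) if "sleep_accel" in out.columns else (
        pd.Series(False, index=out.index)
    )
    bad = short_wear | bad_duration
    for col in ("sleep_accel", "sleep_efficiency"):
        if col in out.columns:
            out.loc[bad, col] = np.nan
    n_bad = int(bad.sum())
    logger.info("filter_accelerometer: %d accelerometer records set missing", n_bad)
    if report is not None:
        report["accelerometer_removed"] = n_bad
    return out


def code_insomnia(cohort: pd.DataFrame, report: dict | None = None) -> pd.DataFrame:
    """Binary probable insomnia: sometimes/usually = case, never_rarely = control,
    prefer_not_answer / missing = NaN."""
    out = cohort.copy()
    resp = out["insomnia_response"]
    known = set(INSOMNIA_CASES) | {INSOMNIA_CONTROL, INSOMNIA_REFUSED}
    unknown = resp.dropna()[~resp.dropna().isin(known)]
    if len(unknown):
        raise ValueError(f"unknown insomnia response category: {unknown.iloc[0]!r}")
    coded = pd.Series(np.nan, index=out.index, dtype=float)
    coded[resp.isin(INSOMNIA_CASES)] = 1.0
    coded[resp == INSOMNIA_CONTROL] = 0.0
    out["probable_insomnia"] = coded
    if report is not None:
        report["insomnia_refused_removed"] = int((resp == INSOMNIA_REFUSED).sum())
        report["insomnia_cases"] = int((coded == 1.0).sum())
        report["insomnia_controls"] = int((coded == 0.0).sum())
    return out


def zscore_adjust(score, age, sex) -> np.ndarray:
    """Residualize a raw score on age and sex, then scale to unit SD.

    Returns NaN where any input is missing.  If sex is constant the
    adjustment falls back to age only, with a warning.
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ok = np.isfinite(score) & np.isfinite(age) & np.isfinite(sex)
    if ok.sum() < 30:
        raise ValueError(f"need >= 30 non-missing scores, got {int(ok.sum())}")
    cols = [np.ones(ok.sum()), age[ok]]
    if np.ptp(sex[ok]) > 0:
        cols.append(sex[ok])
    else:
        warnings.warn("sex is constant; adjusting for age only", stacklevel=2)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, score[ok], rcond=None)
    resid = score[ok] - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("score has zero residual variance")
    out = np.full(score.shape, np.nan)
    out[ok] = resid / sd
    return out


def sensitivity_subset(
    cohort: pd.DataFrame,
    drop_medication: bool = False,
    drop_over65: bool = False,
    report: dict | None = None,
) -> pd.DataFrame:
    """Sensitivity re-run subset: optionally remove medicated individuals
    and those strictly above 65 years."""
    keep = pd.Series(True, index=cohort.index)
    if drop_medication and "medication_flag" in cohort.columns:
        keep &= ~cohort["medication_flag"].astype(bool)
    if drop_over65:
        keep &= ~(cohort["age"] > 65.0)
    out = cohort.loc[keep].reset_index(drop=True)
    logger.info("sensitivity_subset: kept %d of %d rows", len(out), len(cohort))
    if report is not None:
        report["sensitivity_kept"] = int(len(out))
        report["sensitivity_removed"] = int(len(cohort) - len(out))
    return out


def apply_qc(
    cohort: pd.DataFrame,
    drop_medication: bool = False,
    drop_over65: bool = False,
    adjust_cognition: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full QC chain and return (cohort, per-filter report)."""
    report: dict = {"n_input": int(len(cohort))}
    out = filter_sleep_duration(cohort, report)
    out = filter_accelerometer(out, report)
    out = code_insomnia(out, report)
    if adjust_cognition:
        for col in ("cognition", "trail_making", "tower"):
            if col in out.columns:
                out[col] = zscore_adjust(out[col], out["age"], out["sex"])
    out = sensitivity_subset(out, drop_medication, drop_over65, report)
    report["n_output"] = int(len(out))
    return out, report


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
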