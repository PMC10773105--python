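"""Case/control/excluded status, onset ages, and covariate selection.

Diseases are defined by ICD-10-style inclusion and exclusion code lists.
A sample is a *case* if any hospital diagnosis matches the inclusion list;
it is *excluded* if, while not being a case, it carries any hospital or
self-reported code on the exclusion list or a self-reported counterpart of
the case definition (self-reported cases are excluded, not counted as
cases); otherwise it is a *control*. Case status takes precedence over
exclusion. Second-level (3-character) codes match all their subcodes; full
codes match exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = date(2021, 9, 30)
DAYS_PER_YEAR = 365.25

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


@dataclass(frozen=True)
class DiseaseDefinition:
    """Inclusion/exclusion code lists defining one disease."""

    disease: str
    inclusion: tuple[str, ...]
    exclusion: tuple[str, ...] = ()
    self_report_exclusion: tuple[str, ...] = ()
    sex_restriction: str = "none"  # none | female_only | male_only

    def __post_init__(self):
        if self.sex_restriction not in ("none", "female_only", "male_only"):
            raise ValueError(f"bad sex_restriction {self.sex_restriction!r}")


def _normalize_code(code: str) -> str | None:
    c = str(code).replace(".", "").strip().upper()
    return c if _CODE_RE.match(c) else None


def _matches(code: str, code_list: tuple[str, ...]) -> bool:
    """Second-level (3-char) codes match all subcodes, full codes exactly."""
    for ref in code_list:
        ref = ref.replace(".", "").upper()
        if len(ref) == 3:
            if code.startswith(ref):
                return True
        elif code == ref:
            return True
    return False


def assign_status(
    records: pd.DataFrame,
    defs: list[DiseaseDefinition],
    samples,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample case/control/excluded status for each disease.

    ``records`` carries (sample_id, code, date, source) with source in
    {hospital, self_report}. ``samples`` is the full cohort roster (samples
    without records are controls). ``sex`` (1 = female), indexed by
    sample_id, is required when any definition is sex-restricted.
    """
    samples = list(samples)
    rec = records.copy()
    rec["norm"] = rec["code"].map(_normalize_code)
    bad = rec["norm"].isna()
    if bad.any():
        logger.warning("rejected %d records with unparseable codes", int(bad.sum()))
        rec = rec.loc[~bad]
    if not rec["source"].isin(["hospital", "self_report"]).all():
        raise ValueError("record source must be 'hospital' or 'self_report'")

    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    by_sample = dict(tuple(rec.groupby("sample_id")))
    for d in defs:
        status = pd.Series("control", index=out.index, dtype=object)
        for sid, sub in by_sample.items():
            if sid not in out.index:
                continue
            hosp = sub.loc[sub["source"] == "hospital", "norm"]
            selfr = sub.loc[sub["source"] == "self_report", "norm"]
            if any(_matches(c, d.inclusion) for c in hosp):
                status[sid] = "case"  # case precedence over exclusion
                continue
            excluded = (
                any(_matches(c, d.exclusion) for c in sub["norm"])
                or any(_matches(c, d.inclusion) for c in selfr)
                or any(_matches(c, d.self_report_exclusion) for c in selfr)
            )
            if excluded:
                status[sid] = "excluded"
        if d.sex_restriction != "none":
            if sex is None:
                raise ValueError(f"{d.disease} is sex-restricted but sex not provided")
            wanted = 1 if d.sex_restriction == "female_only" else 0
            status[sex.reindex(out.index) != wanted] = "excluded"
        out[d.disease] = status
    return out


def birth_date(birth_year: int, birth_month: int) -> date:
    """Birthday imputed to the 15th of the birth month."""
    return date(int(birth_year), int(birth_month), 15)


def age_at_diagnosis(first_dx_date, birth_year: int, birth_month: int) -> float:
    """Years between the (imputed) birth date and the first diagnosis date."""
    b = pd.Timestamp(birth_date(birth_year, birth_month))
    dx = pd.Timestamp(first_dx_date)
    days = (dx - b).days
    if days < 0:
        raise ValueError("diagnosis date precedes birth date")
    return days / DAYS_PER_YEAR


def first_diagnosis_dates(
    records: pd.DataFrame, definition: DiseaseDefinition
) -> pd.Series:
    """Earliest hospital inclusion-code date per sample (cases only)."""
    rec = records.copy()
    rec["norm"] = rec["code"].map(_normalize_code)
    rec = rec.loc[rec["norm"].notna() & (rec["source"] == "hospital")]
    hit = rec.loc[[_matches(c, definition.inclusion) for c in rec["norm"]]]
    return pd.to_datetime(hit["date"]).groupby(hit["sample_id"]).min()


def age_last_healthy(
    status: str,
    age_at_dx: float | None,
    birth: date,
    cutoff: date = DEFAULT_CUTOFF,
) -> float:
    """Age at diagnosis for cases; age at the cutoff date for controls."""
    if status == "case":
        if age_at_dx is None or not np.isfinite(age_at_dx):
            raise ValueError("case without an age at diagnosis")
        return float(age_at_dx)
    if status == "control":
        days = (pd.Timestamp(cutoff) - pd.Timestamp(birth)).days
        if days < 0:
            raise ValueError("control born after the cutoff date")
        return days / DAYS_PER_YEAR
    raise ValueError(f"age_last_healthy undefined for status {status!r}")


def select_covariates(
    status: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Retain covariates nominally associated with disease status.

    A single multivariable logistic regression of status (1 = case,
    0 = control; anything else dropped) on all covariates jointly; columns
    with coefficient p <= alpha are retained. Constant columns are dropped
    before fitting; missing covariate values are handled complete-case. On
    non-convergence every covariate is retained with a warning.
    """
    y = status.map({"case": 1, "control": 0, 1: 1, 0: 0})
    keep = y.notna()
    X = covariates.loc[keep.to_numpy()].copy()
    y = y.loc[keep.to_numpy()].astype(float)
    cc = X.notna().all(axis=1)
    if not cc.all():
        logger.info("covariate selection: dropping %d incomplete rows", int((~cc).sum()))
        X, y = X.loc[cc], y.loc[cc]
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.info("covariate selection: dropping constant columns %s", constant)
        X = X.drop(columns=constant)
    if (y.sum() < 2) or ((1 - y).sum() < 2):
        raise ValueError("need >= 2 cases and >= 2 controls")
    candidates = list(X.columns)
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("no convergence")
        pvals = fit.pvalues
    except Exception as exc:  # non-convergence / separation: keep everything
        logger.warning("covariate selection regression failed (%s); retaining all", exc)
        return candidates
    return [c for c in candidates if pvals[c] <= alpha]


def select_covariates_linear(
    outcome: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Covariate selection for a quantitative outcome (disease burden):
    one joint OLS, retaining columns with coefficient p <= alpha."""
    y = pd.Series(outcome).astype(float)
    X = covariates.copy()
    cc = X.notna().all(axis=1).to_numpy() & y.notna().to_numpy()
    X, y = X.loc[cc], y.loc[cc]
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        X = X.drop(columns=constant)
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.OLS(y, Xd).fit()
    return [c for c in X.columns if fit.pvalues[c] <= alpha]
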