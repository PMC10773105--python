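"""Probe pre-filtering, dosage-model encodings, and the CNV-GWAS scans.

Four dosage models translate the signed probe genotype g in {-1, 0, +1}
into the regressor of a per-probe regression:

* ``mirror``  — g itself: each additional copy shifts risk additively, so
  deletions and duplications act in opposite directions;
* ``ushape``  — |g|: any deviation from the copy-neutral state shifts risk
  in the same direction;
* ``duponly`` — duplication carriers vs copy-neutral, deletion carriers
  masked (dropped from that regression);
* ``delonly`` — deletion carriers vs copy-neutral, duplication carriers
  masked.

Effects are harmonized so the reported beta is the effect of carrying the
CNV — or of one additional copy for the mirror model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .firth import firth_logistic
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

MODELS = ("mirror", "ushape", "duponly", "delonly")

DEFAULT_FISHER_CUT = 1e-3
DEFAULT_MIN_CASES = 2
MAX_CONDITIONAL_ROUNDS = 20


def encode_genotypes(g: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
    """Dosage and validity mask of signed genotypes under a model.

    Masked entries (the disregarded CNV type of the type-specific models)
    have ``valid`` False and should be dropped from the regression rather
    than imputed to zero, which would contaminate the reference class.
    """
    g = np.asarray(g)
    if not np.all(np.isin(g[np.isfinite(g)], [-1, 0, 1])):
        raise ValueError("genotypes must lie in {-1, 0, +1}")
    valid = np.isfinite(g)
    dose = np.where(valid, g, 0.0).astype(float)
    if model == "mirror":
        pass
    elif model == "ushape":
        dose = np.abs(dose)
    elif model == "duponly":
        valid = valid & (g != -1)
        dose = np.where(dose == 1, 1.0, 0.0)
    elif model == "delonly":
        valid = valid & (g != 1)
        dose = np.where(dose == -1, 1.0, 0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return dose, valid


def genotypic_fisher(genotypes: np.ndarray, status: np.ndarray) -> float:
    """Exact two-sided p of the 2x3 (control/case x del/neutral/dup) table.

    Two-sided by probability-mass ordering: sum the probabilities, under the
    multivariate hypergeometric null with fixed margins, of all tables no
    more probable than the observed one. A genotype column with zero margin
    collapses the test to the 2x2 exact test.
    """
    g = np.asarray(genotypes)
    y = np.asarray(status)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("status must be binary 0/1")
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one case and one control")
    table = np.zeros((2, 3), dtype=int)
    for row, sel in ((0, y == 0), (1, y == 1)):
        gg = g[sel]
        table[row] = [(gg == -1).sum(), (gg == 0).sum(), (gg == 1).sum()]
    return fisher_2x3(table)


def fisher_2x3(table: np.ndarray) -> float:
    """Exact two-sided p-value for a 2x3 contingency table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 3) or (table < 0).any():
        raise ValueError("expected a nonnegative 2x3 table")
    col = table.sum(axis=0)
    nonzero = col > 0
    if nonzero.sum() <= 1:
        return 1.0
    if nonzero.sum() == 2:  # zero-margin column: collapse to 2x2 exact test
        return float(stats.fisher_exact(table[:, nonzero])[1])
    r0 = int(table[0].sum())
    n = int(table.sum())
    c0, c1, c2 = (int(c) for c in col)
    log_denom = _log_comb(n, r0)

    def log_prob(a: int, b: int) -> float:
        m = r0 - a - b  # control x neutral cell
        return (
            _log_comb(c0, a) + _log_comb(c1, m) + _log_comb(c2, b) - log_denom
        )

    lp_obs = log_prob(int(table[0, 0]), int(table[0, 2]))
    total = 0.0
    for a in range(0, min(r0, c0) + 1):
        b_lo = max(0, r0 - a - c1)
        b_hi = min(c2, r0 - a)
        for b in range(b_lo, b_hi + 1):
            lp = log_prob(a, b)
            if lp <= lp_obs + 1e-9:
                total += np.exp(lp)
    return float(min(total, 1.0))


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def prefilter(
    m: GenotypeMatrix,
    frequencies: pd.DataFrame,
    status: np.ndarray,
    fisher_cut: float = DEFAULT_FISHER_CUT,
    min_cases: int = DEFAULT_MIN_CASES,
) -> pd.DataFrame:
    """Per-probe Fisher screen and carrier-case counting.

    ``status`` is 1/0/NaN over ``m.samples`` (NaN = excluded). A probe
    enters the mirror/U-shape scan if its Fisher p <= ``fisher_cut`` and it
    has >= ``min_cases`` cases among CNV carriers; the duplication-only
    (deletion-only) scan additionally requires >= ``min_cases`` cases among
    duplication (deletion) carriers. Probes failing the frequency filter
    (``retained`` False in ``frequencies``) are excluded before testing.
    """
    status = np.asarray(status, dtype=float)
    analyzed = np.isfinite(status)
    y = status[analyzed]
    retained = frequencies["retained"].to_numpy()
    rows = []
    for i in range(m.n_probes):
        rec = {
            "probe_id": m.probes["probe_id"].iat[i],
            "fisher_p": np.nan,
            "n_case_cnv": 0,
            "n_case_dup": 0,
            "n_case_del": 0,
        }
        if not retained[i]:
            rec.update(
                freq_excluded=True,
                pass_mirror=False, pass_ushape=False,
                pass_duponly=False, pass_delonly=False,
            )
            rows.append(rec)
            continue
        g = m.row(i)[analyzed]
        n_case_dup = int(((g == 1) & (y == 1)).sum())
        n_case_del = int(((g == -1) & (y == 1)).sum())
        n_case_cnv = n_case_dup + n_case_del
        fp = genotypic_fisher(g, y)
        pass_joint = fp <= fisher_cut and n_case_cnv >= min_cases
        rec.update(
            fisher_p=fp,
            n_case_cnv=n_case_cnv,
            n_case_dup=n_case_dup,
            n_case_del=n_case_del,
            freq_excluded=False,
            pass_mirror=pass_joint,
            pass_ushape=pass_joint,
            pass_duponly=fp <= fisher_cut and n_case_dup >= min_cases,
            pass_delonly=fp <= fisher_cut and n_case_del >= min_cases,
        )
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["probe_id", "fisher_p", "n_case_cnv", "n_case_dup",
                 "n_case_del", "freq_excluded", "pass_mirror", "pass_ushape",
                 "pass_duponly", "pass_delonly"],
    )


def _standardize(C: np.ndarray) -> np.ndarray:
    """Variance-standardize covariate columns (zero-variance left centered)."""
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        return C
    mu = C.mean(axis=0)
    sd = C.std(axis=0)
    sd[sd == 0] = 1.0
    return (C - mu) / sd


def _collinear_with(d: np.ndarray, other: np.ndarray) -> bool:
    """True if the dosage is (numerically) in the span of the other columns."""
    coef, *_ = np.linalg.lstsq(other, d, rcond=None)
    resid = d - other @ coef
    scale = float(d @ d) or 1.0
    return float(resid @ resid) / scale < 1e-10


def _empty_cell(dose: np.ndarray, y: np.ndarray) -> bool:
    """True if any genotype-class x outcome cell of the table is empty."""
    for v in np.unique(dose):
        sub = y[dose == v]
        if (sub == 1).sum() == 0 or (sub == 0).sum() == 0:
            return True
    return False


RECORD_COLUMNS = [
    "probe_id", "chrom", "pos", "model", "beta", "se", "p", "or",
    "ci_low", "ci_high", "firth", "skipped_reason", "n_case", "n_control",
    "n_case_carrier",
]


def _assoc_record(m, i, model, beta, se, p, firth_used, skipped, y, dose):
    probe = m.probes.iloc[i]
    rec = {
        "probe_id": probe["probe_id"],
        "chrom": probe["chrom"],
        "pos": int(probe["pos"]),
        "model": model,
        "beta": beta,
        "se": se,
        "p": p,
        "or": np.exp(beta) if np.isfinite(beta) else np.nan,
        "ci_low": np.exp(beta - 1.959963984540054 * se) if np.isfinite(se) else np.nan,
        "ci_high": np.exp(beta + 1.959963984540054 * se) if np.isfinite(se) else np.nan,
        "firth": bool(firth_used),
        "skipped_reason": skipped,
    }
    if y is not None:
        rec["n_case"] = int((y == 1).sum())
        rec["n_control"] = int((y == 0).sum())
        rec["n_case_carrier"] = int(((dose != 0) & (y == 1)).sum())
    else:
        rec["n_case"] = rec["n_control"] = rec["n_case_carrier"] = 0
    return rec


def run_gwas(
    m: GenotypeMatrix,
    status: np.ndarray,
    covariates: pd.DataFrame | None,
    model: str,
    probe_mask: np.ndarray | None = None,
    conditioning: np.ndarray | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
) -> pd.DataFrame:
    """Per-probe Firth-fallback logistic scan under one dosage model.

    ``status`` is 1/0/NaN over ``m.samples``; ``covariates`` holds the
    pre-selected, per-disease covariate columns (variance-standardized
    before fitting); ``conditioning`` optionally appends encoded lead-probe
    genotypes (samples x leads) for the stepwise conditional analysis.
    Samples with a masked dosage, excluded status, or missing conditioning
    value are dropped per probe.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    status = np.asarray(status, dtype=float)
    C = covariates.to_numpy(dtype=float) if covariates is not None and len(
        covariates.columns
    ) else np.empty((m.n_samples, 0))
    if C.shape[0] != m.n_samples:
        raise ValueError("covariates not aligned with matrix samples")
    cond = (
        np.asarray(conditioning, dtype=float).reshape(m.n_samples, -1)
        if conditioning is not None
        else np.empty((m.n_samples, 0))
    )
    probe_iter = (
        np.flatnonzero(np.asarray(probe_mask, dtype=bool))
        if probe_mask is not None
        else range(m.n_probes)
    )
    records = []
    for i in probe_iter:
        dose, valid = encode_genotypes(m.row(i), model)
        keep = (
            valid
            & np.isfinite(status)
            & np.all(np.isfinite(C), axis=1)
            & np.all(np.isfinite(cond), axis=1)
        )
        y, d = status[keep], dose[keep]
        if len(np.unique(d)) < 2:
            records.append(
                _assoc_record(m, i, model, np.nan, np.nan, np.nan, False,
                              "no_informative_carriers", None, None)
            )
            continue
        if ((d != 0) & (y == 1)).sum() < min_cases:
            records.append(
                _assoc_record(m, i, model, np.nan, np.nan, np.nan, False,
                              "fewer_than_min_cases_after_masking", None, None)
            )
            continue
        other = np.column_stack([np.ones(keep.sum()), _standardize(C[keep]), cond[keep]])
        if _collinear_with(d, other):
            # e.g. the lead probe itself after conditioning: p = 1 by construction
            records.append(
                _assoc_record(m, i, model, 0.0, np.inf, 1.0, False,
                              "collinear_with_conditioning", y, d)
            )
            continue
        X = np.column_stack(
            [np.ones(keep.sum()), d, _standardize(C[keep]), cond[keep]]
        )
        try:
            fit = firth_logistic(y, X, force_firth=_empty_cell(d, y))
        except ValueError as exc:
            records.append(
                _assoc_record(m, i, model, np.nan, np.nan, np.nan, False,
                              str(exc), None, None)
            )
            continue
        records.append(
            _assoc_record(
                m, i, model, fit.beta[1], fit.se[1], fit.p[1], fit.firth_used,
                "", y, d,
            )
        )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def run_burden_gwas(
    m: GenotypeMatrix,
    burden_phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    model: str,
    probe_mask: np.ndarray | None = None,
    conditioning: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-probe ordinary least squares scan for the quantitative disease
    burden, with the same encodings, masking, and covariates as the
    logistic scan. Betas are in diseases per encoded unit."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    yv = np.asarray(burden_phenotype, dtype=float)
    if np.nanstd(yv) == 0:
        raise ValueError("burden phenotype is constant")
    C = covariates.to_numpy(dtype=float) if covariates is not None and len(
        covariates.columns
    ) else np.empty((m.n_samples, 0))
    cond = (
        np.asarray(conditioning, dtype=float).reshape(m.n_samples, -1)
        if conditioning is not None
        else np.empty((m.n_samples, 0))
    )
    probe_iter = (
        np.flatnonzero(np.asarray(probe_mask, dtype=bool))
        if probe_mask is not None
        else range(m.n_probes)
    )
    records = []
    for i in probe_iter:
        dose, valid = encode_genotypes(m.row(i), model)
        keep = (
            valid
            & np.isfinite(yv)
            & np.all(np.isfinite(C), axis=1)
            & np.all(np.isfinite(cond), axis=1)
        )
        y, d = yv[keep], dose[keep]
        if len(np.unique(d)) < 2:
            records.append(
                _assoc_record(m, i, model, np.nan, np.nan, np.nan, False,
                              "no_informative_carriers", None, None)
            )
            continue
        other = np.column_stack([np.ones(keep.sum()), _standardize(C[keep]), cond[keep]])
        if _collinear_with(d, other):
            rec = _assoc_record(m, i, model, 0.0, np.inf, 1.0, False,
                                "collinear_with_conditioning", None, d)
            rec["n_case"] = rec["n_control"] = 0
            records.append(rec)
            continue
        X = np.column_stack(
            [np.ones(keep.sum()), d, _standardize(C[keep]), cond[keep]]
        )
        beta, se, p = _ols_focal(y, X, focal=1)
        rec = _assoc_record(m, i, model, beta, se, p, False, "", None, d)
        rec["n_case"] = rec["n_control"] = 0
        rec["n_case_carrier"] = int((d != 0).sum())
        records.append(rec)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def _ols_focal(y: np.ndarray, X: np.ndarray, focal: int) -> tuple[float, float, float]:
    """Classical OLS coefficient, SE, and normal-approximation p."""
    n, k = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[focal, focal]))
    if se == 0:
        return float(beta[focal]), se, 1.0
    t = beta[focal] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[focal]), se, float(p)


def stepwise_conditional(
    m: GenotypeMatrix,
    status: np.ndarray,
    covariates: pd.DataFrame | None,
    model: str,
    threshold: float,
    probe_mask: np.ndarray | None = None,
    burden_phenotype: np.ndarray | None = None,
    max_rounds: int = MAX_CONDITIONAL_ROUNDS,
) -> pd.DataFrame:
    """Iterative conditional analysis returning independent lead probes.

    Each round takes the most significant probe with p <= ``threshold`` as a
    lead, appends its encoded genotype to the conditioning covariates, and
    rescans, stopping when no probe passes. Leads are returned in discovery
    order with their (unconditional-round) association records.
    """
    leads = []
    cond_cols: list[np.ndarray] = []
    for round_no in range(max_rounds + 1):
        cond = np.column_stack(cond_cols) if cond_cols else None
        if burden_phenotype is not None:
            scan = run_burden_gwas(
                m, burden_phenotype, covariates, model,
                probe_mask=probe_mask, conditioning=cond,
            )
        else:
            scan = run_gwas(
                m, status, covariates, model,
                probe_mask=probe_mask, conditioning=cond,
            )
        ok = scan.loc[scan["p"].notna() & (scan["p"] <= threshold)]
        if ok.empty:
            return pd.DataFrame(leads)
        if round_no == max_rounds:
            raise RuntimeError(
                f"conditional analysis did not terminate in {max_rounds} rounds; "
                f"{len(ok)} probes still significant (min p = {ok['p'].min():.3g})"
            )
        best = ok.loc[ok["p"].idxmin()].to_dict()
        best["round"] = round_no + 1
        leads.append(best)
        i = m.probe_index(best["probe_id"])
        dose, valid = encode_genotypes(m.row(i), model)
        cond_cols.append(np.where(valid, dose, np.nan))
    raise AssertionError("unreachable")


def genomic_inflation(pvals: np.ndarray) -> float:
    """Median-based genomic inflation factor of 1-df chi-square statistics."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) < 100:
        logger.warning("genomic inflation on %d p-values is unstable", len(p))
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
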