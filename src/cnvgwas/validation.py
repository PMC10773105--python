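"""Post-GWAS statistical validation, confidence tiers, replication, and the
BMI-confounding analysis.

Because the scanned CNVs are rare, every primary association rests on a
handful of diseased carriers and is corroborated by three orthogonal
statistics — the genotypic Fisher test, a linear regression of logistic
response residuals on the CNV dosage, and a Cox proportional-hazards model
of age of disease onset. Associations are ranked by how many of the three
confirm them at p <= 1e-4 (tier 1: all three, tier 2: two, tier 3: one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from scipy.special import expit, ndtri

from .association import _ols_focal, _standardize, encode_genotypes
from .firth import firth_logistic
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_TIER_ALPHA = 1e-4
REPLICATION_ALPHA_GRID = tuple(np.round(np.arange(0.005, 0.1001, 0.005), 3))


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def residual_regression(
    status: np.ndarray,
    covariates: pd.DataFrame | None,
    encodings: dict[str, np.ndarray],
) -> dict:
    """Regress logistic response residuals on each candidate CNV encoding.

    The binary status is first explained by covariates alone (logistic);
    the response residual r = y - p_hat is then regressed (OLS,
    homoskedastic Wald inference) on each significantly-associated encoding,
    and the encoding with the lowest p is reported.
    """
    if not encodings:
        raise ValueError("at least one candidate encoding is required")
    y = np.asarray(status, dtype=float)
    keep = np.isfinite(y)
    C = (
        covariates.to_numpy(dtype=float)
        if covariates is not None and len(covariates.columns)
        else np.empty((len(y), 0))
    )
    keep &= np.all(np.isfinite(C), axis=1)
    Xcov = np.column_stack([np.ones(int(keep.sum())), _standardize(C[keep])])
    fit = firth_logistic(y[keep], Xcov)
    p_hat = expit(Xcov @ fit.beta)
    resid = y[keep] - p_hat
    if np.allclose(resid, 0.0):
        raise ValueError("covariate-only model is saturated; residuals all zero")
    best = None
    for name, dose in encodings.items():
        d = np.asarray(dose, dtype=float)[keep]
        ok = np.isfinite(d)
        if d[ok].std() == 0:
            continue
        X = np.column_stack([np.ones(int(ok.sum())), d[ok]])
        beta, se, p = _ols_focal(resid[ok], X, focal=1)
        rec = {"encoding": name, "beta": beta, "se": se, "p": p}
        if best is None or p < best["p"]:
            best = rec
    if best is None:
        raise ValueError("no encoding with variance among analyzed samples")
    return best


def coxph_fit(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | None,
    encodings: dict[str, np.ndarray],
) -> dict:
    """Cox proportional-hazards fit of age of onset on each CNV encoding.

    Partial likelihood with Efron tie handling (lifelines); per encoding the
    hazard ratio exp(beta) and Wald p on the genotype term are extracted and
    the lowest-p encoding is reported. Encodings without genotype variance
    among analyzable samples are skipped with a reason.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    base_ok = np.isfinite(t) & np.isfinite(e) & (t > 0)
    if e[base_ok].sum() < 1:
        raise ValueError("need at least one event")
    C = (
        covariates.loc[:, covariates.columns].reset_index(drop=True)
        if covariates is not None and len(covariates.columns)
        else None
    )
    best, skipped = None, []
    for name, dose in encodings.items():
        d = np.asarray(dose, dtype=float)
        ok = base_ok & np.isfinite(d)
        if C is not None:
            cc = C.notna().all(axis=1).to_numpy()
            ok &= cc
        if ok.sum() < 3 or d[ok].std() == 0:
            skipped.append((name, "no genotype variance"))
            continue
        df = pd.DataFrame({"time": t[ok], "event": e[ok], "dosage": d[ok]})
        if C is not None:
            for col in C.columns:
                vals = C[col].to_numpy(dtype=float)[ok]
                if np.std(vals) > 0:
                    df[col] = vals
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                # intermediate overflow in the partial-likelihood iterations
                # is routine for near-separated rare-carrier data
                _warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            skipped.append((name, str(exc)))
            continue
        rec = {
            "encoding": name,
            "hr": float(np.exp(cph.params_["dosage"])),
            "beta": float(cph.params_["dosage"]),
            "se": float(cph.standard_errors_["dosage"]),
            "p": float(cph.summary.loc["dosage", "p"]),
        }
        if best is None or rec["p"] < best["p"]:
            best = rec
    if best is None:
        raise ValueError(f"no fittable encoding: {skipped}")
    best["skipped"] = skipped
    return best


def kaplan_meier(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group with 95% confidence bands.

    Bands are lifelines' Greenwood-variance-based (log-log) intervals.
    Empty groups are skipped.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(groups)
    out = {}
    for label in pd.unique(g):
        sel = (g == label) & np.isfinite(t) & np.isfinite(e)
        if sel.sum() == 0:
            logger.warning("Kaplan-Meier group %r empty; skipped", label)
            continue
        km = KaplanMeierFitter(alpha=alpha)
        km.fit(t[sel], e[sel])
        df = km.survival_function_.copy()
        df.columns = ["survival"]
        ci = km.confidence_interval_
        df["ci_low"] = ci.iloc[:, 0].to_numpy()
        df["ci_high"] = ci.iloc[:, 1].to_numpy()
        out[str(label)] = df
    return out


# ---------------------------------------------------------------------------
# tiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierRecord:
    signal_id: str
    fisher_p: float
    residual_p: float
    coxph_p: float
    hazard_ratio: float
    tier: int


def assign_tier(
    fisher_p: float,
    residual_p: float,
    coxph_p: float,
    is_burden_signal: bool = False,
    alpha: float = DEFAULT_TIER_ALPHA,
) -> int:
    """Confidence tier from the three validation p-values.

    Tier 1/2/3 when 3/2/1 of the p-values pass ``alpha``. Disease-burden
    signals are quantitative, not subject to the binary-trait caveats, and
    are tier 1 unconditionally. A signal confirmed by none of the three is
    demoted to tier 4 with a warning rather than dropped.
    """
    if is_burden_signal:
        return 1
    n_pass = sum(
        1 for p in (fisher_p, residual_p, coxph_p) if np.isfinite(p) and p <= alpha
    )
    if n_pass == 0:
        logger.warning("signal confirmed by no validation method; demoted")
        return 4
    return 4 - n_pass


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationRecord:
    signal_id: str
    replication_probe: str | None
    p_old: float
    concordant: bool
    p_new: float
    evaluable: bool
    strictly_replicated: bool = False


def directional_p(p_old: float, concordant: bool) -> float:
    """One-sided adjustment of a two-sided replication p for effect-sign
    concordance with the discovery effect: p/2 if concordant, 1 - p/2 if
    not."""
    if not (0.0 < p_old <= 1.0):
        raise ValueError("p_old must lie in (0, 1]")
    return p_old / 2.0 if concordant else 1.0 - p_old / 2.0


def replicate(
    signals: pd.DataFrame,
    replication_results: pd.DataFrame,
    strict_alpha: float = 0.05,
) -> list[ReplicationRecord]:
    """Match each discovery lead to the closest successfully-regressed
    replication probe and apply the directional p adjustment.

    ``signals`` needs columns signal_id, chrom, pos, beta, cnvr_start,
    cnvr_end; ``replication_results`` needs probe_id, chrom, pos, beta, p
    (failed regressions: p NaN). A signal with no usable replication probe
    inside its CNVR is marked non-evaluable. The strict replication flag
    uses ``strict_alpha`` / number-of-evaluable-signals; equidistant probe
    ties break toward the smaller position.
    """
    ok = replication_results.loc[replication_results["p"].notna()]
    records: list[ReplicationRecord] = []
    for _, sig in signals.iterrows():
        cand = ok.loc[
            (ok["chrom"].astype(str) == str(sig["chrom"]))
            & (ok["pos"] >= sig["cnvr_start"])
            & (ok["pos"] <= sig["cnvr_end"])
        ]
        if cand.empty:
            records.append(
                ReplicationRecord(sig["signal_id"], None, np.nan, False, np.nan, False)
            )
            continue
        dist = (cand["pos"] - sig["pos"]).abs()
        # ties toward the smaller position
        best = cand.loc[
            cand.assign(_d=dist).sort_values(["_d", "pos"]).index[0]
        ]
        concordant = bool(np.sign(best["beta"]) == np.sign(sig["beta"]))
        p_new = directional_p(float(best["p"]), concordant)
        records.append(
            ReplicationRecord(
                sig["signal_id"], best["probe_id"], float(best["p"]),
                concordant, p_new, True,
            )
        )
    n_eval = sum(r.evaluable for r in records)
    if n_eval:
        cut = strict_alpha / n_eval
        for r in records:
            r.strictly_replicated = bool(r.evaluable and r.p_new <= cut)
    return records


def replication_enrichment(
    k_significant: int, n_evaluable: int, alpha: float
) -> tuple[float, float]:
    """Fold enrichment and one-sided binomial tail of replication counts.

    fold = k / (n * alpha); p = P(X >= k), X ~ Binomial(n, alpha).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 <= k_significant <= n_evaluable):
        raise ValueError("need 0 <= k <= n")
    fold = k_significant / (n_evaluable * alpha)
    p = float(
        stats.binomtest(k_significant, n_evaluable, alpha, alternative="greater").pvalue
    )
    return fold, p


def replication_enrichment_grid(
    p_values: np.ndarray,
    alphas=REPLICATION_ALPHA_GRID,
) -> pd.DataFrame:
    """Enrichment over the standard alpha grid (0.005 to 0.1 by 0.005)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    rows = []
    for a in sorted(alphas, reverse=True):
        k = int((p <= a).sum())
        fold, bp = replication_enrichment(k, len(p), a)
        rows.append({"alpha": a, "k": k, "n": len(p), "fold": fold, "binomial_p": bp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BMI confounding
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform Phi^-1((rank - 0.5) / n).

    Ties share the average rank; NaNs are propagated; constant input is an
    error. Invariant under monotone rescaling of the input.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    vv = v[ok]
    if len(np.unique(vv)) < 2:
        raise ValueError("constant input cannot be inverse-normal transformed")
    ranks = stats.rankdata(vv, method="average")
    out[ok] = ndtri((ranks - 0.5) / len(vv))
    return out


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


@dataclass
class BmiConfoundingResult:
    signal_id: str
    evaluable: bool
    eligible: bool
    bmi_disease_p: float = np.nan
    genotype_bmi_p: float = np.nan
    beta_unadjusted: float = np.nan
    beta_adjusted: float = np.nan
    p_adjusted: float = np.nan
    t_p: float = np.nan
    likely_bmi_driven: bool = False


def bmi_confounding(
    signals: pd.DataFrame,
    m: GenotypeMatrix,
    status_by_disease: dict[str, np.ndarray],
    covariates_by_disease: dict[str, pd.DataFrame],
    bmi: np.ndarray,
    bmi_residual_covariates: pd.DataFrame,
    gw_p: float,
    n_traits: int,
    alpha: float = 0.05,
) -> list[BmiConfoundingResult]:
    """Flag associations likely driven by the CNV's effect on BMI.

    A signal is *eligible* when (i) BMI associates with the disease at
    p <= alpha/n_traits in the covariate-adjusted disease model and (ii)
    the lead genotype associates with inverse-normal-transformed,
    covariate-residualized BMI at p <= alpha/n_signals. Eligible signals
    are refit with BMI as an extra covariate; the unadjusted and adjusted
    genotype coefficients are compared with a two-sided z-test
    (z = (b1 - b2)/sqrt(se1^2 + se2^2), independence assumed — conservative)
    significant at alpha/n_eligible, and a signal whose adjusted p rises
    above the genome-wide threshold is flagged as likely BMI-driven.

    ``signals`` needs columns signal_id, disease, probe_id, model, beta, se.
    Signals with BMI missing for more than half their carriers are marked
    non-evaluable.
    """
    bmi = np.asarray(bmi, dtype=float)
    n_signals = len(signals)
    bmi_int = inverse_normal_transform(bmi)
    Xres = np.column_stack(
        [
            np.ones(len(bmi)),
            bmi_residual_covariates.to_numpy(dtype=float),
        ]
    )
    ok_res = np.all(np.isfinite(Xres), axis=1) & np.isfinite(bmi_int)
    bmi_resid = np.full(len(bmi), np.nan)
    bmi_resid[ok_res] = _residualize(bmi_int[ok_res], Xres[ok_res])

    results: list[BmiConfoundingResult] = []
    for _, sig in signals.iterrows():
        sid, disease = sig["signal_id"], sig["disease"]
        status = np.asarray(status_by_disease[disease], dtype=float)
        cov = covariates_by_disease[disease]
        i = m.probe_index(sig["probe_id"])
        dose, valid = encode_genotypes(m.row(i), sig["model"])
        carriers = valid & (dose != 0)
        if carriers.sum() and np.mean(~np.isfinite(bmi[carriers])) > 0.5:
            results.append(BmiConfoundingResult(sid, evaluable=False, eligible=False))
            continue

        C = cov.to_numpy(dtype=float) if cov is not None and len(cov.columns) else \
            np.empty((m.n_samples, 0))
        keep = (
            np.isfinite(status)
            & np.isfinite(bmi)
            & np.all(np.isfinite(C), axis=1)
            & valid
        )
        # (i) BMI-disease association in the covariate-adjusted model
        Xb = np.column_stack(
            [np.ones(int(keep.sum())), _standardize(C[keep]), bmi[keep]]
        )
        fit_b = firth_logistic(status[keep], Xb)
        bmi_disease_p = float(fit_b.p[-1])
        # (ii) genotype-BMI association on transformed residualized BMI
        keep2 = keep & np.isfinite(bmi_resid)
        Xg = np.column_stack([np.ones(int(keep2.sum())), dose[keep2]])
        _, _, genotype_bmi_p = _ols_focal(bmi_resid[keep2], Xg, focal=1)

        eligible = (
            bmi_disease_p <= alpha / n_traits
            and genotype_bmi_p <= alpha / n_signals
        )
        res = BmiConfoundingResult(
            sid, evaluable=True, eligible=eligible,
            bmi_disease_p=bmi_disease_p, genotype_bmi_p=genotype_bmi_p,
            beta_unadjusted=float(sig["beta"]),
        )
        if eligible:
            Xa = np.column_stack(
                [np.ones(int(keep.sum())), dose[keep], _standardize(C[keep]),
                 bmi[keep]]
            )
            from .association import _empty_cell

            fit_a = firth_logistic(
                status[keep], Xa, force_firth=_empty_cell(dose[keep], status[keep])
            )
            res.beta_adjusted = float(fit_a.beta[1])
            res.p_adjusted = float(fit_a.p[1])
            se1, se2 = float(sig["se"]), float(fit_a.se[1])
            z = (res.beta_unadjusted - res.beta_adjusted) / np.sqrt(
                se1**2 + se2**2
            )
            res.t_p = float(2.0 * stats.norm.sf(abs(z)))
            res.likely_bmi_driven = bool(res.p_adjusted > gw_p)
        results.append(res)
    return results


def bmi_eligibility_thresholds(
    n_traits: int, n_signals: int, n_eligible: int, alpha: float = 0.05
) -> dict[str, float]:
    """The three Bonferroni cutoffs of the BMI-confounding analysis."""
    return {
        "bmi_disease_p": alpha / n_traits,
        "genotype_bmi_p": alpha / n_signals,
        "coefficient_t_p": alpha / n_eligible,
    }
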