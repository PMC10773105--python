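"""Per-individual CNV burden metrics and burden association studies.

The burden of a sample is the total genomic footprint of its
high-confidence (|QS| > 0.5) autosomal CNVs, measured either in megabases
or in number of distinct genes affected, separately for all CNVs,
duplications, and deletions — six metrics in total, with
cnv = dup + del holding in both units on every table emitted.

Partitioned burdens split each metric into the part overlapping a set of
genomic regions (subset burden) and the remainder (corrected burden =
total - subset); overlap is either any >= 1 bp intersection or reciprocal
50% coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import intersection_length, interval_length
from .association import _ols_focal, _standardize
from .firth import firth_logistic, _loglik

logger = logging.getLogger(__name__)

BURDEN_TYPES = ("cnv", "dup", "del")
BURDEN_UNITS = ("mb", "genes")
OVERLAP_RULES = ("any_1bp", "reciprocal_50")

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass(frozen=True)
class Partition:
    """A named set of genomic intervals with type applicability.

    ``intervals`` has columns chrom/start/end and optionally ``applies_to``
    (comma-joined subset of cnv,dup,del; default all three). The canonical
    partitions are CNVR (disease-associated regions), GD (known genomic
    disorders), R1 = CNVR ∩ GD, R2 = GD \\ R1, R3 = CNVR \\ R1.
    """

    name: str
    intervals: pd.DataFrame
    overlap_rule: str = "any_1bp"

    def __post_init__(self):
        if self.overlap_rule not in OVERLAP_RULES:
            raise ValueError(f"unknown overlap rule {self.overlap_rule!r}")
        for col in ("chrom", "start", "end"):
            if col not in self.intervals.columns:
                raise ValueError(f"partition intervals need a {col!r} column")

    def applies(self, row) -> set[str]:
        raw = row.get("applies_to") if hasattr(row, "get") else None
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return set(BURDEN_TYPES)
        types = {t.strip() for t in str(raw).split(",") if t.strip()}
        unknown = types - set(BURDEN_TYPES)
        if unknown:
            raise ValueError(f"unknown burden types {unknown} in applies_to")
        return types


def overlap(call: tuple, region: tuple, rule: str = "any_1bp") -> bool:
    """Overlap test between two 1-based inclusive intervals.

    ``any_1bp``: intervals share at least one base pair. ``reciprocal_50``:
    the intersection covers more than half of *both* intervals.
    """
    if rule not in OVERLAP_RULES:
        raise ValueError(f"unknown overlap rule {rule!r}")
    s1, e1 = int(call[0]), int(call[1])
    s2, e2 = int(region[0]), int(region[1])
    inter = intersection_length(s1, e1, s2, e2)
    if rule == "any_1bp":
        return inter >= 1
    return inter > 0.5 * interval_length(s1, e1) and inter > 0.5 * interval_length(
        s2, e2
    )


def _filter_calls(calls: pd.DataFrame, qs_cut: float, autosomal_only: bool):
    out = calls.loc[calls["qs"].abs() > qs_cut]
    if autosomal_only:
        out = out.loc[out["chrom"].astype(str).isin(AUTOSOMES)]
    return out


def _genes_hit(call_rows: pd.DataFrame, genes: pd.DataFrame) -> set[int]:
    """Indices of gene intervals overlapped >= 1 bp by any of the calls."""
    hit: set[int] = set()
    for _, call in call_rows.iterrows():
        sub = genes.loc[genes["chrom"].astype(str) == str(call["chrom"])]
        for gi, g in sub.iterrows():
            if gi in hit:
                continue
            if intersection_length(
                int(call["start"]), int(call["end"]), int(g["start"]), int(g["end"])
            ) >= 1:
                hit.add(gi)
    return hit


def compute_burden(
    calls: pd.DataFrame,
    sample_ids,
    genes: pd.DataFrame | None = None,
    qs_cut: float = 0.5,
    autosomal_only: bool = True,
) -> pd.DataFrame:
    """Six burden metrics per sample.

    Mb burden sums (end - start + 1)/1e6 over a sample's calls of each type;
    gene burden counts *distinct* gene intervals overlapped >= 1 bp by the
    sample's calls of that type (a gene hit twice counts once per type).
    The cnv metric is the sum of the dup and del metrics. Requesting gene
    units without a gene interval table is an error at association time
    (the columns are simply absent here).
    """
    sample_ids = list(sample_ids)
    cols = {f"{t}_mb": np.zeros(len(sample_ids)) for t in BURDEN_TYPES}
    if genes is not None:
        cols.update({f"{t}_genes": np.zeros(len(sample_ids)) for t in BURDEN_TYPES})
    out = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    use = _filter_calls(calls, qs_cut, autosomal_only)
    for sid, sub in use.groupby("sample_id"):
        if sid not in out.index:
            raise ValueError(f"call sample {sid!r} not in sample_ids")
        for t, type_label in (("dup", "DUP"), ("del", "DEL")):
            rows = sub.loc[sub["type"] == type_label]
            mb = sum(
                interval_length(int(r["start"]), int(r["end"])) for _, r in rows.iterrows()
            ) / 1e6
            out.loc[sid, f"{t}_mb"] = mb
            if genes is not None:
                out.loc[sid, f"{t}_genes"] = len(_genes_hit(rows, genes))
    out["cnv_mb"] = out["dup_mb"] + out["del_mb"]
    if genes is not None:
        out["cnv_genes"] = out["dup_genes"] + out["del_genes"]
    return out


def burden_association(
    burden: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    binary: bool = True,
) -> dict:
    """Association of one burden metric with a disease or the disease burden.

    Logistic regression (Firth fallback) for binary disease outcomes, OLS
    for the quantitative disease burden, adjusting for the supplied
    covariates. Variance explained comes from a covariate-free model:
    McFadden pseudo-R^2 (1 - ll_model/ll_null) for diseases, adjusted R^2
    for the disease burden.
    """
    b = np.asarray(burden, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.nanstd(b) == 0:
        raise ValueError("zero-variance burden")
    C = (
        covariates.to_numpy(dtype=float)
        if covariates is not None and len(covariates.columns)
        else np.empty((len(y), 0))
    )
    keep = np.isfinite(b) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    bb, yy = b[keep], y[keep]
    X = np.column_stack([np.ones(int(keep.sum())), bb, _standardize(C[keep])])
    X0 = np.column_stack([np.ones(int(keep.sum())), bb])
    if binary:
        fit = firth_logistic(yy, X)
        beta, se, p = float(fit.beta[1]), float(fit.se[1]), float(fit.p[1])
        # covariate-free variance explained (McFadden)
        fit0 = firth_logistic(yy, X0)
        ll_model = _loglik(yy, X0, fit0.beta)
        p_bar = yy.mean()
        ll_null = float(len(yy) * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar)))
        r2 = 1.0 - ll_model / ll_null
        return {"beta": beta, "se": se, "p": p,
                "or": float(np.exp(min(beta, 700.0))),
                "variance_explained": float(r2), "n": int(keep.sum())}
    beta, se, p = _ols_focal(yy, X, focal=1)
    b0, _, _ = _ols_focal(yy, X0, focal=1)
    resid0 = yy - X0 @ np.linalg.lstsq(X0, yy, rcond=None)[0]
    tss = float(((yy - yy.mean()) ** 2).sum())
    r2 = 1.0 - float((resid0**2).sum()) / tss if tss > 0 else 0.0
    n, k = X0.shape
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - k, 1)
    return {"beta": float(beta), "se": float(se), "p": float(p), "or": np.nan,
            "variance_explained": float(adj_r2), "n": int(keep.sum())}


def _call_overlaps_partition(call, partition: Partition, burden_type: str) -> bool:
    for _, region in partition.intervals.iterrows():
        if str(region["chrom"]) != str(call["chrom"]):
            continue
        if burden_type not in partition.applies(region):
            continue
        if overlap(
            (call["start"], call["end"]), (region["start"], region["end"]),
            partition.overlap_rule,
        ):
            return True
    return False


def subset_and_corrected_burden(
    calls: pd.DataFrame,
    partition: Partition,
    sample_ids,
    genes: pd.DataFrame | None = None,
    qs_cut: float = 0.5,
    autosomal_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Burden inside a genomic partition, and the remainder.

    The subset burden counts calls overlapping the partition under its
    overlap rule and type-applicability map; corrected = total - subset by
    definition, so subset + corrected = total holds exactly per sample,
    type, and unit. In gene units this means a gene whose distinct count
    entered the subset is subtracted from the corrected burden even if a
    non-subset call of the same sample also touches it (distinct genes are
    counted once per sample and type within each table).
    """
    use = _filter_calls(calls, qs_cut, autosomal_only)
    total = compute_burden(calls, sample_ids, genes, qs_cut, autosomal_only)

    if len(use):
        type_key = use["type"].map({"DUP": "dup", "DEL": "del"})
        flags = pd.Series(
            [
                _call_overlaps_partition(use.loc[k], partition, type_key.loc[k])
                for k in use.index
            ],
            index=use.index,
        )
        subset_calls = use.loc[flags]
    else:
        subset_calls = use
    subset = compute_burden(subset_calls, sample_ids, genes, qs_cut, autosomal_only)
    corrected = total - subset
    return subset, corrected


def gwas_signal_corrected_burden(
    calls: pd.DataFrame,
    cnvr_table: pd.DataFrame,
    sample_ids,
    genes: pd.DataFrame | None = None,
    qs_cut: float = 0.5,
    autosomal_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Disease-specific burdens with disease-associated CNV regions removed.

    ``cnvr_table`` has one row per (disease, region) with columns disease,
    chrom, start, end, models (comma-joined significant models). A call is
    omitted when it overlaps (>= 1 bp) a region associated with that
    disease through a model family matching the call's type: mirror/U-shape
    omit either type, duplication-only omits duplications, deletion-only
    omits deletions. The cnv metric stays dup + del after omission.
    """
    out: dict[str, pd.DataFrame] = {}
    use = _filter_calls(calls, qs_cut, autosomal_only)
    for disease, regions in cnvr_table.groupby("disease"):
        drop = pd.Series(False, index=use.index)
        for _, region in regions.iterrows():
            models = {s.strip() for s in str(region["models"]).split(",")}
            joint = bool(models & {"mirror", "ushape"})
            for k in use.index:
                call = use.loc[k]
                if str(call["chrom"]) != str(region["chrom"]):
                    continue
                applies = joint or (
                    (call["type"] == "DUP" and "duponly" in models)
                    or (call["type"] == "DEL" and "delonly" in models)
                )
                if applies and overlap(
                    (call["start"], call["end"]), (region["start"], region["end"]),
                    "any_1bp",
                ):
                    drop[k] = True
        out[disease] = compute_burden(
            use.loc[~drop], sample_ids, genes, qs_cut, autosomal_only
        )
    return out


def make_partitions(
    cnvr: pd.DataFrame,
    gd: pd.DataFrame,
    overlap_rule: str = "any_1bp",
) -> dict[str, Partition]:
    """Build the CNVR/GD/R1/R2/R3 partition family.

    R1 is the set of CNVR regions intersecting (>= 1 bp) any GD region plus
    the GD regions they intersect; R2 the remaining GD regions; R3 the
    remaining CNVR regions.
    """
    def hits(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
        flags = []
        for _, ra in a.iterrows():
            hit = any(
                str(ra["chrom"]) == str(rb["chrom"])
                and intersection_length(
                    int(ra["start"]), int(ra["end"]), int(rb["start"]), int(rb["end"])
                )
                >= 1
                for _, rb in b.iterrows()
            )
            flags.append(hit)
        return pd.Series(flags, index=a.index)

    cnvr_in_gd = hits(cnvr, gd)
    gd_in_cnvr = hits(gd, cnvr)
    r1 = pd.concat(
        [cnvr.loc[cnvr_in_gd], gd.loc[gd_in_cnvr]], ignore_index=True
    )
    return {
        "CNVR": Partition("CNVR", cnvr.reset_index(drop=True), overlap_rule),
        "GD": Partition("GD", gd.reset_index(drop=True), overlap_rule),
        "R1": Partition("R1", r1, overlap_rule),
        "R2": Partition("R2", gd.loc[~gd_in_cnvr].reset_index(drop=True), overlap_rule),
        "R3": Partition("R3", cnvr.loc[~cnvr_in_gd].reset_index(drop=True), overlap_rule),
    }
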