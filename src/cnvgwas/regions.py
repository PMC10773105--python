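"""CNV region (CNVR) definition, merging, labeling, and carrier comparisons.

A CNVR is the genomic footprint of an association signal: the most distant
probes within a +/- 3 Mb window of the lead probe whose genotypes are
correlated (r^2 >= 0.5) with the lead. Regions from different diseases and
models that overlap by at least one base pair are merged transitively into
unique, non-overlapping regions whose boundaries are the union extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import intersection_length
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.5
DEFAULT_WINDOW_BP = 3_000_000


@dataclass
class Cnvr:
    """A merged, disease-associated CNV region with its member signals."""

    chrom: str
    start: int
    end: int
    signals: list[dict] = field(default_factory=list)
    best_model: str | None = None
    main_model: str | None = None
    gene_count: int | None = None
    tier: int | None = None

    @property
    def diseases(self) -> list[str]:
        return sorted({s["disease"] for s in self.signals if "disease" in s})

    @property
    def models(self) -> list[str]:
        return sorted({s["model"] for s in self.signals if "model" in s})


def _tagging_dosage(g: np.ndarray, model: str) -> np.ndarray:
    """Genotype encoding used for lead-probe correlation (tagging).

    The U-shape dosage is |g|; the type-specific models mask the disregarded
    CNV type (NaN), with correlations computed over pairwise-complete
    samples.
    """
    g = g.astype(float)
    if model == "mirror":
        return g
    if model == "ushape":
        return np.abs(g)
    if model == "duponly":
        g[g == -1] = np.nan
        return g
    if model == "delonly":
        g[g == 1] = np.nan
        g[g == -1] = 1.0
        return g
    raise ValueError(f"unknown model {model!r}")


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return 0.0
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        return 0.0
    return float(np.corrcoef(aa, bb)[0, 1] ** 2)


def define_cnvr(
    m: GenotypeMatrix,
    lead_probe_id: str,
    model: str,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[str, int, int]:
    """Boundaries spanned by probes tagging the lead (r^2 >= r2_min within
    +/- window_bp). An isolated lead yields the single-probe interval."""
    li = m.probe_index(lead_probe_id)
    lead = m.probes.iloc[li]
    chrom, lead_pos = lead["chrom"], int(lead["pos"])
    g_lead = _tagging_dosage(m.row(li), model)
    if np.nanstd(g_lead) == 0:
        raise ValueError(f"lead probe {lead_probe_id} has zero variance")
    cand = m.probes.loc[
        (m.probes["chrom"] == chrom)
        & (m.probes["pos"] >= lead_pos - window_bp)
        & (m.probes["pos"] <= lead_pos + window_bp)
    ]
    tagged = [lead_pos]
    for i in cand.index:
        if i == li:
            continue
        if _pairwise_r2(g_lead, _tagging_dosage(m.row(int(i)), model)) >= r2_min:
            tagged.append(int(cand.loc[i, "pos"]))
    return chrom, min(tagged), max(tagged)


def merge_cnvrs(intervals: list[dict]) -> list[Cnvr]:
    """Merge signal intervals overlapping by >= 1 bp (transitive closure).

    Each input dict needs chrom/start/end plus arbitrary signal metadata
    (disease, model, lead probe, p, ...). Output is sorted, disjoint, with
    member signals concatenated; boundaries are the union extent.
    """
    out: list[Cnvr] = []
    key = lambda iv: (str(iv["chrom"]), int(iv["start"]), int(iv["end"]))
    for iv in sorted(intervals, key=key):
        chrom, start, end = key(iv)
        if start > end:
            raise ValueError(f"interval start > end: {iv}")
        if out and out[-1].chrom == chrom and start <= out[-1].end:
            out[-1].end = max(out[-1].end, end)
            out[-1].signals.append(dict(iv))
        else:
            out.append(Cnvr(chrom=chrom, start=start, end=end, signals=[dict(iv)]))
    return out


def label_models(signals: list[dict]) -> tuple[str, str]:
    """Best (lowest p) and main (CNV-type-driving) model of an association.

    ``signals`` lists the genome-wide-significant models of one association
    as dicts with ``model`` and ``p``. The main model is the duplication- or
    deletion-only model when either is significant — these indicate which
    CNV type drives the signal — otherwise the lowest-p model. Both
    type-specific models significant at once is flagged for manual review.
    """
    if not signals:
        raise ValueError("no significant models")
    best = min(signals, key=lambda s: s["p"])["model"]
    specific = [s for s in signals if s["model"] in ("duponly", "delonly")]
    if {s["model"] for s in specific} == {"duponly", "delonly"}:
        logger.warning(
            "both duplication-only and deletion-only models significant; "
            "flagging for manual review"
        )
    main = min(specific, key=lambda s: s["p"])["model"] if specific else best
    return best, main


def count_genes(cnvr: Cnvr | tuple, genes: pd.DataFrame) -> int:
    """Number of gene intervals overlapping the region by >= 1 bp."""
    if isinstance(cnvr, Cnvr):
        chrom, start, end = cnvr.chrom, cnvr.start, cnvr.end
    else:
        chrom, start, end = cnvr
    sub = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    n = 0
    for _, g in sub.iterrows():
        if intersection_length(start, end, int(g["start"]), int(g["end"])) >= 1:
            n += 1
    return n


def assign_carriers_by_category(
    calls: pd.DataFrame,
    categories: pd.DataFrame,
    rule: str = "reciprocal_50",
) -> pd.DataFrame:
    """Assign CNV carriers to breakpoint-category subgroups.

    ``categories`` has columns (label, chrom, start, end); a call is
    assigned to the category it matches under the overlap rule (reciprocal
    50% by default). Calls matching no category are labeled ``atypical``.
    """
    from .burden import overlap

    labels = []
    for _, call in calls.iterrows():
        label = "atypical"
        for _, cat in categories.iterrows():
            if str(cat["chrom"]) != str(call["chrom"]):
                continue
            if overlap(
                (call["start"], call["end"]), (cat["start"], cat["end"]), rule
            ):
                label = cat["label"]
                break
        labels.append(label)
    out = calls.copy()
    out["category"] = labels
    return out


def group_prevalence(
    groups: dict[str, pd.Series],
    neutral_label: str = "copy_neutral",
) -> pd.DataFrame:
    """Disease prevalence per carrier group vs the copy-neutral reference.

    ``groups`` maps a label to the binary status series of its members
    (1 = case). Prevalence q = c/n with SE = sqrt(q(1-q)/n); each carrier
    group is compared to the copy-neutral group with a two-sided 2x2 exact
    test. Empty groups are skipped with a log entry.
    """
    if neutral_label not in groups:
        raise ValueError(f"reference group {neutral_label!r} missing")
    ref = np.asarray(groups[neutral_label], dtype=float)
    ref_c, ref_n = int(np.nansum(ref)), int(np.isfinite(ref).sum())
    rows = []
    for label, status in groups.items():
        s = np.asarray(status, dtype=float)
        n = int(np.isfinite(s).sum())
        if n == 0:
            logger.warning("group %r is empty; skipped", label)
            continue
        c = int(np.nansum(s))
        q = c / n
        se = float(np.sqrt(q * (1 - q) / n))
        if label == neutral_label:
            p = np.nan
        else:
            table = [[c, n - c], [ref_c, ref_n - ref_c]]
            p = float(stats.fisher_exact(table)[1])
        rows.append({"group": label, "n": n, "cases": c, "q": q, "se": se,
                     "fisher_p": p})
    return pd.DataFrame(rows)


def compare_continuous(
    groups: dict[str, np.ndarray],
    neutral_label: str = "copy_neutral",
) -> pd.DataFrame:
    """Two-sided Welch t-test of each carrier group vs copy-neutral for a
    continuous trait (the counterpart of ``group_prevalence``)."""
    if neutral_label not in groups:
        raise ValueError(f"reference group {neutral_label!r} missing")
    ref = np.asarray(groups[neutral_label], dtype=float)
    ref = ref[np.isfinite(ref)]
    rows = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            logger.warning("group %r is empty; skipped", label)
            continue
        if label == neutral_label:
            p = np.nan
        else:
            p = float(stats.ttest_ind(v, ref, equal_var=False)[1])
        rows.append({"group": label, "n": len(v), "mean": float(v.mean()),
                     "t_p": p})
    return pd.DataFrame(rows)
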