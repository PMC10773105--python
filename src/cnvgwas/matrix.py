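"""Probe-level genotype matrices.

CNV calls passing the quality-score filter (|QS| > 0.5 by default) are
encoded into a sparse probe x sample matrix with entries +1 (duplication),
-1 (deletion), and 0 (no/low-quality CNV). Type-specific views mask the
other CNV type as missing: the DUP view turns deletions into missing
entries, the DEL view turns duplications into missing entries and recodes
deletions as +1.

Coordinates are 1-based inclusive throughout; a probe at position ``pos`` is
covered by a call iff ``start <= pos <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_QS_CUT = 0.5
DEFAULT_FREQ_CUT = 1e-4


@dataclass
class GenotypeMatrix:
    """Sparse probe x sample genotype matrix in {-1, 0, +1}.

    ``probes`` is ordered by (chrom, pos) and aligned with matrix rows;
    ``samples`` with columns.
    """

    probes: pd.DataFrame  # columns: probe_id, chrom, pos
    samples: np.ndarray  # sample ids, aligned with matrix columns
    data: sp.csr_matrix  # int8 entries in {-1, 0, +1}
    n_conflicts: int = 0  # same-sample DUP/DEL collisions zeroed at encoding

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, i: int) -> np.ndarray:
        """Dense signed genotype vector of probe ``i`` over all samples."""
        return np.asarray(self.data.getrow(i).todense(), dtype=np.int8).ravel()

    def view_row(self, i: int, which: str) -> np.ndarray:
        """Probe ``i`` under the CNV/DUP/DEL view; missing entries are NaN."""
        g = self.row(i).astype(float)
        if which == "cnv":
            return g
        if which == "dup":
            g[g == -1] = np.nan
            return g
        if which == "del":
            g[g == 1] = np.nan
            g[g == -1] = 1.0
            return g
        raise ValueError(f"unknown view {which!r}")

    def to_dense(self, which: str = "cnv") -> np.ndarray:
        """Dense float matrix under a view (tests and small problems only)."""
        return np.vstack([self.view_row(i, which) for i in range(self.n_probes)])

    def subset_probes(self, mask_or_ids) -> "GenotypeMatrix":
        """New matrix restricted to a probe subset (boolean mask or id list)."""
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "OU"
        ):
            keep = self.probes["probe_id"].isin(list(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            probes=self.probes.loc[keep].reset_index(drop=True),
            samples=self.samples,
            data=self.data[keep],
            n_conflicts=self.n_conflicts,
        )

    def probe_index(self, probe_id: str) -> int:
        idx = np.flatnonzero((self.probes["probe_id"] == probe_id).to_numpy())
        if len(idx) != 1:
            raise KeyError(probe_id)
        return int(idx[0])


def encode_probe_matrix(
    calls: pd.DataFrame,
    probes: pd.DataFrame,
    qs_cut: float = DEFAULT_QS_CUT,
    sample_ids=None,
    conflict_policy: str = "zero",
) -> GenotypeMatrix:
    """Encode high-confidence CNV calls into a probe x sample matrix.

    Entry (p, s) is +1 iff sample s carries a duplication with |QS| > qs_cut
    whose interval contains probe p, -1 likewise for deletions, 0 otherwise.
    Calls with |QS| <= qs_cut contribute nothing. A same-sample DUP/DEL
    collision at one probe is resolved per ``conflict_policy``: "zero"
    (default) sets the entry to 0 and logs the conflict, "error" raises.

    ``sample_ids`` fixes the sample universe (columns); by default it is the
    set of samples appearing in ``calls``, but the analysis cohort is usually
    larger, so pipelines should pass the full roster.
    """
    if conflict_policy not in ("zero", "error"):
        raise ValueError(f"unknown conflict_policy {conflict_policy!r}")
    probes = probes.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if sample_ids is None:
        sample_ids = np.array(sorted(calls["sample_id"].unique()))
    else:
        sample_ids = np.asarray(list(sample_ids))
    sample_pos = {s: j for j, s in enumerate(sample_ids)}

    retained = calls.loc[calls["qs"].abs() > qs_cut]
    bad_sign = retained.loc[
        ((retained["type"] == "DEL") & (retained["qs"] > 0))
        | ((retained["type"] == "DUP") & (retained["qs"] < 0))
    ]
    if len(bad_sign):
        raise ValueError(
            f"{len(bad_sign)} calls have a QS sign inconsistent with their type"
        )

    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for chrom, chrom_probes in probes.groupby("chrom", sort=False):
        pos = chrom_probes["pos"].to_numpy()
        base = chrom_probes.index.to_numpy()
        sub = retained.loc[retained["chrom"] == chrom]
        if sub.empty or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        types = sub["type"].to_numpy()
        sids = sub["sample_id"].to_numpy()
        for k in range(len(sub)):
            if hi[k] <= lo[k]:
                continue
            j = sample_pos.get(sids[k])
            if j is None:
                raise ValueError(f"call sample {sids[k]!r} not in sample_ids")
            v = 1 if types[k] == "DUP" else -1
            for p in base[lo[k] : hi[k]]:
                rows.append(int(p))
                cols.append(j)
                vals.append(v)

    n_conflicts = 0
    if rows:
        df = pd.DataFrame({"r": rows, "c": cols, "v": vals})
        agg = df.groupby(["r", "c"])["v"].agg(["min", "max"]).reset_index()
        conflict = (agg["min"] == -1) & (agg["max"] == 1)
        n_conflicts = int(conflict.sum())
        if n_conflicts:
            if conflict_policy == "error":
                raise ValueError(f"{n_conflicts} DUP/DEL conflicts at single probes")
            logger.warning(
                "%d probe/sample entries had both a retained DUP and DEL; set to 0",
                n_conflicts,
            )
        agg["v"] = np.where(conflict, 0, agg["max"].where(agg["max"] != 0, agg["min"]))
        agg = agg.loc[agg["v"] != 0]
        mat = sp.coo_matrix(
            (agg["v"].astype(np.int8), (agg["r"], agg["c"])),
            shape=(len(probes), len(sample_ids)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(probes), len(sample_ids)), dtype=np.int8)

    return GenotypeMatrix(
        probes=probes, samples=sample_ids, data=mat, n_conflicts=n_conflicts
    )


def probe_frequencies(
    m: GenotypeMatrix, freq_cut: float = DEFAULT_FREQ_CUT
) -> pd.DataFrame:
    """Per-probe CNV/duplication/deletion carrier frequencies.

    Returns a frame aligned with ``m.probes`` with columns ``dup_freq``,
    ``del_freq``, ``cnv_freq`` and a boolean ``retained`` flag implementing
    the strict ``cnv_freq < freq_cut`` exclusion (frequencies exactly at the
    threshold are retained).
    """
    if m.n_probes == 0 or m.n_samples == 0:
        raise ValueError("empty genotype matrix")
    indptr, vals = m.data.indptr, m.data.data
    dup = np.add.reduceat(
        np.concatenate([(vals == 1).astype(int), [0]]), indptr[:-1]
    ) * (np.diff(indptr) > 0)
    dels = np.add.reduceat(
        np.concatenate([(vals == -1).astype(int), [0]]), indptr[:-1]
    ) * (np.diff(indptr) > 0)
    out = m.probes.copy()
    out["dup_freq"] = dup / m.n_samples
    out["del_freq"] = dels / m.n_samples
    out["cnv_freq"] = out["dup_freq"] + out["del_freq"]
    out["retained"] = ~(out["cnv_freq"] < freq_cut)
    return out


def _window_r2(rows: sp.csr_matrix, n: int) -> np.ndarray:
    """Squared Pearson correlation between all probe pairs of a window."""
    X = rows.astype(float)
    s = np.asarray(X.sum(axis=1)).ravel()
    ss = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    G = np.asarray((X @ X.T).todense())
    cov = G - np.outer(s, s) / n
    var = ss - s**2 / n
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov / denom) ** 2
    r2[~np.isfinite(r2)] = 0.0  # zero-variance probes correlate with nothing
    return r2


def prune_probes(
    m: GenotypeMatrix,
    r2_max: float = 0.9999,
    window: int = 500,
    step: int = 250,
) -> list[str]:
    """Greedy windowed pruning on the signed CNV genotypes.

    Within each window of ``window`` probes (per chromosome), any pair with
    squared Pearson correlation > ``r2_max`` loses one member — the probe
    later in genomic position, keeping the proxy earliest in the region —
    then the window slides by ``step`` probes. Deterministic and order
    stable; zero-variance probes are never removed.
    """
    removed = np.zeros(m.n_probes, dtype=bool)
    for chrom, chrom_probes in m.probes.groupby("chrom", sort=False):
        idx = chrom_probes.index.to_numpy()
        start = 0
        while True:
            w = idx[start : start + window]
            if len(w) >= 2:
                r2 = _window_r2(m.data[w], m.n_samples)
                k = len(w)
                for a in range(k):
                    if removed[w[a]]:
                        continue
                    for b in range(a + 1, k):
                        if removed[w[b]]:
                            continue
                        if r2[a, b] > r2_max:
                            removed[w[b]] = True  # later position loses
            if start + window >= len(idx):
                break
            start += step
    keep = ~removed
    return m.probes.loc[keep, "probe_id"].tolist()
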