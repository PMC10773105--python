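"""Effective number of independent tests and significance thresholds.

Recurrent CNVs leave neighboring probes highly correlated, so a Bonferroni
correction over the raw probe count would be far too strict. The effective
test count is estimated from the eigenvalue spectrum of the per-chromosome
probe correlation matrices: the number of leading eigenvalues needed to
explain a given fraction (99.5% by default) of the total variance, summed
over chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import round_sig
from .matrix import GenotypeMatrix

DEFAULT_VARIANCE_FRACTION = 0.995
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ThresholdSet:
    """Genome-wide and experiment-wide Bonferroni-style thresholds."""

    n_eff: int
    n_traits: int
    alpha: float
    gw_p: float  # alpha / n_eff
    xw_p: float  # alpha / (n_eff * n_traits)

    def display(self, digits: int = 2) -> dict[str, float]:
        """Thresholds rounded to significant figures for reporting."""
        return {
            "gw_p": round_sig(self.gw_p, digits),
            "xw_p": round_sig(self.xw_p, digits),
        }


def _n_eff_spectrum(eigvals: np.ndarray, variance_fraction: float) -> int:
    """Smallest k with the top-k eigenvalues summing to >= the cut fraction."""
    ev = np.sort(np.clip(eigvals, 0.0, None))[::-1]
    total = ev.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def effective_tests(
    m: GenotypeMatrix,
    per_chromosome: bool = True,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> int:
    """Effective number of independent probes of a (filtered, pruned) matrix.

    Zero-variance probes are excluded from the correlation matrices and
    contribute nothing; a chromosome with a single variable probe
    contributes exactly 1.
    """
    if not (0.0 < variance_fraction <= 1.0):
        raise ValueError("variance_fraction must lie in (0, 1]")
    groups = (
        m.probes.groupby("chrom", sort=False).indices.values()
        if per_chromosome
        else [np.arange(m.n_probes)]
    )
    total = 0
    for idx in groups:
        idx = np.asarray(list(idx))
        G = np.vstack([m.row(i).astype(float) for i in idx])
        G = G[G.std(axis=1) > 0]
        if G.shape[0] == 0:
            continue
        if G.shape[0] == 1:
            total += 1
            continue
        corr = np.corrcoef(G)
        eig = np.linalg.eigvalsh(corr)
        total += _n_eff_spectrum(eig, variance_fraction)
    return total


def thresholds(
    n_eff: int, n_traits: int, alpha: float = DEFAULT_ALPHA
) -> ThresholdSet:
    """Genome-wide (alpha/n_eff) and experiment-wide (alpha/(n_eff*n_traits))
    significance thresholds; full precision internally, rounded on display."""
    if n_eff < 1 or n_traits < 1:
        raise ValueError("n_eff and n_traits must be >= 1")
    return ThresholdSet(
        n_eff=int(n_eff),
        n_traits=int(n_traits),
        alpha=alpha,
        gw_p=alpha / n_eff,
        xw_p=alpha / (n_eff * n_traits),
    )
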