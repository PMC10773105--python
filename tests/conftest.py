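"""Shared fixtures and builders for the test suite.

All fixtures generate data programmatically (no stored files); moderate
cohort simulations are session-scoped so their cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cnvgwas.matrix import GenotypeMatrix


def matrix_from_dense(G, positions=None, chrom="1") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dense probes x samples int array."""
    G = np.asarray(G, dtype=np.int8)
    n_probes, n_samples = G.shape
    if positions is None:
        positions = 1000 * (np.arange(n_probes) + 1)
    if np.ndim(chrom) == 0:
        chroms = [chrom] * n_probes
    else:
        chroms = list(chrom)
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "chrom": chroms,
            "pos": positions,
        }
    )
    samples = np.array([f"s{j}" for j in range(n_samples)])
    return GenotypeMatrix(
        probes=probes, samples=samples, data=sp.csr_matrix(G, dtype=np.int8)
    )


def rare_genotypes(rng, n_probes, n_samples, freq=0.01):
    """Random sparse signed genotypes emulating rare CNV carriers."""
    G = np.zeros((n_probes, n_samples), dtype=np.int8)
    for i in range(n_probes):
        carriers = rng.random(n_samples) < freq
        signs = rng.choice([-1, 1], size=n_samples)
        G[i, carriers] = signs[carriers]
    return G


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run (n = 20,000, seed 1), shared read-only."""
    from cnvgwas.pipeline import PipelineRun, demo_config

    outdir = tmp_path_factory.mktemp("demo_run")
    pr = PipelineRun(demo_config(seed=1, n_samples=20_000), outdir)
    pr.run()
    return pr


@pytest.fixture(scope="session")
def mirror_cohort():
    """Single-locus cohort generated under a mirror effect (log-OR 1.0),
    n = 30,000, used by parameter-recovery and validation tests."""
    from cnvgwas.matrix import encode_probe_matrix
    from cnvgwas.pipeline import RunConfig
    from cnvgwas.simulate import (
        CovariateSpec,
        EffectSpec,
        demo_genome,
        simulate_calls,
        simulate_phenotypes,
    )

    genome = demo_genome(n_loci=1, dup_freq=0.005, del_freq=0.005)
    effects = [
        EffectSpec("disease_1", "locus_1", "mirror", log_odds=1.0, hazard_ratio=2.0)
    ]
    spec = CovariateSpec()
    n = 30_000
    calls = simulate_calls(genome, n, seed=7)
    pheno = simulate_phenotypes(
        calls, genome, effects, spec, n, seed=7, diseases={"disease_1": 0.05}
    )
    m = encode_probe_matrix(
        calls, genome.probe_table(), sample_ids=pheno["sample_id"]
    )
    return {"genome": genome, "calls": calls, "pheno": pheno, "matrix": m}
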