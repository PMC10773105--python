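"""Dosage encodings, exact genotypic Fisher test, Firth fallback, scans."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from cnvgwas.association import (
    encode_genotypes,
    fisher_2x3,
    genomic_inflation,
    genotypic_fisher,
    prefilter,
    run_burden_gwas,
    run_gwas,
    stepwise_conditional,
)
from cnvgwas.firth import fit_firth, fit_ml, firth_logistic
from cnvgwas.matrix import probe_frequencies

from conftest import matrix_from_dense


class TestEncodings:
    @pytest.mark.parametrize(
        "model,expected_dose,expected_valid",
        [
            ("mirror", [-1.0, 0.0, 1.0], [True, True, True]),
            ("ushape", [1.0, 0.0, 1.0], [True, True, True]),
            ("duponly", [0.0, 0.0, 1.0], [False, True, True]),
            ("delonly", [1.0, 0.0, 0.0], [True, True, False]),
        ],
    )
    def test_encoding_table(self, model, expected_dose, expected_valid):
        dose, valid = encode_genotypes(np.array([-1, 0, 1]), model)
        assert dose.tolist() == expected_dose
        assert valid.tolist() == expected_valid

    def test_only_signed_genotypes_accepted(self):
        with pytest.raises(ValueError, match="-1, 0"):
            encode_genotypes(np.array([2, 0]), "mirror")
        with pytest.raises(ValueError, match="unknown model"):
            encode_genotypes(np.array([0, 1]), "dominance")


def oracle_fisher_2x3(table):
    """Independent full-enumeration oracle in exact rational arithmetic."""
    table = np.asarray(table, dtype=int)
    r0, r1 = int(table[0].sum()), int(table[1].sum())
    cols = table.sum(axis=0)
    n = r0 + r1

    def prob(top):
        num = Fraction(1)
        for c, a in zip(cols, top):
            num *= comb(int(c), int(a))
        return Fraction(num, comb(n, r0))

    p_obs = prob(table[0])
    total = Fraction(0)
    for a in range(int(cols[0]) + 1):
        for b in range(int(cols[1]) + 1):
            c = r0 - a - b
            if 0 <= c <= cols[2]:
                p = prob((a, b, c))
                if p <= p_obs:
                    total += p
    return float(min(total, Fraction(1)))


class TestGenotypicFisher:
    def test_identical_rows_give_p_one(self):
        g = np.array([-1] * 10 + [0] * 180 + [1] * 10)
        y = np.array(([0] * 5 + [1] * 5) + ([0] * 90 + [1] * 90) * 1
                     + [0] * 5 + [1] * 5)
        assert genotypic_fisher(g, y) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_spec_table(self):
        table = np.array([[0, 20, 0], [5, 10, 5]])
        assert fisher_2x3(table) == pytest.approx(oracle_fisher_2x3(table))

    def test_zero_margin_column_collapses_to_2x2(self):
        # one case carrier, no deletions at all
        table = np.array([[0, 99, 0], [0, 0, 1]])
        expected = stats.fisher_exact(table[:, 1:])[1]
        assert fisher_2x3(table) == pytest.approx(expected)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 41))
            cells = rng.multinomial(n, np.full(6, 1 / 6)).reshape(2, 3)
            if cells.sum(axis=1).min() == 0:
                continue
            assert fisher_2x3(cells) == pytest.approx(
                oracle_fisher_2x3(cells), rel=1e-9
            ), cells

    def test_requires_case_and_control(self):
        with pytest.raises(ValueError, match="case"):
            genotypic_fisher(np.array([0, 1]), np.array([1, 1]))


class TestPrefilter:
    def _setup(self, g_rows, status):
        m = matrix_from_dense(np.asarray(g_rows, dtype=np.int8))
        freqs = probe_frequencies(m, freq_cut=0.0)
        return prefilter(m, freqs, np.asarray(status, dtype=float))

    def test_single_diseased_carrier_fails_all_models(self):
        g = np.zeros((1, 2000), dtype=np.int8)
        g[0, :1] = 1
        status = np.zeros(2000)
        status[0] = 1
        status[1:101] = 1
        pf = self._setup(g, status)
        assert not pf.loc[0, ["pass_mirror", "pass_ushape", "pass_duponly",
                              "pass_delonly"]].any()

    def test_two_dup_cases_pass_dup_models_not_del(self):
        g = np.zeros((1, 5000), dtype=np.int8)
        g[0, :6] = 1  # 6 duplication carriers
        status = np.zeros(5000)
        status[:6] = 1  # all carriers are cases -> tiny Fisher p
        status[6:206] = 1
        pf = self._setup(g, status)
        assert pf.loc[0, "fisher_p"] <= 1e-3
        assert pf.loc[0, "pass_mirror"] and pf.loc[0, "pass_ushape"]
        assert pf.loc[0, "pass_duponly"] and not pf.loc[0, "pass_delonly"]

    def test_frequency_excluded_probe_skipped_regardless_of_signal(self):
        g = np.zeros((1, 5000), dtype=np.int8)
        g[0, :4] = 1
        status = np.zeros(5000)
        status[:4] = 1
        m = matrix_from_dense(g)
        freqs = probe_frequencies(m, freq_cut=0.01)  # 4/5000 < 1%
        pf = prefilter(m, freqs, status)
        assert pf.loc[0, "freq_excluded"]
        assert not pf.loc[0, "pass_mirror"]


def simulate_logistic(rng, n, beta, carrier_freq, signed=False, intercept=-3.0):
    if signed:
        u = rng.random(n)
        g = np.where(u < carrier_freq / 2, 1,
                     np.where(u < carrier_freq, -1, 0)).astype(float)
    else:
        g = (rng.random(n) < carrier_freq).astype(float)
    y = (rng.random(n) < expit(intercept + beta * g)).astype(float)
    return g, y


class TestFirthLogistic:
    def test_null_wald_calibration(self):
        rng = np.random.default_rng(0)
        hits = 0
        runs = 60
        for _ in range(runs):
            g, y = simulate_logistic(rng, 1000, 0.0, 0.3, intercept=-1.0)
            X = np.column_stack([np.ones(1000), g])
            fit = firth_logistic(y, X)
            hits += abs(fit.beta[1]) < 3 * fit.se[1]
        assert hits >= int(0.95 * runs)

    def test_ml_and_firth_agree_without_separation(self):
        rng = np.random.default_rng(1)
        g, y = simulate_logistic(rng, 500, 1.0, 0.5, intercept=-0.5)
        X = np.column_stack([np.ones(500), g])
        ml = fit_ml(y, X)
        fr = fit_firth(y, X)
        assert ml.converged and fr.converged
        assert abs(ml.beta[1] - fr.beta[1]) / abs(ml.beta[1]) < 0.1
        fit = firth_logistic(y, X)
        assert not fit.firth_used  # fallback not triggered

    def test_complete_separation_falls_back_to_finite_firth(self):
        rng = np.random.default_rng(2)
        n = 1000
        g = np.zeros(n)
        g[:5] = 1.0
        y = np.zeros(n)
        y[:5] = 1.0  # all 5 carriers are cases
        y[5:105] = 1.0
        X = np.column_stack([np.ones(n), g])
        fit = firth_logistic(y, X)
        assert fit.firth_used
        assert np.all(np.isfinite(fit.beta))
        assert 0.0 < fit.p[1] < 1.0

    def test_no_fallback_with_all_cells_at_least_ten(self):
        rng = np.random.default_rng(3)
        g, y = simulate_logistic(rng, 4000, 1.0, 0.1, intercept=-1.5)
        assert min(((g == v) & (y == s)).sum() for v in (0, 1) for s in (0, 1)) >= 10
        X = np.column_stack([np.ones(len(y)), g])
        assert not firth_logistic(y, X).firth_used

    def test_collinear_column_dropped_and_reported(self):
        rng = np.random.default_rng(4)
        g, y = simulate_logistic(rng, 500, 1.0, 0.3, intercept=-1.0)
        X = np.column_stack([np.ones(500), g, g])  # duplicated column
        fit = firth_logistic(y, X)
        assert len(fit.dropped) == 1
        j = fit.dropped[0]
        assert fit.beta[j] == 0.0 and fit.p[j] == 1.0

    def test_constant_outcome_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="one class"):
            firth_logistic(np.ones(10), X)


class TestRunGwas:
    def test_mirror_recovers_simulated_log_odds(self, mirror_cohort):
        m = mirror_cohort["matrix"]
        pheno = mirror_cohort["pheno"]
        status = pheno["disease_1_status"].map(
            {"case": 1.0, "control": 0.0}
        ).to_numpy(dtype=float)
        cov = pheno[["age", "sex"]]
        freqs = probe_frequencies(m, freq_cut=1e-4)
        mask = freqs["retained"].to_numpy() & (freqs["cnv_freq"] > 0).to_numpy()
        res = run_gwas(m, status, cov, "mirror", probe_mask=mask)
        best = res.loc[res["p"].idxmin()]
        assert abs(best["beta"] - 1.0) <= 2 * best["se"]

    def test_mirror_equals_ushape_without_deletions(self):
        rng = np.random.default_rng(5)
        g = np.zeros((1, 4000), dtype=np.int8)
        g[0, rng.choice(4000, 60, replace=False)] = 1  # duplications only
        m = matrix_from_dense(g)
        y = (rng.random(4000) < expit(-2.5 + 1.2 * (m.row(0) == 1))).astype(float)
        a = run_gwas(m, y, None, "mirror")
        b = run_gwas(m, y, None, "ushape")
        assert a.loc[0, "beta"] == pytest.approx(b.loc[0, "beta"])
        assert a.loc[0, "p"] == pytest.approx(b.loc[0, "p"])

    def test_delonly_probe_without_deletions_skipped(self):
        g = np.zeros((1, 1000), dtype=np.int8)
        g[0, :20] = 1  # only duplications
        y = np.zeros(1000)
        y[:50] = 1
        res = run_gwas(matrix_from_dense(g), y, None, "delonly")
        assert res.loc[0, "skipped_reason"] == "no_informative_carriers"
        assert np.isnan(res.loc[0, "p"])

    def test_too_few_carrier_cases_skipped(self):
        g = np.zeros((1, 1000), dtype=np.int8)
        g[0, :10] = 1
        y = np.zeros(1000)
        y[0] = 1  # one diseased carrier
        y[500:550] = 1
        res = run_gwas(matrix_from_dense(g), y, None, "duponly", min_cases=2)
        assert res.loc[0, "skipped_reason"] == "fewer_than_min_cases_after_masking"

    def test_or_confidence_interval_brackets_or(self):
        rng = np.random.default_rng(6)
        g = np.zeros((1, 3000), dtype=np.int8)
        g[0, :150] = 1
        y = (rng.random(3000) < expit(-2.0 + 1.0 * (g[0] == 1))).astype(float)
        res = run_gwas(matrix_from_dense(g), y, None, "duponly")
        assert res.loc[0, "ci_low"] < res.loc[0, "or"] < res.loc[0, "ci_high"]


class TestStepwiseConditional:
    def test_no_significant_probe_gives_empty_list(self):
        rng = np.random.default_rng(7)
        g = np.zeros((3, 2000), dtype=np.int8)
        for i in range(3):
            g[i, rng.choice(2000, 30, replace=False)] = 1
        y = (rng.random(2000) < 0.1).astype(float)
        leads = stepwise_conditional(matrix_from_dense(g), y, None, "mirror",
                                     threshold=1e-8)
        assert leads.empty

    def test_perfect_proxies_collapse_to_single_lead(self):
        rng = np.random.default_rng(8)
        base = np.zeros(6000, dtype=np.int8)
        base[rng.choice(6000, 80, replace=False)] = 1
        G = np.vstack([base] * 12)  # 12 perfectly correlated proxies
        y = (rng.random(6000) < expit(-2.5 + 1.6 * base)).astype(float)
        leads = stepwise_conditional(matrix_from_dense(G), y, None, "mirror",
                                     threshold=1e-4)
        assert len(leads) == 1

    def test_two_independent_loci_give_two_leads(self):
        rng = np.random.default_rng(9)
        n = 8000
        g1 = np.zeros(n, dtype=np.int8)
        g2 = np.zeros(n, dtype=np.int8)
        g1[rng.choice(n, 100, replace=False)] = 1
        g2[rng.choice(n, 100, replace=False)] = 1
        G = np.vstack([g1, g1, g2, g2])
        m = matrix_from_dense(G, chrom=["1", "1", "2", "2"],
                              positions=[1000, 2000, 1000, 2000])
        y = (rng.random(n) < expit(-2.5 + 1.5 * g1 + 1.5 * g2)).astype(float)
        leads = stepwise_conditional(m, y, None, "mirror", threshold=1e-4)
        assert len(leads) == 2
        assert set(leads["chrom"]) == {"1", "2"}

    def test_lead_conditional_p_is_one_after_conditioning(self):
        rng = np.random.default_rng(10)
        base = np.zeros(4000, dtype=np.int8)
        base[rng.choice(4000, 60, replace=False)] = 1
        m = matrix_from_dense(np.vstack([base, base]))
        y = (rng.random(4000) < expit(-2.5 + 1.5 * base)).astype(float)
        dose, valid = encode_genotypes(m.row(0), "mirror")
        res = run_gwas(m, y, None, "mirror",
                       conditioning=np.where(valid, dose, np.nan))
        assert (res["p"] == 1.0).all()
        assert (res["skipped_reason"] == "collinear_with_conditioning").all()


class TestBurdenGwas:
    def test_recovers_simulated_diseases_per_deletion(self):
        rng = np.random.default_rng(11)
        n = 20_000
        g = np.zeros((1, n), dtype=np.int8)
        g[0, rng.choice(n, 200, replace=False)] = -1
        burden = rng.poisson(1.0, n).astype(float) + 3.0 * (g[0] == -1)
        res = run_burden_gwas(matrix_from_dense(g), burden, None, "delonly")
        assert abs(res.loc[0, "beta"] - 3.0) <= 2 * res.loc[0, "se"]

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        n = 3000
        G = np.zeros((120, n), dtype=np.int8)
        for i in range(120):
            G[i, rng.choice(n, 40, replace=False)] = rng.choice([-1, 1], 40)
        burden = rng.poisson(1.5, n).astype(float)
        res = run_burden_gwas(matrix_from_dense(G), burden, None, "mirror")
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.001

    def test_constant_burden_rejected(self):
        g = np.zeros((1, 100), dtype=np.int8)
        g[0, 0] = 1
        with pytest.raises(ValueError, match="constant"):
            run_burden_gwas(matrix_from_dense(g), np.ones(100), None, "mirror")


class TestModelIdentification:
    def test_duponly_mechanism_favors_duponly_model(self):
        """Data generated under a duplication-only mechanism yields lower
        median p for the duplication-only than the deletion-only model."""
        from cnvgwas.matrix import encode_probe_matrix, probe_frequencies
        from cnvgwas.simulate import (
            CovariateSpec,
            EffectSpec,
            demo_genome,
            simulate_calls,
            simulate_phenotypes,
        )

        genome = demo_genome(n_loci=1, dup_freq=0.008, del_freq=0.008)
        effects = [EffectSpec("d", "locus_1", "duponly", log_odds=1.8)]
        p_dup, p_del = [], []
        for r in range(8):
            n = 8000
            calls = simulate_calls(genome, n, seed=300 + r)
            pheno = simulate_phenotypes(
                calls, genome, effects, CovariateSpec(), n, seed=300 + r,
                diseases={"d": 0.05},
            )
            m = encode_probe_matrix(calls, genome.probe_table(),
                                    sample_ids=pheno["sample_id"])
            status = pheno["d_status"].map(
                {"case": 1.0, "control": 0.0}
            ).to_numpy(float)
            freqs = probe_frequencies(m)
            mask = (freqs["cnv_freq"] > 0).to_numpy()
            for model, sink in (("duponly", p_dup), ("delonly", p_del)):
                scan = run_gwas(m, status, None, model, probe_mask=mask)
                ps = scan["p"].dropna()
                sink.append(ps.min() if len(ps) else 1.0)
        assert np.median(p_dup) < np.median(p_del)


class TestGenomicInflation:
    def test_uniform_p_lambda_near_one(self):
        rng = np.random.default_rng(13)
        lam = genomic_inflation(rng.random(10_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_all_half_is_exactly_one(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_enriched_small_p_inflates_lambda(self):
        rng = np.random.default_rng(14)
        assert genomic_inflation(rng.random(5000) ** 2) > 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            genomic_inflation(np.array([0.5] * 100 + [0.0]))
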