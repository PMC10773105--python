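"""Validation statistics, tiers, replication arithmetic, BMI confounding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from cnvgwas.matrix import encode_probe_matrix
from cnvgwas.simulate import (
    CovariateSpec,
    EffectSpec,
    demo_genome,
    simulate_calls,
    simulate_phenotypes,
)
from cnvgwas.validation import (
    ReplicationRecord,
    assign_tier,
    bmi_confounding,
    bmi_eligibility_thresholds,
    coxph_fit,
    directional_p,
    inverse_normal_transform,
    kaplan_meier,
    replicate,
    replication_enrichment,
    replication_enrichment_grid,
    residual_regression,
)


class TestResidualRegression:
    def test_strong_effect_detected(self, mirror_cohort):
        pheno = mirror_cohort["pheno"]
        m = mirror_cohort["matrix"]
        status = pheno["disease_1_status"].map({"case": 1.0, "control": 0.0})
        from cnvgwas.association import encode_genotypes
        from cnvgwas.matrix import probe_frequencies

        freqs = probe_frequencies(m)
        i = int(freqs["cnv_freq"].idxmax())  # a probe inside the locus
        dose, valid = encode_genotypes(m.row(i), "mirror")
        out = residual_regression(
            status.to_numpy(float), pheno[["age", "sex"]],
            {"mirror": np.where(valid, dose, np.nan)},
        )
        assert out["encoding"] == "mirror"
        assert out["p"] <= 1e-4

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        n = 3000
        cov = pd.DataFrame({"age": rng.uniform(40, 70, n)})
        pvals = []
        for _ in range(200):
            y = (rng.random(n) < 0.1).astype(float)
            g = np.zeros(n)
            g[rng.choice(n, 150, replace=False)] = 1.0
            pvals.append(residual_regression(y, cov, {"ushape": g})["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_constant_outcome_rejected(self):
        y = np.ones(50)
        cov = pd.DataFrame({"x": np.arange(50.0)})
        with pytest.raises(ValueError, match="one class"):
            residual_regression(y, cov, {"mirror": (np.arange(50) < 5) * 1.0})


def exponential_two_group(rng, n, hr, censor_quantile=0.7):
    g = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0, n) / np.exp(np.log(hr) * g)
    c = np.quantile(t, censor_quantile)
    event = (t <= c).astype(float)
    return np.minimum(t, c) + 1e-9, event, g


class TestCoxph:
    def test_recovers_exponential_rate_ratio(self):
        rng = np.random.default_rng(1)
        time, event, g = exponential_two_group(rng, 5000, hr=2.0)
        out = coxph_fit(time, event, None, {"mirror": g})
        # closed-form exponential MLE oracle: (d1/T1)/(d0/T0)
        d1, t1 = event[g == 1].sum(), time[g == 1].sum()
        d0, t0 = event[g == 0].sum(), time[g == 0].sum()
        oracle = (d1 / t1) / (d0 / t0)
        assert out["hr"] == pytest.approx(oracle, rel=0.1)
        assert 1.7 <= out["hr"] <= 2.4

    def test_null_effect_is_calibrated(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(60):
            time, event, g = exponential_two_group(rng, 800, hr=1.0)
            out = coxph_fit(time, event, None, {"mirror": g})
            pvals.append(out["p"])
            assert abs(out["beta"]) < 4 * out["se"]
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_lowest_p_encoding_reported(self):
        rng = np.random.default_rng(3)
        time, event, g = exponential_two_group(rng, 3000, hr=2.0)
        noise = rng.random(3000)
        out = coxph_fit(time, event, None, {"real": g, "noise": noise})
        assert out["encoding"] == "real"

    def test_no_variance_encoding_skipped(self):
        rng = np.random.default_rng(4)
        time, event, g = exponential_two_group(rng, 500, hr=1.5)
        out = coxph_fit(time, event, None,
                        {"flat": np.zeros(500), "real": g})
        assert out["encoding"] == "real"
        assert out["skipped"][0][0] == "flat"

    def test_requires_events(self):
        with pytest.raises(ValueError, match="event"):
            coxph_fit(np.ones(10), np.zeros(10), None, {"g": np.arange(10.0)})


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at 2 and 4; censored at 3, 5, 5
        time = np.array([2.0, 3.0, 4.0, 5.0, 5.0])
        event = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        curves = kaplan_meier(time, event, np.array(["all"] * 5))
        s = curves["all"]["survival"]
        assert s.loc[4.0] == pytest.approx((4 / 5) * (2 / 3))

    def test_no_events_curve_constant_one(self):
        curves = kaplan_meier(np.array([1.0, 2.0]), np.zeros(2),
                              np.array(["a", "a"]))
        assert (curves["a"]["survival"] == 1.0).all()

    def test_all_events_at_one_time_step_to_zero(self):
        curves = kaplan_meier(np.ones(4), np.ones(4), np.array(["a"] * 4))
        assert curves["a"]["survival"].iloc[-1] == 0.0


class TestAssignTier:
    @pytest.mark.parametrize(
        "pattern", list(itertools.product([True, False], repeat=3))
    )
    def test_truth_table(self, pattern):
        alpha = 1e-4
        ps = [alpha / 10 if hit else 0.3 for hit in pattern]
        tier = assign_tier(*ps, is_burden_signal=False, alpha=alpha)
        n_pass = sum(pattern)
        assert tier == (4 - n_pass if n_pass else 4)

    def test_representative_p_value_triples(self):
        assert assign_tier(1e-5, 1e-6, 1e-9) == 1
        assert assign_tier(0.3, 1e-5, 1e-6) == 2
        assert assign_tier(0.3, 0.2, 1e-5) == 3

    def test_burden_signals_always_tier_one(self):
        assert assign_tier(0.9, 0.9, 0.9, is_burden_signal=True) == 1

    def test_boundary_p_exactly_alpha_counts(self):
        assert assign_tier(1e-4, 1.0, 1.0) == 3


class TestDirectionalP:
    def test_concordant_halves(self):
        assert directional_p(0.01, True) == pytest.approx(0.005)

    def test_discordant_penalized(self):
        assert directional_p(0.01, False) == pytest.approx(0.995)

    def test_boundary_p_one(self):
        assert directional_p(1.0, True) == pytest.approx(0.5)
        assert directional_p(1.0, False) == pytest.approx(0.5)

    def test_monotone_and_rewarding(self):
        grid = np.linspace(0.01, 1.0, 50)
        conc = [directional_p(p, True) for p in grid]
        disc = [directional_p(p, False) for p in grid]
        assert all(np.diff(conc) > 0)
        assert all(np.diff(disc) < 0)
        assert all(c < p for c, p in zip(conc, grid))


class TestReplicate:
    SIGNALS = pd.DataFrame(
        [
            {"signal_id": "a", "chrom": "1", "pos": 500, "beta": 1.0,
             "cnvr_start": 100, "cnvr_end": 900},
            {"signal_id": "b", "chrom": "2", "pos": 500, "beta": -1.0,
             "cnvr_start": 100, "cnvr_end": 900},
            {"signal_id": "c", "chrom": "3", "pos": 500, "beta": 1.0,
             "cnvr_start": 100, "cnvr_end": 900},
        ]
    )
    REP = pd.DataFrame(
        [
            {"probe_id": "r1", "chrom": "1", "pos": 480, "beta": 0.5, "p": 0.01},
            {"probe_id": "r2", "chrom": "1", "pos": 520, "beta": 0.5, "p": 0.5},
            {"probe_id": "r3", "chrom": "2", "pos": 490, "beta": 0.2, "p": 0.04},
            {"probe_id": "r4", "chrom": "3", "pos": 450, "beta": 1.0,
             "p": np.nan},  # failed regression
        ]
    )

    def test_nearest_probe_tie_breaks_to_smaller_position(self):
        recs = {r.signal_id: r for r in replicate(self.SIGNALS, self.REP)}
        assert recs["a"].replication_probe == "r1"  # equidistant: 480 wins

    def test_directional_adjustment_applied(self):
        recs = {r.signal_id: r for r in replicate(self.SIGNALS, self.REP)}
        assert recs["a"].concordant and recs["a"].p_new == pytest.approx(0.005)
        assert not recs["b"].concordant
        assert recs["b"].p_new == pytest.approx(1 - 0.04 / 2)

    def test_failed_regressions_make_signal_non_evaluable(self):
        recs = {r.signal_id: r for r in replicate(self.SIGNALS, self.REP)}
        assert not recs["c"].evaluable

    def test_strict_threshold_uses_evaluable_count(self):
        recs = replicate(self.SIGNALS, self.REP, strict_alpha=0.05)
        n_eval = sum(r.evaluable for r in recs)
        assert n_eval == 2
        for r in recs:
            if r.evaluable:
                assert r.strictly_replicated == (r.p_new <= 0.05 / n_eval)


class TestReplicationEnrichment:
    def test_study_scale_values(self):
        fold, p = replication_enrichment(7, 49, 0.05)
        assert round(fold, 1) == 2.9
        assert float(f"{p:.2g}") == 0.011

    def test_zero_hits(self):
        fold, p = replication_enrichment(0, 30, 0.05)
        assert fold == 0.0 and p == pytest.approx(1.0)

    def test_all_hits_closed_form(self):
        fold, p = replication_enrichment(5, 5, 0.1)
        assert p == pytest.approx(0.1**5)

    def test_grid_monotone_in_k(self):
        rng = np.random.default_rng(5)
        grid = replication_enrichment_grid(rng.random(49) * 0.5)
        assert set(np.round(np.diff(sorted(grid["alpha"])), 3)) == {0.005}
        for n, alpha in [(49, 0.05)]:
            ps = [replication_enrichment(k, n, alpha)[1] for k in range(n + 1)]
            assert all(np.diff(ps) < 0)

    def test_alpha_bounds_checked(self):
        with pytest.raises(ValueError):
            replication_enrichment(1, 10, 1.5)


class TestInverseNormalTransform:
    def test_three_point_quantiles(self):
        got = inverse_normal_transform(np.array([1.0, 2.0, 3.0]))
        expected = stats.norm.ppf([(1 - 0.5) / 3, (2 - 0.5) / 3, (3 - 0.5) / 3])
        np.testing.assert_allclose(got, expected)
        np.testing.assert_allclose(got, [-0.967, 0.0, 0.967], atol=5e-4)

    def test_symmetric_input_sums_to_zero(self):
        got = inverse_normal_transform(np.arange(10.0))
        assert got.sum() == pytest.approx(0.0, abs=1e-12)

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.random(50)
        np.testing.assert_allclose(
            inverse_normal_transform(x),
            inverse_normal_transform(np.exp(5 * x) + 2),
        )

    def test_ties_share_average_rank(self):
        got = inverse_normal_transform(np.array([1.0, 1.0, 2.0]))
        assert got[0] == got[1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform(np.ones(5))


def _bmi_setup(bmi_shift, bmi_log_odds, direct_log_odds, seed, n=50_000):
    genome = demo_genome(n_loci=1, dup_freq=0.01, del_freq=0.01)
    effects = [
        EffectSpec("d", "locus_1", "ushape", log_odds=direct_log_odds,
                   bmi_shift=bmi_shift)
    ]
    spec = CovariateSpec(bmi_log_odds=bmi_log_odds)
    calls = simulate_calls(genome, n, seed=seed)
    pheno = simulate_phenotypes(calls, genome, effects, spec, n, seed=seed,
                                diseases={"d": 0.05})
    m = encode_probe_matrix(calls, genome.probe_table(),
                            sample_ids=pheno["sample_id"])
    status = pheno["d_status"].map({"case": 1.0, "control": 0.0}).to_numpy(float)
    from cnvgwas.matrix import probe_frequencies

    freqs = probe_frequencies(m)
    probe = m.probes["probe_id"].iloc[int(freqs["cnv_freq"].idxmax())]
    from cnvgwas.association import run_gwas

    mask = np.zeros(m.n_probes, dtype=bool)
    mask[m.probe_index(probe)] = True
    scan = run_gwas(m, status, pheno[["age", "sex"]], "ushape", probe_mask=mask)
    signals = pd.DataFrame(
        [{"signal_id": "sig", "disease": "d", "probe_id": probe,
          "model": "ushape", "beta": scan["beta"].iloc[0],
          "se": scan["se"].iloc[0]}]
    )
    resid_cov = pheno[["age", "sex", "array"]].assign(age2=pheno["age"] ** 2)
    results = bmi_confounding(
        signals, m, {"d": status}, {"d": pheno[["age", "sex"]]},
        pheno["bmi"].to_numpy(float), resid_cov,
        gw_p=1e-4, n_traits=1,
    )
    return results[0]


class TestBmiConfounding:
    def test_pure_mediation_flagged(self):
        res = _bmi_setup(bmi_shift=1.0, bmi_log_odds=0.7, direct_log_odds=0.0,
                         seed=11)
        assert res.eligible
        assert res.likely_bmi_driven

    def test_direct_effect_not_flagged(self):
        res = _bmi_setup(bmi_shift=0.0, bmi_log_odds=0.7, direct_log_odds=1.5,
                         seed=12)
        assert not res.likely_bmi_driven

    def test_eligibility_thresholds_at_study_scale(self):
        cuts = bmi_eligibility_thresholds(61, 73, 25)
        assert cuts["bmi_disease_p"] == pytest.approx(0.05 / 61)
        assert cuts["genotype_bmi_p"] == pytest.approx(0.05 / 73)
        assert cuts["coefficient_t_p"] == pytest.approx(0.002)
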