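"""Association engine: scaling, OLS, permutation control, FDR, scans."""

import numpy as np
import pytest
from scipy import stats

from splicestr import SimConfig, simulate_genotypes, simulate_psi
from splicestr.association import (
    bh_fdr,
    expression_factors,
    permutation_control,
    run_snp_scan,
    run_str_scan,
    zscale,
)
from splicestr.association import test_association as assoc_test


class TestZscale:
    def test_three_point_example(self):
        np.testing.assert_allclose(zscale([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        v = zscale(rng.normal(size=50))
        np.testing.assert_allclose(zscale(v), v, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscale([5, 5, 5])


class TestAssociation:
    def test_perfect_fit(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2.0])
        rec = assoc_test(x, x * 10 + 3, variant_class="SNP")
        assert rec.beta == pytest.approx(1.0)
        assert rec.p < 1e-12

    def test_beta_bounded_by_one(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 80).astype(float)
            y = rng.normal(size=80) + 0.5 * x
            rec = assoc_test(x, y, variant_class="SNP")
            assert abs(rec.beta) <= 1 + 1e-9

    def test_ols_unbiased_recovery(self, rng):
        # planted standardized effect 0.3 at n=500 over many loci
        betas = []
        for _ in range(400):
            x = rng.integers(0, 5, 500).astype(float) * 3
            y = 0.3 * zscale(x) + np.sqrt(1 - 0.09) * rng.normal(size=500)
            rec = assoc_test(x, y)
            betas.append(rec.beta)
        assert np.mean(betas) == pytest.approx(0.3, abs=0.01)

    def test_type_one_calibration(self, rng):
        hits = 0
        n_tests = 2000
        for _ in range(n_tests):
            x = rng.integers(0, 4, 120).astype(float)
            y = rng.normal(size=120)
            rec = assoc_test(x, y)
            hits += rec.p < 0.05
        assert hits / n_tests == pytest.approx(0.05, abs=0.015)

    def test_str_class_filter_applied(self):
        # rare dosage class is dropped before testing
        x = np.array([0.0] * 30 + [3.0] * 30 + [6.0] * 30 + [9.0] * 2)
        y = np.arange(92, dtype=float)
        rec = assoc_test(x, y)
        assert rec.n == 90

    def test_too_few_unique_genotypes_skipped(self):
        x = np.array([0.0] * 50 + [3.0] * 50)
        rec = assoc_test(x, np.random.default_rng(0).normal(size=100))
        assert not rec.ok and "unique" in rec.skip_reason

    def test_covariate_confounding_removed(self, rng):
        n = 400
        conf = rng.normal(size=n)
        x = rng.integers(0, 3, n).astype(float) + (conf > 0)
        y = 0.8 * conf + rng.normal(size=n)  # no direct x effect
        rec_naive = assoc_test(x, y, variant_class="SNP")
        rec_adj = assoc_test(x, y, covariates=conf[:, None],
                                   variant_class="SNP")
        assert abs(rec_adj.beta) < abs(rec_naive.beta)


class TestPermutationControl:
    def test_identity_permutation_preserves_p(self, rng):
        x = rng.integers(0, 3, 100).astype(float)
        y = 0.5 * x + rng.normal(size=100)
        base = assoc_test(x, y, variant_class="SNP")
        ctrl = permutation_control(x, y, permutation=np.arange(100),
                                   variant_class="SNP")
        assert ctrl.p == pytest.approx(base.p)

    def test_seed_determinism(self, rng):
        x = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        p1 = permutation_control(x, y, seed=5, variant_class="SNP").p
        p2 = permutation_control(x, y, seed=5, variant_class="SNP").p
        assert p1 == p2

    def test_uniform_under_true_effect(self, rng):
        # shuffling destroys even strong planted effects
        ps = []
        for i in range(600):
            x = rng.integers(0, 3, 150).astype(float)
            y = 0.6 * zscale(x) + rng.normal(size=150)
            ps.append(permutation_control(x, y, seed=i, variant_class="SNP").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_stepup_example(self):
        q, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        q, rej = bh_fdr(np.array([1.0]))
        assert q[0] == 1.0 and not rej[0]

    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=200)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))


class TestExpressionFactors:
    def test_recovers_global_confounder(self, rng):
        n, n_events = 300, 120
        conf = rng.normal(size=n)
        psi = rng.normal(size=(n_events, n)) + 0.9 * conf
        f = expression_factors(psi, k=3)
        assert abs(np.corrcoef(f[:, 0], conf)[0, 1]) > 0.9

    def test_k_zero(self, rng):
        assert expression_factors(rng.normal(size=(10, 8)), k=0).shape == (8, 0)

    def test_permutation_equivariance(self, rng):
        psi = rng.normal(size=(40, 60))
        perm = rng.permutation(60)
        f1 = expression_factors(psi, k=2)
        f2 = expression_factors(psi[:, perm], k=2)
        np.testing.assert_allclose(f1[perm], f2, atol=1e-8)


class TestScans:
    def test_str_scan_detects_planted_effects(self, small_cohort):
        res = run_str_scan(small_cohort["events"], small_cohort["genotypes"],
                           small_cohort["covariates"].to_numpy())
        truth = small_cohort["truth"]
        # every event has a causal variant (STR or tagging SNP); the STR is
        # either causal or in strong LD, so most should reach significance
        assert len(res.significant) >= 0.7 * len(small_cohort["events"])

    def test_scan_determinism(self, small_cohort):
        kw = dict(permute=True, seed=3)
        r1 = run_str_scan(small_cohort["events"], small_cohort["genotypes"],
                          small_cohort["covariates"].to_numpy(), **kw)
        r2 = run_str_scan(small_cohort["events"], small_cohort["genotypes"],
                          small_cohort["covariates"].to_numpy(), **kw)
        assert r1.table.equals(r2.table)

    def test_snp_scan_restricted_to_str_events(self, small_cohort):
        res = run_str_scan(small_cohort["events"], small_cohort["genotypes"],
                           small_cohort["covariates"].to_numpy())
        snp = run_snp_scan(small_cohort["events"], small_cohort["genotypes"],
                           small_cohort["covariates"].to_numpy(),
                           str_results=res)
        tested_events = set(snp.table["event_id"])
        assert tested_events <= set(res.significant_event_ids())

    def test_summary_counts_match_table(self, small_cohort):
        res = run_str_scan(small_cohort["events"], small_cohort["genotypes"],
                           small_cohort["covariates"].to_numpy())
        s = res.summary()
        assert s["n_tests"].sum() == len(res.table)
        assert s["n_significant"].sum() == int(res.table["significant"].sum())


class TestReplicationCorrelation:
    def test_effects_replicate_across_cohorts(self):
        # two independent synthetic cohorts from the same truth layout:
        # effect sizes of significant pairs correlate positively
        betas = {}
        for seed in (21, 22):
            cfg = SimConfig(n_samples=250, n_events=15, snps_per_locus=5,
                            seed=seed, causal_effect=0.4,
                            effect_profile="ramp")
            gt, truth, ex = simulate_genotypes(cfg)
            evs, cov = simulate_psi(gt, truth, cfg, ex)
            res = run_str_scan(evs, gt, cov.to_numpy())
            ok = res.table.loc[res.table["skip_reason"] == ""]
            betas[seed] = ok.set_index(["event_id", "variant_id"])["beta"]
        joined = betas[21].to_frame("a").join(betas[22].to_frame("b")).dropna()
        r = np.corrcoef(joined["a"], joined["b"])[0, 1]
        assert r > 0.5
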