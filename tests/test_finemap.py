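"""Fine-mapping: residualization, equivalence filter, ANOVA, Lasso,
Bayesian configuration model, and the strict/lenient consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicestr import FineMapper, run_snp_scan, run_str_scan
from splicestr.finemap import (
    FineMapInput,
    anova_str_test,
    bayes_finemap,
    classify_consensus,
    equivalence_filter,
    lasso_select,
    residualize_phenotype,
)


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.normal(5, 2, size=40)
        np.testing.assert_allclose(residualize_phenotype(y, None), y - y.mean())

    def test_exact_linear_function_annihilated(self, rng):
        C = rng.normal(size=(60, 3))
        y = C @ [1.0, -2.0, 0.5] + 4.0
        assert np.max(np.abs(residualize_phenotype(y, C))) < 1e-8

    def test_orthogonal_to_covariates(self, rng):
        C = rng.normal(size=(80, 4))
        y = rng.normal(size=80) + C[:, 0]
        r = residualize_phenotype(y, C)
        assert np.max(np.abs(C.T @ r)) < 1e-8

    def test_rank_deficiency_reported(self, rng):
        C = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            residualize_phenotype(rng.normal(size=30), C)


class TestEquivalenceFilter:
    def test_equal_betas_retained(self):
        keep = equivalence_filter([0.5, 0.5], [0.05, 0.08], [1e-10, 1e-4])
        assert keep.all()

    def test_discrepant_beta_filtered(self):
        # Z = (0.1-0.5)/sqrt(2*0.05^2) = -5.657 -> p ~ 1.5e-8
        keep = equivalence_filter([0.5, 0.1], [0.05, 0.05], [1e-10, 0.04])
        assert keep[0] and not keep[1]

    def test_strongest_always_retained(self):
        keep = equivalence_filter([0.5, -0.5], [0.01, 0.01], [1e-20, 1e-3])
        assert keep[0]


class TestAnova:
    def test_exact_copy_of_snp_flagged(self, rng):
        snp = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        rec = anova_str_test(y, snp, snp.copy())
        assert rec.collinear and rec.p == 1.0

    def test_null_calibration(self, rng):
        ps = []
        for _ in range(800):
            snp = rng.integers(0, 3, 120).astype(float)
            strv = rng.integers(0, 4, 120).astype(float)
            y = 0.3 * snp + rng.normal(size=120)
            ps.append(anova_str_test(y, snp, strv).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_independent_str_effect(self, rng):
        ps = []
        for _ in range(30):
            snp = rng.integers(0, 3, 300).astype(float)
            strv = rng.integers(0, 4, 300).astype(float) * 3
            zs = (strv - strv.mean()) / strv.std()
            y = 0.3 * zs + rng.normal(size=300)
            ps.append(anova_str_test(y, snp, strv).p)
        assert np.median(ps) < 1e-3

    def test_f_equals_squared_t_of_added_regressor(self, rng):
        # algebraic identity: partial F for one added regressor = t^2
        import statsmodels.api as sm

        snp = rng.integers(0, 3, 150).astype(float)
        strv = rng.integers(0, 4, 150).astype(float)
        y = 0.2 * strv + rng.normal(size=150)
        rec = anova_str_test(y, snp, strv)
        zs = lambda v: (v - v.mean()) / v.std(ddof=1)
        X = sm.add_constant(np.column_stack([zs(snp), zs(strv)]))
        fit = sm.OLS(y, X).fit()
        assert rec.f_stat == pytest.approx(fit.tvalues[2] ** 2, rel=1e-8)
        assert rec.p == pytest.approx(fit.pvalues[2], rel=1e-8)


class TestLasso:
    def test_causal_str_selected_among_noise(self, rng):
        hits = 0
        for _ in range(10):
            n = 300
            strv = rng.integers(0, 5, n).astype(float) * 3
            snps = rng.integers(0, 3, (n, 20)).astype(float)
            zs = (strv - strv.mean()) / strv.std()
            y = 0.4 * zs + rng.normal(size=n)
            X = np.column_stack([strv, snps])
            ids = ["str0"] + [f"snp{j}" for j in range(20)]
            flags = [True] + [False] * 20
            res = lasso_select(y, X, ids, flags)
            hits += res.selected_str == "str0"
        assert hits >= 9

    def test_snp_with_larger_coefficient_blocks_str(self, rng):
        # the causal variant is a SNP; an STR correlated with it must not win
        n = 400
        snp = rng.integers(0, 3, n).astype(float)
        strv = snp * 3 + (rng.random(n) < 0.3) * 3  # noisy copy
        y = 0.5 * (snp - snp.mean()) / snp.std() + 0.3 * rng.normal(size=n)
        X = np.column_stack([strv, snp])
        res = lasso_select(y, X, ["str0", "snp0"], [True, False])
        assert res.selected_str is None
        assert abs(res.coefficients["snp0"]) > abs(res.coefficients["str0"])

    def test_tiny_n_raises(self, rng):
        with pytest.raises(ValueError):
            lasso_select(rng.normal(size=3), rng.normal(size=(3, 2)),
                         ["a", "b"], [True, False])


def _random_locus(rng, m, n=400, causal=None, effect=0.0):
    """Small LD block with optional causal variant; returns FineMapInput."""
    base = rng.normal(size=(n, 3))
    load = rng.normal(size=(3, m))
    X = base @ load + rng.normal(size=(n, m))
    y = rng.normal(size=n)
    if causal is not None:
        y = y + effect * (X[:, causal] - X[:, causal].mean()) / X[:, causal].std()
    z = np.array([
        stats.pearsonr(X[:, j], y).statistic * np.sqrt(n) for j in range(m)
    ])
    R = np.corrcoef(X, rowvar=False)
    return FineMapInput([f"v{j}" for j in range(m)], z, R, n=n)


class TestBayesFinemap:
    def test_no_evidence_pips_below_prior(self):
        m = 8
        R = np.eye(m)
        inp = FineMapInput([f"v{j}" for j in range(m)], np.zeros(m), R, n=300)
        pips = bayes_finemap(inp)
        assert (pips <= inp.inclusion_prior + 1e-12).all()

    def test_perfectly_correlated_pair_shares_pip(self):
        # two copies of the same variant with a strong shared signal
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        inp = FineMapInput(["a", "b"], np.array([6.0, 6.0]), R, n=300)
        pips = bayes_finemap(inp)
        assert abs(pips["a"] - pips["b"]) < 1e-6

    def test_strong_single_signal_concentrates(self, rng):
        inp = _random_locus(rng, 10, causal=4, effect=0.5)
        pips = bayes_finemap(inp)
        assert pips.idxmax() == "v4"
        assert pips["v4"] > 0.5

    def test_posterior_sums_to_one(self, rng):
        inp = _random_locus(rng, 9)
        _, post = bayes_finemap(inp, return_posterior=True)
        assert post["posterior"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pip_sum_equals_expected_causal_count(self, rng):
        inp = _random_locus(rng, 7)
        pips, post = bayes_finemap(inp, return_posterior=True)
        expected = sum(len(c) * w for c, w in zip(post["config"],
                                                  post["posterior"]))
        assert pips.sum() == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sss_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        inp = _random_locus(rng, 12, causal=3, effect=0.2)
        ex = bayes_finemap(inp, mode="exhaustive")
        ss = bayes_finemap(inp, mode="sss", seed=seed)
        assert np.max(np.abs(ex.to_numpy() - ss.to_numpy())) < 1e-6

    def test_asymmetric_r_rejected(self):
        R = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            FineMapInput(["a", "b"], np.zeros(2), R, n=100)


class TestConsensus:
    def test_classification_logic(self):
        pairs = [("e1", "s1"), ("e1", "s2"), ("e2", "s3")]
        out = classify_consensus(
            anova_pass={("e1", "s1"): True, ("e1", "s2"): True},
            finemap_pass={("e1", "s1"): True},
            lasso_pass={("e1", "s1"): True},
            pairs=pairs,
        )
        by = out.set_index(["event_id", "str_id"])
        assert by.loc[("e1", "s1"), "strict"] and by.loc[("e1", "s1"), "lenient"]
        assert by.loc[("e1", "s2"), "lenient"] and not by.loc[("e1", "s2"), "strict"]
        assert not by.loc[("e2", "s3"), "lenient"]

    def test_strict_subset_property(self, small_cohort):
        gt = small_cohort["genotypes"]
        cov = small_cohort["covariates"].to_numpy()
        res = run_str_scan(small_cohort["events"], gt, cov)
        snp = run_snp_scan(small_cohort["events"], gt, cov, str_results=res)
        fm = FineMapper(small_cohort["events"], gt, cov, res, snp).fit()
        strict = fm.str_set("strict")
        lenient = fm.str_set("lenient")
        sig = fm.str_set("significant")
        assert strict <= lenient <= sig
        c = fm.consensus
        for method in ("anova_pass", "finemap_pass", "lasso_pass"):
            method_set = set(zip(c.loc[c[method], "event_id"],
                                 c.loc[c[method], "str_id"]))
            assert strict <= method_set <= lenient

    def test_events_without_significant_snp_excluded(self, small_cohort):
        gt = small_cohort["genotypes"]
        cov = small_cohort["covariates"].to_numpy()
        res = run_str_scan(small_cohort["events"], gt, cov)
        snp = run_snp_scan(small_cohort["events"], gt, cov, str_results=res)
        mapper = FineMapper(small_cohort["events"], gt, cov, res, snp)
        eligible = set(mapper.eligible_events())
        assert eligible <= set(res.significant_event_ids())
        assert eligible <= set(snp.significant_event_ids())
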