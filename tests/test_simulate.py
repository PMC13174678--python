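"""Synthetic-data generator: determinism, frequency/LD recovery, null model."""

import numpy as np
import pytest

from splicestr.genotypes import compute_ld
from splicestr.simulate import (
    SimConfig,
    simulate_genotypes,
    simulate_gwas,
    simulate_psi,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig(n_samples=100, n_events=5, snps_per_locus=5, seed=42)
        g1, t1, e1 = simulate_genotypes(cfg)
        g2, t2, e2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert t1.causal_variant == t2.causal_variant
        ev1, c1 = simulate_psi(g1, t1, cfg, e1)
        ev2, c2 = simulate_psi(g2, t2, cfg, e2)
        for a, b in zip(ev1, ev2):
            np.testing.assert_array_equal(a.psi, b.psi)
        assert c1.equals(c2)

    def test_different_seed_differs(self):
        g1, _, _ = simulate_genotypes(SimConfig(n_samples=100, n_events=2,
                                                snps_per_locus=3, seed=1))
        g2, _, _ = simulate_genotypes(SimConfig(n_samples=100, n_events=2,
                                                snps_per_locus=3, seed=2))
        assert not np.array_equal(g1.dosages, g2.dosages)


class TestFrequencyAndLd:
    def test_snp_frequency_recovery_large_n(self):
        cfg = SimConfig(n_samples=10_000, n_events=2, snps_per_locus=8,
                        seed=5, confound_genotypes=False)
        gt, truth, _ = simulate_genotypes(cfg)
        for snp_id, f in truth.snp_freqs.items():
            realized = gt.dosage(snp_id).mean() / 2
            assert realized == pytest.approx(f, abs=0.02)

    def test_zero_ld_target_independent(self):
        cfg = SimConfig(n_samples=10_000, n_events=2, snps_per_locus=5,
                        target_ld_r2=0.0, seed=6, confound_genotypes=False)
        gt, truth, ex = simulate_genotypes(cfg)
        for event_id, (str_id, snp_ids) in ex["event_variants"].items():
            for snp_id in snp_ids:
                rec = compute_ld(gt.dosage(str_id), gt.dosage(snp_id))
                assert rec.r2 < 0.05

    def test_first_snp_hits_ld_target(self):
        cfg = SimConfig(n_samples=10_000, n_events=3, snps_per_locus=3,
                        target_ld_r2=0.5, seed=7, confound_genotypes=False)
        gt, truth, ex = simulate_genotypes(cfg)
        for event_id, (str_id, snp_ids) in ex["event_variants"].items():
            rec = compute_ld(gt.dosage(str_id), gt.dosage(snp_ids[0]))
            assert rec.r2 == pytest.approx(0.5, abs=0.07)

    def test_infeasible_ld_target_names_locus(self):
        cfg = SimConfig(n_samples=50, n_events=1, snps_per_locus=1,
                        target_ld_r2=0.95, seed=8)
        with pytest.raises(ValueError, match="SNP0000_00"):
            simulate_genotypes(cfg)

    def test_str_dosage_is_even_ladder_sum(self):
        # dosages are sums of two per-allele offsets on a 3 bp ladder
        cfg = SimConfig(n_samples=500, n_events=1, snps_per_locus=1, seed=9)
        gt, _, _ = simulate_genotypes(cfg)
        d = gt.dosage("STR0000")
        assert np.all(d % 3 == 0)


class TestPsi:
    def test_psi_bounds(self, small_cohort):
        for ev in small_cohort["events"]:
            ok = ev.psi[~np.isnan(ev.psi)]
            assert ok.min() >= 0 and ok.max() <= 100

    def test_null_model_no_correlation(self):
        cfg = SimConfig(n_samples=2_000, n_events=6, snps_per_locus=2,
                        causal_effect=0.0, covariate_effects=(),
                        confound_genotypes=False, seed=10)
        gt, truth, ex = simulate_genotypes(cfg)
        events, _ = simulate_psi(gt, truth, cfg, ex)
        bound = 3 / np.sqrt(cfg.n_samples)
        for ev in events:
            str_id = ex["event_variants"][ev.id][0]
            ok = ~np.isnan(ev.psi)
            r = np.corrcoef(gt.dosage(str_id)[ok], ev.psi[ok])[0, 1]
            assert abs(r) < bound

    def test_planted_effect_recovered_by_ols(self):
        # standardized effect 0.5 at n=1000, total variance ~ 1
        from splicestr.association import test_association as assoc

        cfg = SimConfig(n_samples=1_000, n_events=8, snps_per_locus=1,
                        causal_effect=0.5, covariate_effects=(),
                        confound_genotypes=False,
                        noise_sd=float(np.sqrt(1 - 0.25)), seed=12)
        gt, truth, ex = simulate_genotypes(cfg)
        events, _ = simulate_psi(gt, truth, cfg, ex)
        betas = []
        for ev in events:
            rec = assoc(gt.dosage(ex["event_variants"][ev.id][0]), ev.psi)
            betas.append(rec.beta)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)


class TestGwas:
    @staticmethod
    def _region(seed=13, n=400, m=12):
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 2, (n, 3)).astype(float)
        X = np.column_stack([(base[:, j % 3] + (rng.random(n) < 0.3)) % 3
                             for j in range(m)]) + rng.integers(0, 2, (n, m))
        return np.clip(X, 0, 2)

    def test_determinism(self):
        cfg = SimConfig()
        X = self._region()
        ids = [f"v{j}" for j in range(X.shape[1])]
        g1 = simulate_gwas(X, ids, 4, 0.05, cfg, seed=3)
        g2 = simulate_gwas(X, ids, 4, 0.05, cfg, seed=3)
        assert g1.equals(g2)

    def test_causal_region_has_signal(self):
        cfg = SimConfig(gwas_n=50_000)
        X = self._region()
        ids = [f"v{j}" for j in range(X.shape[1])]
        g = simulate_gwas(X, ids, 4, 0.05, cfg, seed=3)
        assert g.loc[4, "p"] < 1e-8

    def test_null_region_min_p_not_extreme(self):
        cfg = SimConfig()
        X = self._region()
        ids = [f"v{j}" for j in range(X.shape[1])]
        extreme = 0
        for seed in range(40):
            g = simulate_gwas(X, ids, None, 0.0, cfg, seed=seed)
            extreme += g["p"].min() < 1e-4
        assert extreme <= 4  # most replicates show no spurious hit
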