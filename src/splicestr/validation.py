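"""End-to-end validation experiments on synthetic cohorts.

Each function runs one self-contained experiment — null calibration of the
association scan, power and fine-mapping precision on planted causal STRs,
oracle agreement of the stochastic fine-mapping search, logistic
length-binding recovery, colocalization recovery — and returns plain numbers.
They are used by the acceptance checks and are convenient for benchmarking
parameter choices on simulated data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import SpliceQtlScan, run_snp_scan, run_str_scan, test_association
from .coloc import ColocInput, coloc_abf
from .finemap import FineMapInput, FineMapper, bayes_finemap
from .genotypes import GenotypeTable
from .rbp import length_binding_logistic
from .simulate import SimConfig, simulate_genotypes, simulate_gwas, simulate_psi


# ---------------------------------------------------------------------------
# null calibration


def null_scan(seed: int, n_events: int = 100, n_strs: int = 100,
              n_samples: int = 300):
    """All-by-all STR-event scan on a cohort with no planted effects.

    Events and STR dosages come from the standard generator with
    ``causal_effect=0``; every event is tested against every STR
    (n_events * n_strs tests).  Returns the scan results.
    """
    cfg = SimConfig(n_samples=n_samples, n_events=max(n_events, n_strs),
                    snps_per_locus=0, causal_effect=0.0, covariate_effects=(),
                    confound_genotypes=False, psi_missing_frac=0.0, seed=seed)
    gt, truth, extras = simulate_genotypes(cfg)
    events, _ = simulate_psi(gt, truth, cfg, extras)
    events = events[:n_events]
    strs = gt.subset_kind("STR")
    dosages = strs.dosages[:, :n_strs]
    bare = GenotypeTable(
        strs.samples,
        pd.DataFrame({"chrom": "NA", "start": -1, "end": -1, "kind": "NA",
                      "repeat_unit": "", "ref_length_bp": np.nan},
                     index=list(strs.variants.index[:n_strs])),
        dosages)
    return SpliceQtlScan(events, bare, covariates=None).fit("STR")


def null_calibration(seed: int, n_events: int = 100, n_strs: int = 100):
    """Fraction of null tests with p < 0.05 and the BH discovery count."""
    res = null_scan(seed, n_events=n_events, n_strs=n_strs)
    ok = res.table.loc[res.table["skip_reason"] == ""]
    frac = float((ok["p"] < 0.05).mean())
    n_disc = int(res.table["significant"].sum())
    return {"n_tests": len(ok), "frac_p_lt_05": frac, "n_discoveries": n_disc,
            "ks_p": float(stats.kstest(ok["p"], "uniform").pvalue)}


# ---------------------------------------------------------------------------
# planted power and fine-mapping precision


def planted_scan(seed: int, n_events: int = 200, snps_per_locus: int = 50,
                 n_samples: int = 300, causal_effect: float = 0.3,
                 snp_causal_fraction: float = 0.0, finemap: bool = False):
    """Cohort with one planted causal variant per event; returns a dict with
    the STR power and (optionally) fine-mapping precision per category."""
    cfg = SimConfig(n_samples=n_samples, n_events=n_events,
                    snps_per_locus=snps_per_locus, causal_effect=causal_effect,
                    snp_causal_fraction=snp_causal_fraction, seed=seed)
    gt, truth, extras = simulate_genotypes(cfg)
    events, cov = simulate_psi(gt, truth, cfg, extras)
    cov = cov.to_numpy()
    str_res = run_str_scan(events, gt, cov)
    causal_strs = truth.causal_strs()
    planted = [extras["event_variants"][ev.id][0] for ev in events
               if truth.causal_is_str[ev.id]]
    sig_pairs = set(zip(str_res.significant["event_id"],
                        str_res.significant["variant_id"]))
    detected = sum((f"event{sid[3:]}", sid) in sig_pairs for sid in planted)
    out = {"n_planted_str": len(planted),
           "power": detected / len(planted) if planted else float("nan")}
    if finemap:
        snp_res = run_snp_scan(events, gt, cov, str_results=str_res)
        fm = FineMapper(events, gt, cov, str_res, snp_res, seed=seed).fit()
        for cat in ("significant", "lenient", "strict"):
            pairs = fm.str_set(cat)
            out[f"precision_{cat}"] = (
                float(np.mean([s in causal_strs for _, s in pairs]))
                if pairs else float("nan"))
            out[f"n_{cat}"] = len(pairs)
    return out


def precision_ordering(seeds, n_events: int = 40, snps_per_locus: int = 50,
                       snp_causal_fraction: float = 0.0):
    """Average fine-mapping precision per category over seeds."""
    rows = [planted_scan(s, n_events=n_events, snps_per_locus=snps_per_locus,
                         snp_causal_fraction=snp_causal_fraction, finemap=True)
            for s in seeds]
    df = pd.DataFrame(rows)
    return {f"precision_{c}": float(df[f"precision_{c}"].mean())
            for c in ("significant", "lenient", "strict")}


# ---------------------------------------------------------------------------
# stochastic-search oracle


def random_finemap_locus(seed: int, m: int = 12, n: int = 400):
    """A random LD block with a moderate planted signal for oracle checks."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 3))
    load = rng.normal(size=(3, m))
    X = base @ load + rng.normal(size=(n, m))
    causal = int(rng.integers(m))
    y = rng.normal(size=n) + 0.3 * (X[:, causal] - X[:, causal].mean())
    z = np.array([stats.pearsonr(X[:, j], y).statistic * np.sqrt(n)
                  for j in range(m)])
    R = np.corrcoef(X, rowvar=False)
    return FineMapInput([f"v{j}" for j in range(m)], z, R, n=n)


def sss_oracle_check(seed: int, n_loci: int = 100, m_max: int = 12):
    """Max |PIP difference| between SSS and exhaustive enumeration, and the
    worst posterior-normalization error, over random loci."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    max_norm_err = 0.0
    for i in range(n_loci):
        m = int(rng.integers(6, m_max + 1))
        inp = random_finemap_locus(int(rng.integers(2**31)), m=m)
        ex, post = bayes_finemap(inp, mode="exhaustive", return_posterior=True)
        ss = bayes_finemap(inp, mode="sss", seed=i)
        max_diff = max(max_diff, float(np.abs(ex.to_numpy() - ss.to_numpy()).max()))
        max_norm_err = max(max_norm_err, abs(float(post["posterior"].sum()) - 1.0))
    return {"max_pip_diff": max_diff, "max_norm_err": max_norm_err,
            "n_loci": n_loci}


# ---------------------------------------------------------------------------
# logistic length-binding recovery


def logistic_recovery(seeds, beta0: float = -2.0, beta1: float = 0.3,
                      n_strs: int = 5000):
    """95% CI coverage of the planted length-binding slope across seeds."""
    covered = 0
    estimates = []
    for s in seeds:
        rng = np.random.default_rng([s, 5])
        x = rng.integers(3, 20, n_strs).astype(float)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
        y = rng.random(n_strs) < p
        m = length_binding_logistic(x, y)
        if m.skip_reason:
            continue
        lo, hi = m.beta1 - 1.96 * m.se_beta1, m.beta1 + 1.96 * m.se_beta1
        covered += lo <= beta1 <= hi
        estimates.append(m.beta1)
    return {"coverage": covered / len(seeds), "n_seeds": len(seeds),
            "mean_beta1": float(np.mean(estimates))}


# ---------------------------------------------------------------------------
# colocalization recovery


def coloc_region(seed: int, shared: bool, m: int = 30, n: int = 400,
                 effect: float = 0.4, gwas_n: int = 100_000):
    """Summary statistics for one region: splicing betas from per-SNP OLS on
    a simulated quantitative trait, GWAS statistics from the case-control
    sampler, with a shared or distinct causal variant."""
    rng = np.random.default_rng([seed, 7])
    # LD block of SNP dosages
    hap = (rng.random((2 * n, 4)) < 0.5).astype(float)
    load = rng.random((4, m)) < 0.55
    haps = ((hap @ load) + (rng.random((2 * n, m)) < 0.2)) % 2
    X = haps[0::2] + haps[1::2]
    keep = X.std(axis=0) > 0.05
    X = X[:, keep]
    m = X.shape[1]
    ids = [f"v{j}" for j in range(m)]
    causal_1 = m // 3
    r_to_c1 = np.corrcoef(X, rowvar=False)[causal_1]
    if shared:
        causal_2 = causal_1
    else:
        causal_2 = int(np.argmin(np.abs(r_to_c1)))  # weakly linked variant
    zc1 = (X[:, causal_1] - X[:, causal_1].mean()) / X[:, causal_1].std()
    y = effect * zc1 + rng.normal(size=n)
    beta1, V1 = [], []
    for j in range(m):
        rec = test_association(X[:, j], y, variant_class="SNP")
        beta1.append(rec.beta)
        V1.append(rec.se**2)
    cfg = SimConfig(gwas_n=gwas_n)
    gwas = simulate_gwas(X, ids, causal_2, effect, cfg, seed=seed)
    return ColocInput(ids, np.array(beta1), np.array(V1),
                      gwas["beta"].to_numpy(), gwas["se"].to_numpy() ** 2)


def coloc_recovery(seeds, shared: bool):
    """Fraction of regions where the correct hypothesis wins."""
    h4_high = 0
    h3_best = 0
    worst_norm = 0.0
    for s in seeds:
        post = coloc_abf(coloc_region(s, shared=shared))
        worst_norm = max(worst_norm, abs(sum(post.pp.values()) - 1.0))
        h4_high += post["H4"] > 0.9
        h3_best += post.best == "H3"
    n = len(seeds)
    return {"frac_h4_gt_09": h4_high / n, "frac_h3_best": h3_best / n,
            "max_norm_err": worst_norm, "n_regions": n}
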