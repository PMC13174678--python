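"""Synthetic cohort generator with planted ground truth.

Every downstream stage of the pipeline is testable without access-controlled
data: the generator emits multiallelic STRs in tunable LD with flanking SNPs,
PSI values produced under the same linear model the association engine fits,
length-dependent Bernoulli RBP binding, and GWAS summary statistics with a
shared or distinct causal variant — together with a :class:`TruthSet` naming
every planted effect.

Genotypes
---------
Each splice event owns one genomic region (regions are spaced 1 Mb apart so
association windows never overlap) containing one multiallelic STR and
``snps_per_locus`` biallelic SNPs.  Haplotypes are built from the STR outward:
allele lengths are drawn from the configured ladder, a binary tag T splits the
ladder at its frequency-weighted median, and each SNP copies T with a mixing
weight chosen so the haplotype-level STR-SNP Pearson r^2 matches
``target_ld_r2`` in expectation while preserving the SNP's target allele
frequency.  Diploid samples are formed by random haplotype pairing.  Mild
population structure is induced by tilting STR allele frequencies in the
half of the cohort with positive first confounder.

Phenotypes
----------
PSI is generated on a latent linear scale,

    latent = effect * z(causal dosage) + covariate effects + N(0, noise_sd),

then mapped affinely to [0, 100] (50 + 15 * latent) and clipped; the analysis
model is linear in PSI, so no logit link is used.  Read counts are negative
binomial so the event-level read-support filter is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, StrLocus
from .rbp import RbpPeak
from .splicing import SpliceEvent

DEFAULT_STR_ALLELES = ((12, 0.05), (15, 0.15), (18, 0.30), (21, 0.25),
                       (24, 0.15), (27, 0.10))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``str_alleles`` is a ladder of (length_bp, frequency) pairs at one
    repeat-unit spacing; frequencies must sum to 1.  ``snp_causal_fraction``
    plants the causal effect on a tagging SNP instead of the STR in that
    fraction of events (the STR is then merely linked), which makes
    fine-mapping precision measurable.
    """

    n_samples: int = 300
    n_events: int = 200
    snps_per_locus: int = 50
    str_alleles: tuple = DEFAULT_STR_ALLELES
    repeat_unit: str = "AGC"
    target_ld_r2: float = 0.6
    causal_effect: float = 0.3
    effect_profile: str = "constant"  # or "ramp": signed 0.5x-1.5x spread
    snp_causal_fraction: float = 0.0
    covariate_effects: tuple = (0.3, 0.2)  # the two genotype-linked confounders
    noise_sd: float = 0.9
    confound_genotypes: bool = True
    rbp_intercept: float = -2.0
    rbp_slope: float = 0.3
    gwas_n: int = 50_000
    gwas_case_fraction: float = 0.5
    psi_missing_frac: float = 0.02
    mean_reads: float = 60.0
    seed: int = 0

    def __post_init__(self):
        freqs = [f for _, f in self.str_alleles]
        if abs(sum(freqs) - 1.0) > 1e-8:
            raise ValueError("STR allele frequencies must sum to 1")
        if not 0.0 <= self.target_ld_r2 <= 1.0:
            raise ValueError("target_ld_r2 must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class TruthSet:
    """Planted ground truth: per event, the causal variant and its effect."""

    causal_variant: dict  # event_id -> variant id
    causal_effect: dict  # event_id -> standardized effect
    causal_is_str: dict  # event_id -> bool
    snp_freqs: dict = field(default_factory=dict)  # snp id -> target frequency
    rbp_binding_prob: dict = field(default_factory=dict)  # str id -> p(bound)
    gwas_causal: dict = field(default_factory=dict)  # region -> (variant, shared)

    def causal_strs(self) -> set:
        return {v for e, v in self.causal_variant.items() if self.causal_is_str[e]}


# ---------------------------------------------------------------------------
# genotypes

_REGION_SPAN = 1_000_000
_WINDOW = 100_000


def _event_geometry(i: int, strand: str):
    """Deterministic exon layout for event i inside its 1 Mb region."""
    base = i * _REGION_SPAN + 400_000
    up_exon = (base, base + 150)
    target = (base + 5_000, base + 5_120)
    down_exon = (base + 10_000, base + 10_150)
    return up_exon, target, down_exon


def _str_tag_split(alleles):
    """Binary split of the allele ladder maximizing |corr(length, tag)|."""
    lengths = np.array([a for a, _ in alleles], float)
    freqs = np.array([f for _, f in alleles], float)
    best = None
    for cut in range(1, len(alleles)):
        tag = (np.arange(len(alleles)) >= cut).astype(float)
        p = float(freqs @ tag)
        if not 0 < p < 1:
            continue
        mu_l = freqs @ lengths
        cov = freqs @ ((lengths - mu_l) * (tag - p))
        rho = cov / np.sqrt((freqs @ (lengths - mu_l) ** 2) * p * (1 - p))
        if best is None or abs(rho) > abs(best[2]):
            best = (cut, p, float(rho))
    return best


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, TruthSet, dict]:
    """Generate the cohort genotype table and planted truth.

    Returns ``(genotypes, truth, extras)`` where ``extras`` carries the
    latent confounders (needed by :func:`simulate_psi`) and per-event variant
    ids.  Raises ``ValueError`` naming the locus when the LD target is
    infeasible for the configured allele frequencies.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, n_hap = config.n_samples, 2 * config.n_samples
    lengths = np.array([a for a, _ in config.str_alleles], float)
    freqs = np.array([f for _, f in config.str_alleles], float)
    cut, p_tag, rho0 = _str_tag_split(config.str_alleles)
    confounders = rng.standard_normal((n, 2))
    pop = confounders[:, 0] > 0  # subpopulation indicator for both haplotypes

    ids, metas, cols = [], [], []
    causal_variant, causal_effect, causal_is_str = {}, {}, {}
    snp_freqs: dict = {}
    event_variants: dict = {}
    for i in range(config.n_events):
        lrng = np.random.default_rng([config.seed, 2, i])
        event_id = f"event{i:04d}"
        str_id = f"STR{i:04d}"
        # allele frequency tilt between subpopulations (mild stratification)
        if config.confound_genotypes:
            tilt = 0.15 * (lengths - lengths.mean()) / lengths.std()
            f_pop1 = freqs * np.exp(tilt)
            f_pop1 /= f_pop1.sum()
        else:
            f_pop1 = freqs
        hap_pop = np.repeat(pop, 2)
        allele_idx = np.empty(n_hap, dtype=int)
        n1 = int(hap_pop.sum())
        allele_idx[hap_pop] = lrng.choice(len(freqs), size=n1, p=f_pop1)
        allele_idx[~hap_pop] = lrng.choice(len(freqs), size=n_hap - n1, p=freqs)
        hap_len = lengths[allele_idx]
        tag = (allele_idx >= cut).astype(float)

        up_exon, target, down_exon = _event_geometry(i, "+")
        str_start = target[0] - 2_000
        ref_len = int(lengths[np.argmax(freqs)])
        metas.append({"id": str_id, "chrom": "chrS", "start": str_start,
                      "end": str_start + ref_len, "kind": "STR",
                      "repeat_unit": config.repeat_unit,
                      "ref_length_bp": ref_len})
        str_dos = (hap_len.reshape(n, 2).sum(axis=1) - 2 * ref_len)
        cols.append(str_dos)
        ids.append(str_id)

        snp_ids = []
        for j in range(config.snps_per_locus):
            snp_id = f"SNP{i:04d}_{j:02d}"
            # LD spectrum: the first SNP sits at the configured maximum,
            # the rest spread below it (a realistic decaying LD block)
            r2_j = config.target_ld_r2 * (1.0 if j == 0
                                          else float(lrng.uniform(0.2, 1.0)))
            hap_snp, f = _couple_snp(lrng, tag, p_tag, rho0, r2_j, snp_id)
            snp_dos = hap_snp.reshape(n, 2).sum(axis=1).astype(float)
            pos = str_start - 50_000 + j * 2_000
            metas.append({"id": snp_id, "chrom": "chrS", "start": pos,
                          "end": pos + 1, "kind": "SNP", "repeat_unit": "",
                          "ref_length_bp": np.nan})
            cols.append(snp_dos)
            ids.append(snp_id)
            snp_ids.append(snp_id)
            snp_freqs[snp_id] = f
        event_variants[event_id] = (str_id, snp_ids)
        if lrng.random() < config.snp_causal_fraction:
            causal_variant[event_id] = snp_ids[len(snp_ids) // 2]
            causal_is_str[event_id] = False
        else:
            causal_variant[event_id] = str_id
            causal_is_str[event_id] = True
        if config.effect_profile == "ramp":
            # deterministic per-event spread of signed effect magnitudes,
            # identical across cohorts that share the event layout
            scale = 0.5 + (i / max(config.n_events - 1, 1))
            sign = -1.0 if i % 2 else 1.0
            causal_effect[event_id] = config.causal_effect * scale * sign
        else:
            causal_effect[event_id] = config.causal_effect

    samples = [f"S{k:04d}" for k in range(n)]
    variants = pd.DataFrame(metas).set_index("id")
    table = GenotypeTable(samples, variants, np.column_stack(cols))
    truth = TruthSet(causal_variant, causal_effect, causal_is_str, snp_freqs)
    extras = {"confounders": confounders, "event_variants": event_variants}
    return table, truth, extras


def _feasible(gamma, f, p_tag):
    if not 0.0 < gamma <= 1.0:
        return None
    if gamma == 1.0:
        return 0.0 if abs(f - p_tag) < 1e-12 else None
    f_bg = (f - gamma * p_tag) / (1 - gamma)
    return f_bg if 0.0 <= f_bg <= 1.0 else None


def _couple_snp(rng, tag, p_tag, rho0, target_r2, snp_id):
    """Haplotype SNP alleles tagging the STR at the requested r^2.

    The SNP copies the binary STR tag with a mixing weight gamma and falls
    back to an independent Bernoulli otherwise; gamma and the background
    frequency are solved so that both the target frequency and the target
    haplotype-level r^2 hold in expectation.  The SNP's allele frequency is
    drawn from the feasible region (falling back to the tag frequency when
    the region is tight); a target beyond the ladder's maximum attainable
    r^2 (rho0^2) raises an explicit error naming the variant.
    """
    if target_r2 == 0:
        f = float(rng.uniform(0.15, 0.85))
        return rng.binomial(1, f, size=tag.size).astype(float), f
    rho_goal = np.sqrt(target_r2)
    if rho_goal > abs(rho0) + 1e-12:
        raise ValueError(
            f"{snp_id}: LD target r2={target_r2:.3f} infeasible for the "
            f"configured allele ladder (max attainable r2 = {rho0**2:.3f})")
    sd_t = np.sqrt(p_tag * (1 - p_tag))
    for _ in range(100):
        f = float(rng.uniform(0.15, 0.85))
        gamma = rho_goal * np.sqrt(f * (1 - f)) / (abs(rho0) * sd_t)
        f_bg = _feasible(gamma, f, p_tag)
        if f_bg is not None:
            break
    else:
        f = p_tag
        gamma = rho_goal / abs(rho0)
        f_bg = _feasible(gamma, f, p_tag)
        if f_bg is None:
            raise ValueError(
                f"{snp_id}: LD target r2={target_r2:.3f} infeasible at any "
                f"frequency for the configured allele ladder")
    copy = rng.random(tag.size) < gamma
    background = rng.binomial(1, f_bg, size=tag.size).astype(float)
    return np.where(copy, tag, background).astype(float), f


# ---------------------------------------------------------------------------
# phenotypes


def simulate_psi(genotypes: GenotypeTable, truth: TruthSet, config: SimConfig,
                 extras: dict) -> tuple[list[SpliceEvent], pd.DataFrame]:
    """PSI and read counts under the latent linear model; covariates emitted.

    Returns ``(events, covariates)`` with the covariate DataFrame carrying
    age/sex/read-count analogues (genotype-independent) and the two latent
    confounders.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_samples
    conf = extras["confounders"]
    age = rng.normal(50, 15, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    log_reads = rng.normal(0, 1, size=n)
    cov_fx = np.asarray(config.covariate_effects, float)
    events = []
    etypes = ("SE", "MXE", "A3SS", "A5SS", "RI")
    for i, event_id in enumerate(sorted(truth.causal_variant)):
        erng = np.random.default_rng([config.seed, 4, i])
        dosage = genotypes.dosage(truth.causal_variant[event_id])
        z = (dosage - dosage.mean()) / (dosage.std() or 1.0)
        latent = truth.causal_effect[event_id] * z
        latent = latent + conf[:, :cov_fx.size] @ cov_fx
        latent = latent + erng.normal(0, config.noise_sd, size=n)
        psi = np.clip(50 + 15 * latent, 0, 100)
        miss = erng.random(n) < config.psi_missing_frac
        psi[miss] = np.nan
        reads = erng.negative_binomial(10, 10 / (10 + config.mean_reads), size=n)
        up_exon, target, down_exon = _event_geometry(i, "+")
        strand = "+" if i % 2 == 0 else "-"
        events.append(SpliceEvent(
            id=event_id, event_type=etypes[i % len(etypes)],
            gene=f"gene{i:04d}", chrom="chrS", strand=strand,
            constitutive_exons=[up_exon, down_exon],
            target_exons=[target] if etypes[i % len(etypes)] != "MXE"
            else [target, (target[0] + 300, target[1] + 300)],
            psi=psi, read_counts=reads.astype(float)))
    covariates = pd.DataFrame({
        "age": age, "sex": sex, "log_reads": log_reads,
        "conf1": conf[:, 0], "conf2": conf[:, 1],
    }, index=genotypes.samples)
    return events, covariates


# ---------------------------------------------------------------------------
# RBP peaks


def simulate_rbp_peaks(strs, beta0: float, beta1: float, seed: int = 0,
                       rbp: str = "RBP1", cell_line: str = "K562",
                       strands=None) -> tuple[list[RbpPeak], dict]:
    """Bernoulli binding with probability sigmoid(beta0 + beta1 * copies).

    ``strs`` are StrLocus with ``ref_copies`` supplying the length in
    repeat-unit copies.  Returns (peaks, truth_probs); bound STRs receive one
    stranded peak overlapping their 200 bp window.
    """
    rng = np.random.default_rng([seed, 5])
    peaks, probs = [], {}
    strands = strands or ["+"] * len(strs)
    for s, strand in zip(strs, strands):
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * s.ref_copies)))
        probs[s.id] = float(p)
        if rng.random() < p:
            mid = (s.start + s.end) // 2
            peaks.append(RbpPeak(s.chrom, mid - 30, mid + 30, strand, rbp,
                                 cell_line))
    return peaks, probs


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas(snp_dosages: np.ndarray, snp_ids, causal_idx: int | None,
                  effect: float, config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Case-control GWAS summary statistics for one region.

    Marginal z-scores are drawn from MVN(R z_c, R) where R is the cohort LD
    matrix and z_c places a standardized effect of ``effect`` at
    ``causal_idx`` (None = null region).  Standard errors follow the usual
    case-control approximation 1 / sqrt(2 f (1-f) N s (1-s)).
    """
    rng = np.random.default_rng([seed, 6])
    d = np.asarray(snp_dosages, float)
    R = np.corrcoef(d, rowvar=False)
    m = len(snp_ids)
    zc = np.zeros(m)
    if causal_idx is not None:
        n_eff = config.gwas_n * config.gwas_case_fraction * (1 - config.gwas_case_fraction) * 4
        zc[causal_idx] = effect * np.sqrt(n_eff)
    mean = R @ zc
    L = np.linalg.cholesky(R + 1e-8 * np.eye(m))
    z = mean + L @ rng.standard_normal(m)
    f = d.mean(axis=0) / 2.0
    s = config.gwas_case_fraction
    se = 1.0 / np.sqrt(2 * f * (1 - f) * config.gwas_n * s * (1 - s))
    beta = z * se
    from scipy import stats as _st

    return pd.DataFrame({
        "variant_id": list(snp_ids), "beta": beta, "se": se,
        "p": 2 * _st.norm.sf(np.abs(z)), "n": config.gwas_n,
        "case_fraction": s,
    })
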