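"""Approximate-Bayes-factor colocalization with GWAS summary statistics.

For each shared variant j and each trait, the single-variant approximate
Bayes factor (Wakefield) against the null is

    log ABF_j = 0.5 * log(V_j / (V_j + W)) + z_j^2 * W / (2 * (V_j + W))

with z = beta/sqrt(V), V the squared standard error and W the prior effect
variance.  Under the single-causal-variant assumption per trait, the five
hypotheses are scored by summing ABFs over causal-variant configurations:

    H0 no association; H1/H2 one trait only; H3 two distinct causal
    variants; H4 a shared causal variant,

weighted by priors p1, p2, p12, and normalized to posterior probabilities
PP.H0..PP.H4.  The splicing trait is quantitative with sdY = 1 (effects on
z-scaled PSI), giving W1 = (0.15)^2; the GWAS trait is case-control with
W2 = 0.2^2.

A colocalized splice event must additionally carry a fine-mapped STR in at
least moderate LD (r^2 > 0.1) with the trait's lead GWAS variant, since STRs
themselves have no GWAS summary statistics; passing events are aggregated to
the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def wakefield_abf(beta, V, W) -> float | np.ndarray:
    """Log approximate Bayes factor for a single variant-trait association."""
    beta = np.asarray(beta, float)
    V = np.asarray(V, float)
    if np.any(V <= 0) or W <= 0:
        raise ValueError("variances must be positive")
    z2 = beta * beta / V
    r = W / (V + W)
    out = 0.5 * np.log1p(-r) + 0.5 * z2 * r
    return float(out) if out.ndim == 0 else out


@dataclass
class ColocInput:
    """Aligned summary statistics for the shared variants of one region."""

    variant_ids: list[str]
    beta1: np.ndarray  # splicing trait (quant, sdY = 1)
    V1: np.ndarray
    beta2: np.ndarray  # GWAS trait (case-control)
    V2: np.ndarray
    W1: float = 0.15**2
    W2: float = 0.2**2
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, float)
        self.V1 = np.asarray(self.V1, float)
        self.beta2 = np.asarray(self.beta2, float)
        self.V2 = np.asarray(self.V2, float)
        m = len(self.variant_ids)
        if not (self.beta1.size == self.V1.size == self.beta2.size
                == self.V2.size == m):
            raise ValueError("summary-statistic vectors are not aligned")
        if m < 2:
            raise ValueError("need at least 2 shared variants")


@dataclass
class ColocPosterior:
    pp: dict  # {"H0": ..., ..., "H4": ...}
    n_variants: int

    def __getitem__(self, k):
        return self.pp[k]

    @property
    def best(self) -> str:
        return max(self.pp, key=self.pp.get)


def coloc_abf(inp: ColocInput) -> ColocPosterior:
    """Posterior probabilities of the five colocalization hypotheses."""
    l1 = wakefield_abf(inp.beta1, inp.V1, inp.W1)
    l2 = wakefield_abf(inp.beta2, inp.V2, inp.W2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered distinct pairs (i, j), i != j:
    # logsumexp_i l1_i + logsumexp_j l2_j minus the diagonal
    both = s1 + s2
    s3 = both + np.log1p(-np.exp(s12 - both)) if s12 < both else -np.inf
    logs = np.array([
        0.0,
        np.log(inp.p1) + s1,
        np.log(inp.p2) + s2,
        np.log(inp.p1) + np.log(inp.p2) + s3,
        np.log(inp.p12) + s12,
    ])
    w = np.exp(logs - logsumexp(logs))
    w = w / w.sum()
    return ColocPosterior(dict(zip(["H0", "H1", "H2", "H3", "H4"], map(float, w))),
                          len(inp.variant_ids))


def coloc_abf_bruteforce(inp: ColocInput) -> ColocPosterior:
    """Reference enumeration over all (variant-1, variant-2) configuration
    pairs; quadratic in the number of variants, for validation only."""
    l1 = wakefield_abf(inp.beta1, inp.V1, inp.W1)
    l2 = wakefield_abf(inp.beta2, inp.V2, inp.W2)
    m = len(inp.variant_ids)
    terms = {"H0": [0.0], "H1": [], "H2": [], "H3": [], "H4": []}
    for i in range(m):
        terms["H1"].append(np.log(inp.p1) + l1[i])
        terms["H2"].append(np.log(inp.p2) + l2[i])
        terms["H4"].append(np.log(inp.p12) + l1[i] + l2[i])
        for j in range(m):
            if i != j:
                terms["H3"].append(np.log(inp.p1) + np.log(inp.p2) + l1[i] + l2[j])
    logs = np.array([logsumexp(v) if v else -np.inf for v in
                     (terms["H0"], terms["H1"], terms["H2"], terms["H3"], terms["H4"])])
    w = np.exp(logs - logsumexp(logs))
    w = w / w.sum()
    return ColocPosterior(dict(zip(["H0", "H1", "H2", "H3", "H4"], map(float, w))),
                          m)


@dataclass
class ColocRecord:
    event_id: str
    trait: str
    pp: dict
    lead_variant: str
    str_id: str
    str_lead_r2: float
    gene: str

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def select_test_regions(str_positions: dict, leads: pd.DataFrame,
                        window_bp: int = 1_000_000) -> list[tuple]:
    """Event-trait pairs whose fine-mapped STR lies within ``window_bp`` of a
    lead variant for the trait.

    ``str_positions`` maps (event_id, str_id) -> (chrom, midpoint);
    ``leads`` has columns trait, variant_id, chrom, pos.  Returns
    ``(event_id, str_id, trait, lead_variant_id)`` tuples (the nearest
    in-window lead per trait).
    """
    out = []
    for (event_id, str_id), (chrom, pos) in str_positions.items():
        for trait, grp in leads.groupby("trait"):
            sub = grp.loc[grp["chrom"] == chrom]
            if sub.empty:
                continue
            dist = (sub["pos"] - pos).abs()
            i = dist.idxmin()
            if dist[i] <= window_bp:
                out.append((event_id, str_id, str(trait), str(sub.loc[i, "variant_id"])))
    return out


def gate_and_aggregate(records: list[ColocRecord], pp_h4_min: float = 0.5,
                       r2_min: float = 0.1,
                       strict_pairs: set | None = None) -> pd.DataFrame:
    """Apply the PP.H4 and STR-lead LD gates, then aggregate by gene x trait.

    Records with missing LD are excluded.  Returns one row per (gene, trait)
    with the number of colocalized events and whether any passing event's STR
    is in the strictly fine-mapped set.
    """
    strict_pairs = strict_pairs or set()
    rows = []
    for r in records:
        if np.isnan(r.str_lead_r2):
            continue
        if r.pp_h4 > pp_h4_min and r.str_lead_r2 > r2_min:
            rows.append({
                "gene": r.gene, "trait": r.trait, "event_id": r.event_id,
                "str_id": r.str_id,
                "strict": (r.event_id, r.str_id) in strict_pairs,
            })
    if not rows:
        return pd.DataFrame(columns=["gene", "trait", "n_events", "any_strict"])
    df = pd.DataFrame(rows)
    agg = df.groupby(["gene", "trait"]).agg(
        n_events=("event_id", "nunique"), any_strict=("strict", "any")
    ).reset_index()
    return agg
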