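"""STR/SNP - splicing association engine.

The model is ordinary least squares on z-scaled variables:

    Y ~ b0 * X + b1 * C + e

with Y the per-sample PSI of one splice event, X the dosage of one variant
(STR: signed bp from reference; SNP: 0/1/2), and C covariates (age, sex, read
counts, genotype PCs, expression factors).  Per pair, samples with missing
genotype or PSI are dropped, STR dosage classes observed in fewer than three
samples are removed, and Y, X and every covariate column are z-scaled on the
retained samples; z-scaling both sides forces the variant effect size into
[-1, 1].  Two-tailed p-values come from the t statistic of b0.

Discovery control: a single label-shuffled permutation per pair provides a
calibration control, and Benjamini-Hochberg FDR is applied within each splice
type (SE/MXE/A3SS/A5SS/RI) at 5%.

:class:`SpliceQtlScan` wraps the scan as a model object whose :meth:`fit`
returns a :class:`SpliceQtlScanResults` carrying the per-pair records.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from .genotypes import GenotypeTable, filter_str_genotypes
from .splicing import candidate_pairs


def zscale(v: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (denominator n-1).

    Raises ``ValueError`` on constant or <2-element input.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to z-scale")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant vector cannot be z-scaled")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class AssociationRecord:
    variant_id: str
    event_id: str
    variant_class: str  # "STR" / "SNP"
    beta: float
    se: float
    p: float
    n: int
    q: float = np.nan
    permuted_p: float = np.nan
    skip_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.skip_reason is None


def _ols_beta(y: np.ndarray, x: np.ndarray, C: np.ndarray | None):
    """OLS of y on [1, x, C]; returns (beta_x, se_x, two-tailed p, n).

    Raises ``ValueError`` for a rank-deficient design.
    """
    n = y.size
    cols = [np.ones(n), x]
    if C is not None and C.size:
        cols.extend(C.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise ValueError("more predictors than samples")
    q, r = np.linalg.qr(X)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        raise ValueError("rank-deficient design")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    rinv = np.linalg.inv(r)
    xtx_inv_diag = np.sum(rinv * rinv, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag[1])
    if se == 0:
        p = 0.0
        t = np.inf
    else:
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(se), float(p), n


def test_association(dosage, psi, covariates=None, variant_id="x", event_id="y",
                     variant_class="STR", min_unique: int = 3) -> AssociationRecord:
    """One variant-event association test.

    Drops samples with missing dosage or PSI; for STRs applies the
    rare-genotype-class filter (classes with < 3 samples removed, locus
    skipped if < 3 unique dosages remain); z-scales Y, X and covariates on
    the retained samples; fits OLS and returns the variant term's
    standardized beta, SE, two-tailed p and n.  Degenerate inputs yield a
    record with a ``skip_reason`` instead of an exception.
    """
    dosage = np.asarray(dosage, dtype=float)
    psi = np.asarray(psi, dtype=float)
    keep = ~np.isnan(dosage) & ~np.isnan(psi)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        keep &= ~np.isnan(covariates).any(axis=1)

    def _skip(reason):
        return AssociationRecord(variant_id, event_id, variant_class,
                                 np.nan, np.nan, np.nan, int(keep.sum()),
                                 skip_reason=reason)

    if variant_class == "STR":
        class_keep, excluded = filter_str_genotypes(np.where(keep, dosage, np.nan),
                                                    min_unique=min_unique)
        keep &= class_keep
        if excluded:
            return _skip("fewer_than_%d_unique_genotypes" % min_unique)
    x, y = dosage[keep], psi[keep]
    if np.unique(x).size < 2:
        return _skip("constant_genotype")
    if y.size < 2 or y.std(ddof=1) == 0:
        return _skip("constant_phenotype")
    C = None
    if covariates is not None:
        C = covariates[keep]
        sd = C.std(axis=0, ddof=1)
        C = C[:, sd > 0]  # constant covariates carry no information after centering
        if C.size:
            C = (C - C.mean(axis=0)) / C.std(axis=0, ddof=1)
    try:
        beta, se, p, n = _ols_beta(zscale(y), zscale(x), C)
    except ValueError as err:
        return _skip(str(err).replace(" ", "_"))
    return AssociationRecord(variant_id, event_id, variant_class, beta, se, p, n)


def permutation_control(dosage, psi, covariates=None, seed: int = 0,
                        permutation=None, **kwargs) -> AssociationRecord:
    """Label-shuffled control: permute the genotype vector's sample identifiers
    once (drawn from ``seed`` unless an explicit ``permutation`` is given)
    and re-test.  Under exchangeability the resulting p-values are uniform
    regardless of any true effect."""
    dosage = np.asarray(dosage, dtype=float)
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(dosage.size)
    return test_association(dosage[permutation], psi, covariates, **kwargs)


def bh_fdr(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags at ``alpha``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q = fdrcorrection(p, alpha=alpha)
    return q, reject


def expression_factors(psi_matrix: np.ndarray, k: int = 20) -> np.ndarray:
    """Latent expression-structure covariates: top-k PCs of the z-scaled
    event x sample PSI matrix (a PCA stand-in for factor-analysis approaches).

    Missing PSI values are mean-imputed for factor extraction only.  Returns
    an (n_samples, k) score matrix.
    """
    m = np.asarray(psi_matrix, dtype=float).copy()
    if k == 0:
        return np.empty((m.shape[1], 0))
    row_mean = np.nanmean(m, axis=1, keepdims=True)
    m = np.where(np.isnan(m), row_mean, m)
    sd = m.std(axis=1, ddof=1)
    m = m[sd > 0]
    m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=1, keepdims=True)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    if np.sum(s > 1e-10) < k:
        raise ValueError(f"requested {k} factors but rank is {int(np.sum(s > 1e-10))}")
    scores = vt[:k].T * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    return scores


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "variant_id": r.variant_id, "event_id": r.event_id,
            "variant_class": r.variant_class, "beta": r.beta, "se": r.se,
            "p": r.p, "q": r.q, "n": r.n, "permuted_p": r.permuted_p,
            "skip_reason": r.skip_reason or "",
        } for r in records]
    )


class SpliceQtlScan:
    """Association scan model: all candidate STR-event (or SNP-event) pairs.

    Parameters
    ----------
    events : sequence of SpliceEvent
        Filtered splice events with per-sample PSI aligned to ``genotypes``.
    genotypes : GenotypeTable
    covariates : ndarray (n_samples, n_cov) or None
    window_bp : association window around the constitutive exons
    event_types : mapping event_id -> splice type, used as the FDR grouping key
        (derived from the events themselves).
    """

    def __init__(self, events, genotypes: GenotypeTable, covariates=None,
                 window_bp: int = 100_000, fdr_alpha: float = 0.05,
                 permute: bool = False, seed: int = 0):
        self.events = list(events)
        self.genotypes = genotypes
        self.covariates = None if covariates is None else np.asarray(covariates, float)
        self.window_bp = window_bp
        self.fdr_alpha = fdr_alpha
        self.permute = permute
        self.seed = seed
        self._events_by_id = {ev.id: ev for ev in self.events}

    def fit(self, variant_class: str = "STR", variant_loci=None,
            restrict_event_ids=None) -> "SpliceQtlScanResults":
        """Run the scan.  ``variant_loci`` defaults to all loci of
        ``variant_class`` present in the genotype table; ``restrict_event_ids``
        limits the scan (used for the SNP pass over STR-significant events)."""
        gt = self.genotypes
        meta = gt.variants
        events = self.events
        if restrict_event_ids is not None:
            restrict = set(restrict_event_ids)
            events = [ev for ev in events if ev.id in restrict]
        if variant_loci is None and (meta["kind"] == "NA").all():
            # bare dosage matrix without positions: every pair is a candidate
            pairs = [(ev.id, vid) for ev in events for vid in meta.index]
        else:
            from .genotypes import SnpLocus, StrLocus
            if variant_loci is None:
                variant_loci = []
                for vid, row in meta.iterrows():
                    if row["kind"] != variant_class:
                        continue
                    if variant_class == "STR":
                        variant_loci.append(
                            StrLocus(vid, row["chrom"], int(row["start"]),
                                     int(row["end"]), row["repeat_unit"],
                                     int(row["ref_length_bp"])))
                    else:
                        variant_loci.append(
                            SnpLocus(vid, row["chrom"], int(row["start"]),
                                     "N", "N"))
            if variant_class == "STR":
                pairs = candidate_pairs(events, variant_loci, self.window_bp)
            else:
                # SNPs share the window geometry: point intervals
                fake = [StrLocus(v.id, v.chrom, v.pos, v.pos + 1, "A", 1)
                        for v in variant_loci]
                pairs = candidate_pairs(events, fake, self.window_bp)
        records = []
        for event_id, vid in pairs:
            ev = self._events_by_id[event_id]
            dosage = gt.dosage(vid)
            rec = test_association(dosage, ev.psi, self.covariates,
                                   variant_id=vid, event_id=event_id,
                                   variant_class=variant_class)
            if self.permute and rec.ok:
                key = f"{event_id}\t{vid}\t{self.seed}".encode()
                pair_seed = zlib.crc32(key) & 0x7FFFFFFF
                ctrl = permutation_control(dosage, ev.psi, self.covariates,
                                           seed=pair_seed, variant_id=vid,
                                           event_id=event_id,
                                           variant_class=variant_class)
                rec = AssociationRecord(vid, event_id, variant_class, rec.beta,
                                        rec.se, rec.p, rec.n, permuted_p=ctrl.p)
            records.append(rec)
        table = _records_to_frame(records)
        table = self._apply_grouped_fdr(table)
        return SpliceQtlScanResults(self, table, variant_class)

    def _apply_grouped_fdr(self, table: pd.DataFrame) -> pd.DataFrame:
        if table.empty:
            table["event_type"] = pd.Series(dtype=str)
            table["significant"] = pd.Series(dtype=bool)
            return table
        etype = table["event_id"].map(lambda e: self._events_by_id[e].event_type)
        table = table.assign(event_type=etype, significant=False)
        for _, idx in table.groupby("event_type").groups.items():
            sub = table.loc[idx]
            ok = sub["skip_reason"] == ""
            if ok.sum() == 0:
                continue
            q, rej = bh_fdr(sub.loc[ok, "p"].to_numpy(), self.fdr_alpha)
            table.loc[sub.index[ok], "q"] = q
            table.loc[sub.index[ok], "significant"] = rej
        return table


class SpliceQtlScanResults:
    """Per-pair association records plus significance flags.

    ``table`` columns: variant_id, event_id, variant_class, beta, se, p, q, n,
    permuted_p, skip_reason, event_type, significant.
    """

    def __init__(self, model: SpliceQtlScan, table: pd.DataFrame, variant_class: str):
        self.model = model
        self.table = table
        self.variant_class = variant_class

    @property
    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]

    def significant_event_ids(self) -> list[str]:
        return sorted(self.significant["event_id"].unique())

    def summary(self) -> pd.DataFrame:
        """Per-splice-type tallies of tests, skips and discoveries."""
        t = self.table
        rows = []
        for etype, sub in t.groupby("event_type"):
            rows.append({
                "event_type": etype,
                "n_tests": len(sub),
                "n_skipped": int((sub["skip_reason"] != "").sum()),
                "n_significant": int(sub["significant"].sum()),
            })
        return pd.DataFrame(rows)


def run_str_scan(events, genotypes, covariates=None, **kwargs) -> SpliceQtlScanResults:
    """All candidate STR-event pairs tested; BH FDR 5% within each splice type."""
    return SpliceQtlScan(events, genotypes, covariates, **kwargs).fit("STR")


def run_snp_scan(events, genotypes, covariates=None, str_results=None,
                 **kwargs) -> SpliceQtlScanResults:
    """SNP scan restricted to events with at least one significant STR."""
    restrict = None
    if str_results is not None:
        restrict = str_results.significant_event_ids()
    scan = SpliceQtlScan(events, genotypes, covariates, **kwargs)
    return scan.fit("SNP", restrict_event_ids=restrict)
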