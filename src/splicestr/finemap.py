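"""Three orthogonal fine-mapping procedures and their consensus.

For each splice event with both a significant STR and a significant SNP, three
independent lines of evidence are computed for every significant STR-event
pair:

1. **Nested ANOVA** — does the STR explain covariate-residualized PSI (Y*)
   beyond the event's best SNP?  ``Y* ~ best_SNP`` vs ``Y* ~ best_SNP + STR``,
   F-test on the added term, BH FDR at 10% across all retained pairs.  Before
   testing, STRs whose effect size differs significantly (two-tailed Z) from
   the event's strongest-p STR are dropped, removing near-null hangers-on.
2. **Lasso selection** — L1-penalized regression of Y* on all nominally
   associated variants (p < 0.05), penalty chosen by 5-fold cross-validation;
   the STR with the largest absolute coefficient among *all* variants is
   selected (none, if a SNP has the largest coefficient).
3. **Bayesian fine-mapping** — a summary-statistic configuration model: each
   causal configuration C (|C| <= K) receives a Bayes factor from the
   multivariate-normal model of the z-scores given LD, with prior effect SD
   ``s`` at causal positions; PIP_j sums the normalized posterior over
   configurations containing j.  Exhaustive enumeration for small loci;
   shotgun stochastic search (with a completeness short-circuit) otherwise.

A pair is *leniently* fine-mapped if it passes at least one method and
*strictly* fine-mapped if it passes all three.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from .association import bh_fdr, zscale
from .genotypes import GenotypeTable, ld_matrix


# ---------------------------------------------------------------------------
# residualization and the effect-size equivalence filter


def residualize_phenotype(psi: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of PSI on the covariates (intercept always included)."""
    psi = np.asarray(psi, dtype=float)
    n = psi.size
    if covariates is None or np.asarray(covariates).size == 0:
        return psi - psi.mean()
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        sd = C[:, 1:].std(axis=0)
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"rank-deficient covariates (constant columns: {bad})")
    beta, *_ = np.linalg.lstsq(C, psi, rcond=None)
    return psi - C @ beta


def equivalence_filter(betas, ses, ps, alpha: float = 0.05) -> np.ndarray:
    """Keep STRs whose effect is statistically indistinguishable from the
    event's strongest-p STR.

    Z = (beta_i - beta_best) / sqrt(se_i^2 + se_best^2), two-tailed; records
    with p >= ``alpha`` are retained.  The strongest-p STR is always retained.
    Returns a boolean mask.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    ps = np.asarray(ps, float)
    best = int(np.argmin(ps))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (betas - betas[best]) / np.sqrt(ses**2 + ses[best] ** 2)
    pz = 2.0 * stats.norm.sf(np.abs(z))
    keep = pz > alpha
    keep[best] = True
    return keep


# ---------------------------------------------------------------------------
# nested ANOVA


@dataclass(frozen=True)
class AnovaRecord:
    event_id: str
    str_id: str
    best_snp_id: str
    f_stat: float
    p: float
    collinear: bool = False
    q: float = np.nan


def anova_str_test(y_star, best_snp_dosage, str_dosage, event_id="event",
                   str_id="str", best_snp_id="snp") -> AnovaRecord:
    """F-test of the STR term added to the best-SNP model of residual PSI.

    Both dosages are z-scaled on the analysis samples.  If the STR is
    (numerically) an exact linear copy of the best SNP the added term explains
    nothing: p is set to 1 and the record flagged collinear.
    """
    y = np.asarray(y_star, float)
    snp = zscale(np.asarray(best_snp_dosage, float))
    strv = zscale(np.asarray(str_dosage, float))
    r = float(np.corrcoef(snp, strv)[0, 1])
    if abs(r) > 1 - 1e-10:
        return AnovaRecord(event_id, str_id, best_snp_id, 0.0, 1.0, collinear=True)
    n = y.size
    X0 = np.column_stack([np.ones(n), snp])
    X1 = np.column_stack([np.ones(n), snp, strv])
    rss0 = _rss(y, X0)
    rss1 = _rss(y, X1)
    df1 = n - X1.shape[1]
    f = (rss0 - rss1) / (rss1 / df1)
    p = float(stats.f.sf(f, 1, df1))
    return AnovaRecord(event_id, str_id, best_snp_id, float(f), p)


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# Lasso


@dataclass
class LassoResult:
    event_id: str
    coefficients: pd.Series  # indexed by variant id
    selected_alpha: float
    selected_str: str | None  # STR with largest |coef| among ALL variants, or None


def lasso_select(y_star, dosage_matrix: np.ndarray, variant_ids, str_flags,
                 event_id="event", cv: int = 5, max_iter: int = 5000,
                 seed: int = 0) -> LassoResult:
    """CV-tuned L1 regression of residual PSI on all candidate variants.

    ``str_flags`` marks which columns are STRs.  The variant with the largest
    absolute coefficient decides selection: an STR wins only if it beats every
    SNP.  Raises ``ValueError`` when n is too small for ``cv`` folds.
    """
    y = zscale(np.asarray(y_star, float))
    X = np.asarray(dosage_matrix, float)
    if y.size < cv:
        raise ValueError(f"n={y.size} too small for {cv}-fold CV")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    X = (X - X.mean(axis=0)) / sd
    cv_model = LassoCV(cv=cv, max_iter=max_iter, alphas=30, random_state=seed)
    with np.errstate(all="ignore"):
        cv_model.fit(X, y)
    model = Lasso(alpha=cv_model.alpha_, max_iter=max_iter)
    model.fit(X, y)
    coefs = pd.Series(model.coef_, index=list(variant_ids))
    str_flags = np.asarray(str_flags, bool)
    order = np.argsort(-np.abs(model.coef_), kind="stable")
    selected = None
    if order.size and str_flags[order[0]] and np.abs(model.coef_[order[0]]) > 0:
        selected = list(variant_ids)[order[0]]
    return LassoResult(event_id, coefs, float(cv_model.alpha_), selected)


# ---------------------------------------------------------------------------
# Bayesian configuration fine-mapping


@dataclass
class FineMapInput:
    """Summary statistics and LD for one locus.

    z : per-variant beta/SE
    R : LD correlation matrix (symmetric, unit diagonal); a small ridge is
        added before use to guarantee positive definiteness
    n : analysis sample size (converts the standardized-effect prior SD to
        the z-score scale: the z-scale prior variance is n * s^2)
    prior_sd : prior SD of standardized causal effects (default 0.05)
    max_causal : K, the maximum number of causal variants per configuration
    inclusion_prior : per-variant prior inclusion probability (default 1/m)
    """

    variant_ids: list[str]
    z: np.ndarray
    R: np.ndarray
    n: int
    prior_sd: float = 0.05
    max_causal: int = 3
    inclusion_prior: float | None = None
    ridge: float = 1e-6

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.R = np.asarray(self.R, float)
        m = self.z.size
        if self.R.shape != (m, m):
            raise ValueError("z and R are not aligned")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R is not symmetric")
        if self.inclusion_prior is None:
            self.inclusion_prior = 1.0 / m
        self.R = self.R + self.ridge * np.eye(m)
        try:
            np.linalg.cholesky(self.R)
        except np.linalg.LinAlgError as err:
            raise ValueError("LD matrix not positive definite after ridge") from err


def _log_bf_batch(z: np.ndarray, R: np.ndarray, configs: np.ndarray, sz2: float) -> np.ndarray:
    """Log Bayes factors for a batch of same-size configurations.

    ``configs`` is (B, k) variant indices.  BF(C) compares
    N(z_C; 0, R_CC + sz2 * R_CC R_CC) against the null N(z_C; 0, R_CC).
    """
    Rcc = R[configs[:, :, None], configs[:, None, :]]  # (B, k, k)
    zc = z[configs]  # (B, k)
    A = Rcc + sz2 * (Rcc @ Rcc)
    sign_a, logdet_a = np.linalg.slogdet(A)
    sign_r, logdet_r = np.linalg.slogdet(Rcc)
    quad_a = np.einsum("bi,bi->b", zc, np.linalg.solve(A, zc[..., None])[..., 0])
    quad_r = np.einsum("bi,bi->b", zc, np.linalg.solve(Rcc, zc[..., None])[..., 0])
    return -0.5 * (logdet_a - logdet_r) - 0.5 * (quad_a - quad_r)


class _ConfigPosterior:
    """Accumulates log posterior mass per configuration (frozenset of indices)."""

    def __init__(self, inp: FineMapInput):
        self.inp = inp
        self.sz2 = inp.n * inp.prior_sd**2
        m = inp.z.size
        pi = inp.inclusion_prior
        self._log_pi = np.log(pi)
        self._log_1mpi = np.log1p(-pi)
        self.m = m
        self.log_post: dict[frozenset, float] = {frozenset(): m * self._log_1mpi}

    def evaluate(self, configs: list[tuple]) -> None:
        new = [c for c in configs if frozenset(c) not in self.log_post]
        if not new:
            return
        by_size: dict[int, list[tuple]] = {}
        for c in new:
            by_size.setdefault(len(c), []).append(tuple(sorted(c)))
        for k, group in by_size.items():
            idx = np.array(group, dtype=int)
            lbf = _log_bf_batch(self.inp.z, self.inp.R, idx, self.sz2)
            lprior = k * self._log_pi + (self.m - k) * self._log_1mpi
            for c, v in zip(group, lbf):
                self.log_post[frozenset(c)] = float(v) + lprior

    def pips(self) -> np.ndarray:
        keys = list(self.log_post)
        vals = np.array([self.log_post[c] for c in keys])
        w = np.exp(vals - vals.max())
        w /= w.sum()
        pip = np.zeros(self.m)
        for c, wi in zip(keys, w):
            for j in c:
                pip[j] += wi
        return pip

    def posterior_table(self) -> pd.DataFrame:
        keys = list(self.log_post)
        vals = np.array([self.log_post[c] for c in keys])
        w = np.exp(vals - vals.max())
        w /= w.sum()
        return pd.DataFrame({"config": [tuple(sorted(c)) for c in keys],
                             "posterior": w})


def _n_configs(m: int, k_max: int) -> int:
    from math import comb

    return sum(comb(m, k) for k in range(0, k_max + 1))


def bayes_finemap(inp: FineMapInput, mode: str = "exhaustive", seed: int = 0,
                  n_iter: int = 400, patience: int = 150,
                  return_posterior: bool = False):
    """Posterior inclusion probabilities under the configuration model.

    ``mode='exhaustive'`` enumerates every configuration with |C| <= K.
    ``mode='sss'`` runs a shotgun stochastic search: random restarts followed
    by neighborhood moves (add/drop/swap), caching every evaluated
    configuration; it stops early once all configurations have been evaluated,
    so on small loci it reproduces the exhaustive posterior exactly.

    Returns a pandas Series of PIPs indexed by variant id (and the
    configuration posterior table if ``return_posterior``).
    """
    post = _ConfigPosterior(inp)
    m, K = inp.z.size, inp.max_causal
    total = _n_configs(m, K)
    if mode == "exhaustive":
        return _exhaustive(inp, return_posterior)
    elif mode == "sss":
        rng = np.random.default_rng(seed)
        current: tuple = ()
        stall = 0
        it = -1
        while True:
            it += 1
            if len(post.log_post) >= total or it >= max(n_iter, 50 * patience):
                break
            if it == 0 or rng.random() < 0.2 or not current:
                k = int(rng.integers(1, K + 1))
                current = tuple(sorted(rng.choice(m, size=min(k, m), replace=False)))
            neighbors = _neighborhood(current, m, K)
            before = len(post.log_post)
            post.evaluate(neighbors + [current])
            if len(post.log_post) == before:
                stall += 1
                if stall > patience:
                    break
            else:
                stall = 0
            lp = np.array([post.log_post[frozenset(c)] for c in neighbors])
            w = np.exp(lp - lp.max())
            current = neighbors[int(rng.choice(len(neighbors), p=w / w.sum()))]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pips = pd.Series(post.pips(), index=inp.variant_ids)
    if return_posterior:
        return pips, post.posterior_table()
    return pips


def _exhaustive(inp: FineMapInput, return_posterior: bool):
    """Vectorized full enumeration of configurations with |C| <= K."""
    m, K = inp.z.size, inp.max_causal
    sz2 = inp.n * inp.prior_sd**2
    pi = inp.inclusion_prior
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    blocks = []  # (index array (B, k), log posterior (B,))
    null_lp = m * log_1mpi
    for k in range(1, K + 1):
        idx = np.array(list(itertools.combinations(range(m), k)), dtype=int)
        if idx.size == 0:
            continue
        lbf = _log_bf_batch(inp.z, inp.R, idx, sz2)
        blocks.append((idx, lbf + k * log_pi + (m - k) * log_1mpi))
    vals = np.concatenate([[null_lp]] + [lp for _, lp in blocks])
    top = vals.max()
    w = np.exp(vals - top)
    w /= w.sum()
    pip = np.zeros(m)
    offset = 1
    for idx, lp in blocks:
        wb = w[offset:offset + len(lp)]
        np.add.at(pip, idx.ravel(), np.repeat(wb, idx.shape[1]))
        offset += len(lp)
    pips = pd.Series(pip, index=inp.variant_ids)
    if return_posterior:
        configs = [()] + [tuple(row) for idx, _ in blocks for row in idx]
        table = pd.DataFrame({"config": configs, "posterior": w})
        return pips, table
    return pips


def _neighborhood(config: tuple, m: int, k_max: int) -> list[tuple]:
    cset = set(config)
    out = []
    if len(config) < k_max:
        out.extend(tuple(sorted(cset | {j})) for j in range(m) if j not in cset)
    for i in cset:
        rest = cset - {i}
        out.append(tuple(sorted(rest)))
        out.extend(tuple(sorted(rest | {j})) for j in range(m) if j not in cset)
    return [c for c in out if c]  # the empty config is always cached


# ---------------------------------------------------------------------------
# consensus


@dataclass(frozen=True)
class FineMapConsensusRecord:
    event_id: str
    str_id: str
    anova_pass: bool
    finemap_pass: bool
    lasso_pass: bool

    @property
    def lenient(self) -> bool:
        return self.anova_pass or self.finemap_pass or self.lasso_pass

    @property
    def strict(self) -> bool:
        return self.anova_pass and self.finemap_pass and self.lasso_pass


def classify_consensus(anova_pass: dict, finemap_pass: dict, lasso_pass: dict,
                       pairs) -> pd.DataFrame:
    """Combine per-pair verdicts of the three methods.

    Each ``*_pass`` maps (event_id, str_id) -> bool; ``pairs`` enumerates the
    significant STR-event pairs under consideration.
    """
    rows = []
    for event_id, str_id in pairs:
        key = (event_id, str_id)
        rec = FineMapConsensusRecord(
            event_id, str_id,
            bool(anova_pass.get(key, False)),
            bool(finemap_pass.get(key, False)),
            bool(lasso_pass.get(key, False)),
        )
        rows.append({
            "event_id": event_id, "str_id": str_id,
            "anova_pass": rec.anova_pass, "finemap_pass": rec.finemap_pass,
            "lasso_pass": rec.lasso_pass, "lenient": rec.lenient,
            "strict": rec.strict,
        })
    return pd.DataFrame(rows, columns=["event_id", "str_id", "anova_pass",
                                       "finemap_pass", "lasso_pass",
                                       "lenient", "strict"])


# ---------------------------------------------------------------------------
# orchestration: FineMapper model / FineMapResults


class FineMapper:
    """Fine-mapping study over the significant STR-event pairs of a scan.

    Parameters
    ----------
    events : the splice events (with PSI) used in the association scan
    genotypes : GenotypeTable
    covariates : covariate matrix used in the scan (residualized out of PSI)
    str_results, snp_results : SpliceQtlScanResults from the two scan passes
    anova_fdr : FDR threshold for the ANOVA verdict (default 10%)
    pip_threshold : PIP cut for the Bayesian verdict (default 0.5)
    nominal_p : candidate-variant inclusion threshold for Lasso / Bayesian
    anova_fdr_scope : 'joint' (default) or 'per_type'
    """

    def __init__(self, events, genotypes: GenotypeTable, covariates,
                 str_results, snp_results, anova_fdr: float = 0.10,
                 pip_threshold: float = 0.5, nominal_p: float = 0.05,
                 prior_sd: float = 0.05, max_causal: int = 3,
                 mode: str = "exhaustive", seed: int = 0,
                 anova_fdr_scope: str = "joint"):
        self.events = {ev.id: ev for ev in events}
        self.genotypes = genotypes
        self.covariates = None if covariates is None else np.asarray(covariates, float)
        self.str_results = str_results
        self.snp_results = snp_results
        self.anova_fdr = anova_fdr
        self.pip_threshold = pip_threshold
        self.nominal_p = nominal_p
        self.prior_sd = prior_sd
        self.max_causal = max_causal
        self.mode = mode
        self.seed = seed
        self.anova_fdr_scope = anova_fdr_scope

    def eligible_events(self) -> list[str]:
        """Events with >= 1 significant STR AND >= 1 significant SNP.

        Events whose only significant variants are STRs are excluded from
        fine-mapping (no SNP to compete against).
        """
        str_ev = set(self.str_results.significant_event_ids())
        snp_ev = set(self.snp_results.significant_event_ids())
        return sorted(str_ev & snp_ev)

    def fit(self) -> "FineMapResults":
        str_sig = self.str_results.significant
        snp_tab = self.snp_results.table
        anova_records: list[AnovaRecord] = []
        lasso_pass: dict = {}
        finemap_pass: dict = {}
        pip_values: dict = {}
        pairs: list[tuple] = []
        equivalence_kept: dict = {}
        for event_id in self.eligible_events():
            ev = self.events[event_id]
            strs = str_sig.loc[str_sig["event_id"] == event_id]
            pairs.extend((event_id, sid) for sid in strs["variant_id"])
            # effect-size equivalence filter against the strongest-p STR
            keep = equivalence_filter(strs["beta"].to_numpy(),
                                      strs["se"].to_numpy(),
                                      strs["p"].to_numpy())
            kept_strs = strs.loc[keep]
            for sid in kept_strs["variant_id"]:
                equivalence_kept[(event_id, sid)] = True
            # best SNP for the event: strongest p, ties by coordinate then id
            snps = snp_tab.loc[(snp_tab["event_id"] == event_id)
                               & (snp_tab["skip_reason"] == "")]
            if snps.empty:
                continue
            best_snp_id = self._best_snp(snps)
            y_star, sample_keep = self._residual(ev)
            best_snp_dos = self.genotypes.dosage(best_snp_id)[sample_keep]
            for sid in kept_strs["variant_id"]:
                strd = self.genotypes.dosage(sid)[sample_keep]
                ok = ~np.isnan(strd) & ~np.isnan(best_snp_dos) & ~np.isnan(y_star)
                rec = anova_str_test(y_star[ok], best_snp_dos[ok], strd[ok],
                                     event_id=event_id, str_id=sid,
                                     best_snp_id=best_snp_id)
                anova_records.append(rec)
            # Lasso + Bayesian fine-mapping over nominal candidates
            cand = self._candidates(event_id)
            if cand is None:
                continue
            vids, dos, flags, z, betas, ses = cand
            dos_keep = dos[sample_keep]
            ok = ~np.isnan(dos_keep).any(axis=1) & ~np.isnan(y_star)
            try:
                las = lasso_select(y_star[ok], dos_keep[ok], vids, flags,
                                   event_id=event_id, seed=self.seed)
                if las.selected_str is not None:
                    lasso_pass[(event_id, las.selected_str)] = True
            except ValueError:
                pass
            try:
                R = ld_matrix(dos_keep[ok])
                inp = FineMapInput(vids, z, R, n=int(ok.sum()),
                                   prior_sd=self.prior_sd,
                                   max_causal=self.max_causal)
                pips = bayes_finemap(inp, mode=self.mode, seed=self.seed)
                for vid, flag in zip(vids, flags):
                    if flag:
                        pip_values[(event_id, vid)] = float(pips[vid])
                        if pips[vid] >= self.pip_threshold:
                            finemap_pass[(event_id, vid)] = True
            except ValueError:
                pass
        anova_table = self._anova_fdr(anova_records)
        anova_pass = {
            (r.event_id, r.str_id): bool(q < self.anova_fdr)
            for r, q in zip(anova_records, anova_table["q"])
        }
        consensus = classify_consensus(anova_pass, finemap_pass, lasso_pass, pairs)
        if not consensus.empty:
            consensus["pip"] = [pip_values.get((e, s), np.nan)
                                for e, s in zip(consensus["event_id"],
                                                consensus["str_id"])]
        return FineMapResults(self, consensus, anova_table, lasso_pass, pip_values)

    def _best_snp(self, snps: pd.DataFrame) -> str:
        meta = self.genotypes.variants
        sub = snps.assign(start=[meta.loc[v, "start"] for v in snps["variant_id"]])
        sub = sub.sort_values(["p", "start", "variant_id"], kind="stable")
        return str(sub.iloc[0]["variant_id"])

    def _residual(self, ev):
        psi = np.asarray(ev.psi, float)
        keep = ~np.isnan(psi)
        if self.covariates is not None:
            keep &= ~np.isnan(self.covariates).any(axis=1)
            y_star = residualize_phenotype(psi[keep], self.covariates[keep])
        else:
            y_star = residualize_phenotype(psi[keep], None)
        return y_star, keep

    def _candidates(self, event_id: str):
        """All variants with nominal p < threshold for the event."""
        frames = []
        for res in (self.str_results, self.snp_results):
            t = res.table
            sub = t.loc[(t["event_id"] == event_id) & (t["skip_reason"] == "")
                        & (t["p"] < self.nominal_p)]
            frames.append(sub)
        cand = pd.concat(frames, ignore_index=True)
        if len(cand) < 2:
            return None
        cand = cand.drop_duplicates("variant_id")
        vids = list(cand["variant_id"])
        dos = np.column_stack([self.genotypes.dosage(v) for v in vids])
        flags = (cand["variant_class"] == "STR").to_numpy()
        z = (cand["beta"] / cand["se"]).to_numpy()
        return vids, dos, flags, z, cand["beta"].to_numpy(), cand["se"].to_numpy()

    def _anova_fdr(self, records: list[AnovaRecord]) -> pd.DataFrame:
        tab = pd.DataFrame([{
            "event_id": r.event_id, "str_id": r.str_id,
            "best_snp_id": r.best_snp_id, "f_stat": r.f_stat, "p": r.p,
            "collinear": r.collinear,
        } for r in records])
        if tab.empty:
            tab["q"] = pd.Series(dtype=float)
            return tab
        if self.anova_fdr_scope == "per_type":
            tab["q"] = np.nan
            etype = tab["event_id"].map(lambda e: self.events[e].event_type)
            for _, idx in tab.groupby(etype).groups.items():
                q, _ = bh_fdr(tab.loc[idx, "p"].to_numpy(), self.anova_fdr)
                tab.loc[idx, "q"] = q
        else:
            q, _ = bh_fdr(tab["p"].to_numpy(), self.anova_fdr)
            tab["q"] = q
        return tab


class FineMapResults:
    """Consensus verdicts for every significant STR-event pair.

    ``consensus`` columns: event_id, str_id, anova_pass, finemap_pass,
    lasso_pass, lenient, strict, pip.
    """

    def __init__(self, model: FineMapper, consensus: pd.DataFrame,
                 anova_table: pd.DataFrame, lasso_pass: dict, pip_values: dict):
        self.model = model
        self.consensus = consensus
        self.anova_table = anova_table
        self.lasso_pass = lasso_pass
        self.pip_values = pip_values

    def str_set(self, category: str) -> set:
        """(event_id, str_id) pairs in 'significant', 'lenient' or 'strict'."""
        c = self.consensus
        if c.empty:
            return set()
        if category == "significant":
            sub = c
        elif category in ("lenient", "strict"):
            sub = c.loc[c[category]]
        else:
            raise ValueError(category)
        return set(zip(sub["event_id"], sub["str_id"]))

    def summary(self) -> pd.DataFrame:
        c = self.consensus
        return pd.DataFrame([{
            "n_pairs": len(c),
            "n_anova": int(c["anova_pass"].sum()) if len(c) else 0,
            "n_finemap": int(c["finemap_pass"].sum()) if len(c) else 0,
            "n_lasso": int(c["lasso_pass"].sum()) if len(c) else 0,
            "n_lenient": int(c["lenient"].sum()) if len(c) else 0,
            "n_strict": int(c["strict"].sum()) if len(c) else 0,
        }])
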