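"""RBP binding-site overlap and the repeat-length -> binding logistic model.

STR windows: every STR is centered and extended to a fixed 200 bp window so
overlap detection does not favour long repeats.  A window counts as bound by
an RBP iff a peak of that RBP on the *matching strand* (the coding strand of
the STR's associated gene) overlaps it by at least one base, in either cell
line.

Length model: within each (repeat unit, RBP) stratum the probability that an
STR overlaps a binding site is modelled as

    logit p = b0 + b1 * X

with X the reference repeat-unit copy number.  A stratum is only fitted when
it has >= 100 overlapping loci and every retained copy-number value is backed
by >= 10 distinct STRs (rarer lengths are dropped first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .enrichment import fisher_enrichment, _records_frame
from .genotypes import StrLocus


@dataclass(frozen=True)
class RbpPeak:
    chrom: str
    start: int
    end: int
    strand: str
    rbp: str
    cell_line: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def center_window(str_locus, width: int = 200) -> tuple[int, int]:
    """Fixed-width window centered on the STR midpoint.

    For odd STR spans the midpoint rounds toward the lower coordinate.
    """
    start, end = str_locus.start, str_locus.end
    mid = (start + end) // 2
    half = width // 2
    return (mid - half, mid - half + width)


def strand_matched_overlap(strs, str_strands, peaks, width: int = 200) -> pd.DataFrame:
    """Per-(STR, RBP) overlap booleans with strand matching.

    ``strs`` are StrLocus, ``str_strands`` the coding strand of each STR's
    gene (None excludes the STR from the analysis).  Returns a DataFrame of
    booleans indexed by STR id with one column per RBP; a cell is True iff any
    peak of that RBP on the matching strand, in any cell line, overlaps the
    STR's window by >= 1 bp (half-open intervals).
    """
    rbps = sorted({p.rbp for p in peaks})
    peaks_by_key: dict[tuple, list] = {}
    for p in peaks:
        peaks_by_key.setdefault((p.chrom, p.strand, p.rbp), []).append((p.start, p.end))
    ids, rows = [], []
    for s, strand in zip(strs, str_strands):
        if strand not in ("+", "-"):
            continue
        w = center_window(s, width)
        row = []
        for r in rbps:
            ivs = peaks_by_key.get((s.chrom, strand, r), ())
            row.append(any(w[0] < e and b < w[1] for b, e in ivs))
        ids.append(s.id)
        rows.append(row)
    return pd.DataFrame(rows, index=ids, columns=rbps, dtype=bool)


@dataclass
class RbpLengthModel:
    repeat_unit: str
    rbp: str
    n: int
    n_overlapping: int
    beta0: float
    beta1: float
    se_beta1: float
    p: float
    separation: bool = False
    skip_reason: str | None = None


def length_binding_logistic(lengths, bound_flags, repeat_unit: str = "",
                            rbp: str = "", min_overlapping: int = 100,
                            min_per_length: int = 10,
                            require_distinct_lengths: bool = False) -> RbpLengthModel:
    """Logistic fit of binding on repeat copy number for one unit-RBP stratum.

    Eligibility: >= ``min_overlapping`` bound loci; by default every distinct
    length value must be represented by >= ``min_per_length`` STRs (rarer
    lengths are dropped before fitting).  With
    ``require_distinct_lengths=True`` the alternative reading is used: the
    stratum needs >= ``min_per_length`` distinct length values instead.
    Ineligible strata and complete separation are reported via
    ``skip_reason``/``separation`` rather than an estimate.
    """
    x = np.asarray(lengths, float)
    y = np.asarray(bound_flags, float)

    def _skip(reason):
        return RbpLengthModel(repeat_unit, rbp, x.size, int(y.sum()), np.nan,
                              np.nan, np.nan, np.nan, skip_reason=reason)

    if y.sum() < min_overlapping:
        return _skip(f"fewer_than_{min_overlapping}_overlapping_loci")
    if require_distinct_lengths:
        if np.unique(x).size < min_per_length:
            return _skip(f"fewer_than_{min_per_length}_distinct_lengths")
    else:
        vals, counts = np.unique(x, return_counts=True)
        keep_vals = vals[counts >= min_per_length]
        mask = np.isin(x, keep_vals)
        x, y = x[mask], y[mask]
        if np.unique(x).size < 2:
            return _skip("fewer_than_2_retained_lengths")
        if y.sum() < min_overlapping:
            return _skip(f"fewer_than_{min_overlapping}_overlapping_loci")
    if y.min() == y.max():
        return _skip("constant_response")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return RbpLengthModel(repeat_unit, rbp, x.size, int(y.sum()), np.nan,
                              np.nan, np.nan, np.nan, separation=True,
                              skip_reason="separation")
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
        return RbpLengthModel(repeat_unit, rbp, x.size, int(y.sum()), np.nan,
                              np.nan, np.nan, np.nan, separation=True,
                              skip_reason="separation")
    return RbpLengthModel(repeat_unit, rbp, x.size, int(y.sum()),
                          float(fit.params[0]), float(fit.params[1]),
                          float(fit.bse[1]), float(fit.pvalues[1]))


def fit_length_models(str_meta: pd.DataFrame, overlap: pd.DataFrame,
                      **kwargs) -> pd.DataFrame:
    """Fit the length-binding model for every (repeat unit, RBP) stratum.

    ``str_meta`` is indexed by STR id with columns ``repeat_unit`` and
    ``ref_copies``; ``overlap`` is the boolean frame from
    :func:`strand_matched_overlap`.  BH adjustment across fitted strata.
    """
    from .association import bh_fdr

    rows = []
    common = str_meta.index.intersection(overlap.index)
    meta = str_meta.loc[common]
    ov = overlap.loc[common]
    for unit, grp in meta.groupby("repeat_unit"):
        for rbp in ov.columns:
            m = length_binding_logistic(grp["ref_copies"].to_numpy(),
                                        ov.loc[grp.index, rbp].to_numpy(),
                                        repeat_unit=unit, rbp=rbp, **kwargs)
            rows.append({
                "repeat_unit": m.repeat_unit, "rbp": m.rbp, "n": m.n,
                "n_overlapping": m.n_overlapping, "beta0": m.beta0,
                "beta1": m.beta1, "se_beta1": m.se_beta1, "p": m.p,
                "separation": m.separation, "skip_reason": m.skip_reason or "",
            })
    tab = pd.DataFrame(rows)
    tab["adjusted_p"] = np.nan
    ok = tab["p"].notna()
    if ok.any():
        q, _ = bh_fdr(tab.loc[ok, "p"].to_numpy())
        tab.loc[ok, "adjusted_p"] = q
    return tab


def rbp_enrichment(fine_mapped_flags: pd.Series, overlap: pd.DataFrame,
                   min_fine_mapped_overlaps: int = 3,
                   sided: str = "two-sided") -> pd.DataFrame:
    """Per-RBP Fisher enrichment of fine-mapped STRs among bound STRs.

    RBPs with fewer than ``min_fine_mapped_overlaps`` fine-mapped overlapping
    STRs are excluded from the panel.  BH adjustment across retained RBPs.
    """
    fm = fine_mapped_flags.reindex(overlap.index).fillna(False).astype(bool)
    records = []
    for rbp in overlap.columns:
        bound = overlap[rbp].to_numpy()
        if int(np.sum(bound & fm.to_numpy())) < min_fine_mapped_overlaps:
            continue
        records.append(fisher_enrichment(fm.to_numpy(), bound, sided=sided,
                                         stratum=rbp))
    return _records_frame(records)
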