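"""Contingency-table enrichments and group comparisons.

Fisher's exact test drives every enrichment: genomic-context membership,
stranded distance bins around the target exon, repeat-unit strata, and RBP
overlap.  Mann-Whitney U covers length (reference copy-number) and case/control
PSI comparisons.  Benjamini-Hochberg adjustment is applied within each
analysis (across bins, across units, across RBPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

# Default stranded distance bins (bp) around the target exon; negative is
# upstream in transcription direction.  The 0 bin is overlap.
DEFAULT_DISTANCE_BINS = (-np.inf, -10_000, -1_000, -100, 0, 100, 1_000, 10_000, np.inf)


@dataclass
class EnrichmentRecord:
    stratum: str
    odds_ratio: float  # np.inf / 0.0 possible; see zero_cell flag
    p: float
    table: tuple  # ((a, b), (c, d))
    zero_cell: bool
    adjusted_p: float = np.nan


def fisher_enrichment(set_flags, annotation_flags, sided: str = "two-sided",
                      stratum: str = "") -> EnrichmentRecord:
    """Fisher's exact test of set membership against an annotation.

    The 2x2 table is [[in&ann, in&~ann], [out&ann, out&~ann]] with the
    cross-product odds ratio.  Zero cells give OR of 0 or inf with
    ``zero_cell`` set; an empty margin gives p = NaN and the same flag.
    """
    s = np.asarray(set_flags, bool)
    a = np.asarray(annotation_flags, bool)
    if s.shape != a.shape:
        raise ValueError("flag vectors must have equal length")
    t11 = int(np.sum(s & a))
    t12 = int(np.sum(s & ~a))
    t21 = int(np.sum(~s & a))
    t22 = int(np.sum(~s & ~a))
    table = ((t11, t12), (t21, t22))
    zero = (t11 == 0 or t12 == 0 or t21 == 0 or t22 == 0)
    if (t11 + t12 == 0) or (t21 + t22 == 0) or (t11 + t21 == 0) or (t12 + t22 == 0):
        return EnrichmentRecord(stratum, np.nan, np.nan, table, True)
    if t12 * t21 == 0:
        odds = np.inf if t11 * t22 > 0 else 0.0
    else:
        odds = (t11 * t22) / (t12 * t21)
    _, p = stats.fisher_exact(table, alternative=sided)
    return EnrichmentRecord(stratum, float(odds), float(p), table, zero)


def _records_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([{
        "stratum": r.stratum, "odds_ratio": r.odds_ratio, "p": r.p,
        "zero_cell": r.zero_cell, "table": r.table,
    } for r in records])
    if df.empty:
        return df
    ok = df["p"].notna()
    df["adjusted_p"] = np.nan
    if ok.any():
        q, _ = bh_fdr(df.loc[ok, "p"].to_numpy())
        df.loc[ok, "adjusted_p"] = q
    return df


def distance_bin_enrichment(category_flags, distances, bin_edges=DEFAULT_DISTANCE_BINS,
                            sided: str = "two-sided") -> pd.DataFrame:
    """Per-distance-bin Fisher enrichment of a category vs all tested STRs.

    Within each bin the test compares category membership among the bin's STRs
    against membership outside the bin; distances as produced by
    ``nearest_splice_site_distance``.  Empty bins are skipped; BH adjustment
    runs across bins.
    """
    cat = np.asarray(category_flags, bool)
    d = np.asarray(distances, float)
    records = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        in_bin = (d > lo) & (d <= hi)
        if in_bin.sum() == 0 or cat[in_bin].sum() == 0:
            continue
        rec = fisher_enrichment(cat, in_bin, sided=sided,
                                stratum=f"({lo:g},{hi:g}]")
        records.append(rec)
    return _records_frame(records)


def unit_stratified_enrichment(category_flags, units,
                               sided: str = "two-sided") -> pd.DataFrame:
    """Per-repeat-unit Fisher enrichment of a category vs all tested STRs."""
    cat = np.asarray(category_flags, bool)
    units = np.asarray(units, object)
    records = []
    for u in sorted(set(units)):
        rec = fisher_enrichment(cat, units == u, sided=sided, stratum=str(u))
        records.append(rec)
    return _records_frame(records)


def length_compare(group_a, group_b, alternative: str = "two-sided"):
    """Mann-Whitney U comparison of two length (or PSI) distributions.

    Returns ``(U, p)``; exact p when both groups are small and tie-free.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
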