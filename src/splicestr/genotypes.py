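"""Genotype data model for SNPs and multiallelic STRs.

Dosage conventions
------------------
* SNP dosage: count of alternate alleles, 0/1/2.
* STR dosage: the summed signed base-pair difference of the two allele lengths
  from the reference allele, ``(a1 - ref) + (a2 - ref)``.  Distinct genotypes
  can collapse to the same dosage (22/18 vs 20/20 on a 20 bp reference are both
  0); the association model operates on dosage classes, not genotypes.

Coordinates are 0-based half-open internally; VCF I/O converts to and from
1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StrLocus:
    """A short-tandem-repeat locus: 1-6 bp unit repeated in tandem."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    repeat_unit: str  # reference-strand sequence of the unit
    ref_length_bp: int  # reference allele length in bp

    def __post_init__(self):
        if not 1 <= len(self.repeat_unit) <= 6:
            raise ValueError(f"{self.id}: repeat unit must be 1-6 bp")
        if self.end - self.start < len(self.repeat_unit):
            raise ValueError(f"{self.id}: interval shorter than one repeat unit")

    @property
    def period(self) -> int:
        return len(self.repeat_unit)

    @property
    def ref_copies(self) -> float:
        """Reference-allele length in repeat-unit copies."""
        return self.ref_length_bp / self.period


@dataclass(frozen=True)
class SnpLocus:
    id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


@dataclass
class GenotypeTable:
    """samples x variants dosage matrix with per-variant metadata.

    ``dosages`` uses NaN for missing genotypes.  ``variants`` is a DataFrame
    indexed by variant id with columns: chrom, start, end, kind ("STR"/"SNP"),
    repeat_unit, ref_length_bp (NaN for SNPs).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # (n_samples, n_variants), float, NaN = missing

    def __post_init__(self):
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def dosage(self, variant_id: str) -> np.ndarray:
        j = self.variants.index.get_loc(variant_id)
        return self.dosages[:, j]

    def subset_kind(self, kind: str) -> "GenotypeTable":
        mask = (self.variants["kind"] == kind).to_numpy()
        return GenotypeTable(self.samples, self.variants.loc[mask], self.dosages[:, mask])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.samples, columns=self.variants.index)
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path, variants: pd.DataFrame | None = None) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if variants is None:
            variants = pd.DataFrame(
                {"chrom": "NA", "start": -1, "end": -1, "kind": "NA",
                 "repeat_unit": "", "ref_length_bp": np.nan},
                index=df.columns,
            )
        return cls(list(df.index), variants, df.to_numpy(dtype=float))


def str_dosage(allele_lengths, ref_length: float) -> float:
    """Summed signed bp offset of both alleles from the reference length.

    Returns NaN if either allele is missing (None/NaN).
    """
    a1, a2 = allele_lengths
    if a1 is None or a2 is None or np.isnan(a1) or np.isnan(a2):
        return float("nan")
    if a1 < 0 or a2 < 0:
        raise ValueError("allele lengths must be non-negative")
    return float((a1 - ref_length) + (a2 - ref_length))


def filter_str_genotypes(dosages: np.ndarray, min_class_count: int = 3,
                         min_unique: int = 3) -> tuple[np.ndarray, bool]:
    """Outlier-genotype and polymorphism filters for one STR.

    Missing dosages are removed; samples whose dosage class has fewer than
    ``min_class_count`` members are removed; if fewer than ``min_unique``
    distinct dosage values remain the locus is flagged excluded.

    Returns ``(keep_mask, excluded)`` where ``keep_mask`` is a boolean mask
    over the input vector (missing and rare-class samples False).
    """
    dosages = np.asarray(dosages, dtype=float)
    keep = ~np.isnan(dosages)
    vals, counts = np.unique(dosages[keep], return_counts=True)
    rare = set(vals[counts < min_class_count])
    if rare:
        keep &= ~np.isin(dosages, list(rare))
    n_unique = np.unique(dosages[keep]).size
    return keep, n_unique < min_unique


@dataclass(frozen=True)
class LdRecord:
    id_a: str
    id_b: str
    r: float
    n: int

    @property
    def r2(self) -> float:
        return self.r * self.r


def compute_ld(x: np.ndarray, y: np.ndarray, id_a: str = "a", id_b: str = "b") -> LdRecord:
    """Pearson correlation between two dosage vectors over pairwise-complete samples.

    Raises ``ValueError`` if fewer than 3 complete pairs remain or either
    vector is constant (LD undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 pairwise-complete observations")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant dosage vector: LD undefined")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return LdRecord(id_a, id_b, r, int(ok.sum()))


def ld_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of dosage columns (complete rows only)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d).any(axis=1)
    d = d[ok]
    sd = d.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant dosage column: LD matrix undefined")
    return np.corrcoef(d, rowvar=False)


def heterozygosity(allele_frequencies) -> float:
    """Expected heterozygosity 1 - sum(p_i^2) of a locus."""
    p = np.asarray(allele_frequencies, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def maf_filter(snp_dosages: np.ndarray, min_maf: float = 0.05) -> np.ndarray:
    """Mask of SNP columns whose minor-allele frequency is >= min_maf (ties kept)."""
    d = np.asarray(snp_dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    return maf >= min_maf


def genotype_pcs(snp_dosages: np.ndarray, k: int, min_maf: float = 0.05) -> np.ndarray:
    """Top-k principal components of column-standardized SNP dosages.

    SNPs are filtered to MAF >= ``min_maf`` and non-constant columns before
    the decomposition; missing dosages are mean-imputed for the PCA only.
    Returns an (n_samples, k) score matrix.
    """
    d = np.asarray(snp_dosages, dtype=float).copy()
    if k == 0:
        return np.empty((d.shape[0], 0))
    col_mean = np.nanmean(d, axis=0)
    nan_pos = np.isnan(d)
    d[nan_pos] = np.take(col_mean, np.nonzero(nan_pos)[1])
    d = d[:, maf_filter(d, min_maf)]
    sd = d.std(axis=0)
    d = d[:, sd > 0]
    if d.shape[1] < k:
        raise ValueError(f"requested {k} PCs but only {d.shape[1]} usable SNPs")
    d = (d - d.mean(axis=0)) / d.std(axis=0)
    # scores from the SVD of the standardized matrix
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    if np.sum(s > 1e-10) < k:
        raise ValueError(f"requested {k} PCs but rank is {int(np.sum(s > 1e-10))}")
    scores = u[:, :k] * s[:k]
    # sign convention: largest-|loading| element positive, for reproducibility
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    return scores
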