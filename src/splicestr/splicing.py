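"""Splice-event data model, filters, STR-event pairing and positional geometry.

Events follow the rMATS taxonomy (SE, MXE, A3SS, A5SS, RI) and carry per-sample
percent-spliced-in (PSI, 0-100) values with supporting read counts.  Each event
has two constitutive (flanking) exons anchoring the 100 kb association window
and one or more target (alternative) exon intervals anchoring splice-site
distance measurements.

All intervals are 0-based half-open on genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import StrLocus

EVENT_TYPES = ("SE", "MXE", "A3SS", "A5SS", "RI")


@dataclass
class SpliceEvent:
    id: str
    event_type: str  # SE / MXE / A3SS / A5SS / RI
    gene: str
    chrom: str
    strand: str  # + / -
    constitutive_exons: list[tuple[int, int]]  # two intervals, genomic order
    target_exons: list[tuple[int, int]]  # one (SE, A3SS, A5SS, RI) or two (MXE)
    psi: np.ndarray | None = None  # per-sample, NaN = missing
    read_counts: np.ndarray | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for s, e in self.constitutive_exons + self.target_exons:
            if e <= s:
                raise ValueError(f"{self.id}: empty exon interval [{s},{e})")
        if self.psi is not None:
            ok = self.psi[~np.isnan(self.psi)]
            if ok.size and (ok.min() < 0 or ok.max() > 100):
                raise ValueError(f"{self.id}: PSI outside [0,100]")

    @property
    def constitutive_intron(self) -> tuple[int, int]:
        """The intron between the two constitutive exons (genomic interval)."""
        (s1, e1), (s2, e2) = sorted(self.constitutive_exons)
        return (e1, s2)


@dataclass(frozen=True)
class GeneModel:
    """Gene span from the transcript combination with the longest TSS-TES range."""

    gene: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.tss == self.tes:
            raise ValueError(f"{self.gene}: TSS equals TES")


def filter_splice_events(events, segdup_intervals=None,
                         max_extreme_frac: float = 0.90,
                         min_reads: int = 10,
                         min_read_frac: float = 0.80):
    """Apply the three event-level reliability filters.

    Keep an event iff (1) PSI is 0 or 100 in less than ``max_extreme_frac`` of
    non-missing samples, (2) at least ``min_reads`` supporting reads in more
    than ``min_read_frac`` of samples, and (3) no target exon overlaps any
    segmental-duplication interval.  ``segdup_intervals`` maps chrom ->
    list of (start, end) half-open intervals.
    """
    segdup_intervals = segdup_intervals or {}
    kept = []
    for ev in events:
        psi = ev.psi[~np.isnan(ev.psi)]
        if psi.size == 0:
            continue
        extreme = np.mean((psi == 0) | (psi == 100))
        if extreme >= max_extreme_frac:
            continue
        counts = ev.read_counts
        if counts is None or np.mean(np.nan_to_num(counts) >= min_reads) <= min_read_frac:
            continue
        if any(_overlaps(t, iv) for t in ev.target_exons
               for iv in segdup_intervals.get(ev.chrom, ())):
            continue
        kept.append(ev)
    return kept


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def filter_samples(psi_matrix: np.ndarray, max_missing_frac: float = 0.20) -> np.ndarray:
    """Mask of samples with <= ``max_missing_frac`` missing events (strict > drops).

    ``psi_matrix`` is events x samples with NaN for undetected events.
    """
    missing = np.mean(np.isnan(psi_matrix), axis=0)
    return missing <= max_missing_frac


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two half-open intervals; 0 when they overlap or abut."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def candidate_pairs(events, strs, window_bp: int = 100_000):
    """Enumerate STR-event pairs with the STR within ``window_bp`` of either
    constitutive exon (overlap counts as distance 0).

    Returns a list of ``(event_id, str_id)`` tuples, ordered by event then STR.
    """
    strs_by_chrom: dict[str, list[StrLocus]] = {}
    for s in strs:
        strs_by_chrom.setdefault(s.chrom, []).append(s)
    pairs = []
    for ev in events:
        for s in strs_by_chrom.get(ev.chrom, ()):
            d = min(_interval_distance((s.start, s.end), exon)
                    for exon in ev.constitutive_exons)
            if d <= window_bp:
                pairs.append((ev.id, s.id))
    return pairs


def nearest_splice_site_distance(str_locus: StrLocus, event: SpliceEvent) -> tuple[int, int]:
    """Signed stranded distance from an STR to the nearest target-exon boundary.

    Negative values are upstream of the exon in transcription direction,
    positive downstream, 0 when the STR overlaps a target exon.  For MXE the
    minimum-|distance| exon is used; returns ``(distance, exon_index)`` with
    the index of the anchoring target exon.
    """
    best = None
    for idx, exon in enumerate(event.target_exons):
        iv = (str_locus.start, str_locus.end)
        if _overlaps(iv, exon):
            d = 0
        elif str_locus.end <= exon[0]:  # STR genomically left of exon
            gap = exon[0] - str_locus.end
            d = -gap if event.strand == "+" else gap
        else:  # genomically right
            gap = str_locus.start - exon[1]
            d = gap if event.strand == "+" else -gap
        if best is None or abs(d) < abs(best[0]):
            best = (d, idx)
    if best is None:
        raise ValueError(f"{event.id}: event has no target exon")
    return best


def scaled_gene_position(str_locus: StrLocus, gene: GeneModel) -> float:
    """STR midpoint position scaled to the gene body: 0 at TSS, 1 at TES.

    Values below 0 are upstream of the TSS in transcription direction, above 1
    downstream of the TES.
    """
    span = abs(gene.tes - gene.tss)
    if span == 0:
        raise ValueError(f"{gene.gene}: zero-length gene span")
    mid = (str_locus.start + str_locus.end) / 2.0
    if gene.strand == "+":
        return (mid - gene.tss) / span
    return (gene.tss - mid) / span


def isoform_relative_abundance(tpm: pd.DataFrame, gene_of: dict[str, str]) -> pd.DataFrame:
    """Per-sample relative abundance of each transcript within its gene.

    ``tpm`` is transcripts x samples.  Transcripts with zero TPM in every
    sample are dropped first; where a gene's total TPM is 0 in a sample the
    ratios are NaN for that gene/sample.
    """
    tpm = tpm.loc[(tpm != 0).any(axis=1)]
    genes = tpm.index.map(gene_of)
    totals = tpm.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = tpm / totals
    return ratios.where(totals > 0)


def match_intron_events(se_event: SpliceEvent, intron_records: pd.DataFrame,
                        lo: float = 0.95, hi: float = 1.05) -> pd.DataFrame:
    """Match intron-based splicing records to a skipped-exon event.

    ``intron_records`` needs columns ``str_id``, ``intron_length`` and
    ``beta``.  A record matches when it names the same STR (``str_id``
    compared against ``se_event``'s paired STR ids supplied in the records)
    and its intron length over the event's constitutive-intron length lies in
    ``[lo, hi]``.  Matched betas are sign-flipped (``beta_flipped``) because
    intron-inclusion and exon-inclusion phenotypes point in opposite
    directions for the same splicing change.
    """
    s, e = se_event.constitutive_intron
    length = e - s
    ratio = intron_records["intron_length"] / length
    matched = intron_records.loc[(ratio >= lo) & (ratio <= hi)].copy()
    matched["length_ratio"] = ratio[matched.index]
    matched["beta_flipped"] = -matched["beta"]
    return matched
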