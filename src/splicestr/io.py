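"""Readers and writers for the pipeline's on-disk formats.

VCF carries genotypes (STR records with repeat-unit and reference-length INFO
fields plus a DS dosage FORMAT field); BED carries peaks and variant
positions (0-based half-open); splice events travel as an rMATS-like TSV with
comma-packed per-sample PSI/read vectors; GWAS summary statistics as
whitespace/tab-delimited tables with a declared column map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .genotypes import GenotypeTable
from .rbp import RbpPeak
from .splicing import SpliceEvent


# ---------------------------------------------------------------------------
# VCF


def write_vcf(table: GenotypeTable, path: str) -> None:
    """Write the dosage table as VCF (1-based positions; DS format field).

    STR records carry ``RU`` (repeat unit) and ``REFLEN`` (reference allele
    length, bp) INFO fields.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">')
    header.add_line('##INFO=<ID=REFLEN,Number=1,Type=Integer,Description="Reference allele length (bp)">')
    header.add_line('##INFO=<ID=VT,Number=1,Type=String,Description="Variant kind (STR/SNP)">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')
    for chrom in dict.fromkeys(table.variants["chrom"]):
        header.contigs.add(str(chrom))
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, (vid, row) in enumerate(table.variants.iterrows()):
            rec = out.new_record(contig=str(row["chrom"]), start=int(row["start"]),
                                 stop=int(row["start"]) + 1, alleles=("N", "<VAR>"),
                                 id=str(vid))
            rec.info["VT"] = str(row["kind"])
            if row["kind"] == "STR":
                rec.info["RU"] = str(row["repeat_unit"])
                rec.info["REFLEN"] = int(row["ref_length_bp"])
            for k, s in enumerate(table.samples):
                d = table.dosages[k, j]
                rec.samples[s]["DS"] = None if np.isnan(d) else float(d)
            out.write(rec)


def read_vcf(path: str) -> GenotypeTable:
    """Read a genotype VCF back into a :class:`GenotypeTable`.

    Dosage comes from the DS FORMAT field when present; otherwise from GT
    allele sequences (SNPs: alternate-allele count; STRs: summed length
    offset from the reference allele).
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        metas, cols = [], []
        for rec in vf:
            kind = rec.info.get("VT", "STR" if "RU" in rec.info else "SNP")
            ru = rec.info.get("RU", "")
            reflen = rec.info.get("REFLEN", len(rec.ref) if rec.ref else np.nan)
            metas.append({"id": rec.id, "chrom": rec.contig, "start": rec.start,
                          "end": rec.start + (int(reflen) if kind == "STR" and reflen
                                              else 1),
                          "kind": kind, "repeat_unit": ru,
                          "ref_length_bp": reflen if kind == "STR" else np.nan})
            col = np.full(len(samples), np.nan)
            for k, s in enumerate(samples):
                fmt = rec.samples[s]
                if "DS" in fmt and fmt["DS"] is not None:
                    col[k] = float(fmt["DS"])
                elif fmt.get("GT") and None not in fmt["GT"]:
                    alleles = [rec.alleles[a] for a in fmt["GT"]]
                    if kind == "STR":
                        col[k] = sum(len(a) - len(rec.ref) for a in alleles)
                    else:
                        col[k] = sum(a != 0 for a in fmt["GT"])
            cols.append(col)
    variants = pd.DataFrame(metas).set_index("id")
    return GenotypeTable(samples, variants, np.column_stack(cols))


# ---------------------------------------------------------------------------
# BED


def write_peaks_bed(peaks, path: str) -> None:
    """Stranded 6-column BED; the name field packs RBP and cell line."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.rbp}:{p.cell_line}"
                     f"\t0\t{p.strand}\n")


def read_peaks_bed(path: str) -> list[RbpPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split()[:6]
            rbp, _, cell = name.partition(":")
            peaks.append(RbpPeak(chrom, int(start), int(end), strand, rbp,
                                 cell or "NA"))
    return peaks


def write_variants_bed(table: GenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        for vid, row in table.variants.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{vid}\n")


# ---------------------------------------------------------------------------
# splice events


def _pack(v) -> str:
    return ",".join("NA" if np.isnan(x) else f"{x:.17g}" for x in v)


def _unpack(s: str) -> np.ndarray:
    return np.array([np.nan if x == "NA" else float(x) for x in s.split(",")])


def write_events_tsv(events, path: str) -> None:
    rows = []
    for ev in events:
        rows.append({
            "id": ev.id, "event_type": ev.event_type, "gene": ev.gene,
            "chrom": ev.chrom, "strand": ev.strand,
            "constitutive_exons": ";".join(f"{s}-{e}" for s, e in ev.constitutive_exons),
            "target_exons": ";".join(f"{s}-{e}" for s, e in ev.target_exons),
            "psi": _pack(ev.psi) if ev.psi is not None else "",
            "reads": _pack(ev.read_counts) if ev.read_counts is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    events = []
    for _, r in df.iterrows():
        events.append(SpliceEvent(
            id=r["id"], event_type=r["event_type"], gene=r["gene"],
            chrom=r["chrom"], strand=r["strand"],
            constitutive_exons=[tuple(map(int, x.split("-")))
                                for x in r["constitutive_exons"].split(";")],
            target_exons=[tuple(map(int, x.split("-")))
                          for x in r["target_exons"].split(";")],
            psi=_unpack(r["psi"]) if r["psi"] else None,
            read_counts=_unpack(r["reads"]) if r["reads"] else None,
        ))
    return events


# ---------------------------------------------------------------------------
# GWAS summary statistics

GWAS_DEFAULT_COLUMNS = {"variant_id": "variant_id", "beta": "beta", "se": "se",
                        "p": "p", "n": "n", "case_fraction": "case_fraction"}


def read_gwas_table(path: str, column_map: dict | None = None) -> pd.DataFrame:
    """Whitespace/tab-delimited GWAS summary statistics with a column map.

    ``column_map`` maps canonical names (variant_id, beta, se, p, n,
    case_fraction) to the file's column names; an ``or`` column named ``OR``
    is converted to beta = log(OR) when mapped as ``beta``.
    """
    cmap = dict(GWAS_DEFAULT_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path, sep=None, engine="python")
    out = pd.DataFrame()
    for canon, name in cmap.items():
        if name in df.columns:
            out[canon] = df[name]
    if "beta" not in out.columns and "OR" in df.columns:
        out["beta"] = np.log(df["OR"].astype(float))
    missing = {"variant_id", "beta", "se"} - set(out.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    return out


def write_gwas_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
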