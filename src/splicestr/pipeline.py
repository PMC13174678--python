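"""End-to-end orchestration: filters -> association -> fine-mapping ->
characterization -> RBP -> colocalization, with per-stage TSV outputs and a
reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .association import run_snp_scan, run_str_scan
from .coloc import ColocInput, ColocRecord, coloc_abf, gate_and_aggregate, select_test_regions
from .enrichment import distance_bin_enrichment, unit_stratified_enrichment
from .finemap import FineMapper
from .genotypes import StrLocus, compute_ld
from .rbp import fit_length_models, rbp_enrichment, strand_matched_overlap
from .repeats import canonical_unit, strand_bias_class, stranded_unit
from .simulate import SimConfig, simulate_genotypes, simulate_psi
from .splicing import filter_splice_events, filter_samples, nearest_splice_site_distance


@dataclass
class PipelineConfig:
    out_dir: str = "splicestr_out"
    seed: int = 0
    # inputs: either simulate, or point at files
    simulate: bool = True
    sim: SimConfig | None = None
    genotypes_path: str | None = None
    events_path: str | None = None
    covariates_path: str | None = None
    peaks_path: str | None = None
    gwas_path: str | None = None
    gwas_leads_path: str | None = None
    # thresholds
    window_bp: int = 100_000
    fdr_alpha: float = 0.05
    anova_fdr: float = 0.10
    pip_threshold: float = 0.5
    pp_h4_min: float = 0.5
    ld_r2_min: float = 0.1
    coloc_window_bp: int = 1_000_000
    max_causal: int = 3
    finemap_mode: str = "exhaustive"
    permute: bool = False

    def validate(self):
        for name, v in [("fdr_alpha", self.fdr_alpha), ("anova_fdr", self.anova_fdr),
                        ("pip_threshold", self.pip_threshold),
                        ("pp_h4_min", self.pp_h4_min), ("ld_r2_min", self.ld_r2_min)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.simulate:
            for p in (self.genotypes_path, self.events_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"declared input missing: {p}")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    counts: dict = field(default_factory=dict)
    skips: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps({k: (asdict(v) if isinstance(v, SimConfig) else v)
                          for k, v in asdict(config).items()}, sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _str_loci(genotypes) -> list[StrLocus]:
    out = []
    for vid, row in genotypes.variants.iterrows():
        if row["kind"] == "STR":
            out.append(StrLocus(vid, row["chrom"], int(row["start"]), int(row["end"]),
                                row["repeat_unit"], int(row["ref_length_bp"])))
    return out


def run_pipeline(config: PipelineConfig):
    """Execute all stages in order; returns (manifest, outputs dict).

    Every stage's table is written under ``config.out_dir``; record counts
    and skip tallies are accumulated in the manifest.
    """
    from . import __version__

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), __version__, config.seed)
    outputs: dict = {}

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        sim = config.sim or SimConfig(seed=config.seed)
        genotypes, truth, extras = simulate_genotypes(sim)
        events, covariates = simulate_psi(genotypes, truth, sim, extras)
        outputs["truth"] = truth
    else:
        genotypes = (sio.read_vcf(config.genotypes_path)
                     if config.genotypes_path.endswith(".vcf")
                     else __import__("splicestr.genotypes", fromlist=["GenotypeTable"])
                     .GenotypeTable.from_tsv(config.genotypes_path))
        events = sio.read_events_tsv(config.events_path)
        covariates = (pd.read_csv(config.covariates_path, sep="\t", index_col=0)
                      if config.covariates_path else None)

    # ---- filters ----------------------------------------------------------
    n_events_in = len(events)
    events = filter_splice_events(events)
    psi_matrix = np.array([ev.psi for ev in events])
    sample_mask = filter_samples(psi_matrix)
    for ev in events:
        ev.psi = np.where(sample_mask, ev.psi, np.nan)
    manifest.counts["events_in"] = n_events_in
    manifest.counts["events_kept"] = len(events)
    manifest.counts["samples_kept"] = int(sample_mask.sum())
    manifest.skips["events_filtered"] = n_events_in - len(events)

    cov = None if covariates is None else covariates.to_numpy(dtype=float)

    # ---- association ------------------------------------------------------
    str_res = run_str_scan(events, genotypes, cov, window_bp=config.window_bp,
                           fdr_alpha=config.fdr_alpha, permute=config.permute,
                           seed=config.seed)
    snp_res = run_snp_scan(events, genotypes, cov, str_results=str_res,
                           window_bp=config.window_bp,
                           fdr_alpha=config.fdr_alpha, seed=config.seed)
    str_res.table.to_csv(out_dir / "str_associations.tsv", sep="\t", index=False)
    snp_res.table.to_csv(out_dir / "snp_associations.tsv", sep="\t", index=False)
    outputs["str_scan"], outputs["snp_scan"] = str_res, snp_res
    manifest.counts["str_tests"] = len(str_res.table)
    manifest.counts["str_significant"] = int(str_res.table["significant"].sum())
    manifest.counts["snp_tests"] = len(snp_res.table)
    manifest.skips["str_skipped"] = int((str_res.table["skip_reason"] != "").sum())

    # events with a significant STR but no significant SNP are set aside
    str_ev = set(str_res.significant_event_ids())
    snp_ev = set(snp_res.significant_event_ids())
    manifest.counts["events_str_only"] = len(str_ev - snp_ev)

    # ---- fine-mapping -----------------------------------------------------
    mapper = FineMapper(events, genotypes, cov, str_res, snp_res,
                        anova_fdr=config.anova_fdr,
                        pip_threshold=config.pip_threshold,
                        max_causal=config.max_causal, mode=config.finemap_mode,
                        seed=config.seed)
    fm = mapper.fit()
    fm.consensus.to_csv(out_dir / "finemap_consensus.tsv", sep="\t", index=False)
    outputs["finemap"] = fm
    for k, v in fm.summary().iloc[0].items():
        manifest.counts[f"finemap_{k}"] = int(v)

    # ---- characterization -------------------------------------------------
    strs = _str_loci(genotypes)
    events_by_id = {ev.id: ev for ev in events}
    sig_pairs = set(zip(str_res.significant["event_id"],
                        str_res.significant["variant_id"]))
    tested = str_res.table.loc[str_res.table["skip_reason"] == ""]
    str_by_id = {s.id: s for s in strs}
    char_rows = []
    for _, r in tested.iterrows():
        s = str_by_id[r["variant_id"]]
        ev = events_by_id[r["event_id"]]
        dist, _ = nearest_splice_site_distance(s, ev)
        unit = s.repeat_unit if ev.strand == "+" else None
        coding_unit = (s.repeat_unit if ev.strand == "+"
                       else _revcomp(s.repeat_unit))
        char_rows.append({
            "event_id": r["event_id"], "str_id": r["variant_id"],
            "distance": dist, "canonical_unit": canonical_unit(s.repeat_unit),
            "stranded_unit": stranded_unit(coding_unit),
            "strand_bias": strand_bias_class(coding_unit).value,
            "significant": (r["event_id"], r["variant_id"]) in sig_pairs,
            "lenient": (r["event_id"], r["variant_id"]) in fm.str_set("lenient"),
            "strict": (r["event_id"], r["variant_id"]) in fm.str_set("strict"),
        })
    char = pd.DataFrame(char_rows)
    char.to_csv(out_dir / "str_characterization.tsv", sep="\t", index=False)
    outputs["characterization"] = char
    if not char.empty:
        for cat in ("significant", "lenient", "strict"):
            enr = distance_bin_enrichment(char[cat].to_numpy(),
                                          char["distance"].to_numpy())
            enr.to_csv(out_dir / f"distance_enrichment_{cat}.tsv", sep="\t",
                       index=False)
        unit_enr = unit_stratified_enrichment(char["lenient"].to_numpy(),
                                              char["canonical_unit"].to_numpy())
        unit_enr.to_csv(out_dir / "unit_enrichment.tsv", sep="\t", index=False)

    # ---- RBP --------------------------------------------------------------
    if config.simulate or config.peaks_path:
        peaks = (sio.read_peaks_bed(config.peaks_path) if config.peaks_path
                 else None)
        if peaks:
            strands = ["+"] * len(strs)
            overlap = strand_matched_overlap(strs, strands, peaks)
            meta = pd.DataFrame({
                "repeat_unit": [s.repeat_unit for s in strs],
                "ref_copies": [s.ref_copies for s in strs],
            }, index=[s.id for s in strs])
            models = fit_length_models(meta, overlap)
            models.to_csv(out_dir / "rbp_length_models.tsv", sep="\t", index=False)
            outputs["rbp_models"] = models

    # ---- colocalization ---------------------------------------------------
    if config.gwas_path and config.gwas_leads_path:
        gwas = sio.read_gwas_table(config.gwas_path)
        leads = pd.read_csv(config.gwas_leads_path, sep="\t")
        records = run_coloc_stage(genotypes, snp_res, fm, gwas, leads,
                                  events_by_id, config)
        coloc_tab = pd.DataFrame([{
            "event_id": r.event_id, "trait": r.trait, "gene": r.gene,
            "str_id": r.str_id, "lead": r.lead_variant, "r2": r.str_lead_r2,
            **{f"pp_{h}": v for h, v in r.pp.items()},
        } for r in records])
        coloc_tab.to_csv(out_dir / "coloc_records.tsv", sep="\t", index=False)
        agg = gate_and_aggregate(records, config.pp_h4_min, config.ld_r2_min,
                                 strict_pairs=fm.str_set("strict"))
        agg.to_csv(out_dir / "coloc_genes.tsv", sep="\t", index=False)
        outputs["coloc"], outputs["coloc_genes"] = records, agg
        manifest.counts["coloc_tested"] = len(records)
        manifest.counts["coloc_genes"] = len(agg)

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest, outputs


def run_coloc_stage(genotypes, snp_res, fm, gwas, leads, events_by_id, config):
    """Colocalize every fine-mapped splice event near a GWAS lead."""
    meta = genotypes.variants
    str_positions = {}
    for event_id, str_id in fm.str_set("lenient"):
        row = meta.loc[str_id]
        str_positions[(event_id, str_id)] = (row["chrom"],
                                             (row["start"] + row["end"]) // 2)
    pairs = select_test_regions(str_positions, leads, config.coloc_window_bp)
    gwas_by_id = gwas.set_index("variant_id")
    records = []
    for event_id, str_id, trait, lead in pairs:
        sub = snp_res.table
        sub = sub.loc[(sub["event_id"] == event_id) & (sub["skip_reason"] == "")]
        shared = sub.loc[sub["variant_id"].isin(gwas_by_id.index)]
        if len(shared) < 2:
            continue
        g = gwas_by_id.loc[shared["variant_id"]]
        inp = ColocInput(list(shared["variant_id"]),
                         shared["beta"].to_numpy(), shared["se"].to_numpy() ** 2,
                         g["beta"].to_numpy(), g["se"].to_numpy() ** 2)
        post = coloc_abf(inp)
        try:
            ld = compute_ld(genotypes.dosage(str_id), genotypes.dosage(lead))
            r2 = ld.r2
        except (ValueError, KeyError):
            r2 = float("nan")
        records.append(ColocRecord(event_id, trait, post.pp, lead, str_id, r2,
                                   events_by_id[event_id].gene
                                   if event_id in events_by_id else ""))
    return records


def write_report(manifest: RunManifest, outputs: dict, path: str) -> dict:
    """Machine-readable run summary; returns the report dict."""
    report = {"counts": manifest.counts, "skips": manifest.skips,
              "config_hash": manifest.config_hash}
    fm = outputs.get("finemap")
    if fm is not None:
        strict = fm.str_set("strict")
        lenient = fm.str_set("lenient")
        report["strict_subset_of_lenient"] = strict <= lenient
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _revcomp(seq: str) -> str:
    from .repeats import reverse_complement

    return reverse_complement(seq)
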