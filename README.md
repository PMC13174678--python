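# splicestr

Splicing-QTL discovery for short tandem repeats: association testing between
STR dosages and exon inclusion, multi-method fine-mapping, repeat-sequence
and RBP-binding characterization, and colocalization with GWAS summary
statistics.

## The problem

Short tandem repeats (STRs — 1–6 bp units repeated in tandem) are a large,
routinely-ignored source of genetic variation.  Their copy number can change
how nearby exons are spliced: a repeat near a splice site can lengthen a
polypyrimidine tract, create or destroy an RNA-binding-protein (RBP) binding
site, or form secondary structure.  `splicestr` is for statistical
geneticists who want to scan STR genotypes against percent-spliced-in (PSI)
phenotypes, decide which associated STRs are plausibly *causal* rather than
LD passengers, and connect them to disease GWAS signals.

The core model is OLS on z-scaled variables,

    Y ~ β₀·X + β₁·C + ε,

with Y an event's PSI, X an STR dosage (summed signed bp offset of both
alleles from the reference) or SNP dosage (0/1/2), and C covariates.
Z-scaling both sides bounds β₀ in [−1, 1].  Discoveries (BH FDR 5% per
splice type) are fine-mapped by three orthogonal methods — a nested ANOVA
against the event's best SNP, cross-validated Lasso selection, and a
Bayesian configuration model producing posterior inclusion probabilities
(PIPs) — whose consensus defines *leniently* (≥ 1 method) and *strictly*
(all 3) fine-mapped spliceSTRs.  Colocalization with GWAS traits uses
Wakefield approximate Bayes factors (PP.H0–PP.H4) gated by STR–lead-variant
LD (r² > 0.1).  A synthetic-cohort generator with planted causal variants
makes the whole pipeline testable end to end.

## Worked example

```python
import numpy as np
from splicestr import (SimConfig, simulate_genotypes, simulate_psi,
                       run_str_scan, run_snp_scan, FineMapper)

cfg = SimConfig(n_samples=300, n_events=20, snps_per_locus=20,
                snp_causal_fraction=0.5, seed=7)
genotypes, truth, extras = simulate_genotypes(cfg)
events, covariates = simulate_psi(genotypes, truth, cfg, extras)

scan = run_str_scan(events, genotypes, covariates.to_numpy())
print(scan.summary().to_string(index=False))

snps = run_snp_scan(events, genotypes, covariates.to_numpy(), str_results=scan)
fm = FineMapper(events, genotypes, covariates.to_numpy(), scan, snps).fit()
print(fm.summary().to_string(index=False))

causal = truth.causal_strs()
for cat in ("significant", "lenient", "strict"):
    pairs = fm.str_set(cat)
    prec = np.mean([s in causal for _, s in pairs])
    print(f"precision({cat}) = {prec:.2f}  (n={len(pairs)})")
```

Output:

```
event_type  n_tests  n_skipped  n_significant
      A3SS        4          0              3
      A5SS        4          0              3
       MXE        4          0              4
        RI        4          0              4
        SE        4          0              3
 n_pairs  n_anova  n_finemap  n_lasso  n_lenient  n_strict
      17        9          8        8          9         7
precision(significant) = 0.53  (n=17)
precision(lenient) = 1.00  (n=9)
precision(strict) = 1.00  (n=7)
```

Half of the 20 events were planted with a causal STR and half with a causal
SNP that the local STR merely tags.  The scan finds 17 significant STR–event
pairs, but only 53% of those STRs are truly causal — the rest ride on LD.
Fine-mapping cleans this up: all 9 leniently and all 7 strictly fine-mapped
STRs are planted causal variants.

The same stages are available from the shell:

```bash
splicestr simulate --n-events 20 --out cohort/
splicestr assoc --genotypes cohort/genotypes.tsv --events cohort/events.tsv \
    --covariates cohort/covariates.tsv --out assoc.tsv
splicestr run --out results/   # full pipeline on a synthetic cohort
```

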