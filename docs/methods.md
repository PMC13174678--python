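# Methods

## Scope and model

`splicestr` implements a splicing-QTL discovery pipeline for short tandem
repeats (STRs): variants of 1–6 bp units whose copy number varies in the
population.  The phenotype is the percent-spliced-in (PSI, 0–100) of an
alternative splicing event (rMATS taxonomy: SE, MXE, A3SS, A5SS, RI); the
genotype is the STR *dosage* — the summed signed base-pair difference of both
allele lengths from the reference allele — or, for SNPs, the 0/1/2
alternate-allele count.

The association model is ordinary least squares on z-scaled variables,

    Y ~ β₀·X + β₁·C + ε,

with Y the PSI vector of one event, X one variant's dosage, and C covariates
(age, sex, read counts, genotype PCs, latent expression factors).  Per pair:
samples with a missing genotype or PSI are dropped; STR dosage classes seen
in fewer than three samples are removed and the locus is skipped if fewer
than three distinct dosages remain; Y, X and the covariates are z-scaled
(sample SD, n−1) on the retained samples, which bounds the fitted variant
effect in [−1, 1].  Significance uses the two-tailed t-test on β₀,
Benjamini–Hochberg FDR 5% applied *within each splice type*.  A single
label-shuffled permutation per pair serves as a calibration control.  SNPs
are tested only for events that already have a significant STR.

## Fine-mapping

Because STRs are typically in LD with flanking SNPs, a significant STR may
tag a causal SNP (or vice versa).  Three orthogonal verdicts are computed per
significant STR–event pair:

1. **Nested ANOVA.**  PSI is residualized on all covariates (Y*), the
   event's best SNP (smallest p; ties broken by coordinate then id) defines
   the base model, and the F-test of `Y* ~ SNP + STR` against `Y* ~ SNP`
   scores the STR's added explanatory power.  Before testing, STRs whose
   effect differs significantly (two-tailed Z on β_i − β_best with
   independent-SE combination √(SE_i² + SE_best²)) from the event's
   strongest-p STR are dropped.  BH FDR 10% across all retained pairs
   (jointly by default; a per-splice-type flag exists).
2. **Lasso selection.**  All variants with nominal p < 0.05 for the event
   enter an L1-penalized regression of Y* (5-fold cross-validated penalty,
   `max_iter` 5000).  Coefficients are never thresholded: the single variant
   with the largest |coefficient| decides, and an STR is selected only if it
   beats every SNP.
3. **Bayesian configuration model.**  From summary statistics z = β/SE and
   the LD matrix R (ridge-regularized by 1e−6·I), each causal configuration
   C with |C| ≤ K receives the Bayes factor of
   N(z_C; 0, R_CC + s²n·R_CC²) against N(z_C; 0, R_CC), where s is the
   prior SD of standardized effects (default 0.05) and n the sample size
   (s²n converts the prior to the z scale).  The configuration prior is
   Bernoulli with per-variant inclusion probability 1/m.  PIP_j sums the
   normalized posterior over configurations containing j.  Exhaustive
   enumeration is the default at desk scale (K = 3); a shotgun stochastic
   search (random restarts + add/drop/swap moves, caching every evaluated
   configuration, with a completeness short-circuit that stops once every
   configuration has been scored) handles larger loci and provably matches
   exhaustive enumeration on small ones.

A pair passing ANOVA (q < 0.10), Bayesian fine-mapping (PIP ≥ 0.5) or Lasso
is *leniently* fine-mapped; passing all three is *strict*.  Strict ⊆ each
single-method set ⊆ lenient holds by construction and is asserted on every
run.  Events whose only significant variants are STRs (no significant SNP)
are excluded from fine-mapping — there is no competitor to fine-map against.

## Repeat-sequence characterization

`canonical_unit` reduces a repeat tract to its primitive unit and takes the
lexicographic minimum (A<C<G<T) over all rotations of the unit and of its
reverse complement; `stranded_unit` minimizes over rotations only,
preserving coding-strand identity.  Strand-bias classes on coding-strand
units: equal A/T counts are excluded first, then units with G+C ≥ 50% of the
length; the remainder are T-rich (T > A) or A-rich.  The precedence order
matters only for units (e.g. CG) that satisfy both exclusions and is
configurable.  The T-rich fraction within a distance bin is tested against
0.5 with a one-sided exact binomial test.

Enrichment analyses are two-sided Fisher exact tests: per stranded distance
bin around the target exon (default edges ±100 bp, ±1 kb, ±10 kb), per
canonical unit, and per RBP, each with BH adjustment within the analysis.
Zero cells are reported as OR 0/∞ with a flag rather than corrected.
Length and case/control comparisons use Mann–Whitney U.

## RBP binding

Every STR is centered in a fixed 200 bp window (odd spans round toward the
lower coordinate) so overlap detection does not favour long repeats.  A
window is *bound* by an RBP iff a peak of that RBP on the matching strand
(the coding strand of the STR's gene) overlaps it by ≥ 1 bp in either cell
line.  Within each (repeat unit, RBP) stratum the binding probability is a
logistic function of reference copy number, `logit p = β₀ + β₁·X`; a stratum
is fitted only with ≥ 100 bound loci and ≥ 10 distinct STRs at every
retained copy-number value (rarer lengths dropped first; the alternative
"≥ 10 distinct lengths" reading is available behind a flag).  Complete
separation is flagged, not estimated.  Per-RBP enrichment panels require
≥ 3 fine-mapped bound STRs.

## Colocalization

Wakefield's single-variant approximate Bayes factor,
`log ABF = ½·log(V/(V+W)) + z²W/(2(V+W))`, scores each shared variant per
trait; under the one-causal-variant-per-trait assumption the five hypotheses
H0–H4 are summed over configurations and normalized with priors
p1 = p2 = 1e−4, p12 = 1e−5 (the conventional defaults; configurable).  The
splicing trait is quantitative with sdY = 1 (betas are on z-scaled PSI), so
W₁ = 0.15²; GWAS traits are case-control with W₂ = 0.2².  A splice event
colocalizes with a trait when PP.H4 > 0.5 *and* its fine-mapped STR has
r² > 0.1 with the trait's lead variant (STRs carry no GWAS summary
statistics, so the LD gate is what ties the STR to the GWAS signal).
Passing events are aggregated per gene × trait.  A quadratic brute-force
enumeration over (variant-1, variant-2) pairs validates the implementation.

## Synthetic cohorts

The generator plants known truth so every stage is testable without
access-controlled genotype data.  Defaults describe the emulated study
conditions: n = 300 samples, one multiallelic STR per event region on a
six-allele ladder at 3 bp spacing (frequencies 0.05/0.15/0.30/0.25/0.15/0.10),
50 flanking SNPs per region, standardized causal effect 0.3, noise SD 0.9
(total latent variance ≈ 1), regions spaced 1 Mb so 100 kb windows never
cross.  Haplotype construction couples each SNP to a binary split of the STR
ladder with a mixing weight solved so the haplotype-level r² matches its
target while preserving the SNP's allele frequency; the ladder bounds the
attainable single-SNP r² at ≈ 0.70, so the default LD ceiling is 0.6 and an
infeasible target raises an error naming the variant.  PSI is generated on a
latent linear scale (effect·z(dosage) + confounders + Gaussian noise) mapped
affinely to [0,100] and clipped — the analysis model is linear in PSI, so no
logit link is used.  Two standardized Gaussian confounders tilt STR allele
frequencies between cohort halves (mild stratification) and load on PSI;
age/sex/read-count analogues are genotype-independent.  Read counts are
negative binomial (mean 60) so the read-support filter is exercisable.
GWAS summary statistics are drawn analytically, z ~ MVN(R·z_c, R) with the
case-control SE approximation 1/√(2f(1−f)·N·s(1−s)).

What the generator does *not* emulate: realistic mutation processes
(stepwise mutation, recombination maps), sequence-level reads, genotyping
error, imputation uncertainty, and tissue-specific event structure.  Passing
tests therefore demonstrate statistical correctness of the procedures under
the stated model, not robustness to those real-data complications.

## Problem sizes used in validation

The validation experiments (tests and `scripts/acceptance.py`) run at desk
scale chosen to keep a full run within minutes on one CPU: null calibration
uses 100 events × 100 STRs (10,000 all-pair tests), with 20 seeds for the
FDR-control check; planted-causal power uses one 200-event cohort
(50 SNPs/locus, n = 300, effect 0.3); the fine-mapping precision ordering
averages 50 seeds of 40-event cohorts under the same per-event conditions;
the stochastic-search oracle uses 100 loci of 6–12 variants with K = 3; the
logistic recovery uses 200 seeds of 5,000 STRs; colocalization recovery uses
100 shared and 100 distinct regions of ~30 variants.

## Numerical choices and edge cases

- Constant vectors cannot be z-scaled: such tests are skipped with a
  recorded reason, never silently passed.
- Rank-deficient designs are rejected via the QR diagonal (tolerance
  1e−10 relative).
- An STR numerically collinear with the best SNP (|r| > 1 − 1e−10) gets
  ANOVA p = 1 with a collinearity flag.
- LD matrices receive a 1e−6 ridge before Cholesky; non-PSD after ridge is
  an error.
- Best-SNP ties break by genomic coordinate, then id, for reproducibility.
- PCA-based factors fix their sign by making the largest-|score| element
  positive.
- Missing PSI/genotypes are dropped pairwise per test; factor extraction
  mean-imputes internally only.
- Latent expression factors are principal components of the z-scaled
  event × sample PSI matrix — a deliberate PCA stand-in for
  factor-analysis-style estimators, adequate for linear confounder removal.

## Known limitations

- The Bayesian fine-mapper evaluates configurations only at the variants in
  each configuration (not the full z-vector likelihood); with the shared
  ridge and prior this is the standard summary-statistic shortcut and is
  internally consistent between exhaustive and stochastic modes.
- Single-causal-variant colocalization only; no multi-signal decomposition.
- The pipeline assumes harmonized coordinates and alleles across inputs.
- Fine-mapping precision on synthetic data with every causal variant an STR
  is necessarily 1.0 in all categories; mixed STR/SNP-causal cohorts
  (`snp_causal_fraction > 0`) make the strict ≥ lenient ≥ significant
  precision ordering informative and are used in the deeper property tests.
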