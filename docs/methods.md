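# Methods

This note documents the statistical procedures, conventions and design
decisions of `lncsnp`, and what the synthetic generators do and do not
emulate.

## Data model and missingness

Genotypes are unphased diploid allele pairs at biallelic SNPs, normalized
to alphabetically sorted tuples; a missing call is `None`.  Analysis is
complete-case per SNP: each SNP is analyzed on its non-missing samples, so
per-SNP sample sizes vary below the enrolled cohort size (in the reference
study: 254–291 analyzable cases per SNP against 291 enrolled).  No
imputation is performed and multi-allelic records are skipped on read.

Coordinates: BED intervals are 0-based half-open; GWAS-catalog positions
are 1-based and converted to 0-based points at the reader boundary, so
overlap tests (`start <= pos < end`) never mix conventions.  Strand is
carried but ignored for overlap — SNP membership in an lncRNA is purely
positional.  Genome build is metadata on both SNPs and intervals; a
mismatch raises rather than lifting over.

## Candidate screen

1. **Tumor-vs-normal DE.**  Per gene, a Welch (unequal-variance) two-sample
   t-test on log2(x+1) expression; log2FC is the difference of group means
   on that scale.  The filter keeps |linear FC| > 1.5 — i.e.
   |log2FC| > log2 1.5 ≈ 0.585 — and p < 0.001.  The linear reading of the
   1.5 threshold is deliberate: the reference study's candidate table
   contains rows with |log2FC| as low as 0.69 that passed its filter, which
   is only consistent with a linear fold-change cut.  The test itself is
   isolated behind one function (`de_test`) because the study never names
   its DE method; any monotone location test would serve.  No
   multiple-testing correction is applied — the raw p < 0.001 cut is part
   of the screen's published definition (a note field records the number of
   tests run by the engine).
2. **GWAS intersection and MAF.**  SNPs are paired with every interval
   containing them (a SNP inside two overlapping lncRNAs yields two pairs)
   and kept when the catalog MAF is strictly above 0.20 ("higher than"
   reads as strict).
3. **Subtype DE.**  The same test, per subtype-vs-rest contrast over the
   four molecular subtypes (luminal A, luminal B, HER2-enriched,
   basal-like) at the same thresholds; a candidate survives with at least
   one non-`ns` flag.  The contrast design is this package's choice — the
   study states only that subtype DE was required.
4. **Top-OR pick.**  Candidate rows sorted by GWAS-reported OR descending,
   taken until `n_select` (default 4) distinct rsIDs are collected; a row
   may carry two SNPs in strong LD and both count.  Ties break by rsID
   lexicographic order and the tie-break is logged.

Filters have set-intersection semantics (idempotent, order-commutative)
and each surviving record carries its flag trail.

## Association engine

For one SNP and two groups, genotype counts are ordered (hom-major, het,
hom-minor), with the minor allele decided from the pooled frequency unless
explicitly overridden.  Model tables:

* codominant — three rows, hom-major reference;
* dominant — het + hom-minor vs hom-major;
* recessive — hom-minor vs the rest;
* overdominant — het vs both homozygotes.

**Odds-ratio orientation.**  With 2×2 cells n₁(ref), n₂(ref), n₁(exp),
n₂(exp) for column groups 1 and 2, the default "paper" orientation is
OR = [n₂(exp)·n₁(ref)]/[n₁(exp)·n₂(ref)] — the column-2 group treated as
outcome.  This reverse-engineers to every printed OR and CI in the
reference study's case-control and stratified tables, including its
recessive panels where the printed "1.00" sits beside the rest-group row;
the engine always reports the homozygous-minor class as the exposure in
recessive models.  `orientation="standard"` gives the epidemiological
reciprocal; the two multiply to 1 on every table.  The tension between
this orientation and the study's verbal "higher risk" reading is
documented here rather than silently corrected.

**Confidence intervals.**  Wald on the log scale:
exp(ln OR ± 1.96·√(Σ 1/cell)).  A single zero cell triggers the
Haldane–Anscombe +0.5 correction on all four cells and flags the result;
two zero cells in one margin leave the OR undefined (error).

**Association test.**  The likelihood-ratio statistic
G = 2·Σ obs·ln(obs/exp), expectations from independence margins,
df = rows − 1, no continuity correction; a zero observed cell contributes
0 (lim x·ln x = 0) and is flagged.  G was chosen as primary because it
reproduces the study's printed p-values (e.g. 0.015 and 0.041 in the
recessive panels) where the Pearson statistic does not; Pearson χ² is
co-reported, and Yates correction contradicts every printed value checked.

**HWE.**  Expected counts n·(p², 2pq, q²) with p estimated per group;
chi-square with 1 df.  Monomorphic groups return chi2 = 0 flagged
degenerate.  Reported as raw p plus a boolean at a configurable α
(default 0.05).

**Allele frequency.**  freq = (2·n_hom + n_het)/(2n), per group or pooled.
The published cohort frequency column is reproduced by pooling
cases + controls (control-only rounds identically for all four SNPs, so
the ambiguity is immaterial); note that column's "alt" allele is the
*major* allele for two of the four SNPs, so the frequency function takes an
explicit allele argument.

**Rounding.**  Display values use decimal round-half-up to 2 dp (ORs/CIs),
matching the printed cells; full precision is retained internally and in
TSV output (a `*_display` column carries the rounded form).

## Haplotype EM and LD

For two biallelic SNPs, only the double heterozygote is phase-ambiguous.
The EM iterates: E-step splits double heterozygotes between cis
(A1B1/A2B2) and trans (A1B2/A2B1) resolutions in proportion to the current
frequency products; M-step renormalizes expected haplotype counts.
Initialization is at linkage equilibrium (products of observed allele
frequencies), making the outcome deterministic; when the two resolutions
are exactly equally likely the estimate stays at the symmetric point and
is flagged.  Convergence: max |Δf| < 1e-8, cap 1000 iterations (a
four-parameter problem; machine-fast), non-convergence flags rather than
raises.  The observed-data log-likelihood is asserted non-decreasing at
every iteration, and with no double heterozygotes the estimate equals
direct gamete counting.

LD from a frequency 4-vector: D = f(A1B1) − f(A1)f(B1);
D′ = D/Dmax with Dmax = min(f(A1)f(B2), f(A2)f(B1)) for D > 0 (mirrored
for D < 0); r² = D²/(f(A1)f(A2)f(B1)f(B2)).  The identity r² ≤ D′² is
property-tested on random simplex draws.  Because (D′, r²) underdetermine
the frequency simplex, `haplotype_freqs_for_ld` fixes the locus-B allele
frequency (default 0.75, near the European C-allele frequency of
rs4784227) and solves for the locus-A frequency on the D > 0 branch; the
published CEU pair (D′ = 0.97, r² = 0.91) is realized and verified by
closed-form evaluation.

Haplotype association converts per-group EM frequencies to estimated
counts round(2N·f) (flagged as estimated — phase is resolved
statistically, not observed) and forms each haplotype's 2×2 table against
the most frequent pooled haplotype, fed to the same OR/G-test machinery.
The reference study's haplotype table cannot be reproduced cell-exactly —
it never printed the joint two-SNP genotype table, and its haplotype
software is unnamed — so validation is parameter recovery on synthetic
cohorts drawn at the published frequency vector (±0.01 at n = 10⁴,
binomial-SE tolerance) and a planted protective OR of 0.20 recovered
within 2 SEs.

## Clinical stratification

Cases only, controls never enter.  Rules: dichotomize-at-mean for age
(values ≥ cutoff go to the "higher" stratum — the boundary convention is
this package's choice, the study does not state one; default cutoff 57.90,
the study's mean age at diagnosis), binary status for ER/PR/lymph-node,
ordinal levels for grade (contrasted pairwise, grade I reference, since the
study printed no grade table).  Column order is (negative, positive) so
the paper-orientation OR reads off the published stratified tables
unchanged.  Missing clinical values are dropped with counts logged;
stratification is a partition (stratum sizes + missing = total cases,
property-tested).  ER, grade and age tables have no published golden
values and are covered by property tests only.

## Synthetic generators

All randomness descends from one integer seed split deterministically per
sub-generator (`SeedSequence(seed, spawn_key=...)`), so adding a generator
never shifts existing streams; fixed seed ⇒ byte-identical output.

* **Cohorts**: genotypes drawn i.i.d. per sample, either HWE at a given
  MAF or explicit per-group genotype probabilities; missingness applied
  after the draw.  Disease effects are expressed as per-group genotype
  probabilities rather than a logistic model because every published
  quantity is a genotype-count contrast — this makes expected ORs
  analytic and recovery tests exact.  Defaults of interest mirror the
  reference cohort: 291 cases / 370 controls enrolled, per-SNP genotype
  probabilities equal to the printed count fractions, per-SNP missing
  rates equal to 1 − printed n / enrolled n.
* **Two-locus cohorts**: two haplotypes i.i.d. from a group-specific
  distribution over (A1B1, A1B2, A2B1, A2B2); only unphased genotypes are
  exposed, with the true phase in `dataset.audit_haplotypes` for tests.
  Frequency vectors summing to 1 within 2e-3 are renormalized so published
  rounded columns (which sum to 1.0016) can serve directly as truth.
* **Expression**: value = 2^(baseline + planted per-group log2 offset +
  Gaussian noise), noise SD 0.3 by default — enough monotone separation
  for the screen's filters; the reference study's DE method being
  unstated, nothing stronger is claimed.
* **GWAS records**: stated ORs/MAFs with positions placed inside or
  outside given intervals.

What the generators do **not** emulate: linkage beyond two loci,
population structure and admixture (a real concern in the Brazilian
cohort), genotyping error, covariate-genotype correlation, and
RNA-seq count noise (expression is i.i.d. log-normal).  Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated sampling models, not robustness to those real-data features.

## Problem sizes and tolerances

Recovery tests use n = 10⁴ individuals for EM haplotype estimation
(binomial SE of the rarest published frequency ≈ 0.0006, so the ±0.01
band is generous), n = 10⁴ per group for the planted haplotype OR, and
n = 10⁵ per group for planted genotype-model ORs, each asserted within
2 standard errors of the planted value (Wald SE of the estimated table).
The EM tolerance 1e-8 and iteration cap 1000 are far below/above anything
the four-parameter problem needs.  Published-value checks are exact after
half-up rounding to the printed precision; printed p-values are matched
within ±0.003 (the published 0.047 appears to mix LR ≈ 0.046 / Pearson
≈ 0.048 rounding, which the band covers).

## Known limitations

* The engine offers no covariate-adjusted (logistic) models; the reference
  study's "multivariate analysis" printed no results to reproduce, and
  exact (Fisher) tests are not the default anywhere.
* Haplotype association uses estimated-count tables; a score test on the
  EM posterior would propagate phase uncertainty and can give slightly
  wider intervals.
* The study's statement that samples were in HWE "(p < 0.05)" is almost
  certainly a typo for p > 0.05; the engine reports raw p-values and a
  boolean at a configurable α without inheriting the typo.
* The genome build of the reference study's mapping step is unstated;
  build metadata is enforced for consistency but no liftover is provided.
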