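# Methods

## Scope and data model

`panelval` evaluates the analytical validity of a targeted gene panel
*downstream of variant calling*: it consumes calls (VCF or TSV with
GT/GQ/DP/AD), target regions (BED6, 0-based half-open), per-base depth
tables (TSV, 1-based), a per-ancestry population MAF table, and truth
tables from orthogonal assays. Upstream read processing (trimming,
alignment, calling, annotation) is out of scope; functional class and
clinical-significance labels are carried as opaque annotations.

## Filtering cascade

Three conjunctive predicates, hence order-independent and idempotent:

* **gene restriction** to the assessed gene set;
* **rarity**: keep iff MAF ≤ cutoff (default 0.02, inclusive) in
  *every* ancestry group. A variant absent from the population table is
  treated as rare — population repositories omit variants they have
  not observed, and rare variants are exactly the ones absent.
  MAFs are proportions throughout, never percentages.
* **position**: coding classes (nonsynonymous, synonymous, frameshift)
  always pass; intronic calls pass iff their distance to the nearest
  intron–exon boundary is ≤ the window (default 10 bp, matching the
  intronic flank the capture design retains). Distance comes from the
  call's HGVS c.-string offset when present (`c.1066-6T>G` → 6),
  otherwise from the target exon model; calls outside every target are
  dropped with a warning.

## Confidence triage

Allele balance is defined as AB = AD_alt / DP (undefined at DP = 0; a
depthless call is never high confidence). True heterozygotes
concentrate near 0.5, homozygous-alternate calls at 1.0, and artifacts
skew low. A call is **high confidence** iff DP ≥ 100 *and* AB ≥ 0.40,
both inclusive; such calls validate without orthogonal confirmation,
which is the operational payoff of the assessment. The separate
exclusion filter removes AB ≤ 0.20 (boundary excluded): on the
benchmark no confirmed call sits at or below 0.20. Triage uses the
call's own reported DP, not the locus depth from the coverage table —
artifacts can sit at 12–63X inside regions averaging >400X.

GQ is parsed and carried through but takes part in no filter.

## Concordance

TP/FP come from variant-level Sanger outcomes; FN from clinically
known, laboratory-confirmed variants the panel missed; TN from
(sample, gene) pairs with a negative *full-gene* clinical screen and no
pathogenic panel call in that gene. Design choices worth noting:

* The TN unit is a (sample, gene) pair pooled over the clinical gene
  set (six negative-screen samples over two genes give TN = 12, and
  with one FP a pooled specificity of 12/13 = 92.3%). Per-individual
  pooling cannot reproduce that arithmetic.
* Only calls whose clinical-significance label is pathogenic (or risk
  factor) break TN status; VUS/benign calls do not.
* A targeted familial-variant test that returns negative never
  establishes a TN — the rest of the gene was not screened.
* Truth-to-call variant matching tolerates indel renaming: identical
  chrom/ref/alt with positions differing by at most the indel length
  are one variant (deletions in short tandem repeats legitimately carry
  several HGVS names).
* Undefined ratios (zero denominators) are NaN, never 0.
* FDR is computed in two modes — all calls, and after the AB ≤ 0.20
  exclusion — because the exclusion is itself part of the validated
  screening criteria.

Class summaries (mean and range of DP and AB per confusion class, the
below-threshold subset, heterozygous high-depth calls, and the
high-confidence set) are arithmetic means reported at the conventional
precision: depth to whole X, proportions to 2 decimals.

## Coverage summaries

Region summaries report the arithmetic mean, quartiles, and percent of
bases ≥ t for t ∈ {1, 10, 20, 50, 100, 250, 500, 1000, 10000}.
Numerical conventions: quartiles use linear interpolation between order
statistics ("type 7", the numpy default); bases absent from the depth
table count as depth 0 (uncovered target bases are real data); panel
aggregation pools the per-base multiset (so the pooled mean is exactly
the length-weighted mean of region means, asserted in tests). Depth
bins are closed-left: [0,100), [100,200), …, [1400,1500), [1500,∞),
labeled `<100` … `>1500`; per-bin threshold percentages are unweighted
means over member regions, and whether per-gene rows pool bases across
samples or average per-sample summaries is resolved in favor of pooling
(the reports say so).

## Exact 2×2 inference

Two-sided Fisher p-values use the minimum-likelihood rule with the
customary 1+1e-7 relative tolerance. The odds ratio is the conditional
MLE — the noncentrality ψ maximizing the Fisher noncentral
hypergeometric likelihood of the observed cell with all margins fixed —
with a 95% CI from inverting the two one-sided exact tests
(P(X ≥ a; ψ_lo) = 0.025, P(X ≤ a; ψ_hi) = 0.025), degenerating to 0/∞
at the support boundary. This is the convention of R's `fisher.test`
and differs from the sample cross-product ratio (18.0 vs 16.82 on the
benchmark's 22/1 vs 11/20 table). Implementation: scipy's
`fisher_exact` and `contingency.odds_ratio`; an independent grid-search
maximizer of the noncentral hypergeometric log-likelihood (dense in
log ψ ∈ [−15, 15], refined twice) cross-checks the estimate in tests to
1e-3 relative on 200 random tables. scipy's root finder resolves CI
bounds slightly more tightly than R's uniroot default (upper bound
823.7 vs 819.7 on the benchmark table, a 0.5% difference at an extreme
bound where the CDF is nearly flat).

Carrier frequency: for heterozygous carriers, carriers / 2N (each
carrier contributes one of 2N alleles); a counted-alleles mode accepts
homozygotes.

## Synthetic-data generator

The generator emulates the study conditions of a 43-sample
(23 AA / 20 EA), 10-gene, 225-region screening:

* **Depth.** Region mean depth ~ LogNormal(ln 675, 0.6), giving an
  expected panel mean ≈ 808X with the long right tail and wide IQR a
  HaloPlex capture shows. Per-base noise is AR(1) on the log scale
  (coefficient 0.9, stationary sd 0.25) with independent per-base
  dropout (default 0.01), so deeply covered regions still contain
  uncovered bases. A per-sample log-normal factor (sd 0.3) models
  capture-efficiency variation. No published generative model exists
  for these data; these laws were chosen once to match the published
  summaries (mean, IQR, uncovered fraction) and are not tuned further.
* **Genotypes.** Planted variants carry per-group MAFs; genotypes are
  drawn under Hardy–Weinberg by default (`all_het`/`all_hom` schemes
  exist for controlled experiments). Heterozygote alt depth is
  Binomial(DP, 0.5) with no reference-bias skew — the published data
  give only summary means, so the unbiased law is assumed; homozygote
  alt depth equals DP. Calls are emitted when DP reaches the caller
  emission threshold (default 8 reads) with at least one alt read.
* **Artifacts.** Per-region Poisson counts (default rate 0.02 per
  region cohort-wide), depth ~ DiscreteUniform[12, 63] and
  AB ~ Beta(2, 4) truncated to (0.05, 0.70) — calibrated to the
  observed false-positive depth range 12–63X and AB range 0.13–0.68 —
  with an optional designated region receiving a clustered extra
  Poisson load (the PTEN/PTENP1 pseudogene-homology pattern).
* **Truth.** Sanger truth equals ground truth (planted variants
  confirm, artifacts fail); a configurable fraction of samples carries
  full-gene clinical screening records, positive where a pathogenic
  variant was planted.
* **Determinism.** All randomness flows from the master seed through
  named `SeedSequence` substreams (one per file type, sub-keyed by
  region/sample index): identical configs are byte-identical, and
  adding samples does not perturb earlier draws. Ancestry is a bare
  categorical label — group-specific MAFs only, no population
  structure.

What passing tests on synthetic data do *not* show: the generator has
no read-level error model, no mapping or duplicate structure, no
reference bias, no multi-allelic sites, and its artifacts are
independent of local sequence context. Results on real panels depend
on exactly those properties; the synthetic recovery tests demonstrate
the correctness of the bookkeeping and statistics, not panel
performance.

## Problem sizes

The test suite and the acceptance script run the 74-call benchmark
exactly as published, an 11-sample two-gene synthetic cohort for
recovery experiments, 10,000 simulated region profiles for the
depth-law check, and 200 random 2×2 tables for the CMLE oracle sweep —
sizes chosen so each check is statistically informative while the whole
suite completes in well under a minute.

## Known limitations

* The benchmark's clinical truth assigns the six negative full screens
  to named samples; the published record fixes only their count, so the
  assignment is a reconstruction (any six non-positive samples give the
  same metrics).
* BED6 cannot carry exon substructure, so targets read from BED support
  positional filtering only via call-level boundary annotations.
* Specificity requires full-gene clinical truth and is therefore
  undefined (NaN) for genes without it, as in the benchmark's eight
  non-BRCA genes.
* The exact-test CI convention reproduces R's `fisher.test`; other
  conventions (mid-p, score intervals) are not implemented.
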