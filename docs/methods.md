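# Methods

This note documents the statistical models, parameter defaults and
design choices behind `vitivar`, and what the synthetic-data tests do
and do not demonstrate about real data.

## The error model the pipeline targets

A cohort genotyped against a single reference genome mixes two regimes.
Reference-like samples (the `vinifera` stratum) map cleanly; divergent
samples (interspecific `hybrid` cultivars, `wild` relatives) carry
haplotypes whose reads are under-captured, so a true heterozygote is
emitted as a homozygous call while its AD field retains the
minor-allele reads. The pipeline's core quantity, allele balance,

    AB = 100 · min(AD_ref, AD_alt) / (AD_ref + AD_alt),

is the read percentage of the less-supported allele. One threshold
(30%) yields two coherent rules: a called het with AB < 30 has too few
reads on one allele to be credible and is set to missing; a called
homozygote with AB > 30 still carries substantial minor-allele reads
and, in a divergent-taxon sample, is converted to a het. AB is defined
as the *minor*-read fraction (not the alternate-read fraction): this is
the only reading under which both rules are monotone in a single
quantity at the same threshold value. The definition is isolated in
`ab.compute_ab` so a dialect switch could be added.

Conversion is restricted to the divergent strata (`eligible_groups =
{hybrid, wild}`): in reference-like samples the same signature occurs
at a basal rate and is treated as noise, not corrected. Both AB rules
are guarded by a minimum informative depth `min_dp_for_ab = 15`,
aligned with the genotype-level DP filter, because AB on a handful of
reads is dominated by binomial noise. Converted genotypes get GT = het
with AD/DP untouched; no phasing is asserted.

## Filter chain

Order: hard filters → biallelic selection → per-sample depth mask →
stage-1 missing-rate filter (30%) → AB correction → stage-2 filters
(missing rate 10%, MAF 5%, non-reference allele count ≥ 1).

* All inequalities are strict exactly as written; boundary values pass
  (QD = 3.0 survives, AB = 30 is neither filtered nor converted, DP =
  4× the sample mean survives).
* An absent (unset) annotation never triggers its filter; unset counts
  are reported so a caller can audit them.
* The "> 4× per-sample mean depth" rule masks the individual genotype
  rather than removing the site: the signal is sample-local (a repeat
  in one genome), and the downstream missing-rate filters remove sites
  masked in many samples.
* The cohort-total minimum depth (DP < 200) is calibrated for a
  33-sample panel; `FilterThresholds.scaled_for(n)` rescales it as
  200·n/33, and the default pipeline applies that scaling. The raw
  value is used when thresholds are passed explicitly, so hand-built
  tests see the printed numbers.
* Genotype-level DP < 15 masking happens inside `hard_filter` and
  never fails a site.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes;
its defaults are the study conditions for every end-to-end test.

* **Panel**: 20 vinifera + 8 hybrid + 2 wild samples, 15 of the
  non-wild samples carrying seedless-compatible trait genotypes;
  5 chromosomes of 1 Mb (a deliberately scaled-down genome; windows
  and flanks keep their real-data sizes so coordinate logic is
  exercised unchanged).
* **Allele frequencies**: per-stratum Beta distributions —
  vinifera Beta(0.4, 2.6) (rare-skewed), hybrid Beta(0.8, 1.2), wild
  Beta(1.0, 1.0) — chosen to span rare-to-common variants with two
  parameters and to make divergent strata carry more non-reference
  variation, as expected from their phylogenetic distance.
* **Heterozygosity**: hybrid/wild genotype draws inflate the het
  probability by `het_excess_hybrid = 1.3`, with hom probabilities
  adjusted so the allele frequency stays unbiased.
* **Depths**: per-sample mean depths Uniform(37, 65)×; per-genotype DP
  is negative-binomial around the sample mean with dispersion 0.01
  (variance μ + 0.01 μ²), matching the tight depth distributions of
  PCR-free high-depth libraries; dispersion → 0 recovers Poisson.
  Repeat tracts (8% of the genome in 5-kb tracts, kept clear of trait
  windows) multiply the *mean* by 6, so repeat genotypes are reliably
  above the 4× mask threshold.
* **Reads**: alt-read counts are Binomial(DP, p) with p = 0.5 for true
  hets and p = seq_error (0.005) or 1 − seq_error for homozygotes.
* **Dropout**: with per-stratum probability (vinifera 0.002, hybrid
  0.15, wild 0.25) a true het's emitted GT becomes the majority-read
  homozygote while AD is left intact — exactly the signature the AB
  conversion targets. Real data report only totals per accession with
  the ordering wild ≥ hybrid ≫ vinifera; the defaults reproduce that
  ordering, and rates are configurable.
* **Trait architecture**: one dominant regulator and three recessive
  loci on distinct chromosomes (independent inheritance), at the
  chromosome centres. Seedless samples are het at the regulator and
  hom-alt at the recessive loci; seeded samples are hom-ref at the
  regulator, so no non-seedless sample satisfies the rule. Sites
  within 50 kb of a trait locus copy the locus genotype in seedless
  samples with probability 0.9, planting the shared founder haplotype
  that region trees and the F_ST scan should detect.
* **Annotations**: INFO fields are drawn to pass the hard filters; a
  planted fraction (1% per rule, applied to QUAL/QD/FS/MQ/MQRankSum
  and excluding trait windows) fails each filter. Site DP is the true
  genotype-depth sum, so the DP filter sees real depth.
* Identical parameters and seed give byte-identical output files.

What the generator does **not** emulate: background linkage
disequilibrium away from trait loci (LD-decay realism is exercised by
purpose-built constructions in the tests instead), indels, multiallelic
sites (hand-built records cover those code paths), mapping artifacts
beyond depth inflation, and caller-specific annotation distributions.
Passing tests therefore demonstrate correctness of the *rules* under a
controlled error model, not calling accuracy on any particular
sequencing panel.

## Population summaries

* **p-distance**: for two unphased diploid genotypes the similarity is
  the shared-allele fraction (0, ½, 1), i.e. 1 − |dosage₁ − dosage₂|/2;
  distance is one minus the mean over jointly called sites (pairwise
  deletion). External tree programs do not document their heterozygote
  coding; this definition is symmetric, metric on genotypes, and
  reduces to the classical p-distance for homozygous sequences, but
  global branch lengths are not expected to match any specific external
  program numerically.
* **Neighbor joining** is the canonical Saitou–Nei agglomeration on the
  Q-criterion, implemented in-package (and cross-checked against an
  independent implementation in the tests). Negative branch-length
  estimates are clamped to zero with the deficit moved to the sister
  edge, preserving the joined pair's total length; this affects only
  degenerate matrices. On additive input the tree reproduces the matrix
  to 1e−9.
* **Bootstrap** resamples sites with replacement (implemented as
  multinomial site weights over precomputed per-pair difference/validity
  sums, which makes 1000 replicates cheap); an internal edge's support
  is the percentage of replicate trees containing the same bipartition.
  A pair with no jointly called site in a replicate is assigned the
  maximal distance 1.
* **LD**: r² is the squared Pearson correlation of 0/1/2 dosages over
  pairwise-complete samples, averaged in 100-bp distance bins;
  monomorphic pairs are undefined and skipped. The half-decay distance
  is the first bin midpoint at or below the midpoint of the binned
  curve's range — an explicit, configurable definition, since
  "half-maximum" is otherwise ambiguous about its baseline.
* **F_ST**: two-population Weir–Cockerham (1984) variance components
  a, b, c per SNP from sample sizes, allele frequencies and observed
  heterozygosities; windows (100 kb, 10-kb step, BED coordinates on
  output) use the ratio-of-sums estimator Σa / Σ(a+b+c). Per-site
  ratios are biased at small n; the window ratio-of-sums is the
  estimator calibrated against the identical-frequency null in the
  tests. Sites monomorphic across both populations contribute nothing.

## Association

The per-SNP association is a documented stand-in for a logistic mixed
model with kinship: it exposes the same interface (−log10 P per SNP,
binary seeded/seedless phenotype) with two methods. `fisher` (default)
is the two-sided exact test on the 2×2 allele-count table — exact and
assumption-free at a few dozen samples, conservative under the null.
`logistic_score` is a Rao score test for adding the dosage to a null
logistic model with optional covariates (e.g. principal components)
for structure correction; pseudoinverses make collinear covariates a
no-op. Because no kinship matrix enters, published mixed-model −log10 P
values are interface anchors, not reproduction targets. Monomorphic
sites report p = 1.

## Inheritance model and classification

Phenotype rule: seedless iff the regulator genotype is het or hom-alt
AND at least `min_recessive_hom = 2` of the recessive loci are hom-alt;
a missing genotype at any model locus makes the phenotype
undetermined (an error, not a default).

`dominant_consistency` is TRUE iff every *called* seedless genotype
carries the alternate allele and every *called* seeded genotype is
reference homozygous; missing genotypes are ignored and can never
break consistency (the test is monotone in missingness).

Group triage of deleterious SNPs, given an association result:

1. −log10 P ≤ 2.5 → **Group III** (excluded from consideration; the
   boundary value goes to III, since membership of I/II requires a
   value *above* the threshold);
2. else count c = seedless hom-alt genotypes (missing counts as
   non-hom-alt; no imputation is performed, a documented deviation from
   workflows that impute first — both readings are representable since
   the counts are reported): c > 10 (of 15) → **Group I**, the
   recessive-locus pattern;
3. else a site passing `dominant_consistency` → **dominant_consistent**,
   the regulator pattern (checked after the count rule so that a site
   recessive-homozygous in nearly all seedless samples is classified
   as Group I even when no seeded sample carries the allele);
4. else **Group II**. A count of exactly 10 falls to Group II — the
   literal "more than 10"/"less than 10" wording leaves 10 unassigned
   and the conservative side is taken; the threshold is configurable
   and rescales as round-half-up(10 · n_seedless / 15) for other cohort
   sizes.

Sweep peaks take the top 0.5% of scan windows by score (ties broken by
genome order), merge overlapping/adjacent selections, and report the
centre of each run's maximum window with a ±50-kb flank. The scan
feeding the peaks is the implemented F_ST statistic; the peak selector
accepts any per-window score column. Deleteriousness is consumed as an
input flag (an external predictor's call); the simulator plants flags
at trait loci.

## Numerical and degenerate-input choices

* Strict inequalities throughout; ties documented above.
* RNG is NumPy PCG64 seeded per run; all stochastic functions accept a
  seed and are deterministic given it.
* The Fisher p-value is clamped into (1e−300, 1] before taking logs.
* NJ tie-breaks (equal Q values) resolve to the lexicographically
  first index pair, making topologies deterministic.
* Empty call sets round-trip as header-only VCFs; an empty site list
  is a valid input to the filters and an error for the simulator.
* The bundled sweep-SNP panel (`vitivar.datasets`) is a synthetic
  reconstruction: printed facts (region bounds, per-group counts, the
  dominant-site genotype pattern and position) are encoded exactly;
  unprinted details (exact positions of unnamed SNPs, which seeded
  accessions carry hets) are invented deterministically. It validates
  the classification rules on a realistic table; it is not measured
  data.

## Problem sizes

Default test and acceptance sizes are chosen for single-CPU runs:
cohorts of ~1,500–4,000 SNPs × 28–30 samples, a 5-Mb genome, 100
end-to-end replicates, 10,000-site null panels for F_ST/LD/association
calibration, and 50 random additive trees for NJ. All sizes are
parameters; nothing in the implementation depends on them.

## Known limitations

* Two-population F_ST only (the r-population generalisation is a
  mechanical extension of the component formulas).
* No haplotype phasing, imputation, or kinship correction; the
  association stand-in does not reproduce mixed-model P values.
* Multi-allelic sites are carried through I/O and removed by biallelic
  selection, but AB and all downstream statistics assume biallelic
  SNPs.
* The p-distance heterozygote treatment is one defensible convention
  among several; comparisons with external tree programs should be
  topological, not metric.
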