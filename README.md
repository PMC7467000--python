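# vitivar

Variant post-processing and population genomics for **highly diverse
diploid cohorts** — panels that mix reference-like cultivars with
interspecific hybrids and wild relatives, the situation of grape
(*Vitis*) resequencing panels genotyped against a single *V. vinifera*
reference.

## The problem

When samples diverge strongly from the reference genome, reads from the
divergent haplotype of a heterozygous site are under-captured and the
caller emits a **homozygous** genotype even though the allele depths
(AD) still carry the minor-allele reads — *allele dropout*. In a mixed
cohort this error is concentrated in the hybrid/wild samples and
silently erases exactly the variation those samples were sequenced for.

`vitivar` implements a post-calling pipeline built around a single
diagnostic, the **allele balance**

```
AB = 100 · min(AD_ref, AD_alt) / (AD_ref + AD_alt)
```

(the read percentage of the less-supported allele): a called
heterozygote with AB < 30 is implausible and is filtered to missing,
while a called homozygote with AB > 30 in a divergent-taxon sample is
the dropout signature and is **converted back to a heterozygote**.
Around that core sit:

* GATK-style **hard filters** (SNPs: MQRankSum < −12.5, QUAL < 30,
  QD < 3.0, FS > 30.0, MQ < 30.0, total DP < 200; indels:
  ReadPosRankSum < −20.0, QUAL < 30, QD < 2.0, FS > 200, DP < 200; a
  genotype-level DP < 15 mask), biallelic selection, a per-sample
  high-depth mask (> 4× the sample's mean mapped depth flags repeat
  artifacts) and missing-rate/MAF population filters;
* **call-set comparison**: per-sample genotype concordance at shared
  coordinates and validation rates against a truth set (missed calls
  count against the rate);
* **population summaries**: neighbor-joining trees on diploid
  *p*-distances with pairwise deletion and site-bootstrap supports,
  100-kb region trees around candidate loci, r² LD decay in 100-bp
  bins with a half-decay distance, and a 100-kb/10-kb sliding-window
  **Weir–Cockerham F_ST** scan (ratio-of-sums estimator);
* **trait machinery** for Sultanina-type stenospermocarpic
  seedlessness: the inheritance rule (one completely dominant regulator
  gating three complementary recessive loci, of which ≥ 2 must be
  homozygous recessive), per-SNP Fisher-exact / logistic-score
  association, dominant-consistency testing, Group I/II/III triage of
  deleterious SNPs, sweep-peak selection and a candidate-gene report;
* a **synthetic cohort generator** that plants all of the above —
  stratified allele frequencies, dropout errors, repeat-depth
  artifacts, trait loci with linked founder haplotypes — with full
  ground truth, so every stage is testable end to end without any
  sequencing data.

## Worked example

`examples/02_allele_balance_recovery.py` simulates a 30-sample cohort
(20 reference-like, 8 hybrid, 2 wild samples; ~4,000 SNPs; mean depths
37–65×) with a 20% hybrid dropout rate and measures the correction
against ground truth:

```
dropout heterozygotes (eligible, depth >= 15): 3334
restored to het by AB > 30 conversion:          3309 (99.3%)
true homozygotes falsely converted:             0 (0.000%)
truth concordance: 97.20% before -> 99.95% after correction
```

3,334 true heterozygotes were emitted as homozygous calls by the
planted dropout process; the AB rule recovers 99.3% of them, never
touches a clean homozygote, and lifts mean genotype concordance with
the truth from 97.2% to 99.9%. The other example scripts cover the QC
chain (`01`), trees/LD/F_ST (`03`) and the full seedlessness
classification, which recovers the planted dominant locus as
`dominant_consistent` and the recessive loci as Group I (`04`).

A thin CLI mirrors the library:

```bash
vitivar simulate --out-prefix cohort --seed 7
vitivar filter --vcf cohort.vcf --samples cohort.samples.tsv --out filtered.vcf
vitivar abcorrect --vcf filtered.vcf --samples cohort.samples.tsv --out corrected.vcf
vitivar fst --vcf corrected.vcf --samples cohort.samples.tsv --out fst.tsv
```

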