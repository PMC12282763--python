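# chipcall

Sensitive discovery of **CHIP** (clonal hematopoiesis of indeterminate
potential) mutations from standard-depth whole-exome and whole-genome
sequencing alignments.

## The problem

CHIP is the presence of somatic mutations in leukemia-associated driver genes
(*DNMT3A*, *TET2*, *ASXL1*, *TP53*, ...) in the blood of individuals without a
hematologic malignancy, at variant allele fraction (VAF) ≥ 2%. It predicts
elevated risk of hematologic cancers and cardiovascular disease, so screening
population-scale WES/WGS for it is valuable — but at 30–100× coverage a 2–5%
VAF clone is supported by only a handful of reads, and conventional somatic
callers discard most of them. `chipcall` is built for researchers who want to
repurpose existing cohort WES/WGS for CHIP screening without deep targeted
sequencing.

## The method

The workflow trades single-caller precision for ensemble recall and lets a
classifier do the cleanup:

1. **Permissive tracking.** A pileup engine scans coordinate-sorted
   alignments and reports *every* site with alternative-allele evidence —
   down to one supporting read (base quality ≥ 13, ≤ 1000 reads tallied per
   position), together with read-level attributes: alt/total depth, strand
   split, mean mapping and base quality of alt reads, proximity to indels,
   position-in-read. Multiallelic sites keep the best-supported allele
   (seeded random tie-break); MNPs are split into SNVs and indels are
   left-normalized to parsimonious VCF form.
2. **Meta-calling.** Call sets from the tracker and external callers are
   merged on normalized variant keys; each merged call carries a *calling
   status* — the number of callers (1..3) that found it. Status is one of
   the strongest single predictors of a true call.
3. **Classification.** Each functional call (missense, nonsense, frameshift,
   splice, ...) is converted into a fixed feature vector — 26 features for
   SNVs, 24 for indels — covering calling status, quality metrics, sequence
   context (homopolymer runs, short tandem repeats, low-complexity regions,
   GC), germline-database frequencies and somatic-catalogue membership. A
   gradient-boosted-tree or random-forest model assigns
   CHIP / GERMLINE / ARTIFACT, trained separately per data type (WES / WGS)
   and variant type. Evaluation is one-vs-rest on the 3×3 confusion matrix:
   precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP),
   F1 = 2·P·R/(P+R), accuracy (TP+TN)/N.
4. **Refinement.** Known CHIP mutations predicted non-CHIP but seen by ≥ 2
   callers are rescued for review; calls above 30% VAF revert to germline
   unless in one of the five genes where germline variants are essentially
   absent (*DNMT3A*, *ASXL1*, *TET2*, *PPM1D*, *JAK2*). Cohort-level filters
   then remove common germline variants (MAF ≥ 0.3% in any of four
   databases), single-caller calls in low-complexity regions, and variants
   recurring in ≥ 8% of subjects; survivors need ≥ 2% VAF and a
   somatic-catalogue match.
5. **Credible intervals.** A hierarchical two-component model scores each
   CHIP call: the alt count is either background error,
   k ~ BetaBinomial(n, α, β) with (α, β) fitted per site from a reference
   panel of young healthy subjects, or a true clone, k ~ Binomial(n, θ) with
   θ ~ Beta(1, 1) truncated to (0.5%, 50%). The posterior clone probability
   uses the panel's CHIP incidence as prior; the 95% credible interval for θ
   comes from the truncated conjugate posterior.

A spike-in simulator (reference genomes with valid ORFs, reads with
sequencing error, per-read Bernoulli conversion to target VAFs, mock
external callers with VAF-dependent sensitivity) makes the whole chain
testable end to end with known ground truth.

## Worked example

Simulate a genome with 10 CHIP-like SNVs spiked at 10% VAF into 60× reads,
track it, and score against the truth:

```sh
$ chipcall simulate --out-prefix sim --mean-depth 60 --n-spikes 12 --target-vaf 0.1 --seed 4
[chipcall] WARNING wrote sim.{fa,bed,genes.tsv,sam,truth.tsv}
$ chipcall track --alignments sim.sam --fasta sim.fa --out-vcf sim.tracker.vcf
[chipcall] WARNING tracked 177 candidate variants -> sim.tracker.vcf
$ chipcall evaluate --calls-vcf sim.tracker.vcf --truth sim.truth.tsv
{"recall": 1.0, "precision": 0.06779661016949153}
```

The tracker recovers every spiked variant (recall 1.0) at the price of many
single-read candidates (precision 0.07) — exactly the trade the classifier
is there to repair: train one on the synthetic feature table
(`chipcall featurize` → `chipcall train`) and `chipcall run` keeps the
spiked variants while discarding the noise.

For one call with 8 alt reads of 100 against a background error Beta(1, 999)
and 5% prior clone incidence:

```sh
$ chipcall ci --alt-count 8 --depth 100 --alpha 1.0 --beta 999.0 --pi 0.05
{"posterior_chip": 0.9999968539419238, "ci95": [0.04155947105959735, 0.15011620104895154]}
```

The clone is near-certain; its size is between ~4% and ~15% VAF.

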