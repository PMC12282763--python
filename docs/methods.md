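# Methods

This note records the models, parameter choices and numerical decisions
behind `chipcall`, and what the synthetic data used in its tests does and
does not establish about real sequencing data.

## Variant representation and normalization

All modules exchange variants in VCF convention: 1-based position of the
first REF base, anchored alleles for indels. Canonical form is reached by
(1) splitting multi-nucleotide substitutions into their mismatching
per-position SNVs, then (2) left normalization: trim shared trailing bases
(extending leftward through the reference whenever an allele would empty),
then trim shared leading bases down to the single anchor. SNVs are fixed
points; re-application is a no-op. Normalization happens *after*
multiallelic resolution: the tracker first picks one alt allele per site,
then canonicalizes, so the merge key is always one (chrom, pos, ref, alt)
tuple. Symbolic and breakend alleles are rejected; structural variants are
out of scope. Normalization windows carry 50 bp of upstream context —
ample for the repeat lengths the simulator plants; running off a window
raises an explicit truncation error rather than silently under-shifting.

## The permissive tracker

A single-pass pileup engine replaces the usual two-stage
candidate-then-genotype chain: one traversal of the coordinate-sorted reads
computes, per position, the allele tallies *and* the evidence attributes the
classifier needs. Parameters:

| parameter | default | meaning |
|---|---|---|
| `min_base_quality` | 13 (Phred) | bases below this do not count as alt evidence |
| `depth_cap` | 1000 | max reads tallied per position, first-come in stream order |
| `min_mapq` | 0 | mapping-quality floor; permissive by default |
| `min_alt_reads` | 1 | single-read candidates are reported |

Duplicate, secondary, supplementary and QC-fail reads are excluded;
improper pairs are kept. Indel alleles come from the CIGAR, anchored at the
preceding reference base; a deletion of length L at position p becomes
REF = ref[p..p+L], ALT = ref[p]. A site is flagged `spans_indel` when any
tallied read carries an indel within ±5 bp — the window is a design choice
capturing alignment-shadow artifacts and is exposed in the module constants.
Depth-cap selection is deterministic (stream order), not random
subsampling, so identical inputs give identical pileups. At multiallelic
sites the most-supported allele wins; exact ties are broken by a seeded
uniform draw keyed on (seed, position), reproducible across runs.

## Merging and calling status

Call sets are merged on normalized keys. Within one caller, duplicate keys
collapse to the record with the most supporting reads before merging, so
status counts callers, not records. Per-caller counts are all retained;
`best_evidence` (max alt reads) feeds the feature vector — the package
makes no attempt to reconcile conflicting VAF estimates across callers.
Merging is allele-aware; spike-in truth matching is deliberately
position-only (allele-agnostic), a different equivalence chosen to mirror
how spike-in benchmarks are scored.

## Feature schema

SNV vectors have 26 features, indel vectors 24 (the SNV set minus
`is_transition`, `base_change_class`, `mean_read_pos_fraction`, plus signed
`indel_length`). The exact list lives in `feature_annot.SNV_FEATURES` /
`INDEL_FEATURES`; a SHA-256 prefix of the joined names is embedded in every
model bundle and re-checked at prediction time, so train/predict schema
drift is a hard error. The schema is a reconstruction organized around the
feature categories that matter for this problem — calling status, quality
metrics, genomic context, database overlap — with the highest-importance
features (status, mapping quality, VAF, catalogue membership, germline MAF,
repeat context) individually represented. Missing database entries encode
as 0. Consequence classes use a fixed ordinal encoding (noncoding = 0 …
frameshift = 8); tree models ignore the ordering but need determinism.
The consequence annotator is a minimal codon-based translator over a
supplied transcript table: intronic positions within 2 bp of an exon
boundary are essential-splice; coding indels are frameshift unless length
≡ 0 (mod 3); in-frame indels count as functional. COSMIC-style catalogue
matching is exact-key for SNVs and position+type+length for indels — no
fuzzy matching.

## Classifier

Gradient-boosted trees (xgboost) and random forest (scikit-learn) behind
one sklearn-compatible estimator. Pinned defaults — gbt: 300 trees, depth
6, learning rate 0.1; rf: 500 trees, sqrt features — because grid-search
tuning on this problem yields negligible gains; a `tune=True` path with
k = 5 cross-validation exists for completeness. Training uses a stratified
80/20 split; row membership is made content-based (a canonical sort before
the seeded split) so input order cannot change the split. Single-member
classes go to the training side. Classes absent from training are handled
by re-encoding to contiguous codes and expanding predicted probabilities
back to the fixed three columns. Ties in argmax resolve to the first class
in the fixed order (CHIP, GERMLINE, ARTIFACT). Metrics are one-vs-rest
reductions of the 3×3 confusion matrix; division-by-zero cases return NaN
with the metric named, rather than a silent 0. Feature importance is
normalized split gain (xgboost `gain`; Gini importance for rf).

## Refinement, cohort filters, credible intervals

Rescue and reversion rules are applied in this order: the VAF bound first
(a call above 30% VAF reverts to germline, or is held for review in
*DNMT3A*, *ASXL1*, *TET2*, *PPM1D*, *JAK2*), then known-CHIP rescue
(non-CHIP prediction + known mutation + ≥ 2 callers). A CHIP prediction at
≤ 30% VAF is never demoted.

Cohort filters run in fixed order with per-rule tallies that conserve
counts: (1) germline MAF ≥ 0.3% in any of the four databases; (2)
"low-confidence in low-complexity region", operationalized as calling
status 1 (single caller) inside a low-complexity interval — the notion of
low confidence is not standardized, and status 1 is the recorded choice;
(3) recurrence in ≥ 8% of subjects, counting subjects with *any* CHIP-class
call; then retention requires VAF ≥ 2% (and ≤ 30% outside the privileged
genes) plus catalogue membership, with an optional driver-mutation
restriction. Order effects are auditable from the tallies.

The credible-interval model is a two-component mixture committed as this
package's design: background error k ~ BetaBinomial(n, α, β) versus clone
k ~ Binomial(n, θ), θ ~ Beta(a₀=1, b₀=1) truncated to (0.005, 0.5), mixed
with prior clone probability π. The Beta background is fitted by method of
moments from reference-panel counts, subtracting the binomial sampling
variance m(1−m)·E[1/n] before solving for the concentration (without this
correction the pseudocount floor α, β ≥ 0.5 distorts the fitted mean);
sites seen in ≥ 2 panel subjects get per-site fits, others fall back to
gene-level then global fits. π is the fraction of panel subjects carrying a
retained CHIP call, floored at 1/(2·n_panel). The posterior clone
probability is computed on the log-odds scale (exact where the probability
saturates at 1.0 in floats); the 95% interval holds the 2.5/97.5% quantiles
of Beta(1+k, 1+n−k) re-truncated to the prior support. Monte-Carlo checks
at θ = 0.05, n = 1000 put empirical coverage within 95% ± 2.5%. A
hierarchical variant with gene-level incidence strata would be a natural
refinement; the committed model keeps one global π.

## The simulator and what tests show

The simulator emulates the study conditions end to end: a single-contig
reference with valid ORFs named after recurrent CHIP driver genes (one
two-exon transcript, one minus-strand gene, codon-aligned homopolymer and
AC-repeat tracts planted inside a CDS), single-end 100 bp reads at uniform
coverage with per-base error 0.001 and planted germline het/hom variants
(~50%/100% VAF), and per-read Bernoulli conversion at the target VAF with
minimum site depth m = 2 — sites below m are skipped and recorded.
Per-read conversion (not exact count targeting) reproduces the documented
behaviour of read-level mutation engines: realized VAFs scatter binomially
and sit below target at low depth. The uniform spike series is the 13
levels 0.5%, 1–10% by 1%, 20%, 30%; the CHIP-specific mode draws targets
from a log-normal calibrated to median 12.5% (SNV) / 14.8% (indel), σ = 0.7
on the log scale, clipped to (0.5%, 95%]. Mock external callers detect
spiked variants with VAF-binned sensitivities (a precise assembly-like
archetype weak below 10% VAF; a heuristic archetype sensitive at moderate
VAFs), require ≥ 2 supporting reads, and add Poisson false positives per Mb.

The synthetic feature tables used to train desk-scale classifiers draw each
row from the generator of an *effective* class — the true label with
probability `separation`, else a uniformly random class — so separation 0
is exactly uninformative (holdout accuracy ≈ the largest class fraction)
and separation 1 expresses the archetypes fully: CHIP = low VAF,
multi-caller status, clean context, frequent catalogue membership;
GERMLINE = VAF near 0.5/1.0 with population MAF; ARTIFACT = single-caller,
1–2 supporting reads, a mixture of low-quality alignment artifacts and
high-quality sequencing-noise singletons.

What passing tests establish: the arithmetic and bookkeeping of every
stage, exact agreement of tracker counts with brute-force recounts,
normalization correctness against an enumeration oracle, interval coverage
under the model's own assumptions, and that the full chain recovers ≥ 80%
of spiked functional SNVs at ≥ 5% VAF and 100× depth with monotone recall
across the VAF series. What they do not establish: performance on real
reads (mapping artifacts, PCR duplicates, capture bias, platform error
profiles are not simulated), absolute cohort-scale precision, or
transferability of a synthetic-trained model to real data — on real
cohorts the classifier should be trained on labeled calls from comparable
data, exactly as the pipeline's `train` command supports.

## Problem sizes

Test and acceptance runs use desk-scale instances chosen to make the
statistics decisive while keeping the suite quick: ~2.8 kb references with
6 genes, 80–200× simulated coverage, 3000-row feature tables, 500-rep
coverage simulations, 10⁴ random variants for normalization properties,
and 21 × 14 toy spike-in batches for the bookkeeping check.
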