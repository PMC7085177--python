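# Methods

This note documents the models, conventions and design choices behind
`dwmeta`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, which knobs
matter, and what the synthetic tests do and do not establish.

## Scaffold decontamination

Coverage statistics are carried per scaffold under three read sets: true
samples (S), contaminant reads (C; negative-control reads not explained by a
spiked mock community) and the full negative-control read set (NC). Relative
abundance normalizes a scaffold's mean depth by the summed depth of its
co-assembly under the relevant denominator read set — note the asymmetry
that `RA_C` uses the NC total as denominator, so `RA_C` values need not sum
to 1. Normalized coverage deviation (NCD) is the per-base depth SD over the
mean depth, a coverage-evenness statistic: reagent contaminants typically
show patchy coverage in samples and even coverage in blanks.

Conventions chosen where the classification rule is silent:

* **NCD of a zero-coverage scaffold is +inf**, so it can never win a
  "lower NCD" comparison; a scaffold with no reads carries no evenness
  evidence.
* **A scaffold covered by neither S nor C** fires both the `RA_C = 0` (true)
  and `RA_S = 0` (contaminant) branches; it is labeled *ambiguous* and
  excluded. Uninformative scaffolds should not enter profiles either way.
* **Tuples matching no branch** (e.g. higher RA but also higher NCD in
  samples) are ambiguous and excluded — exclusion is the conservative
  reading of "keep only scaffolds that pass the true branch".
* **Pooling.** The S statistics pool all samples of one system's
  co-assembly: pooled depth is the sum of per-sample depths and pooled
  variance the sum of per-sample variances (independent per-position
  contributions). Depth SDs are population SDs; the n−1 correction is
  unstable on short scaffolds and the choice cancels in NCD comparisons at
  equal convention.
* RA and NCD are invariant under any joint positive rescaling of all
  coverages, so classification is unit-free (verified by property test).

Classification runs within each system's co-assembly independently. N50 is
the smallest length L such that scaffolds of length ≥ L cover at least half
the assembly; assembly GC is length-weighted.

## Taxonomic and functional profiles

The SSU RPKM uses read counts reconstructed from depth
(`reads = cov × L / L_read`, nominal read length 250 bp — the generator
supplies coverage, not alignments), divided by scaffold length in kb and
total mapped sample reads in millions; relative abundance renormalizes RPKM
across the SSU-bearing scaffolds of the sample. The total-read factor
cancels in that normalization, so the profile is insensitive to it.
Deduplication keeps the longest SSU gene per scaffold, ties broken by
lexicographic hit id for determinism.

KO retention reads "detected more than once across samples within a single
system" as *detected in ≥ 2 samples of the system* (not ≥ 2 ORF copies),
with detection meaning the KO sits on at least one scaffold exceeding 1×
coverage in that sample. A KO's count sums over its host scaffolds; a KO
annotated by several ORFs on one scaffold counts that scaffold once. The KO
RPKM divides by the summed host-scaffold length within the system.

Module definitions use a flat grammar mirroring KEGG DEFINITION lines:
whitespace separates sequential blocks, commas separate alternatives, `+`
joins complex subunits, parentheses one level deep group alternatives
(`(K1,K2)+K3` expands to `K1+K3 | K2+K3`). Completeness is the fraction of
blocks with at least one fully present alternative. Module abundance is the
median over the module's *retained* KOs in that sample (absent KOs are
excluded from the median rather than counted as zero; a module with no
detected KO reports abundance 0 with a detected=false flag). Even-count
medians use the mean of the two central values. The comparison filter keeps
modules with ≤ 1 missing block and ≥ 50 % completeness; the differential
test itself (e.g. DESeq2 on the module table) is deliberately out of scope —
the module profile table is its exact input.

## Distances and statistics

**Sketches.** Canonical k-mers (minimum of forward and reverse-complement
2-bit encodings, k ≤ 32, windows containing non-ACGT symbols skipped) are
hashed with an invertible 64-bit mixer (murmur-finalizer style) keyed by a
seed; the sketch keeps the `size` smallest distinct values. The Jaccard
index is estimated from the merged sketch (the smallest `size` values of the
union), and `D = -(1/k) ln(2j/(1+j))`, capped at 1, with `j = 0 → D = 1`.
When the sketch cardinality exceeds the number of distinct k-mers the
estimate is exact, which is how the oracle tests pin the implementation to
brute-force Jaccard enumeration. A minimum-multiplicity filter (default off;
2 is conventional for read sets) drops error-dominated singleton k-mers.
Defaults: k = 21, sketch size 1000 (raise to ~100 000 for real read sets).

**BioEnv.** Variables are z-scored with sample SD; for each of the
`2^n − 1` subsets the Euclidean distance between samples is rank-correlated
(Spearman, average ranks on ties) with the community distances. Constant
variables are excluded with a warning, since they carry no distance
information. The search is exhaustive by design; with the 9 standard water
chemistry variables that is 511 evaluations.

**Group permutation test.** The observed statistic is a one-way ANOVA
F-ratio over the pooled pairwise distances grouped into three classes
(within-D, within-ND, between). The null reshuffles group labels; the
permutation stream draws from a *sorted* copy of the label vector so the
null sequence depends only on the group sizes and the seed, never on sample
order. p = (exceedances + 1)/(n_perm + 1), never exactly 0. This is one
reasonable reading of a "permutational ANOVA on distance distributions"; a
PERMANOVA on the distance matrix itself (scikit-bio) is exposed as
`method="permanova"` and neither is claimed to be canonical. Calibration is
verified empirically: under exchangeable distances the rejection rate at
α = 0.05 stays within binomial error of 0.05 (500 replicates × 999
permutations in the acceptance suite).

**Matrix correlation.** Pearson r over condensed upper triangles; a
sample→system mapping first averages the finer matrix over cross-system
sample pairs, for read-level vs scaffold-level comparisons.

## MAG conventions

Quality thresholds are strict (> 50 % completeness, < 10 % redundancy);
breadth detection (≥ 25 %) and category frequency (≥ 20 %) are inclusive,
following the stated wording of each rule. Detection frequencies pool all
samples of a group rather than averaging per system. RPKM is reported only
where the MAG is detected (masked to NaN elsewhere), because relative
abundance of an absent genome is dominated by spurious cross-mapping.
Genome size is `length × 100 / completeness`.

## The synthetic-study generator

The generator's defaults are the study conditions for all tests: 3 D + 3 ND
systems × 3 samples (18 samples), 24 taxa × 8 scaffolds per taxon per
system, 4 contaminant taxa, 2 negative controls, mean depth 10×, read
length 250 bp, 9 environmental variables, and a log-scale group effect of
2.5 for enriched taxa.

* **Abundances** are log-normal per taxon per sample. Enriched taxa get a
  ± effect/2 mean shift; in disinfected samples the shift scales with the
  sample's chlorine concentration relative to the group mean, so chlorine
  concentration mechanically drives community distances (this is the planted
  analogue of a residual-driven community). ND samples use twice the
  log-scale dispersion (dispersion 0.4 vs 0.8), reproducing the more
  variable, more heterogeneous character of non-disinfected communities.
* **Water chemistry**: chlorine is N(0.37, 0.15) mg Cl2/l in D (clipped at
  0) and exactly 0 in ND; phosphate (2.3 mg PO4/l, dosed for corrosion
  control alongside chlorine) likewise; temperature runs ~5 °C warmer in D;
  the remaining six variables differ mildly or not at all between groups.
* **Contaminants** contribute coverage only to negative controls by default
  (pure-contaminant mode; a leak rate is configurable), with NC coverage
  inflated 25 % above the contaminant-read coverage to keep the RA_C
  denominator distinct from its numerator read set.
* **Coverage** is abundance × depth × multiplicative log-normal noise
  (SD 0.2); depth SDs are stored explicitly (NCD 0.3 for sample read sets,
  0.6 for the patchier contaminant coverage) so NCD is computable without
  re-simulating reads.
* **MAG founders**: two taxa each with hard presence patterns — D-only
  (absent from every ND sample), ND-only, ubiquitous, and rare (one sample
  only) — plus two quality-control decoys that must be discarded before
  detection. Breadth is `1 − exp(−depth)` (the Poisson/Lander-Waterman
  expectation), monotone in coverage by construction.
* **Sequences** are i.i.d. nucleotides at the taxon's GC; per-sample
  fragment sets are drawn in proportion to abundance. This is adequate for
  sketch testing but has no phylogenetic or genomic realism.
* **Determinism**: one root seed with fixed per-table child streams; the
  same config serializes byte-identically, and adding a table never perturbs
  the others.

What passing tests show — and don't. The planted structure makes recovery
*exact* (pure contaminants, hard MAG presence patterns, strong effects), so
the tests validate the bookkeeping and the decision rules, not robustness to
the messiness of real data: partial contamination of true scaffolds,
chimeric assemblies, cross-mapping between related genomes, compositional
noise in SSU copy number, or mis-annotated KOs. Problem sizes (≈1200–2000
scaffolds, 18 samples, 999 permutations, 500 calibration replicates) were
chosen as the smallest at which every planted property is informative.

## Known limitations

* The decontamination rule is taken as printed; scaffolds that are genuinely
  shared between samples and reagents (kit organisms that also live in
  water) violate its dichotomy and land in the ambiguous class.
* KO read-count reconstruction from mean depth ignores within-scaffold
  coverage variation across the ORF itself.
* The pair-class permutation statistic treats pairwise distances as pooled
  observations; distances sharing a sample are dependent, which the
  permutation null accounts for but an asymptotic F-test would not.
* `read_study` restores every table losslessly but not the generator
  configuration beyond its seed.
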