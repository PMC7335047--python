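# Methods

This note records the models, estimators and numerical choices behind each
module, the defaults that matter, and what the synthetic generators do and
do not emulate.

## Expansion detection (`family_evolution`)

The input is a families × species matrix of non-negative copy counts;
absence is encoded as zero, never as missing data. For a focal species a
family is *expanded* when two conditions hold:

1. the **population variance** of the copy profile over all included
   species (focal included) exceeds 2, and
2. the **leave-one-out Z score** of the focal count exceeds 3:
   `z = (c_focal − mean(others)) / max(sd_pop(others), 1)`.

The leave-one-out form is deliberate. With the focal count inside the
mean/sd, a single-species outlier is bounded at `z ≤ sqrt(n − 1)` under a
population sd — at most 2.83 for a nine-species panel — so a `z > 3`
criterion could never fire for species-specific expansions. Excluding the
focal value from the location/scale makes the criterion attainable and
sharp. The sd floor of one copy handles flat backgrounds (sd = 0) without
manufacturing infinite scores; it also means the smallest detectable
excess over a flat background of mean m is `m + 3` copies. Species whose
ploidy distorts counts (e.g. an allodiploid) can be excluded from the
comparison entirely. All three constants (variance cutoff, z cutoff, sd
floor) are keyword-configurable.

Phylostratification assigns each family the deepest taxonomy stratum
shared by every species with ≥ 1 copy, computed as the longest common
prefix of root-to-leaf lineage paths; a family confined to one species
receives that species' leaf stratum (species-specific). Genes inherit
their family's age.

## Duplicate typing (`duplication`)

*Tandem arrays* are maximal transitive chains of same-family, same-scaffold
genes with rank gaps ≤ `tandem_gap` (default 15, read as rank difference
≤ 15). *Collinear blocks* are chains of ≥ `min_anchors` (default 3) anchor
pairs; an anchor pair is two same-family genes on an ordered scaffold pair
(self-pairs of a gene excluded, within-scaffold comparison allowed), with
consecutive anchors ≤ `gap_size` (default 15) ranks apart on both axes and
a consistent direction (same or inverted). Two choices are worth spelling
out:

* **Tandem collapse before anchoring.** Each array is reduced to its
  lowest-rank member before anchor pairs are enumerated; otherwise one
  array of k genes would contribute O(k²) anchors and could satisfy
  `min_anchors` on its own, fabricating a block out of a tandem event.
* **Chain semantics.** The detector returns *all subset-maximal valid
  chains*: a chain is valid when, sorted along one axis, every consecutive
  step is within the gap on both axes and the second axis is strictly
  monotone; a chain contained in a longer valid chain is dropped. Chains
  below `min_anchors` are discarded, then chains of the same orientation on
  the same scaffold pair closer than `cluster_gap` (default 15) on both
  axes are merged into one block. The implementation enumerates maximal
  paths over the anchor DAG; the test suite proves it equivalent to an
  exhaustive search over every anchor subset on 100 random catalogs.

Classification precedence is tandem > block > dispersed for multi-copy
genes; genes whose family has one member (or none) are single. The four
types always partition the catalog.

## Pan-genome classification (`pangenome`)

Presence of a gene in a strain is called from *horizontal coverage* — the
fraction of its exonic bases covered by ≥ 1 uniquely mapped read, computed
upstream and consumed as a TSV; the module never touches alignments.
A gene is absent below 5% coverage (so 0.049 is absent, 0.050 present).
With n strains (the reference counts as one), *core* means present in all
n; *softcore* means present in ≥ `ceil(0.95 n)` but not all (the ceiling
resolves the fractional bound to an integer; at n = 49 the threshold is
47); everything else is plain dispensable. Softcore is reported as a
labelled subset of the dispensable fraction, which is what makes the
summary arithmetic consistent: core% + dispensable% = 100 and the core
fraction is bounded by [core, core + softcore]. Accumulation curves draw
`n_permutations` (default 100) random strain orderings and track the
cumulative union (pan) and intersection (core); pan is non-decreasing and
core non-increasing along every single ordering, and both endpoints equal
the classification totals. De novo gene deduplication is greedy in
decreasing length order at ≥ 95% pairwise identity, so representatives are
always cluster-longest; identity is taken as symmetric and missing pairs
as non-matching. Strain clustering on coverage profiles (scipy average
linkage, Euclidean) is provided to verify that clade-correlated gene loss
groups strains by clade.

## Selection (`selection`)

Site counting is unweighted Nei–Gojobori under the standard nuclear code:
each codon position contributes s/3 synonymous sites, where s of the three
possible single-base changes preserve the amino acid. Changes creating a
stop codon count as nonsynonymous, which preserves the identity
`L_N + L_S = callable CDS length`. A per-base callable mask restricts both
the totals and, implicitly, which variants should be supplied.

Per SNP with alternate count a of n called chromosomes (p = a/n), the
estimator adds `h = n/(n−1) · 2p(1−p)`; multi-allelic sites contribute
`n/(n−1) · (1 − Σ p_i²)` over all alleles including the reference. This is
exactly the average proportion of chromosome pairs differing at the site,
an identity the tests assert against explicit haplotype sets. π per class
is the h-sum over that class divided by the class site total; the ratio is
undefined (NaN) when π_S = 0. The genome-wide summary reports both the
**ratio of means** (headline; 0.003/0.022 rounds to 0.14) and the mean of
per-gene ratios, which is systematically larger because small-L_S genes
contribute noisy large ratios. Group comparisons use the two-sided
Wilcoxon rank-sum test on defined per-gene ratios; groups with < 2 such
genes are skipped with a warning. Positive-selection candidates default to
ratio ≥ 1 (configurable) and are tested for concentration in
condition-upregulated gene sets with the hypergeometric protocol below.

## Clade signatures (`signature`)

Scores are exact rationals: hits in a clade divided by the clade census
(defaults 32 pennate, 56 centric, 18 raphid, 14 araphid, 8 benthic,
73 planktonic; benthic/planktonic labelling leaves ambiguous species
unlabeled). Signatures are log2 score ratios per axis. Zero denominators
yield signed infinities rather than missing values: a gene with homologs
in the numerator clade and none in the contrast clade is maximal evidence
for the signature, so +∞ passes the ≥ 3 threshold. 0/0 is undefined and
never flagged. Because transcriptome absence is weak evidence, the
high-signature call is validated: pennate/raphid flags additionally
require genomic family support (all diatom homologs of the gene's family
confined to the claimed clade, supplied as input), and benthic flags
require hits in ≥ 2 benthic species. The robustness control takes score
tables under a stringent and a relaxed homolog cutoff and reports, per
axis, the fraction of strictly-flagged genes whose relaxed signature stays
positive.

A planted group with benthic presence 1.0 against planktonic presence 0.1
sits close to the decision boundary: the flag needs the planktonic hit
count k ≤ 73/8 ≈ 9.1 while k ~ Binomial(73, 0.1) has mean 7.3, so the
per-gene flag probability is ≈ 0.81 by construction, not a detector
defect. Group-level recovery (mean finite signature ≥ 3, the quantity the
generator actually controls) is the reliable readout and is what the
acceptance measurements report alongside the per-gene rate.

## Enrichment and expression (`enrichment`)

Expressed means TPM ≥ 2 in ≥ 1 sample; retained means CPM > 1 in ≥ 3
samples, with CPM = count / (library size / 10⁶). Enrichment p-values are
upper-tail hypergeometric `P(X ≥ k)` over a universe defaulting to all
genes with family assignment; q-values are Benjamini–Hochberg over the
labels of one run, and a call requires q < 0.05 *and* ≥ 2 overlapping
genes. Pleiotropic families are enriched in upregulated genes in ≥ 7
conditions; condition-specific families span ≤ 2 related condition groups
(grouping configurable, identity by default).

Expression divergence walks a rooted binary family gene tree: for each
internal node whose two child clades both contain expressed genes, the
Pearson correlation between child-clade mean log2(TPM + 1) condition
profiles is computed and the node is divergent when r < 0.5; the family
score is the percentage of evaluable nodes that diverge, with families
< 4 members excluded. The correlation measure, pseudocount and cutoff are
this module's own construction and are config-exposed; results of this
operation are qualitative (direction of the size trend), not calibrated
percentages.

## Synthetic data (`synthetic`)

All randomness flows from one `numpy.random.Generator` per call; identical
seeds give byte-identical serialized outputs. Fixed defaults: background
copy counts `1 + Poisson(0.5)`; presence coverage Uniform(0.8, 1.0) vs
absence Uniform(0, 0.05); allele frequencies Beta(1, 3) folded to the
minor allele and rounded to chromosome counts; negative-binomial counts as
gamma-Poisson with dispersion 0.1 around log-normal baselines; CDS lengths
300–3000 nt in multiples of three from the 61 sense codons.

Variant dosing places a synonymous SNP at a position with probability
`λ_s · f_s(pos)` where `f_s` is the position's fractional synonymous site
content and `λ_s = target π_S / E[h]`; the expectation of the estimator
then equals the target exactly, with `E[h]` evaluated once by Monte Carlo
under the frequency model. Nonsynonymous dosing is symmetric. The catalog
generator plants tandem arrays and blocks with dedicated family labels and
then scrubs accidental background structure (reassigning offending genes
to singleton families) so that a rate-zero call emits a structure-free
catalog and recovery tests measure exactly the planted signal.

What the generators do **not** emulate: read-level noise (coverage is
drawn, not aligned), linkage between SNPs, mapping bias, assembly
artefacts, phylogenetic correlation between species in the homolog panel,
and library-composition effects in expression. Passing recovery tests
therefore demonstrates correctness of the estimators and detectors under
their stated models, not robustness to upstream artefacts in real data.

## Problem sizes

Default verification sizes were chosen to make every stochastic check
statistically comfortable while staying quick: 5 seeds × 200 families for
expansion recovery, 5 × 400 genes × 49 strains for pan classes,
5 × 100 genes × 96 chromosomes for π recovery (≈ 2,800 synonymous SNPs
total, giving a ≈ 3% standard error against the ±15% band), 5 × 120 genes
for signature groups, and 100 random ≤ 40-gene catalogs for the
exhaustive block oracle.
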