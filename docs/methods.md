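# Methods

## Variant encoding

A variant's identity is the raw VCF tuple (chrom, pos, ref, alt); rsids are
carried for lookup but never enter identity. No left-alignment or indel
normalization is applied: panel amplicon data are called against a fixed
design, so records from different patients are already comparable. This is
a documented limitation — two differently normalized representations of
the same indel would occupy two rows. Multi-allelic records are split into
one row per alternate allele, the per-allele zygosity being the number of
genotype haplotypes carrying that allele. Hom-ref calls and missing
genotypes both encode as 0 ("not present in the patient's VCF"), which
means the cohort allele number is fixed at 2N for every variant; at sites
with genuine missingness this deflates the cohort allele frequency. The
Q30 default quality filter corresponds to a maximum base-call error rate
of 10^(−30/10) = 0.1%. Records without a QUAL value are dropped rather
than kept, the conservative reading of a quality threshold.

Rows are ordered by natural chromosome sort, then position, ref, alt, so
matrices are reproducible across runs and platforms.

## PCA and cluster concordance

Samples are observations, variants are features. Features are
mean-centered but not variance-scaled: on 0/1/2 dosages, unit-variance
scaling would multiply rare variants by large factors and let singletons
dominate the leading components. Component signs are canonicalized by
making the largest-|loading| entry of each component positive, so loadings
tables are stable across BLAS builds. Scores are exactly the centered data
projected on the unit-norm loadings.

Cluster–haplotype concordance uses k-means with k = 3 on the PC1 scores
(the haplotype system is one-dimensional: dosage 0/1/2 of the minor
haplotype), compared with the planted or tag-SNP-derived labels by
adjusted Rand index. Average-linkage hierarchical clustering on any
distance matrix is provided as well and gives the same partition on the
synthetic cohorts. t-SNE (Jaccard distance, precomputed metric, fixed
seed) is a visualization aid only: the package guarantees determinism per
seed and block separation on degenerate inputs, nothing about its
geometry otherwise. Perplexity defaults to 30 and is clamped below
(n − 1)/3 with a warning for small cohorts.

## Allele-frequency screen

The two-sided Fisher exact p-value is computed by direct summation of the
conditional hypergeometric distribution over its support — all tables with
the observed margins whose probability does not exceed the observed
table's. Ties between opposite tails are decided with the relative
tolerance 1 + 1e-7 (the convention of R's fisher.test); this makes exactly
tied symmetric tables contribute both tails regardless of floating-point
rounding. The summation is vectorized over the support, so a test against
a reference of 100,000 chromosomes costs microseconds, and agreement with
scipy's implementation is asserted in the test suite. The odds ratio
reported alongside is the unconditional sample OR with a Haldane–Anscombe
0.5 correction when any cell is zero — chosen for reproducibility and
simplicity, since the screen's decisions rest on the exact p only.

BH correction is applied within each disease group separately, matching a
screen that is run and reported per group; a global family can be obtained
by correcting the pooled p-vector with `benjamini_hochberg` directly.
Variants absent from the reference table are not dropped: they are tested
with AC_ref = 0 against a caller-supplied default AN_ref (100,000) and
flagged `not_in_reference`, because variants novel to the reference
population are exactly the ones downstream stages should see.

The Hardy–Weinberg test is the exact conditional ("Wigginton-style")
test: conditioning on the observed allele counts, the p-value sums the
probabilities of all heterozygote counts of the same parity whose
conditional probability does not exceed the observed one (relative tie
tolerance 1e-12; the mid-p variant is not used). Monomorphic variants
return p = 1 with a flag rather than an error. LD between rows is
composite LD: the squared Pearson correlation of dosage vectors, which
needs no phase information.

## Decision tree

CART with Gini impurity, grown greedily: at each node every (variant,
threshold) pair is scored by weighted child impurity, with thresholds
{0.5} on binary and {0.5, 1.5} on ternary dosages. Ties are broken by
lowest row index, then lower threshold, making the tree a deterministic
function of (matrix, labels, depth, seed). Growth stops at `max_depth`
(default 4, exposed as a parameter since "adequate depth" is
cohort-dependent), at purity, or when no split strictly reduces impurity.
There is no pruning. The single stratified 2/3 / 1/3 split (per-class
rounding, at least one train and one test sample per class) is
deliberately not cross-validation: the object of interest is the tree and
its splitting variants, and stratification protects small classes from
vanishing out of the test set. scikit-learn's tree is used in the test
suite as an independent cross-check, not in the implementation, because
its randomized tie-breaking cannot reproduce a unique canonical tree.

Per-class precision, recall and F1 use the one-vs-rest contingency
formulas; the precision of a class never predicted is defined as 0 and
the class is listed in the report's `zero_division` field.

## Network stage

Edge lists are unioned into an undirected graph with upper-cased gene
symbols, dropped self-loops (counted), and per-edge provenance sets. A
group's subnetwork is the induced graph over its seed genes (those with
≥1 variant at p_adj < α) plus their 1-hop neighbours — no shortest-path
or diffusion expansion. Hubs are ranked by induced degree with
alphabetical tie-breaks. Enrichment of the group-unique gene sets uses the
hypergeometric upper tail over the annotated universe: the background is
every gene with at least one term in the supplied annotation table, since
subnetwork members include neighbours drawn from the full interactome and
a panel-restricted background would be degenerate. Terms with zero query
overlap are not tested, keeping the BH family to terms the query touches.
The group-pair contrast applies the significance threshold to raw p by
default (configurable to p_adj) and returns terms significant in the
first group only.

## Synthetic cohorts

The default cohort mirrors the target study's shape: three groups of
46/40/26 patients (the latter two forming one disease entity), ~1000
background variants, one fully penetrant causal variant per genetic
subgroup, a 6-SNP perfectly linked haplotype block at minor-haplotype
frequency 0.22 tagged by rs1052553/rs1800547-named SNPs, one
heterozygote-excess SNP (f = −0.5 at AF 0.35; genotype frequencies
p² + fpq, 2pq(1 − f), q² + fpq), and five variants per group whose cohort
AF is shifted to 0.30 against a reference AF of 0.01. The reference table
reports drawing AFs over 100,000 chromosomes; causal variants are omitted
from it deliberately, emulating mutations unreported in reference
population databases and exercising the screen's `not_in_reference` path.

Background AFs are drawn from Beta(0.25, 8) clipped to [0.005, 0.5]
(mean ≈ 0.03, mostly rare — the realistic profile of a panel variant
list). The choice is an explicit signal-to-noise calculation rather than
taste: with p ≈ 1000 features and n = 112 samples, sample-PCA noise
eigenvalues reach about σ̄²(1 + √(p/n))², where σ̄² is the mean genotype
variance; the 6-SNP block contributes a signal eigenvalue of about
6 · 2q(1 − q) ≈ 2.06 at q = 0.22, so the mean background variance must
stay below roughly 1/16 for the block to surface cleanly as PC1. This
yields ~65 variants per patient. Genotypes are independent across
variants except inside the block (drawn as a shared binomial haplotype
dosage); there is no genome-wide LD model, no sequencing-error model, and
no realistic site-frequency spectrum. Passing tests therefore demonstrate
recovery of planted structure under idealized independence, not
performance on real panels with pervasive short-range LD.

Three derived spec constructors are fixed study conditions used
throughout the tests: `perfect_separation` (no AF shifts — the causal
variants are the only class-separating signal, so a correct tree must
split on exactly those rows), `with_modifiers` (adds one 0.8-penetrance
modifier per disease subgroup, so masking the causal rows drops accuracy
strictly below 1 but above the majority fraction), and `null_screen`
(one group of 40 drawn exactly at reference frequencies over 500
variants, on which every discovery is false).

Network fixtures plant hub-centred cliques in an Erdős–Rényi background
(default n = 60 genes, edge probability 0.05); each module's hub gains 10
extra spokes so its induced degree strictly dominates, and each module's
term annotates exactly its genes while decoy terms cover the rest.

## Numerical and degenerate-input choices

Phred conversion rejects negative or non-finite qualities. PCA refuses
constant matrices and out-of-range component counts. Jaccard distance
defines d = 0 between two all-zero profiles. Haplotype labelling requires
the ternary matrix and treats tags absent from the matrix as zygosity 0
everywhere; any disagreement between tags yields "inconsistent" (the
"uncallable" label is reserved vocabulary and is never produced by the
current rules). The screen refuses unlabelled samples and empty groups;
masking refuses to empty the matrix and names unresolvable keys.
Problem sizes in the test suite — 20-seed recovery loops, a 200-seed null
FDR simulation, exhaustive exact-test sweeps (all 2×2 tables with total
≤ 60, all genotype triples with n ≤ 30) — were chosen so the planted
effects are measured at the cohort scale the package targets while the
whole suite completes in well under a minute of statistical simulation.

## Known limitations

No indel normalization; no genotype-likelihood or missingness handling;
no phasing (haplotypes only via tag SNPs); no population-structure
correction or covariate-adjusted association; the enrichment stage does
not propagate terms up an ontology; symbols are the node identity in the
network stage, so identifier drift between edge lists must be resolved
upstream.
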