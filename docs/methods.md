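# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish.

## The HA score and re-ranking

For a gene *g* with association p-value *P*(*g*) ∈ (0, 1] and *m*(*g*)
phenotype-ontology terms shared with the disease repository (HPR),

HA(*g*) = *P*(*g*) / (*m*(*g*) + 1).

The +1 regularises the denominator so that an unannotated gene keeps its raw
p-value rather than collapsing to 0 or being undefined. Lists are sorted by
ascending HA; ties break on ascending raw p-value, then lexicographic gene
symbol, so output is fully deterministic. Ranks are dense integers 1..N.

**What counts as a "matching" term.** `count_relevant_terms` counts the
*intersection* of the gene's annotation set with the HPR by default. The
alternative reading — count the gene's *entire* annotation set whenever at
least one term matches — is available as `count_mode="all"`. The
intersection reading is the default because it makes the degenerate case
exact: a gene with *no relevant* terms scores HA = P, and adding ontology
terms that annotate no gene in the list can never change any rank (an
invariant the tests verify).

No statistical enrichment gate is applied before scoring: the raw matched
count enters the formula directly. Any such gate would need a null model the
procedure does not define.

**Rank changes.** delta = rank_before − rank_after, so positive means the
gene moved toward rank 1. Over a fixed gene set deltas always sum to zero.

## The phenotype repository (HPR)

The HPR is the union of phenotype term accessions annotated to a selected
family of diseases (selection by name substring or explicit id list).
Direct annotations are used by default; ancestor closure over the ontology's
`is_a` graph is an opt-in flag. When closure is applied, ontology roots are
excluded (they carry no information) and obsolete terms are dropped with a
warning. Closure is idempotent and can only grow the repository.

OBO parsing is delegated to `obonet`; the package adds stanza-level id
validation (reported with line numbers), cycle detection (reported with the
offending cycle) and the term/root bookkeeping above.

## SNP-level preprocessing

When the gene list must be derived from a SNP association table, three
standard steps are provided:

- **MAF**: allele frequency of the rarer allele from genotype counts,
  filter keeps MAF > 0.05.
- **HWE**: 1-df chi-square goodness of fit against p², 2pq, q² at the
  observed allele frequency; monomorphic markers return p = 1 by
  convention. The filter *excludes* markers with HWE p < 0.001, the
  conventional direction for a genotyping-quality filter (markers violating
  equilibrium are suspected genotyping artifacts). The chi-square
  approximation, not the exact test, matches the default behaviour of the
  era's standard GWAS tooling; its null rejection rate at α = 0.05 is
  verified to be within [0.03, 0.07] by simulation.
- **SNP→gene aggregation**: a SNP is assigned to every gene whose body ±
  a window (default 50 kb) contains it, on the same chromosome; the gene's
  p is the minimum over its SNPs. Min-p is monotone in the window size,
  which the tests exploit. Gene coordinates are 1-based inclusive in this
  package's dialect; a flag converts half-open 0-based input.

## List integration and the hypergeometric test

`top_fraction` keeps genes with rank ≤ floor(q·N) (default q = 0.75). Floor
is the default because it matches published set sizes at this fraction;
ceil is available for rounding-sensitivity studies and guarantees a
non-empty set for any q > 0.

Enrichment of a gene set of size n containing k known disease genes, in a
universe of N genes with K known, is the exact hypergeometric upper tail.
Two conventions are exposed:

- `inclusive=True` (default): P(X ≥ k), the standard enrichment tail,
  equal to 1 at k = 0;
- `inclusive=False`: the strictly-greater tail P(X > k). Published
  enrichment tables are sometimes computed with this convention (it is what
  R's `phyper(k, K, N−K, n, lower.tail=FALSE)` returns when the usual k−1
  adjustment is omitted), and it is the convention that reproduces the
  reference count table bundled with the acceptance script.

The backend accumulates tail mass in log space, so magnitudes of order
1e-31 are returned exactly rather than underflowing; the tests check it
against explicit rational summation of the mass function.

The universe size N is always an explicit input: it is an analysis decision
(all assayed genes? all protein-coding genes?), not something the package
can infer.

## Evaluation statistics

**Wilcoxon rank-sum** (Mann-Whitney) with mid-ranks for ties. Tie-free
samples with total n ≤ 12 take the exact enumeration path; larger or tied
samples use the normal approximation with tie and continuity correction.
The exact path is verified against full enumeration of all C(n, n₁) rank
assignments for every tie-free input with n ≤ 10. The default alternative
is two-sided.

**Nested ranks test.** To compare two conditions across several gene
modules without pooling away the module structure, the package uses a
permutation test: the statistic is the module-size-weighted mean of
within-module rank-sum Z scores, and the null distribution permutes
condition labels *within* each module only. The one-sided p-value uses the
add-one estimator (1 + #{perm ≥ obs}) / (1 + n_perm), which can never
return 0; the two-sided p doubles the smaller tail and caps at 1. Modules
containing a single condition, or with all-tied values, carry no
information and are dropped with a warning. The permutation stream is
consumed in an order keyed by module *content* (size, condition count,
sorted ranks), so results are invariant to module renaming and to
reordering of records within a module, given a seed. This is a deliberately
assumption-light stand-in for a mixed-effects rank model: it conditions on
module membership exactly rather than estimating a random-effect variance.
Empirical type-I error at α = 0.05 over 2,000 null simulations is verified
to lie in [0.03, 0.07].

Log-transforms of |delta| appear only in the plot-data export, never inside
a test — rank tests are invariant to monotone transforms.

## Co-expression modules

The weighted-network core follows the standard recipe:

- **Adjacency**: unsigned a_ij = |cor_ij|^β by default (the historical
  default of the method); signed ((1+cor)/2)^β optionally. β ≥ 1.
- **Soft-threshold choice**: `pick_beta` returns the smallest candidate
  whose scale-free fit R² (regression of log₁₀ frequency on log₁₀ binned
  connectivity, sign-corrected so only decaying distributions score high)
  reaches 0.8, falling back to the best-fitting candidate with a warning.
  Note that block-structured networks — including the package's own planted
  fixtures — are *not* scale-free, so on such data the fallback path is the
  expected behaviour and a conventional fixed power (β = 6 unsigned) is the
  sensible choice.
- **TOM**: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), with
  l_ij = Σ_{u≠i,j} a_iu a_uj, diagonal 1. Verified against a direct
  double-loop oracle.
- **Clustering**: average linkage on 1 − TOM with a *static* cut, then
  clusters below `min_module_size` (default 10) are pooled as
  "unassigned". Module names M1, M2, ... are assigned by descending size,
  making labels invariant to input gene order. A static cut is a documented
  simplification relative to dynamic tree cutting; it is adequate for
  well-separated modules and keeps the contract exactly testable. The
  `cluster_modules` argument default of 0.25 suits dissimilarities that
  have been rescaled to use the full [0, 1] range; for raw 1 − TOM from
  soft-thresholded correlation data the attainable distances are compressed
  upward (within-module ≈ 0.75, between ≈ 0.99 at cor 0.8 and β = 6), so
  the pipeline default is `cut_height = 0.9`, chosen from that expected
  scale, and any value in roughly (0.8, 0.98) recovers the planted fixture
  identically.
- **Module-trait association**: the module eigengene is the first principal
  component across samples of the standardized module submatrix,
  sign-oriented to correlate positively with mean module expression (PCA
  sign is otherwise arbitrary). The module p-value is the two-sided
  correlation t-test of eigengene vs binary trait. A 1-gene module's
  eigengene is its standardized profile.
- **Signature export**: genes of the selected modules are partitioned by
  the sign of their standardized case-minus-control mean difference;
  zero-difference genes are dropped with a warning. GRP files are one
  uppercase symbol per line, sorted, newline-terminated; up and down sets
  must be disjoint and non-empty at export.

## Synthetic fixtures

The generators emulate the premise the re-ranking method relies on:
relevant genes have both smaller association p-values and more
repository-matching annotations. They are pure functions of
(configuration, seed) — identical configs give byte-identical files.

Defaults (the study conditions for the recovery tests): 2,000 genes, 100
relevant; matching-annotation counts Poisson(3) for relevant vs Poisson(0.2)
for background, plus Poisson(1) irrelevant terms per gene from outside the
repository; p-values Beta(1, 9) (mean 0.1) for relevant genes vs Uniform(0,1]
for background (setting Beta(1, 1) gives the null). Expression: 200 genes,
40 samples, 4 equal modules sharing latent factors with loading
√(within-cor), within-module correlation 0.8; the first module's factor is
shifted by the trait effect in cases, and half its genes load negatively,
providing directional up/down truth. SNP panels draw genotype counts under
HWE at true MAF ∈ (0.1, 0.5), with planted fractions of low-MAF
(∈ (0.005, 0.04)) and equilibrium-violating (inbreeding-style F = 0.6)
markers.

What the fixtures do **not** model: linkage disequilibrium, population or
breed stratification, microarray noise and batch structure, realistic
ontology topology, or annotation bias toward well-studied genes. Passing
recovery tests therefore demonstrates that the implementation does what the
formulas say under the stated generative model — not that the method will
rank true disease genes highly on any particular real dataset.

## Problem sizes used in the bundled studies

The acceptance computations use: the published enrichment count table as-is
(universe 19,238); 1,000 random ≤50-gene instances for the re-ranking
oracle; all tie-free rank assignments with n ≤ 10 for the Wilcoxon oracle;
2,000 null simulations (199 permutations each, 4 groups × 12) for the
nested-ranks calibration; 1,000 random 3–8-gene draws for the TOM oracle;
one 200-gene planted fixture for module recovery; and 100 seeds of the
default 2,000-gene fixture for the end-to-end recovery study.

## Known limitations

- Static tree cut (no dynamic cutting or module merging); modules whose
  separation varies along the dendrogram may be split or pooled.
- The nested-ranks permutation test is an interpretation of a
  mixed-effects rank test, not a reimplementation of any specific published
  variant; with very few modules its resolution is limited by n_perm.
- `pick_beta`'s scale-free criterion is meaningful only for networks with
  heavy-tailed connectivity; on block-structured data it falls back.
- The exact Wilcoxon path requires tie-free data; tied small samples use
  the corrected normal approximation, which is conservative at very small n.
- Querying the CMap service, pathway enrichment, and logistic-regression
  association testing are out of scope; the package consumes ranked lists
  and produces the query files.
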