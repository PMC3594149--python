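# Methods

## The GO graph and levels

The ontology is parsed from OBO 1.2/1.4 (via `obonet`) into a typed
directed multigraph with edges child → parent. All seven GO relation
types are retained (`is_a`, `part_of`, `has_part`, `regulates`,
`occurs_in`, `positively_regulates`, `negatively_regulates`), but only
`is_a` and `part_of` — the conventional true-path relations — define
the rooted DAG used for levels, navigation, and annotation propagation.
`has_part` points in the opposite part–whole direction and the
regulation/occurrence relations do not license annotation inheritance,
so traversing them would both corrupt levels and over-propagate genes.
The traversal set is a constructor argument for users who disagree.

Each namespace (MF, BP, CC) is analysed as an independent graph whose
root is its unique parentless term under traversal relations. When a
term is parentless only because its sole connections are non-traversal
edges, it is not considered a root candidate; it simply stays
unreachable (and is logged). The *level* of a term is its shortest-path
edge distance from the root. Shortest rather than longest path was
chosen because it is the natural reading of "k edges away" and is
stable under adding redundant deep paths; with multiple parents a term
therefore takes the level of its shallowest parent plus one. Levels are
computed by breadth-first search after an acyclicity check; a cycle
among traversal edges is a hard error naming a member. Obsolete terms
are dropped at parse time (kept in a skip log), and annotations that
point at them are discarded with a counted warning.

## Annotations and counting semantics

Genes and proteins are treated as one identifier space ("genes" in all
outputs). Counts are always cardinalities of distinct-gene sets, never
annotation-line counts, so multiple evidence lines cannot inflate a
term. GAF 2.0–2.2 and a two-column TSV dialect are read; GAF rows with
a `NOT` qualifier are excluded. The gene key for a GAF row is column 2
(DB Object ID), falling back to column 1 if empty — a composite
DB-prefixed key would never match the bare ids in user gene lists.

Propagation implements the true-path rule by a single topological pass:
each term's gene set is its direct genes plus the union of its
children's propagated sets. Distribution counts at a navigation scope
are always taken from the propagated index (a level-wise count is only
coherent if genes annotated to deep terms are visible at their shallow
ancestors); passing an unpropagated annotation set propagates on the
fly.

## Reference genome and expected counts

The genome-wide index gives each term its K_i = number of distinct
genome genes annotated (after propagation) and a genome size N, either
user-supplied or estimated from a gene-ID table: count distinct ids per
name class (Primary, Synonym, ordered-locus, ORF) and take the class
with the most ids. Ties are broken by the fixed priority ordered-locus
> Primary > ORF > Synonym, reflecting that in bacterial UniProt
extracts the ordered-locus class is the one that tracks the actual gene
complement. If the estimated N is smaller than the number of annotated
genes it is raised to that number with a warning (K_i ≤ N must hold).

Expected counts use the hypergeometric mean E(GO_i) = n·K_i/N for a
sample of n genes; n > N or N = 0 are errors, K_i = 0 gives E = 0.

## Hypothesis tests

**Two-sample comparisons.** The "distribution" being compared is the
vector of per-GO propagated counts over the union of GO groups at the
chosen scope (a term absent from one sample contributes 0). This is the
construction under which "compare all GO groups at once" is well-posed
for two-sample tests. Kolmogorov–Smirnov: the statistic is the maximum
ECDF gap between the two count vectors; the p-value is the classical
asymptotic Kolmogorov survival function evaluated at √(mn/(m+n))·D
(the same limit R's `ks.test` uses by default for large samples) —
chosen over small-sample exact variants because count vectors are
heavily tied and tie-aware exact definitions differ between
implementations. Wilcoxon rank-sum: midranks with tie-corrected
variance and a normal approximation without continuity correction;
when both vectors have ≤ 25 entries and the combined data is tie-free,
the exact null distribution is used instead. Two identical constant
vectors return p = 1 directly (the test statistic has zero variance
and carries no evidence).

**Goodness of fit.** Restricted to the GO groups common to sample and
reference. Chi-square: the expected vector is rescaled to the observed
total (the classical GOF requirement), categories with rescaled
expectation below 1e-9 are dropped with a warning, and the Pearson
statistic is referred to χ² with df = categories − 1. The K–S variant
runs the two-sample K–S above on the observed and raw expected vectors.
No per-GO Fisher testing and no multiple-testing correction are
offered: the package's point is whole-distribution comparison, and
per-GO output is limited to observed vs expected counts.

**Normalization.** For samples ordered by size l_1 ≥ … ≥ l_n, the
coefficients are c_1 = 1 and c_i = l_1/l_i, so c_i·l_i is constant and
two samples with identical per-GO proportions get identical normalized
counts. This is the simplest scheme satisfying the constraint that the
largest sample is the reference (coefficient exactly 1).

## Gene-selection report

One row per scope term with any nonzero count. The rate of change is
defined as last/first in the user-supplied sample order (with more than
two samples the endpoints define the rate; intermediate counts are
displayed only), computed on normalized counts by default — the report
header records which mode was used. A term absent from the first
sample has an *undefined* rate (reported NA, ranked after all defined
rates, and selectable only via the "novel appearance" flag) rather
than an infinite one; a term that vanishes (rate 0) is ranked first,
as an infinite |log rate|. Ties in the ranking break by term id so
output is deterministic. `select_terms` keeps rows with rate ≥ f or
≤ 1/f, boundaries inclusive.

## Synthetic data

The fixture generators cover everything the pipeline consumes without
any downloads. Graphs grow level by level (each new term takes 1–2
existing parents with spare fan-out ≤ 4; is_a:part_of odds 4:1), which
yields a rooted DAG by construction; genes get 1–4 annotations to
uniform random non-root terms; gene-ID tables put the ordered-locus
class on top as in bacterial UniProt extracts; samples are drawn
without replacement, with an optional effect map that multiplies the
sampling weight of genes under chosen terms in every sample after the
first (the first sample is the unweighted baseline). Each generator
draws from its own `numpy` Generator seeded as `[seed, stream]`; equal
seeds give byte-identical files.

What the toys do *not* emulate: realistic GO depth (~15 levels) and
term-frequency skew, correlated multi-term annotation of real genes,
evidence-code structure, inter-namespace links, or any actual
*S. pneumoniae* annotation statistics. Passing tests therefore
demonstrate algorithmic correctness (closure, levels, counting,
test fidelity, calibration, ground-truth recovery), not biological
conclusions about real datasets.

The ground-truth recovery trial (`planted_recovery_rank`) uses a
60-term ontology over 1500 genes, two samples of 500, and a 3×
multiplier planted on a term with closure share near 12% sitting on a
level with ≥ 10 terms — mid-frequency so the enrichment is neither
saturated nor lost in noise, and a populated level so "top decile of
the table" is a meaningful bar. The calibration check draws observed
category-count vectors multinomially over scope terms with
probabilities K_i/ΣK_i: sampling *genes* instead would violate the
independence the chi-square null assumes, because one gene hits
several GO groups at once.

## Numerical and degenerate-input choices

- Chi-square expected floor 1e-9 (post-rescaling); fewer than 2
  remaining categories is an error, as are all-zero expected vectors,
  fewer than 2 common GO groups, and scope mismatches between compared
  distributions.
- A requested level beyond the graph depth yields an empty
  distribution with a warning, not an error; an unknown term in
  children mode is an error.
- Duplicate gene ids in a list are collapsed (order-preserving) and
  logged; empty annotation files and empty gene lists are errors.
- All statistics are deterministic; simulation lives only in tests and
  the acceptance script, under explicit seeds.

## Problem sizes used in the checks

The test suite and acceptance script run on toy scales chosen to make
brute-force oracles exact and exhaustive checks feasible: the
hypergeometric sweep covers every (n, K, N) with N ≤ 60; closure and
level oracles run on 100 random DAGs of 10–100 terms and 20–200 genes;
statistical fidelity uses 100 random vector pairs; calibration uses
200 multinomial draws of n = 500 over ~10 categories; recovery uses
100 (suite) or 40 (script) seeded trials at the 1500-gene scale.

## Known limitations

- Levels use shortest-path distance; a longest-path ("depth") variant
  is not implemented.
- The two-sample tests treat per-GO counts as exchangeable
  observations; counts of overlapping GO groups are in fact dependent,
  so p-values are comparative indices rather than strict error
  probabilities (the goodness-of-fit calibration check covers the
  disjoint-category regime only).
- The K–S p-value is asymptotic; for very few categories it is
  conservative.
- No web interface, database, chart-identical rendering, or live
  UniProt/GO downloads; charts are minimal matplotlib renderings
  behind `--plots`.
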