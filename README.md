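# comparego

Comparative Gene Ontology analysis of bacterial gene lists.

Most GO enrichment tools test one GO term at a time against a reference
set (Fisher's exact test per term, then a p-value list). `comparego`
takes the complementary, whole-distribution view that is useful when you
have *several* gene lists from one organism — for example lists of up-
or down-regulated *Streptococcus pneumoniae* genes harvested from the
nose, lungs, blood, and brain of infected mice — and want to ask: does
the functional profile of these lists differ, where, and which genes
drive the shared biology?

## What it computes

**Leveled GO graph.** The ontology (an OBO file) becomes one rooted DAG
per namespace (MF/BP/CC), with typed edges; `is_a` and `part_of` define
traversal. Every term gets a *level* — its shortest edge distance from
the root (root = 0). Navigation scopes follow the graph: all terms at a
level, the leaves (most specific terms, which may sit at several
levels), or the children of one term.

**Propagated annotations.** Gene→GO annotations (GAF 2.x or a simple
two-column TSV) are propagated up the graph (true-path rule), with
distinct-gene counting, so a gene annotated to a deep term is visible in
every ancestor's count.

**Sample vs genome.** For a sample of n genes from a genome of N genes,
K_i of which carry term i, the expected count in the sample is the
hypergeometric mean

    E(GO_i) = n · K_i / N.

Observed and expected vectors over the common GO groups are then
compared at once with goodness-of-fit tests (Pearson chi-square with the
expected vector rescaled to the observed total, df = categories − 1; or
a two-sample Kolmogorov–Smirnov on the two vectors). The genome size N
can be estimated from a gene-ID table: ids are grouped by name class
(Primary, Synonym, ordered-locus, ORF) and the class with the most
distinct ids wins — for *S. pneumoniae*-style tables this is the
ordered-locus class.

**Sample vs sample.** Two samples' per-GO count vectors at a scope
(union of terms, absent term → 0) are compared with non-parametric
two-sample tests: Kolmogorov–Smirnov and Wilcoxon rank-sum (midranks,
tie-corrected variance; exact null for small tie-free vectors). Samples
of different sizes l_1 ≥ … ≥ l_n are made comparable by coefficients
c_1 = 1 for the largest and c_i = l_1/l_i otherwise, applied
multiplicatively to raw counts.

**Gene selection.** The tabular report lines up each GO term across the
ordered samples and reports the *rate of change* (last sample's
normalized count / first sample's), the common genes (intersection of
the term's gene hits across samples — candidates central to a shared
process) and the union genes. Rows are ranked by |log rate|.

## Worked example

Generate a seeded toy dataset (30-term MF ontology, 200 annotated
genes, two gene lists of 120 and 60 genes) and build the gene-selection
report at level 1 with size normalization:

```sh
comparego make-fixtures --seed 11 --n-terms 30 --n-genes 200 \
    --sample-sizes 120,60 --out fx
comparego gene-table --obo fx/ontology.obo --annotations fx/annotations.tsv \
    --samples fx/sample1.txt --samples fx/sample2.txt \
    --level 1 --normalize --out report
head -7 report/gene_table.tsv
```

```
# scope=molecular_function:level=1
# normalize=true
# sample_order=sample1,sample2
# rate_definition=last_sample / first_sample
go_id	go_name	count_sample1	count_sample2	rate_of_change	common_genes	union_genes
GO:0000017	toy term 16	7	0	0		g00085,g00099,g00104,...
GO:0000007	toy term 6	36	42	1.16667	g00004,g00022,g00028,...	g00003,g00004,...
```

Reading the rows: `GO:0000017` had 7 (normalized) gene hits in the
first list and none in the second — a vanished GO group, ranked first
because its |log rate| is infinite. `GO:0000007` moved from 36 to 42
normalized hits, a 1.17× rate of change; the `common_genes` column
lists the 13 genes hitting that term in *both* lists (the candidates to
investigate), and `union_genes` all genes hitting it in either.
Because sample2 (60 genes) gets coefficient 120/60 = 2, a term keeping
the same *share* of genes in both lists shows rate ≈ 1.

Comparing the two lists across all leaf GO terms at once:

```sh
comparego compare --obo fx/ontology.obo --annotations fx/annotations.tsv \
    --samples fx/sample1.txt --samples fx/sample2.txt --leaves --out cmp
```

reports (in `cmp/compare.json`) K–S statistic 0.667 with p = 0.0097 and
Wilcoxon rank-sum p = 0.0028 over 12 leaf categories: the two lists'
raw leaf-level GO profiles differ, as expected since one list is twice
the size of the other and counts here are unnormalized.

The other subcommands are `distribution` (per-sample counts and
percentages of annotated genes, the pie-chart view) and `vs-genome`
(observed vs expected counts and goodness-of-fit tests against the
reference genome, via `--genome-size N` or `--gene-table FILE`).

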