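# hposhuffle

Phenotype-ontology-aware gene re-ranking (HPO-Shuffle), with the downstream
plumbing needed to turn a re-ranked gene list into a drug-repurposing query:
list integration with hypergeometric enrichment testing, rank-change
evaluation statistics, weighted co-expression module detection, and export
of directional up/down gene signatures in Connectivity Map GRP format.

## The problem

Single GWAS or expression-profiling experiments on complex neurological
disorders such as epilepsy rarely place the genes that are actually causal
near the top of their ranked lists — the association signal per gene is weak
and noisy. The Human Phenotype Ontology (HPO) offers an orthogonal line of
evidence: genes already annotated to phenotype terms characteristic of the
disease family are better candidates than genes with equal p-values but no
phenotypic support.

HPO-Shuffle combines the two. Given a disease-specific **Human Phenotype
Repository** (HPR) — the set of HPO terms annotated to a family of diseases
— each gene's association p-value *P*(*g*) is rescaled by the number
*m*(*g*) of its HPO terms that fall inside the repository:

```
HA(g) = P(g) / (m(g) + 1)
```

Lists are re-ordered by ascending HA, so phenotype-supported genes move
toward rank 1 while genes without relevant annotations keep their raw
p-value (`HA = P` exactly when `m = 0`). Two re-ranked lists (e.g. GWAS and
expression) are then reduced to their top fraction (default 75%),
intersected, and the intersection is tested for enrichment of known disease
genes with the exact hypergeometric upper tail. Co-expression modules of the
intersection genes are detected with the standard weighted-network recipe
(soft-threshold adjacency, topological overlap, average-linkage clustering),
associated with the sample trait through module eigengenes, and split into
up-/down-regulated signatures for a CMap query.

## Worked example

Every input format can be generated synthetically with planted ground truth
(2,000 genes of which 100 are "relevant": smaller p-values and ~3 repository
matching annotations on average, against ~0.2 for background genes):

```sh
hpo-shuffle simulate --seed 7 --out inputs
hpo-shuffle build-hpr --annotations inputs/disease_annotations.tsv --out hpr.txt
hpo-shuffle rerank --genes inputs/gwas_genes.tsv \
    --gene-annotations inputs/gene_annotations.tsv --hpr hpr.txt \
    --out reranked_gwas.tsv
hpo-shuffle evaluate --genes inputs/gwas_genes.tsv --reranked reranked_gwas.tsv \
    --known inputs/known_genes.txt --out changes.tsv
```

which prints

```
200 terms from 1 diseases -> hpr.txt
2000 genes re-ranked -> reranked_gwas.tsv
up=423 down=1573 same=4 max_up=1156 max_down=162
wilcoxon known-vs-other: W=165552.5 p=2.65e-31
```

Read: 423 genes moved up, and the Wilcoxon rank-sum test comparing the rank
deltas of the 100 planted relevant genes against the background rejects
overwhelmingly (p ≈ 3e-31) — the re-ranking concentrates the planted signal.
The re-ranked TSV carries rank, gene, raw p, matched-term count and HA;
a gene with one matching term has its score halved:

```
rank  gene    p_value       matched_terms  ha
1     G01055  4.38e-06      0              4.38e-06
2     G01137  8.17e-04      1              4.08e-04
```

Intersecting the top 75% of two re-ranked lists and testing against the
known-gene set:

```sh
hpo-shuffle integrate --gwas reranked_gwas.tsv --gep reranked_gep.tsv \
    --known inputs/known_genes.txt --universe-size 2000 --out intersection.txt
# intersection 1144 genes, 100 known, p=7.882e-26
```

The full pipeline (repository → re-ranking → evaluation → integration →
modules → GRP export, with a checksum manifest and per-stage resume) runs
from a single YAML config: `hpo-shuffle run --config config.yaml --out run/`.

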