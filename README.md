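# ringfam

Annotation toolkit for RING-H2 zinc-finger ubiquitin-ligase (ATL-type)
gene families: motif-grammar identification, protein feature annotation,
duplication-mode classification, phylogeny-guided nomenclature and
expression-responsiveness profiling — exercisable end-to-end on seeded
synthetic data with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `ringfam.ring_grammar` | scans proteins for the eight-ligand RING-H2 motif (C3H2C3) under a configurable spacing grammar; classifies PxC/PC subtypes and N-terminal structural categories |
| `ringfam.protein_features` | Kyte–Doolittle hydropathy profiles, TM/hydrophobic region calls, GLD-motif grading, pI/MW, external domain-table ingestion |
| `ringfam.genome_context` | GFF3 gene models (introns, ranks), top-k homology filtering, collinear-block chaining by dynamic programming, tandem/proximal/dispersed/segmental duplication calls, Fisher retention enrichment |
| `ringfam.phylo_naming` | alignment block curation, neighbor-joining, support collapsing, reference-anchored name assignment (same-number / lettered / new progressive numbers) |
| `ringfam.expression_profiles` | median centering, Pearson-distance hierarchical clustering, BH-FDR, responsive-gene flagging, weighted co-expression, permutation Mantel test |
| `ringfam.synthetic_data` | seeded generators for proteomes with planted motifs and decoys, genomes with planted duplication modes, expression matrices with planted clusters and responsive genes |
| `ringfam.cli_report` | the packaged 96-member family annotation table (integrity-checked), summary statistics, pipeline orchestration |

## CLI

```sh
ringfam report                      # summary counts of the packaged family table
ringfam simulate --seed 3 --outdir sim     # synthetic bundle + truth.json
ringfam scan sim/proteome.fasta --out matches.tsv
ringfam features sim/proteome.fasta
ringfam genome sim/genome.gff3 sim/hits.tsv
ringfam expr sim/expr.tsv --de sim/de.tsv --n-clusters 3
ringfam name tree.nwk               # needs reference leaves named e.g. AtATL43
ringfam all config.txt --outdir results   # full pipeline from key=value config
```

A pipeline config is a flat `key=value` file; recognised keys:
`proteome`, `domains`, `gff3`, `hits`, `tree`, `expr`, `de`,
`n_clusters`, `mantel`, `proline_rule`, `seed` (mandatory whenever
expression stages run).

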