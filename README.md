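# orthonorm

Cross-species comparative genomics needs a clean mapping of orthologous
genes — genes in different species descended from one gene in their last
common ancestor. The Alliance of Genome Resources (AGR) publishes
harmonized pairwise orthology calls for nine model organisms as a
tab-separated download, but its public API covers few query shapes and
there is no mechanism to fold in species it does not track.

`orthonorm` is a small service that fills both gaps:

1. **Normalize** — parse the combined-orthology TSV dialect (directed gene
   pairs with per-direction best-score flags and per-algorithm agreement
   counts) into a relational model: species, genes (namespace-prefixed
   accessions such as `HGNC:5` or `MGI:87853`), algorithms, and directed
   ortholog pairs.
2. **Augment** — add species absent from the canonical source by
   decomposing externally supplied homology clusters (GeneWeaver-style
   `gene`/`species`/`genedb` tables) into pairwise relationships. A member
   pair {x, y} of a cluster is kept iff at least one endpoint is from a
   newly added species, both endpoints resolve in the gene table, and the
   endpoints are from different species; kept pairs enter the ortholog
   table in both directions with provenance `added:<source>`.
3. **Cluster** — re-aggregate the pairwise table into homology clusters as
   connected components of the undirected pair graph, with incremental
   assignment of newly added genes (join, create, or merge clusters).
4. **Serve** — expose everything through a catalog of exactly 50 JSON
   endpoints in six categories (Genes, Species, Algorithms, Orthology,
   Homology, Integration), including identifier translation between the
   normalized namespace and the external system (`693363` ⇄
   `Entrez:693363`).

A built-in fixture generator emits a synthetic orthology TSV and
GeneWeaver-style CSVs with known ground truth, so the whole pipeline runs
and is testable offline.

## Worked example

```sh
orthonorm fixtures --out demo --seed 1
orthonorm ingest  --orthology-file demo/orthology.tsv --db demo/orthology.sqlite
# species=9 genes=96 algorithms=10 pairs=292 links=1628 skipped=0
orthonorm load-gw --gene demo/gene.csv --species demo/species.csv \
                  --genedb demo/genedb.csv --db demo/orthology.sqlite
# genedb=11 species=12 genes=122
orthonorm augment --clusters demo/clusters.csv \
                  --species "Macaca mulatta:9544" --species "Gallus gallus:9031" \
                  --species "Canis familiaris:9615" --db demo/orthology.sqlite
# new_species=3 new_genes=26 pairs_added=164 skipped_unknown=0 skipped_no_new=37 duplicates=0
orthonorm cluster --db demo/orthology.sqlite
# clusters=10 genes=122
orthonorm serve --db demo/orthology.sqlite --port 8000
```

The ingest line says the TSV contained 292 directed pairs over 96 genes of
the 9 canonical species, called by 10 algorithms. Augmentation registered
the 3 extra species and 26 of their genes, added 164 directed pairs
derived from the external clusters, and skipped 37 cluster pairs that
connected two already-canonical genes (those mappings are already covered
by the canonical data). Clustering grouped all 122 paired genes into 10
homology clusters.

With the service running (or through the WSGI app directly), the
species-to-species query that motivates the augmentation:

```
GET /api/v1/get_ortholog_by_to_and_from_species?from_sp_name=Macaca+mulatta&to_sp_name=Homo+sapiens

[{"ort_id": 329, "from_gene": 103, "to_gene": 79, "is_best": false, ...,
  "ort_source": "added:geneweaver",
  "from_gene_ref": "Entrez:709002", "to_gene_ref": "HGNC:10009"}, ...]
```

Each returned pair links a macaque gene (carried under its native Entrez
accession) to a human gene (HGNC accession); `ort_source` shows the pair
came from cluster decomposition, not the canonical file.
`GET /api/v1/_catalog` lists all 50 endpoints with their parameters.

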