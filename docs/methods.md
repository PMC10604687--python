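# Methods

## Data model

The normalized model is five tables plus three external-system tables.

- **species** (`sp_id`, binomial `sp_name`, NCBI `sp_taxon_id`,
  `sp_source ∈ {canonical, added}`). Names are unique case-insensitively;
  matching is exact otherwise (no fuzzy matching).
- **gene** (`gn_id`, curie `gn_ref_id`, `gn_prefix`, `gn_symbol`,
  `sp_id`). The prefix is the text before the first colon of the
  accession; colon-free accessions take their identifier source's
  registered prefix.
- **algorithm** (`alg_id`, `alg_name`) — the orthology-call algorithms are
  metadata labels only; no calls are computed here.
- **ortholog** (`ort_id`, `from_gene`, `to_gene`, `is_best`,
  `is_best_adjusted`, `is_best_revised`, `num_algorithms_match`,
  `out_of_algorithms`, `ort_source`). Rows are **directed**: the source
  file carries each orthologous gene pair in both directions, and the
  best-score flags are per-direction (the reverse-best column of A→B is
  the best column of B→A), so both rows are stored rather than collapsed.
  `(from_gene, to_gene)` is unique and both endpoints must be from
  different species.
- **homology** (`hom_id`, `gn_id`, `sp_id`, `hom_source`) — the cluster
  partition; each gene belongs to at most one cluster.
- **genedb / gw_gene / species_map** — the external identifier-source
  registry, external gene rows, and the species-key bijection used for
  cross-system translation.

The store is embedded sqlite behind a repository class; a file path gives
a persistent service database, no argument gives an in-memory store.
Internal keys are assigned in first-seen order starting at 1, so a fixed
ingestion order fixes all keys.

## Ingestion

The TSV dialect is 13 tab-separated columns (gene1 and gene2 id / symbol /
taxon token / species name, `|`-separated algorithm list, match and
out-of counts, and two tri-state best-score tokens `Yes` / `No` /
`Yes_Adjusted`), with `#` comment lines and one header line. Validation is
strict — wrong column count, unknown tri-state token, or inconsistent
counts fail with the line number — because silent coercion of a
half-broken download is worse than a parse error. The algorithm list
names the *matching* algorithms; its length equaling the match count is a
property of the fixture generator, not a dialect requirement, so the
parser does not enforce it.

Ingestion is idempotent: entities are get-or-created by their natural
keys, and a duplicate directed pair keeps the first row and is counted as
skipped. Re-ingesting the same rows therefore creates nothing.

## Species augmentation

External homology clusters are decomposed into candidate pairs under three
rules. For each unordered member pair {x, y} of a cluster:

1. **New-species rule** — at least one endpoint must belong to a newly
   added species. Pairs between two canonical genes are skipped (and
   counted): re-deriving canonical-canonical mappings from a coarser
   clustering would risk false positives, and they are already present.
2. **Resolution rule** — both endpoints must resolve in the gene table
   after identifier conversion. A member unknown to the normalized model
   is never invented; affected pairs are skipped and counted.
3. **Cross-species rule** — same-species members (paralogs within a
   cluster) yield no pair; the ortholog table is cross-species by
   construction.

Kept pairs are emitted in both directions with cleared best-score flags
and zero algorithm counts (the external source supplies neither) and
provenance `added:<source>`. Appending is deduplicated against everything
already stored — canonical rows, earlier clusters, and the current batch —
making augmentation idempotent, and canonical rows are never modified.

Two readings of the new-species rule are possible; the symmetric one is
implemented: a pair between two *different* new species is kept, because
excluding it would leave added species orphaned from each other. The
`new_new_pairs` flag (CLI `--new-new-pairs on|off`, default `on`) switches
to the stricter new↔existing-only reading.

Rule order for the skip counters: resolution failures are counted before
the new-species check (a pair with an unresolvable member counts as
unknown-gene even if it also lacks a new-species endpoint).

## Homology clustering

Clusters are connected components of the undirected projection of the
directed pair table — direction encodes scoring, not connectivity.
Implementation is a union-find (union by size, path compression); tests
cross-check it against an independent graph library's component finder.
Cluster ids are deterministic: components are numbered 1..k in ascending
order of their smallest member gene id. Singletons are not materialized —
clusters arise only from relationships.

Incremental assignment (`assign_new_genes`) seeds the union-find with the
existing partition and applies the added pairs: a new gene attached to one
cluster joins it, genes attached only to each other form a fresh cluster
(numbered after the current maximum), and an edge bridging existing
clusters merges them under the smaller id, with merges counted. The
incremental result provably equals a batch rebuild over the union of
edges, up to labels; merging (rather than refusing conflicting
assignments) was chosen because an added edge is positive evidence the
clusters belong together.

## Identifier translation

Conversion from external to normalized accessions is a prefix join
(`693363` under the Entrez source → `Entrez:693363`), idempotent by
construction: already-prefixed accessions pass through, and sources with
an empty prefix keep bare accessions. The per-source prefix table is data
(the genedb CSV), not code. The inverse lookup scans sources in
registration order, so if two sources could claim the same curie the
first-registered source wins; collisions at load time are logged.
Unmappable genes are skipped with a warning, never fabricated.

## API catalog

Exactly 50 endpoints in six categories (Genes 9, Species 4, Algorithms 3,
Orthology 14, Homology 6, Integration 14), served as a WSGI application
over the store; the stdlib server backs the CLI `serve` command and tests
call the WSGI interface directly, so no socket or HTTP client is needed.
The catalog composition is this package's own reconstruction around the
fixed total and category set: full-table dumps, single-key lookups, and
every parameter combination the tables support, plus the
integration routes (key translation both ways, species-map queries, and
ortholog/homology queries keyed by external gene ids). All responses are
JSON; list endpoints return an array (empty on no match, capped at 500
rows by default with `limit`/`offset` paging on `all_*` routes), failed
lookups return a structured `{"error": "not_found"}` payload with HTTP
404, and boolean parameters accept case-insensitive `true`/`false`.
`/api/v1/_catalog` (outside the count) lists descriptors for conformance
testing.

## Fixture generator

The generator emulates the two inputs, with defaults matching the study
conditions: nine canonical species with their real binomials and taxon
numbers, three added species (*Macaca mulatta*, *Gallus gallus*, *Canis
familiaris*), and a ten-name algorithm pool. Defaults of 25 planted
clusters of 2–5 members over 14 genes per species, and 12 external
clusters of 3–6 members, keep the whole pipeline in the hundreds-of-pairs
range — large enough that every filtering rule and endpoint has work to
do, small enough that the suite runs in seconds.

Planted orthology clusters draw members from distinct species
(least-used-first with random tie-breaks, so all nine species appear);
every cross-species pair is written in both directions with a shared
algorithm list and mirrored best/reverse-best flags. External clusters mix
1–3 added-species genes with canonical genes from the orthology fixture;
a configurable fraction of clusters (default 0.15) carries one member
that resolves nowhere, exercising the resolution rule. Added-species
accessions are stored source-native (bare Entrez/CGNC numerals) to
exercise the prefix join; canonical ones are stored fully prefixed to
exercise pass-through.

Ground truth is computed generator-side by independent brute force: the
expected post-filter pair set by enumerating all member pairs under the
three rules, and the expected final partition by a plain breadth-first
search over the union of planted and added edges. Accessions are shapes
only (`HGNC:<int>`, `WB:WBGene<8 digits>`, bare integers, ...) — no real
identifiers, no implied biology. A fixed seed yields byte-identical
output.

What the fixtures do *not* emulate: realistic ortholog-graph topology
(real clusters overlap ambiguously and best-score flags correlate with
algorithm counts), versioned or retired accessions, many-to-many
external-key mappings, and the scale of a real download (hundreds of
thousands of rows). Passing tests therefore demonstrate the relational
logic, filtering rules, and API contracts — not robustness to the noise
of production identifier data.

## Numerical and degenerate-input choices

- Duplicate directed input pairs: first wins, rest counted.
- Empty cluster CSV or empty species spec: no-ops, zero counts.
- A cluster with a single member yields no pairs.
- Tie-breaks everywhere are by smallest internal key, making every
  operation deterministic for a fixed input order.
- Seeds: fixtures accept any integer seed; the acceptance script reduces
  its seed modulo 2^31 before use.

## Known limitations

- Orthology is never inferred beyond the given clusters (no transitive
  closure across clusters; no scoring of added pairs).
- The catalog is read-only; no authentication, rate limiting, or write
  endpoints.
- Symbol-based matching and versioned-accession resolution are out of
  scope for identifier translation.
- The homology table is rebuilt in memory; at millions of pairs the
  union-find is fine but the per-gene writes would warrant batching.
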