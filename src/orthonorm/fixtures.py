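"""Synthetic fixture generator with planted ground truth.

Emits (a) an orthology TSV in the combined-orthology dialect covering the
nine canonical model organisms, built from planted homology clusters whose
cross-species pairs appear in both directions with mutually consistent
best-score flags, and (b) GeneWeaver-style CSV tables (gene, species,
genedb, clusters) supplying three additional species plus a configurable
fraction of unresolvable cluster members, so that every ingestion,
translation, augmentation, and clustering path is exercisable offline.

Accessions are synthesized per namespace shape only (HGNC:<int>,
WB:WBGene<8 digits>, bare Entrez integers, ...); none are real identifiers
and no real biology is implied. A fixed seed yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .models import InputError

# (binomial, NCBI taxon, native identifier source)
CANONICAL_SPECIES: list[tuple[str, int, str]] = [
    ("Homo sapiens", 9606, "HGNC"),
    ("Mus musculus", 10090, "MGI"),
    ("Rattus norvegicus", 10116, "RGD"),
    ("Danio rerio", 7955, "ZFIN"),
    ("Drosophila melanogaster", 7227, "FB"),
    ("Caenorhabditis elegans", 6239, "WB"),
    ("Saccharomyces cerevisiae", 559292, "SGD"),
    ("Xenopus laevis", 8355, "Xenbase"),
    ("Xenopus tropicalis", 8364, "Xenbase"),
]

DEFAULT_ADDED_SPECIES: list[tuple[str, int, str]] = [
    ("Macaca mulatta", 9544, "Entrez"),
    ("Gallus gallus", 9031, "CGNC"),
    ("Canis familiaris", 9615, "Entrez"),
]

DEFAULT_ALGORITHMS = (
    "PANTHER", "OMA", "OrthoFinder", "OrthoInspector", "InParanoid",
    "PhylomeDB", "TreeFam", "Hieranoid", "Ensembl Compara", "SonicParanoid",
)

# genedb registry: (gdb_id, gdb_name, curie_prefix)
GENEDB_REGISTRY: list[tuple[int, str, str]] = [
    (1, "Entrez", "Entrez"),
    (2, "HGNC", "HGNC"),
    (3, "MGI", "MGI"),
    (4, "Ensembl Gene", "Ensembl"),
    (5, "CGNC", "CGNC"),
    (6, "RGD", "RGD"),
    (7, "ZFIN", "ZFIN"),
    (8, "FB", "FB"),
    (9, "WB", "WB"),
    (10, "SGD", "SGD"),
    (11, "Xenbase", "Xenbase"),
]

_GDB_BY_PREFIX = {prefix: gdb_id for gdb_id, _, prefix in GENEDB_REGISTRY}

# accession shape per identifier source
_ACCESSION_SHAPE = {
    "HGNC": lambda i: f"HGNC:{10000 + i}",
    "MGI": lambda i: f"MGI:{87000 + i}",
    "RGD": lambda i: f"RGD:{60000 + i}",
    "ZFIN": lambda i: f"ZFIN:ZDB-GENE-{i:06d}",
    "FB": lambda i: f"FB:FBgn{i:07d}",
    "WB": lambda i: f"WB:WBGene{i:08d}",
    "SGD": lambda i: f"SGD:S{i:09d}",
    "Xenbase": lambda i: f"Xenbase:XB-GENE-{i:07d}",
    "Entrez": lambda i: f"Entrez:{700000 + i}",
    "CGNC": lambda i: f"CGNC:{50000 + i}",
    "Ensembl": lambda i: f"Ensembl:ENSX{i:011d}",
}

BEST_TOKEN_WEIGHTS = (("Yes", 0.6), ("No", 0.3), ("Yes_Adjusted", 0.1))


@dataclass
class FixtureSpec:
    """Knobs of the synthetic data set; defaults match the study conditions
    (nine canonical species, three added species)."""

    n_canonical_species: int = 9
    genes_per_species: int = 14
    n_clusters: int = 25
    cluster_size_range: tuple[int, int] = (2, 5)
    added_species: list[tuple[str, int, str]] = field(
        default_factory=lambda: list(DEFAULT_ADDED_SPECIES))
    algorithm_pool: tuple[str, ...] = DEFAULT_ALGORITHMS
    seed: int = 0
    n_gw_clusters: int = 12
    gw_cluster_size_range: tuple[int, int] = (3, 6)
    unresolvable_fraction: float = 0.15

    def validate(self) -> None:
        if not (1 <= self.n_canonical_species <= len(CANONICAL_SPECIES)):
            raise InputError("n_canonical_species out of range")
        for name, rng in (("cluster_size_range", self.cluster_size_range),
                          ("gw_cluster_size_range", self.gw_cluster_size_range)):
            if rng[0] < 1 or rng[0] > rng[1]:
                raise InputError(f"invalid {name}: {rng}")
        if self.cluster_size_range[1] > self.n_canonical_species:
            raise InputError("cluster size exceeds species count")
        if self.genes_per_species < 1 or self.n_clusters < 0 or self.n_gw_clusters < 0:
            raise InputError("counts must be positive")
        if not 0.0 <= self.unresolvable_fraction <= 1.0:
            raise InputError("unresolvable_fraction must be in [0, 1]")
        if not self.algorithm_pool:
            raise InputError("algorithm pool is empty")


@dataclass
class AgrGroundTruth:
    """What was planted in the orthology TSV."""

    clusters: list[frozenset[str]]          # planted partitions, by accession
    directed_pairs: list[tuple[str, str]]   # one entry per emitted data line
    gene_species: dict[str, str]            # accession -> binomial
    species: list[tuple[str, int, str]]


@dataclass
class GwGroundTruth:
    """Expected outcome of augmenting with the GeneWeaver-style tables."""

    added_species: list[tuple[str, int, str]]
    new_gene_refs: set[str]                    # curie form, after conversion
    expected_added_pairs: set[tuple[str, str]]  # directed, by curie
    emitted_directed: int                      # before any deduplication
    skipped_unknown: int
    skipped_no_new: int
    expected_clusters: list[frozenset[str]]    # components of agr + added pairs
    gene_species: dict[str, str]


def _gene_pools(spec: FixtureSpec, species: list[tuple[str, int, str]],
                start: int = 1) -> dict[str, list[tuple[str, str]]]:
    """Per-species ordered pools of (accession, symbol)."""
    pools: dict[str, list[tuple[str, str]]] = {}
    counter = start
    for name, _taxon, source in species:
        shape = _ACCESSION_SHAPE[source]
        abbrev = "".join(w[0] for w in name.lower().split())
        pool = []
        for _ in range(spec.genes_per_species):
            pool.append((shape(counter), f"{abbrev}g{counter}"))
            counter += 1
        pools[name] = pool
    return pools


def generate_agr_fixture(spec: FixtureSpec) -> tuple[str, AgrGroundTruth]:
    """Emit the orthology TSV plus its planted ground truth.

    Each planted cluster draws members from distinct canonical species, and
    every cross-species member pair is written in both directions. The two
    directions share the algorithm list, and the reverse-best column of one
    direction equals the best column of the other, as in the real dialect.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    species = CANONICAL_SPECIES[: spec.n_canonical_species]
    taxon_of = {name: taxon for name, taxon, _ in species}
    pools = _gene_pools(spec, species)
    remaining = {name: list(pool) for name, pool in pools.items()}

    truth = AgrGroundTruth([], [], {}, list(species))
    lines = [
        "# synthetic combined-orthology fixture",
        f"# seed={spec.seed}",
        "# columns: tab-separated, one directed gene pair per line",
    ]
    lines.append("\t".join((
        "Gene1ID", "Gene1Symbol", "Gene1SpeciesTaxonID", "Gene1SpeciesName",
        "Gene2ID", "Gene2Symbol", "Gene2SpeciesTaxonID", "Gene2SpeciesName",
        "Algorithms", "AlgorithmsMatch", "OutOfAlgorithms", "IsBestScore", "IsBestRevScore",
    )))

    tokens, weights = zip(*BEST_TOKEN_WEIGHTS)
    usage = {name: 0 for name, _, _ in species}
    for _ in range(spec.n_clusters):
        size = rng.randint(*spec.cluster_size_range)
        available = [name for name in remaining if remaining[name]]
        if len(available) < size:
            raise InputError("genes_per_species too small for requested clusters")
        # least-used species first (random tie-break) so every species is
        # represented once enough clusters are drawn
        chosen = sorted(available, key=lambda n: (usage[n], rng.random()))[:size]
        for name in chosen:
            usage[name] += 1
        members = []
        for sp_name in chosen:
            ref, symbol = remaining[sp_name].pop(0)
            members.append((ref, symbol, sp_name))
            truth.gene_species[ref] = sp_name
        truth.clusters.append(frozenset(ref for ref, _, _ in members))
        for i in range(size):
            for j in range(i + 1, size):
                a_ref, a_sym, a_sp = members[i]
                b_ref, b_sym, b_sp = members[j]
                k = rng.randint(1, len(spec.algorithm_pool))
                algorithms = rng.sample(list(spec.algorithm_pool), k)
                out_of = rng.randint(k, len(spec.algorithm_pool))
                fwd = rng.choices(tokens, weights)[0]
                rev = rng.choices(tokens, weights)[0]
                for (g1, s1, sp1, g2, s2, sp2, best, best_rev) in (
                        (a_ref, a_sym, a_sp, b_ref, b_sym, b_sp, fwd, rev),
                        (b_ref, b_sym, b_sp, a_ref, a_sym, a_sp, rev, fwd)):
                    lines.append("\t".join((
                        g1, s1, f"NCBITaxon:{taxon_of[sp1]}", sp1,
                        g2, s2, f"NCBITaxon:{taxon_of[sp2]}", sp2,
                        "|".join(algorithms), str(k), str(out_of), best, best_rev,
                    )))
                    truth.directed_pairs.append((g1, g2))
    return "\n".join(lines) + "\n", truth


def generate_gw_fixture(spec: FixtureSpec) -> tuple[dict[str, str], GwGroundTruth]:
    """Emit GeneWeaver-style gene/species/genedb/clusters CSVs + ground truth.

    Clusters mix genes from the added species with canonical genes drawn
    from the orthology fixture; a configurable fraction of clusters carries
    one member that resolves nowhere in the normalized gene table, to
    exercise the unknown-gene filtering rule. The expected post-filter pair
    set is enumerated here by brute force, independently of the
    augmentation code path.
    """
    spec.validate()
    _, agr_truth = generate_agr_fixture(spec)
    rng = random.Random(spec.seed * 2 + 1)

    gw_sp_ids: dict[str, int] = {}
    species_rows = []
    for n, (name, taxon, _src) in enumerate(agr_truth.species + spec.added_species):
        gw_sp_ids[name] = 101 + n
        species_rows.append(f"{101 + n},{name},{taxon}")

    # gene table: canonical genes stored fully prefixed, added-species genes
    # stored source-native (bare for Entrez/CGNC-shaped accessions)
    gene_rows = []
    ode_of: dict[str, int] = {}
    next_ode = 5001

    def register_gw_gene(stored_ref: str, gdb_id: int, sp_name: str) -> None:
        nonlocal next_ode
        key = f"{gdb_id}|{stored_ref}"
        if key in ode_of:
            return
        ode_of[key] = next_ode
        gene_rows.append(f"{next_ode},{stored_ref},{gdb_id},{gw_sp_ids[sp_name]}")
        next_ode += 1

    prefix_of_sp = {name: src for name, _t, src in CANONICAL_SPECIES + spec.added_species}
    for ref, sp_name in agr_truth.gene_species.items():
        gdb_id = _GDB_BY_PREFIX[prefix_of_sp[sp_name]]
        register_gw_gene(ref, gdb_id, sp_name)

    added_pools = _gene_pools(spec, spec.added_species, start=9001)

    canonical_refs = sorted(agr_truth.gene_species)
    cluster_rows = []
    # member: (stored_ref, gdb_id, sp_name, curie, resolvable, is_new)
    clusters: list[list[tuple]] = []
    unresolvable_counter = 0
    for c in range(spec.n_gw_clusters):
        size = rng.randint(*spec.gw_cluster_size_range)
        n_new = rng.randint(1, min(size - 1, len(spec.added_species))) if size > 1 else 1
        members = []
        for sp_name, _taxon, src in rng.sample(spec.added_species, n_new):
            pool = added_pools[sp_name]
            if not pool:
                raise InputError("genes_per_species too small for GW clusters")
            curie, _symbol = pool.pop(0)
            stored = curie.split(":", 1)[1] if src in ("Entrez", "CGNC") else curie
            members.append((stored, _GDB_BY_PREFIX[src], sp_name, curie, True, True))
        for curie in rng.sample(canonical_refs, size - n_new):
            sp_name = agr_truth.gene_species[curie]
            members.append((curie, _GDB_BY_PREFIX[prefix_of_sp[sp_name]],
                            sp_name, curie, True, False))
        if rng.random() < spec.unresolvable_fraction:
            unresolvable_counter += 1
            fake = f"HGNC:{9900000 + unresolvable_counter}"
            members.append((fake, _GDB_BY_PREFIX["HGNC"], "Homo sapiens", fake, False, False))
        clusters.append(members)
        for stored, gdb_id, sp_name, _curie, _ok, _new in members:
            register_gw_gene(stored, gdb_id, sp_name)
            cluster_rows.append(f"gwc{c + 1},{stored},{gdb_id},{gw_sp_ids[sp_name]}")

    # brute-force expectation under the three decomposition rules
    agr_pair_set = set(agr_truth.directed_pairs)
    expected: set[tuple[str, str]] = set()
    emitted = skipped_unknown = skipped_no_new = 0
    gene_species = dict(agr_truth.gene_species)
    new_gene_refs: set[str] = set()
    for members in clusters:
        for m in members:
            if m[5]:
                new_gene_refs.add(m[3])
                gene_species[m[3]] = m[2]
        n = len(members)
        for i in range(n):
            for j in range(i + 1, n):
                x, y = members[i], members[j]
                if not (x[4] and y[4]):
                    skipped_unknown += 1
                elif not (x[5] or y[5]):
                    skipped_no_new += 1
                elif x[2] == y[2]:
                    pass  # same-species members yield no ortholog pair
                else:
                    emitted += 2
                    expected.add((x[3], y[3]))
                    expected.add((y[3], x[3]))
    expected -= agr_pair_set

    all_edges = [tuple(p) for p in agr_pair_set | expected]
    expected_clusters = _components_by_ref(all_edges)

    csvs = {
        "genedb.csv": "gdb_id,gdb_name,curie_prefix\n" + "\n".join(
            f"{i},{name},{prefix}" for i, name, prefix in GENEDB_REGISTRY) + "\n",
        "species.csv": "sp_id,sp_name,sp_taxonid\n" + "\n".join(species_rows) + "\n",
        "gene.csv": "ode_gene_id,ode_ref_id,gdb_id,sp_id\n" + "\n".join(gene_rows) + "\n",
        "clusters.csv": "cluster_id,ode_ref_id,gdb_id,sp_id\n" + "\n".join(cluster_rows) + "\n",
    }
    truth = GwGroundTruth(
        added_species=list(spec.added_species),
        new_gene_refs=new_gene_refs,
        expected_added_pairs=expected,
        emitted_directed=emitted,
        skipped_unknown=skipped_unknown,
        skipped_no_new=skipped_no_new,
        expected_clusters=expected_clusters,
        gene_species=gene_species,
    )
    return csvs, truth


def _components_by_ref(edges: list[tuple[str, str]]) -> list[frozenset[str]]:
    """Plain breadth-first-search components over accession strings."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    out: list[frozenset[str]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        seen.add(start)
        while queue:
            node = queue.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    queue.append(nxt)
        out.append(frozenset(comp))
    return out


def write_fixtures(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Write the TSV and CSVs (plus ground-truth JSON) under ``outdir``."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    tsv, agr_truth = generate_agr_fixture(spec)
    csvs, gw_truth = generate_gw_fixture(spec)
    paths = {}
    with open(os.path.join(outdir, "orthology.tsv"), "w", encoding="utf-8") as fh:
        fh.write(tsv)
    paths["orthology"] = os.path.join(outdir, "orthology.tsv")
    for name, text in csvs.items():
        p = os.path.join(outdir, name)
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(text)
        paths[name] = p
    summary = {
        "planted_agr_clusters": len(agr_truth.clusters),
        "agr_directed_pairs": len(agr_truth.directed_pairs),
        "expected_added_pairs": len(gw_truth.expected_added_pairs),
        "expected_final_clusters": len(gw_truth.expected_clusters),
        "added_species": [name for name, _, _ in gw_truth.added_species],
    }
    gt_path = os.path.join(outdir, "ground_truth.json")
    with open(gt_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    paths["ground_truth"] = gt_path
    return paths
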