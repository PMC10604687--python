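"""Add species absent from the canonical source by decomposing external
homology clusters into filtered pairwise ortholog calls.

An external cluster is a set of genes asserted to be mutually homologous.
Each unordered member pair {x, y} yields the two directed ortholog rows
x->y and y->x if and only if:

1. at least one of x, y belongs to a newly added species — mappings that do
   not involve a new species are already covered by the canonical data and
   re-deriving them from a coarser source would invite false positives;
2. both x and y resolve in the gene table — a cluster member unknown to the
   normalized model is dropped rather than invented;
3. x and y are from different species — same-species members (paralogs)
   produce no ortholog row.

Added pairs carry cleared best-score flags and zero algorithm counts (the
external source supplies neither) and a distinguishing ``added:<source>``
provenance; canonical rows are never touched.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field

from .id_mapping import gw_ref_to_agr_ref
from .models import AugmentationReport, ConflictError, InputError, NotFoundError, OrthologPair
from .store import Store

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterMember:
    """One cluster member in external coordinates."""

    ode_ref_id: str
    gdb_id: int
    gw_sp_id: int


@dataclass
class ExternalCluster:
    cluster_id: str
    members: list[ClusterMember]
    source_name: str = "geneweaver"


def read_clusters_csv(path: str | os.PathLike, source_name: str = "geneweaver") -> list[ExternalCluster]:
    """Read clusters from CSV rows (cluster_id, ode_ref_id, gdb_id, sp_id)."""
    if not os.path.exists(path):
        raise InputError(f"clusters file not found: {path}")
    grouped: dict[str, ExternalCluster] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            member = ClusterMember(rec["ode_ref_id"], int(rec["gdb_id"]), int(rec["sp_id"]))
            cl = grouped.setdefault(
                rec["cluster_id"], ExternalCluster(rec["cluster_id"], [], source_name))
            cl.members.append(member)
    return list(grouped.values())


def _convert_ref(store: Store, member: ClusterMember) -> str | None:
    gdb = store.genedb_by_id(member.gdb_id)
    if gdb is None:
        return None
    return gw_ref_to_agr_ref(member.ode_ref_id, gdb)


def register_new_species(store: Store, clusters: list[ExternalCluster],
                         species_spec: list[tuple[str, int]]) -> tuple[set[int], int, int]:
    """Register missing species and the cluster genes that belong to them.

    ``species_spec`` lists (binomial name, NCBI taxon) of species to add;
    each must be absent from the species table and present in the loaded
    external species table. Every cluster member from a new species gets a
    gene row keyed by its converted (curie) accession.

    Returns (set of new sp_ids, species added, genes added).
    """
    new_sp_ids: set[int] = set()
    gw_to_new_sp: dict[int, int] = {}
    n_species = 0
    for name, taxon in species_spec:
        if store.species_by_name(name) is not None:
            raise ConflictError(f"species already registered: {name!r}")
        sp = store.add_species(name, taxon, "added")
        n_species += 1
        new_sp_ids.add(sp.sp_id)
        gw_row = store.gw_species_by_name(name)
        if gw_row is None:
            raise NotFoundError(f"new species {name!r} absent from external species table")
        store.add_species_map(sp.sp_id, gw_row["gw_sp_id"])
        gw_to_new_sp[gw_row["gw_sp_id"]] = sp.sp_id

    n_genes = 0
    for cluster in clusters:
        for member in cluster.members:
            sp_id = gw_to_new_sp.get(member.gw_sp_id)
            if sp_id is None:
                continue
            ref = _convert_ref(store, member)
            if ref is None:
                log.warning("unmappable accession %r (genedb %s); skipped",
                            member.ode_ref_id, member.gdb_id)
                continue
            prefix, local = (ref.split(":", 1) if ":" in ref else ("", ref))
            _, created = store.get_or_create_gene(ref, prefix, local, sp_id)
            n_genes += int(created)
    store.commit()
    return new_sp_ids, n_species, n_genes


def decompose_clusters(store: Store, clusters: list[ExternalCluster],
                       new_species: set[int], new_new_pairs: bool = True,
                       report: AugmentationReport | None = None) -> list[OrthologPair]:
    """Decompose clusters into directed candidate pairs under the three rules.

    Rule violations are skipped and counted, never raised. Returned pairs
    are unsaved (ort_id 0); :func:`dedupe_and_append` persists them.
    ``new_new_pairs=False`` additionally drops pairs whose endpoints are
    both from new species, keeping only new<->existing mappings.
    """
    if report is None:
        report = AugmentationReport()
    pairs: list[OrthologPair] = []
    for cluster in clusters:
        resolved = []
        for member in cluster.members:
            ref = _convert_ref(store, member)
            gene = store.gene_by_ref(ref) if ref is not None else None
            resolved.append(gene)
        n = len(cluster.members)
        for i in range(n):
            for j in range(i + 1, n):
                x, y = resolved[i], resolved[j]
                if x is None or y is None:
                    report.pairs_skipped_unknown_gene += 1
                    continue
                x_new, y_new = x.sp_id in new_species, y.sp_id in new_species
                if not (x_new or y_new):
                    report.pairs_skipped_no_new_species += 1
                    continue
                if x_new and y_new and not new_new_pairs:
                    report.pairs_skipped_no_new_species += 1
                    continue
                if x.sp_id == y.sp_id:
                    continue  # paralogs: the ortholog table is cross-species
                source = f"added:{cluster.source_name}"
                pairs.append(OrthologPair(0, x.gn_id, y.gn_id, False, False, False, 0, 0, source))
                pairs.append(OrthologPair(0, y.gn_id, x.gn_id, False, False, False, 0, 0, source))
    return pairs


def dedupe_and_append(store: Store, pairs: list[OrthologPair],
                      report: AugmentationReport | None = None) -> AugmentationReport:
    """Append candidate pairs, skipping any directed pair already stored.

    Deduplicates both within the batch (overlapping clusters) and against
    pairs already present from canonical ingest or earlier augmentations,
    which makes the whole augmentation idempotent.
    """
    if report is None:
        report = AugmentationReport()
    for p in pairs:
        if store.pair_exists(p.from_gene, p.to_gene):
            report.duplicates_removed += 1
            continue
        store.add_pair(p.from_gene, p.to_gene, p.is_best, p.is_best_adjusted,
                       p.is_best_revised, p.num_algorithms_match, p.out_of_algorithms,
                       p.ort_source)
        report.pairs_added += 1
    store.commit()
    return report


def augment(store: Store, clusters: list[ExternalCluster],
            species_spec: list[tuple[str, int]],
            new_new_pairs: bool = True) -> AugmentationReport:
    """Full augmentation: register species and genes, decompose, append."""
    report = AugmentationReport()
    new_sp_ids, report.new_species, report.new_genes = register_new_species(
        store, clusters, species_spec)
    pairs = decompose_clusters(store, clusters, new_sp_ids, new_new_pairs, report)
    dedupe_and_append(store, pairs, report)
    log.info("augment: %s", report)
    return report
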