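"""Aggregate the pairwise ortholog table into homology clusters.

A homology cluster is a connected component of the undirected graph whose
edges are the stored directed pairs (direction encodes scoring, not
connectivity). Genes with no pairs belong to no cluster; singleton clusters
are not materialized. Cluster ids are deterministic: clusters are numbered
1..k in ascending order of their smallest member gene id, so rebuilding
from the same table reproduces identical ids.

New genes arriving with augmentation pairs are sorted incrementally: a gene
linked to one existing cluster joins it, genes linked only to each other
form a new cluster, and an edge bridging two existing clusters merges them
under the smaller cluster id. The incremental result always equals a batch
rebuild over the union of old and new pairs, up to cluster labels.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

from .models import AssignReport, HomologyMembership, OrthologPair
from .store import Store

log = logging.getLogger(__name__)


class UnionFind:
    """Disjoint-set forest with union by size and path compression."""

    def __init__(self):
        self._parent: dict[int, int] = {}
        self._size: dict[int, int] = {}

    def add(self, x: int) -> None:
        if x not in self._parent:
            self._parent[x] = x
            self._size[x] = 1

    def find(self, x: int) -> int:
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        """Join the sets of a and b; True if they were distinct."""
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self._size[ra] < self._size[rb]:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._size[ra] += self._size[rb]
        return True

    def components(self) -> list[set[int]]:
        groups: dict[int, set[int]] = {}
        for x in self._parent:
            groups.setdefault(self.find(x), set()).add(x)
        return list(groups.values())


def components_of_edges(edges: Iterable[tuple[int, int]]) -> list[set[int]]:
    """Connected components of an undirected edge list."""
    uf = UnionFind()
    for a, b in edges:
        uf.union(a, b)
    return uf.components()


def _number_clusters(components: list[set[int]]) -> dict[int, set[int]]:
    """Assign ids 1..k in ascending order of smallest member gene id."""
    ordered = sorted(components, key=min)
    return {i: comp for i, comp in enumerate(ordered, start=1)}


def _write_memberships(store: Store, clusters: dict[int, set[int]]) -> None:
    store.clear_homology()
    for hom_id, members in clusters.items():
        for gn_id in sorted(members):
            gene = store.gene_by_id(gn_id)
            species = store.species_by_id(gene.sp_id)
            source = "agr" if species.sp_source == "canonical" else "added"
            store.add_membership(hom_id, gn_id, gene.sp_id, source)
    store.commit()


def build_clusters(store: Store) -> dict[int, set[int]]:
    """Rebuild the homology table from scratch; returns {hom_id: gene ids}."""
    clusters = _number_clusters(components_of_edges(store.iter_pair_edges()))
    _write_memberships(store, clusters)
    log.info("built %d homology clusters", len(clusters))
    return clusters


def assign_new_genes(store: Store, added_pairs: list[OrthologPair]) -> tuple[dict[int, set[int]], AssignReport]:
    """Sort genes from newly added pairs into the existing cluster partition.

    Existing memberships are read from the homology table; added edges are
    applied incrementally. Clusters connected by a new edge merge and keep
    the smaller of their ids; genes connected only to new genes form fresh
    clusters numbered after the current maximum. The resulting partition
    equals ``build_clusters`` over the union of old and new pairs.
    """
    existing = store.all_memberships()
    old_cluster_of: dict[int, int] = {m.gn_id: m.hom_id for m in existing}
    old_clusters: dict[int, set[int]] = {}
    for m in existing:
        old_clusters.setdefault(m.hom_id, set()).add(m.gn_id)

    uf = UnionFind()
    for members in old_clusters.values():
        members = sorted(members)
        for g in members[1:]:
            uf.union(members[0], g)
        uf.add(members[0])
    for p in added_pairs:
        uf.union(p.from_gene, p.to_gene)

    report = AssignReport()
    final: dict[int, set[int]] = {}  # new hom_id -> members
    fresh: list[set[int]] = []
    next_id = max(old_clusters, default=0) + 1
    for comp in uf.components():
        old_ids = {old_cluster_of[g] for g in comp if g in old_cluster_of}
        if old_ids:
            report.merges += len(old_ids) - 1
            report.placed_in_existing += sum(1 for g in comp if g not in old_cluster_of)
            final[min(old_ids)] = comp  # merge keeps the smaller id
        else:
            fresh.append(comp)
    for comp in sorted(fresh, key=min):
        final[next_id] = comp
        next_id += 1
        report.new_clusters += 1

    _write_memberships(store, final)
    log.info("assign: %s", report)
    return final, report
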