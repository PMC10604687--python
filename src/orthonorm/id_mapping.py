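"""Identifier and species translation between the normalized namespace and a
GeneWeaver-style external system.

The external system keys genes by an internal integer (``ode_gene_id``) and
stores source-native accessions (``ode_ref_id``) whose meaning depends on a
``genedb`` registry row (Entrez, HGNC, Ensembl Gene, ...). Translation to
the normalized namespace is a deterministic prefix join: a bare Entrez
accession ``693363`` becomes the curie ``Entrez:693363``, while an already
prefixed ``MGI:87853`` passes through unchanged. Species are matched by
binomial name, case-insensitively, and linked by an explicit species map.
"""

from __future__ import annotations

import csv
import logging
import os

from .models import GenedbEntry, GWGene, InputError, NotFoundError
from .store import Store

log = logging.getLogger(__name__)


def gw_ref_to_agr_ref(ode_ref_id: str, gdb: GenedbEntry) -> str:
    """Convert a source-native accession to its prefixed (curie) form.

    Idempotent: accessions already carrying the source's prefix are returned
    unchanged, so applying the conversion twice equals applying it once.
    Sources with an empty ``curie_prefix`` keep bare accessions as-is.
    """
    if not ode_ref_id:
        raise InputError("empty accession")
    if not gdb.curie_prefix:
        return ode_ref_id
    if ode_ref_id.startswith(gdb.curie_prefix + ":"):
        return ode_ref_id
    return f"{gdb.curie_prefix}:{ode_ref_id}"


def agr_ref_to_ode_gene(store: Store, agr_ref: str) -> GWGene:
    """Find the external gene whose converted accession equals ``agr_ref``.

    Inverse of :func:`gw_ref_to_agr_ref` on mapped genes. When several
    genedb sources could produce the same curie, the first-registered source
    wins (lowest ``gdb_id``).
    """
    if not agr_ref:
        raise InputError("empty accession")
    for gdb in store.all_genedb():  # ordered by gdb_id: first registered wins
        candidates = []
        if gdb.curie_prefix and agr_ref.startswith(gdb.curie_prefix + ":"):
            local = agr_ref[len(gdb.curie_prefix) + 1:]
            candidates = [local, agr_ref]  # bare or already-prefixed storage
        elif not gdb.curie_prefix:
            candidates = [agr_ref]
        for ref in candidates:
            hit = store.gw_gene_by_ref(ref, gdb.gdb_id)
            if hit is not None:
                return hit
    raise NotFoundError(f"no external gene maps to {agr_ref!r}")


def translate_species(store: Store, name_or_id, direction: str = "to_agr") -> int:
    """Resolve a species to an internal or external key.

    ``direction="to_agr"``: a binomial name (case-insensitive) or an
    external ``gw_sp_id`` resolves to the internal ``sp_id``.
    ``direction="to_gw"``: a name or internal ``sp_id`` resolves to the
    mapped external key.
    """
    if direction not in ("to_agr", "to_gw"):
        raise InputError(f"unknown direction {direction!r}")
    if isinstance(name_or_id, str):
        sp = store.species_by_name(name_or_id)
        if sp is None:
            raise NotFoundError(f"unknown species {name_or_id!r}")
        if direction == "to_agr":
            return sp.sp_id
        gw = store.gw_id_for_sp(sp.sp_id)
        if gw is None:
            raise NotFoundError(f"species {name_or_id!r} has no external mapping")
        return gw
    key = int(name_or_id)
    if direction == "to_agr":
        sp_id = store.sp_id_for_gw(key)
        if sp_id is None:
            raise NotFoundError(f"external species key {key} is not mapped")
        return sp_id
    gw = store.gw_id_for_sp(key)
    if gw is None:
        raise NotFoundError(f"species id {key} has no external mapping")
    return gw


def _read_csv(path: str | os.PathLike) -> list[dict]:
    if not os.path.exists(path):
        raise InputError(f"file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_genedb_csv(store: Store, path: str | os.PathLike) -> int:
    """Load the identifier-source registry (gdb_id, gdb_name, curie_prefix)."""
    n = 0
    seen_prefixes: dict[str, str] = {}
    for rec in _read_csv(path):
        prefix = rec.get("curie_prefix", "")
        if prefix and prefix in seen_prefixes:
            log.warning("curie prefix %r already registered by %r; first wins",
                        prefix, seen_prefixes[prefix])
        else:
            seen_prefixes[prefix] = rec["gdb_name"]
        store.add_genedb(int(rec["gdb_id"]), rec["gdb_name"], prefix)
        n += 1
    store.commit()
    return n


def load_gw_species_csv(store: Store, path: str | os.PathLike) -> int:
    """Load external species rows and map name-matches to internal species."""
    n = 0
    for rec in _read_csv(path):
        gw_sp_id = int(rec["sp_id"])
        taxon = int(rec["sp_taxonid"]) if rec.get("sp_taxonid") else None
        store.add_gw_species(gw_sp_id, rec["sp_name"], taxon)
        sp = store.species_by_name(rec["sp_name"])
        if sp is not None:
            store.add_species_map(sp.sp_id, gw_sp_id)
        n += 1
    store.commit()
    return n


def load_gw_gene_csv(store: Store, path: str | os.PathLike) -> int:
    """Load external gene rows (ode_gene_id, ode_ref_id, gdb_id, sp_id)."""
    n = 0
    for rec in _read_csv(path):
        if store.genedb_by_id(int(rec["gdb_id"])) is None:
            log.warning("gene %s references unregistered genedb %s; skipped",
                        rec["ode_ref_id"], rec["gdb_id"])
            continue
        store.add_gw_gene(int(rec["ode_gene_id"]), rec["ode_ref_id"],
                          int(rec["gdb_id"]), int(rec["sp_id"]))
        n += 1
    store.commit()
    return n


def load_gw_tables(store: Store, gene_csv, species_csv, genedb_csv) -> dict[str, int]:
    """Load genedb, species, and gene CSVs in dependency order."""
    return {
        "genedb": load_genedb_csv(store, genedb_csv),
        "species": load_gw_species_csv(store, species_csv),
        "genes": load_gw_gene_csv(store, gene_csv),
    }
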