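"""Embedded relational store for the normalized orthology model.

A thin repository over sqlite3. The default is a file-backed database so a
local service needs no server; ``Store()`` with no argument gives an
in-memory database for tests and throwaway pipelines. Internal keys are
rowids assigned in first-seen order starting at 1, so ingestion order fixes
the keys and fixture runs are reproducible.
"""

from __future__ import annotations

import sqlite3
from collections.abc import Iterable, Iterator

from .models import (
    AlgorithmRecord,
    ConflictError,
    GenedbEntry,
    GeneRecord,
    GWGene,
    HomologyMembership,
    NotFoundError,
    OrthologPair,
    SpeciesMapEntry,
    SpeciesRecord,
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS species (
    sp_id INTEGER PRIMARY KEY,
    sp_name TEXT NOT NULL UNIQUE COLLATE NOCASE,
    sp_taxon_id INTEGER NOT NULL UNIQUE,
    sp_source TEXT NOT NULL CHECK (sp_source IN ('canonical', 'added'))
);
CREATE TABLE IF NOT EXISTS gene (
    gn_id INTEGER PRIMARY KEY,
    gn_ref_id TEXT NOT NULL UNIQUE,
    gn_prefix TEXT NOT NULL,
    gn_symbol TEXT NOT NULL,
    sp_id INTEGER NOT NULL REFERENCES species(sp_id)
);
CREATE TABLE IF NOT EXISTS algorithm (
    alg_id INTEGER PRIMARY KEY,
    alg_name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS ortholog (
    ort_id INTEGER PRIMARY KEY,
    from_gene INTEGER NOT NULL REFERENCES gene(gn_id),
    to_gene INTEGER NOT NULL REFERENCES gene(gn_id),
    is_best INTEGER NOT NULL,
    is_best_adjusted INTEGER NOT NULL,
    is_best_revised INTEGER NOT NULL,
    num_algorithms_match INTEGER NOT NULL,
    out_of_algorithms INTEGER NOT NULL,
    ort_source TEXT NOT NULL,
    UNIQUE (from_gene, to_gene),
    CHECK (from_gene != to_gene)
);
CREATE TABLE IF NOT EXISTS ortholog_algorithm (
    ort_id INTEGER NOT NULL REFERENCES ortholog(ort_id),
    alg_id INTEGER NOT NULL REFERENCES algorithm(alg_id),
    UNIQUE (ort_id, alg_id)
);
CREATE TABLE IF NOT EXISTS homology (
    hom_id INTEGER NOT NULL,
    gn_id INTEGER NOT NULL UNIQUE REFERENCES gene(gn_id),
    sp_id INTEGER NOT NULL REFERENCES species(sp_id),
    hom_source TEXT NOT NULL,
    UNIQUE (hom_id, gn_id)
);
CREATE TABLE IF NOT EXISTS genedb (
    gdb_id INTEGER PRIMARY KEY,
    gdb_name TEXT NOT NULL UNIQUE,
    curie_prefix TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS gw_gene (
    ode_gene_id INTEGER NOT NULL,
    ode_ref_id TEXT NOT NULL,
    gdb_id INTEGER NOT NULL REFERENCES genedb(gdb_id),
    gw_sp_id INTEGER NOT NULL,
    UNIQUE (ode_ref_id, gdb_id)
);
CREATE TABLE IF NOT EXISTS gw_species (
    gw_sp_id INTEGER PRIMARY KEY,
    gw_sp_name TEXT NOT NULL UNIQUE COLLATE NOCASE,
    gw_taxon_id INTEGER
);
CREATE TABLE IF NOT EXISTS species_map (
    sp_id INTEGER NOT NULL UNIQUE REFERENCES species(sp_id),
    gw_sp_id INTEGER NOT NULL UNIQUE
);
CREATE INDEX IF NOT EXISTS idx_gene_sp ON gene(sp_id);
CREATE INDEX IF NOT EXISTS idx_ort_from ON ortholog(from_gene);
CREATE INDEX IF NOT EXISTS idx_ort_to ON ortholog(to_gene);
CREATE INDEX IF NOT EXISTS idx_hom_id ON homology(hom_id);
"""


def _species(row) -> SpeciesRecord:
    return SpeciesRecord(row["sp_id"], row["sp_name"], row["sp_taxon_id"], row["sp_source"])


def _gene(row) -> GeneRecord:
    return GeneRecord(row["gn_id"], row["gn_ref_id"], row["gn_prefix"], row["gn_symbol"], row["sp_id"])


def _pair(row) -> OrthologPair:
    return OrthologPair(
        row["ort_id"], row["from_gene"], row["to_gene"],
        bool(row["is_best"]), bool(row["is_best_adjusted"]), bool(row["is_best_revised"]),
        row["num_algorithms_match"], row["out_of_algorithms"], row["ort_source"],
    )


class Store:
    """Repository over an embedded sqlite database.

    Parameters
    ----------
    path:
        Database file path, or ``":memory:"`` (the default) for a private
        in-memory database.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._db = sqlite3.connect(path)
        self._db.row_factory = sqlite3.Row
        self._db.executescript(_SCHEMA)
        self._db.commit()

    def close(self) -> None:
        self._db.close()

    def commit(self) -> None:
        self._db.commit()

    # -- species ---------------------------------------------------------

    def add_species(self, name: str, taxon_id: int, source: str) -> SpeciesRecord:
        existing = self.species_by_name(name)
        if existing is not None:
            raise ConflictError(f"species already registered: {name!r}")
        cur = self._db.execute(
            "INSERT INTO species (sp_name, sp_taxon_id, sp_source) VALUES (?, ?, ?)",
            (name, taxon_id, source),
        )
        return SpeciesRecord(cur.lastrowid, name, taxon_id, source)

    def get_or_create_species(self, name: str, taxon_id: int, source: str) -> tuple[SpeciesRecord, bool]:
        existing = self.species_by_name(name)
        if existing is not None:
            return existing, False
        return self.add_species(name, taxon_id, source), True

    def species_by_name(self, name: str) -> SpeciesRecord | None:
        row = self._db.execute(
            "SELECT * FROM species WHERE sp_name = ? COLLATE NOCASE", (name,)
        ).fetchone()
        return _species(row) if row else None

    def species_by_id(self, sp_id: int) -> SpeciesRecord | None:
        row = self._db.execute("SELECT * FROM species WHERE sp_id = ?", (sp_id,)).fetchone()
        return _species(row) if row else None

    def species_by_taxon(self, taxon_id: int) -> SpeciesRecord | None:
        row = self._db.execute("SELECT * FROM species WHERE sp_taxon_id = ?", (taxon_id,)).fetchone()
        return _species(row) if row else None

    def all_species(self) -> list[SpeciesRecord]:
        return [_species(r) for r in self._db.execute("SELECT * FROM species ORDER BY sp_id")]

    # -- genes -----------------------------------------------------------

    def add_gene(self, ref_id: str, prefix: str, symbol: str, sp_id: int) -> GeneRecord:
        cur = self._db.execute(
            "INSERT INTO gene (gn_ref_id, gn_prefix, gn_symbol, sp_id) VALUES (?, ?, ?, ?)",
            (ref_id, prefix, symbol, sp_id),
        )
        return GeneRecord(cur.lastrowid, ref_id, prefix, symbol, sp_id)

    def get_or_create_gene(self, ref_id: str, prefix: str, symbol: str, sp_id: int) -> tuple[GeneRecord, bool]:
        existing = self.gene_by_ref(ref_id)
        if existing is not None:
            return existing, False
        return self.add_gene(ref_id, prefix, symbol, sp_id), True

    def gene_by_ref(self, ref_id: str) -> GeneRecord | None:
        row = self._db.execute("SELECT * FROM gene WHERE gn_ref_id = ?", (ref_id,)).fetchone()
        return _gene(row) if row else None

    def gene_by_id(self, gn_id: int) -> GeneRecord | None:
        row = self._db.execute("SELECT * FROM gene WHERE gn_id = ?", (gn_id,)).fetchone()
        return _gene(row) if row else None

    def genes_by_species(self, sp_id: int) -> list[GeneRecord]:
        return [_gene(r) for r in self._db.execute(
            "SELECT * FROM gene WHERE sp_id = ? ORDER BY gn_id", (sp_id,))]

    def genes_by_prefix(self, prefix: str) -> list[GeneRecord]:
        return [_gene(r) for r in self._db.execute(
            "SELECT * FROM gene WHERE gn_prefix = ? ORDER BY gn_id", (prefix,))]

    def all_genes(self, limit: int | None = None, offset: int = 0) -> list[GeneRecord]:
        q = "SELECT * FROM gene ORDER BY gn_id"
        if limit is not None:
            q += f" LIMIT {int(limit)} OFFSET {int(offset)}"
        return [_gene(r) for r in self._db.execute(q)]

    def gene_count_by_species(self) -> list[dict]:
        return [dict(r) for r in self._db.execute(
            "SELECT s.sp_id, s.sp_name, COUNT(g.gn_id) AS n_genes "
            "FROM species s LEFT JOIN gene g ON g.sp_id = s.sp_id "
            "GROUP BY s.sp_id ORDER BY s.sp_id")]

    # -- algorithms ------------------------------------------------------

    def get_or_create_algorithm(self, name: str) -> tuple[AlgorithmRecord, bool]:
        row = self._db.execute("SELECT * FROM algorithm WHERE alg_name = ?", (name,)).fetchone()
        if row:
            return AlgorithmRecord(row["alg_id"], row["alg_name"]), False
        cur = self._db.execute("INSERT INTO algorithm (alg_name) VALUES (?)", (name,))
        return AlgorithmRecord(cur.lastrowid, name), True

    def algorithm_by_name(self, name: str) -> AlgorithmRecord | None:
        row = self._db.execute("SELECT * FROM algorithm WHERE alg_name = ?", (name,)).fetchone()
        return AlgorithmRecord(row["alg_id"], row["alg_name"]) if row else None

    def algorithm_by_id(self, alg_id: int) -> AlgorithmRecord | None:
        row = self._db.execute("SELECT * FROM algorithm WHERE alg_id = ?", (alg_id,)).fetchone()
        return AlgorithmRecord(row["alg_id"], row["alg_name"]) if row else None

    def all_algorithms(self) -> list[AlgorithmRecord]:
        return [AlgorithmRecord(r["alg_id"], r["alg_name"])
                for r in self._db.execute("SELECT * FROM algorithm ORDER BY alg_id")]

    # -- ortholog pairs --------------------------------------------------

    def pair_exists(self, from_gene: int, to_gene: int) -> bool:
        row = self._db.execute(
            "SELECT 1 FROM ortholog WHERE from_gene = ? AND to_gene = ?",
            (from_gene, to_gene)).fetchone()
        return row is not None

    def add_pair(self, from_gene: int, to_gene: int, is_best: bool, is_best_adjusted: bool,
                 is_best_revised: bool, num_algorithms_match: int, out_of_algorithms: int,
                 ort_source: str) -> OrthologPair:
        cur = self._db.execute(
            "INSERT INTO ortholog (from_gene, to_gene, is_best, is_best_adjusted, "
            "is_best_revised, num_algorithms_match, out_of_algorithms, ort_source) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            (from_gene, to_gene, int(is_best), int(is_best_adjusted), int(is_best_revised),
             num_algorithms_match, out_of_algorithms, ort_source),
        )
        return OrthologPair(cur.lastrowid, from_gene, to_gene, is_best, is_best_adjusted,
                            is_best_revised, num_algorithms_match, out_of_algorithms, ort_source)

    def pair_by_id(self, ort_id: int) -> OrthologPair | None:
        row = self._db.execute("SELECT * FROM ortholog WHERE ort_id = ?", (ort_id,)).fetchone()
        return _pair(row) if row else None

    def all_pairs(self, limit: int | None = None, offset: int = 0) -> list[OrthologPair]:
        q = "SELECT * FROM ortholog ORDER BY ort_id"
        if limit is not None:
            q += f" LIMIT {int(limit)} OFFSET {int(offset)}"
        return [_pair(r) for r in self._db.execute(q)]

    def pairs_where(self, clause: str, params: tuple = ()) -> list[OrthologPair]:
        return [_pair(r) for r in self._db.execute(
            f"SELECT * FROM ortholog WHERE {clause} ORDER BY ort_id", params)]

    def iter_pair_edges(self) -> Iterator[tuple[int, int]]:
        for r in self._db.execute("SELECT from_gene, to_gene FROM ortholog"):
            yield r["from_gene"], r["to_gene"]

    def add_link(self, ort_id: int, alg_id: int) -> None:
        self._db.execute(
            "INSERT INTO ortholog_algorithm (ort_id, alg_id) VALUES (?, ?)", (ort_id, alg_id))

    def link_exists(self, ort_id: int, alg_id: int) -> bool:
        return self._db.execute(
            "SELECT 1 FROM ortholog_algorithm WHERE ort_id = ? AND alg_id = ?",
            (ort_id, alg_id)).fetchone() is not None

    def algorithms_of_pair(self, ort_id: int) -> list[AlgorithmRecord]:
        return [AlgorithmRecord(r["alg_id"], r["alg_name"]) for r in self._db.execute(
            "SELECT a.alg_id, a.alg_name FROM ortholog_algorithm l "
            "JOIN algorithm a ON a.alg_id = l.alg_id WHERE l.ort_id = ? ORDER BY a.alg_id",
            (ort_id,))]

    def genes_by_algorithm(self, alg_id: int) -> list[GeneRecord]:
        """Distinct genes participating in at least one pair linked to the algorithm."""
        return [_gene(r) for r in self._db.execute(
            "SELECT DISTINCT g.* FROM gene g JOIN ortholog o "
            "ON g.gn_id IN (o.from_gene, o.to_gene) "
            "JOIN ortholog_algorithm l ON l.ort_id = o.ort_id "
            "WHERE l.alg_id = ? ORDER BY g.gn_id", (alg_id,))]

    def pairs_by_species(self, from_sp: int | None = None, to_sp: int | None = None,
                         alg_id: int | None = None) -> list[OrthologPair]:
        q = ("SELECT o.* FROM ortholog o "
             "JOIN gene gf ON gf.gn_id = o.from_gene "
             "JOIN gene gt ON gt.gn_id = o.to_gene ")
        clauses, params = [], []
        if from_sp is not None:
            clauses.append("gf.sp_id = ?")
            params.append(from_sp)
        if to_sp is not None:
            clauses.append("gt.sp_id = ?")
            params.append(to_sp)
        if alg_id is not None:
            q += "JOIN ortholog_algorithm l ON l.ort_id = o.ort_id "
            clauses.append("l.alg_id = ?")
            params.append(alg_id)
        if clauses:
            q += "WHERE " + " AND ".join(clauses) + " "
        q += "ORDER BY o.ort_id"
        return [_pair(r) for r in self._db.execute(q, tuple(params))]

    # -- homology --------------------------------------------------------

    def clear_homology(self) -> None:
        self._db.execute("DELETE FROM homology")

    def add_membership(self, hom_id: int, gn_id: int, sp_id: int, source: str) -> None:
        self._db.execute(
            "INSERT INTO homology (hom_id, gn_id, sp_id, hom_source) VALUES (?, ?, ?, ?)",
            (hom_id, gn_id, sp_id, source))

    def all_memberships(self) -> list[HomologyMembership]:
        return [HomologyMembership(r["hom_id"], r["gn_id"], r["sp_id"], r["hom_source"])
                for r in self._db.execute("SELECT * FROM homology ORDER BY hom_id, gn_id")]

    def memberships_where(self, clause: str, params: tuple = ()) -> list[HomologyMembership]:
        return [HomologyMembership(r["hom_id"], r["gn_id"], r["sp_id"], r["hom_source"])
                for r in self._db.execute(
                    f"SELECT * FROM homology WHERE {clause} ORDER BY hom_id, gn_id", params)]

    # -- external (GeneWeaver-style) tables ------------------------------

    def add_genedb(self, gdb_id: int, gdb_name: str, curie_prefix: str) -> GenedbEntry:
        self._db.execute(
            "INSERT OR IGNORE INTO genedb (gdb_id, gdb_name, curie_prefix) VALUES (?, ?, ?)",
            (gdb_id, gdb_name, curie_prefix))
        return GenedbEntry(gdb_id, gdb_name, curie_prefix)

    def genedb_by_id(self, gdb_id: int) -> GenedbEntry | None:
        row = self._db.execute("SELECT * FROM genedb WHERE gdb_id = ?", (gdb_id,)).fetchone()
        return GenedbEntry(row["gdb_id"], row["gdb_name"], row["curie_prefix"]) if row else None

    def genedb_by_name(self, name: str) -> GenedbEntry | None:
        row = self._db.execute("SELECT * FROM genedb WHERE gdb_name = ?", (name,)).fetchone()
        return GenedbEntry(row["gdb_id"], row["gdb_name"], row["curie_prefix"]) if row else None

    def all_genedb(self) -> list[GenedbEntry]:
        return [GenedbEntry(r["gdb_id"], r["gdb_name"], r["curie_prefix"])
                for r in self._db.execute("SELECT * FROM genedb ORDER BY gdb_id")]

    def add_gw_gene(self, ode_gene_id: int, ode_ref_id: str, gdb_id: int, gw_sp_id: int) -> None:
        self._db.execute(
            "INSERT OR IGNORE INTO gw_gene (ode_gene_id, ode_ref_id, gdb_id, gw_sp_id) "
            "VALUES (?, ?, ?, ?)", (ode_gene_id, ode_ref_id, gdb_id, gw_sp_id))

    def gw_gene_by_ref(self, ode_ref_id: str, gdb_id: int) -> GWGene | None:
        row = self._db.execute(
            "SELECT * FROM gw_gene WHERE ode_ref_id = ? AND gdb_id = ?",
            (ode_ref_id, gdb_id)).fetchone()
        return GWGene(row["ode_gene_id"], row["ode_ref_id"], row["gdb_id"], row["gw_sp_id"]) if row else None

    def gw_genes_by_ode_id(self, ode_gene_id: int) -> list[GWGene]:
        return [GWGene(r["ode_gene_id"], r["ode_ref_id"], r["gdb_id"], r["gw_sp_id"])
                for r in self._db.execute(
                    "SELECT * FROM gw_gene WHERE ode_gene_id = ? ORDER BY gdb_id", (ode_gene_id,))]

    def gw_genes_by_gdb(self, gdb_id: int) -> list[GWGene]:
        return [GWGene(r["ode_gene_id"], r["ode_ref_id"], r["gdb_id"], r["gw_sp_id"])
                for r in self._db.execute(
                    "SELECT * FROM gw_gene WHERE gdb_id = ? ORDER BY ode_gene_id", (gdb_id,))]

    def add_gw_species(self, gw_sp_id: int, name: str, taxon_id: int | None) -> None:
        self._db.execute(
            "INSERT OR IGNORE INTO gw_species (gw_sp_id, gw_sp_name, gw_taxon_id) VALUES (?, ?, ?)",
            (gw_sp_id, name, taxon_id))

    def gw_species_by_name(self, name: str) -> dict | None:
        row = self._db.execute(
            "SELECT * FROM gw_species WHERE gw_sp_name = ? COLLATE NOCASE", (name,)).fetchone()
        return dict(row) if row else None

    def all_gw_species(self) -> list[dict]:
        return [dict(r) for r in self._db.execute("SELECT * FROM gw_species ORDER BY gw_sp_id")]

    def add_species_map(self, sp_id: int, gw_sp_id: int) -> None:
        self._db.execute(
            "INSERT OR IGNORE INTO species_map (sp_id, gw_sp_id) VALUES (?, ?)", (sp_id, gw_sp_id))

    def species_map(self) -> list[SpeciesMapEntry]:
        return [SpeciesMapEntry(r["sp_id"], r["gw_sp_id"])
                for r in self._db.execute("SELECT * FROM species_map ORDER BY sp_id")]

    def sp_id_for_gw(self, gw_sp_id: int) -> int | None:
        row = self._db.execute(
            "SELECT sp_id FROM species_map WHERE gw_sp_id = ?", (gw_sp_id,)).fetchone()
        return row["sp_id"] if row else None

    def gw_id_for_sp(self, sp_id: int) -> int | None:
        row = self._db.execute(
            "SELECT gw_sp_id FROM species_map WHERE sp_id = ?", (sp_id,)).fetchone()
        return row["gw_sp_id"] if row else None

    # -- bookkeeping -----------------------------------------------------

    def counts(self) -> dict[str, int]:
        out = {}
        for table in ("species", "gene", "algorithm", "ortholog", "ortholog_algorithm",
                      "homology", "genedb", "gw_gene", "gw_species", "species_map"):
            out[table] = self._db.execute(f"SELECT COUNT(*) AS n FROM {table}").fetchone()["n"]
        return out
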