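"""Core record types of the normalized orthology model.

The relational model mirrors the tables a gene-centric orthology service
needs: species, genes (namespace-prefixed accessions), the orthology-call
algorithms, directed pairwise ortholog calls with per-direction best-score
flags, homology-cluster memberships, and the external (GeneWeaver-style)
identifier tables used for cross-system translation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class OrthonormError(Exception):
    """Base class for all package errors."""


class InputError(OrthonormError):
    """Missing file or invalid caller-supplied value."""


class ParseError(OrthonormError):
    """Malformed input content; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NotFoundError(OrthonormError):
    """Lookup of an unregistered entity."""


class ConflictError(OrthonormError):
    """Attempt to register an entity that already exists."""


@dataclass(frozen=True)
class RawOrthologyRow:
    """One directed gene1->gene2 data line of the orthology TSV."""

    gene1_id: str
    gene1_symbol: str
    gene1_taxon: str
    gene1_species_name: str
    gene2_id: str
    gene2_symbol: str
    gene2_taxon: str
    gene2_species_name: str
    algorithms: tuple[str, ...]
    algorithms_match: int
    out_of_algorithms: int
    is_best: str
    is_best_revised: str


@dataclass(frozen=True)
class SpeciesRecord:
    sp_id: int
    sp_name: str
    sp_taxon_id: int
    sp_source: str  # "canonical" | "added"


@dataclass(frozen=True)
class GeneRecord:
    gn_id: int
    gn_ref_id: str  # prefixed accession (curie)
    gn_prefix: str
    gn_symbol: str
    sp_id: int


@dataclass(frozen=True)
class AlgorithmRecord:
    alg_id: int
    alg_name: str


@dataclass(frozen=True)
class OrthologPair:
    """Directed ortholog call; direction carries the best-score flags."""

    ort_id: int
    from_gene: int
    to_gene: int
    is_best: bool
    is_best_adjusted: bool
    is_best_revised: bool
    num_algorithms_match: int
    out_of_algorithms: int
    ort_source: str  # "agr" | "added:<source name>"


@dataclass(frozen=True)
class HomologyMembership:
    hom_id: int
    gn_id: int
    sp_id: int
    hom_source: str


@dataclass(frozen=True)
class GenedbEntry:
    """One identifier source of the external system's genedb registry."""

    gdb_id: int
    gdb_name: str
    curie_prefix: str  # "" for sources whose accessions stay bare


@dataclass(frozen=True)
class GWGene:
    ode_gene_id: int
    ode_ref_id: str
    gdb_id: int
    gw_sp_id: int


@dataclass(frozen=True)
class SpeciesMapEntry:
    sp_id: int
    gw_sp_id: int


@dataclass
class IngestReport:
    species: int = 0
    genes: int = 0
    algorithms: int = 0
    pairs: int = 0
    links: int = 0
    pairs_skipped_duplicate: int = 0


@dataclass
class AugmentationReport:
    new_species: int = 0
    new_genes: int = 0
    pairs_added: int = 0
    pairs_skipped_unknown_gene: int = 0
    pairs_skipped_no_new_species: int = 0
    duplicates_removed: int = 0


@dataclass
class AssignReport:
    placed_in_existing: int = 0
    new_clusters: int = 0
    merges: int = 0


def as_dict(record) -> dict:
    """JSON-ready view of any record dataclass."""
    d = dataclasses.asdict(record)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
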