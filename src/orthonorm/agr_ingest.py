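"""Parse the combined-orthology TSV dialect and populate the normalized tables.

The input is the tab-separated pairwise orthology download dialect used by
the Alliance of Genome Resources: ``#``-prefixed comment/metadata lines, one
header line, then 13 tab-separated columns per data line::

    Gene1ID  Gene1Symbol  Gene1SpeciesTaxonID  Gene1SpeciesName
    Gene2ID  Gene2Symbol  Gene2SpeciesTaxonID  Gene2SpeciesName
    Algorithms  AlgorithmsMatch  OutOfAlgorithms  IsBestScore  IsBestRevScore

Rows are directed (gene1 -> gene2); both directions normally appear in the
source and are kept as distinct pairs because the best-score flags are
per-direction. ``Algorithms`` is a ``|``-separated list of the algorithms
that called the pair; ``AlgorithmsMatch``/``OutOfAlgorithms`` count how many
of the applicable algorithms agreed. The best-score columns are tri-state:
``Yes``, ``No``, or ``Yes_Adjusted`` (a curated adjustment).
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable, Sequence

from .models import IngestReport, InputError, ParseError, RawOrthologyRow
from .store import Store

log = logging.getLogger(__name__)

N_COLUMNS = 13
ALGORITHM_SEP = "|"
BEST_TOKENS = ("Yes", "No", "Yes_Adjusted")

HEADER = (
    "Gene1ID", "Gene1Symbol", "Gene1SpeciesTaxonID", "Gene1SpeciesName",
    "Gene2ID", "Gene2Symbol", "Gene2SpeciesTaxonID", "Gene2SpeciesName",
    "Algorithms", "AlgorithmsMatch", "OutOfAlgorithms", "IsBestScore", "IsBestRevScore",
)


def parse_taxon(token: str) -> int:
    """Extract the numeric taxon id from a ``NCBITaxon:<digits>`` token."""
    if ":" not in token:
        raise ParseError(f"taxon token has no prefix: {token!r}")
    suffix = token.split(":", 1)[1]
    if not suffix.isdigit():
        raise ParseError(f"taxon token suffix is not numeric: {token!r}")
    return int(suffix)


def split_curie(ref: str) -> tuple[str, str]:
    """Split a prefixed accession at the first colon.

    Returns ``(prefix, local)``; with no colon the prefix is empty and the
    caller supplies a default for its source.
    """
    if not ref:
        raise InputError("empty accession")
    if ":" not in ref:
        return "", ref
    prefix, local = ref.split(":", 1)
    return prefix, local


def parse_best_flag(token: str) -> tuple[bool, bool]:
    """Decode a tri-state best-score token into (best, adjusted)."""
    if token == "Yes":
        return True, False
    if token == "No":
        return False, False
    if token == "Yes_Adjusted":
        return True, True
    raise ParseError(f"unknown best-score token: {token!r}")


def _parse_data_line(fields: list[str], lineno: int) -> RawOrthologyRow:
    if len(fields) != N_COLUMNS:
        raise ParseError(f"expected {N_COLUMNS} columns, found {len(fields)}", line=lineno)
    for tok in (fields[11], fields[12]):
        if tok not in BEST_TOKENS:
            raise ParseError(f"unknown best-score token: {tok!r}", line=lineno)
    try:
        match = int(fields[9])
        out_of = int(fields[10])
    except ValueError:
        raise ParseError(f"non-numeric algorithm counts: {fields[9]!r}/{fields[10]!r}", line=lineno)
    if match < 0 or out_of < 1 or match > out_of:
        raise ParseError(f"invalid algorithm counts {match}/{out_of}", line=lineno)
    if fields[0] == fields[4]:
        raise ParseError(f"self-pair {fields[0]!r}", line=lineno)
    algorithms = tuple(a for a in fields[8].split(ALGORITHM_SEP) if a)
    return RawOrthologyRow(
        gene1_id=fields[0], gene1_symbol=fields[1],
        gene1_taxon=fields[2], gene1_species_name=fields[3],
        gene2_id=fields[4], gene2_symbol=fields[5],
        gene2_taxon=fields[6], gene2_species_name=fields[7],
        algorithms=algorithms, algorithms_match=match, out_of_algorithms=out_of,
        is_best=fields[11], is_best_revised=fields[12],
    )


def parse_orthology_text(text: str) -> list[RawOrthologyRow]:
    """Parse orthology TSV content already in memory."""
    rows: list[RawOrthologyRow] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            header_seen = True  # first non-comment line is the column header
            if len(fields) != N_COLUMNS:
                raise ParseError(f"header has {len(fields)} columns, expected {N_COLUMNS}",
                                 line=lineno)
            continue
        rows.append(_parse_data_line(fields, lineno))
    return rows


def parse_orthology_file(path: str | os.PathLike) -> list[RawOrthologyRow]:
    """Parse an orthology TSV file into raw directed rows."""
    if not os.path.exists(path):
        raise InputError(f"orthology file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return parse_orthology_text(fh.read())


def ingest(store: Store, rows: Iterable[RawOrthologyRow],
           default_prefix: str = "") -> IngestReport:
    """Load parsed rows into the species/gene/algorithm/ortholog tables.

    Every distinct species, gene, and algorithm mentioned is registered
    exactly once; each distinct (gene1, gene2) pair becomes one directed
    ortholog row linked to its matching algorithms. Duplicate directed pairs
    keep the first occurrence and are counted as skipped, which makes the
    operation idempotent. All species created here are ``canonical``.
    """
    report = IngestReport()
    for row in rows:
        sp1, new1 = store.get_or_create_species(
            row.gene1_species_name, parse_taxon(row.gene1_taxon), "canonical")
        sp2, new2 = store.get_or_create_species(
            row.gene2_species_name, parse_taxon(row.gene2_taxon), "canonical")
        report.species += int(new1) + int(new2)

        prefix1, _ = split_curie(row.gene1_id)
        prefix2, _ = split_curie(row.gene2_id)
        g1, created = store.get_or_create_gene(
            row.gene1_id, prefix1 or default_prefix, row.gene1_symbol, sp1.sp_id)
        report.genes += int(created)
        g2, created = store.get_or_create_gene(
            row.gene2_id, prefix2 or default_prefix, row.gene2_symbol, sp2.sp_id)
        report.genes += int(created)

        if store.pair_exists(g1.gn_id, g2.gn_id):
            report.pairs_skipped_duplicate += 1
            continue
        best, adjusted = parse_best_flag(row.is_best)
        rev_best, _ = parse_best_flag(row.is_best_revised)
        pair = store.add_pair(g1.gn_id, g2.gn_id, best, adjusted, rev_best,
                              row.algorithms_match, row.out_of_algorithms, "agr")
        report.pairs += 1
        for name in row.algorithms:
            alg, created = store.get_or_create_algorithm(name)
            report.algorithms += int(created)
            if not store.link_exists(pair.ort_id, alg.alg_id):
                store.add_link(pair.ort_id, alg.alg_id)
                report.links += 1
    store.commit()
    log.info("ingest: %s", report)
    return report
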