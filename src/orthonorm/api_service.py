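"""JSON query API over the normalized orthology model.

A catalog of exactly 50 endpoints in six categories (Genes, Species,
Algorithms, Orthology, Homology, Integration), served as a WSGI
application. Every response body is JSON: list endpoints return a JSON
array (empty on no match), single-entity endpoints return one object, and
unknown-entity lookups return a structured not-found payload with HTTP 404
so an empty filter result is distinguishable from a failed lookup.

The catalog itself is introspectable at ``/api/v1/_catalog`` (outside the
catalog count) for conformance testing. The original upstream API exposes
five orthology endpoints for the nine canonical species; this catalog is a
reconstruction that widens access to every table and parameter combination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from urllib.parse import parse_qs

from . import id_mapping
from .models import InputError, NotFoundError, as_dict
from .store import Store

log = logging.getLogger(__name__)

BASE_PATH = "/api/v1"
DEFAULT_CAP = 500  # default page size on all_* routes

CATEGORIES = ("Genes", "Species", "Algorithms", "Orthology", "Homology", "Integration")


@dataclass(frozen=True)
class EndpointDescriptor:
    category: str
    name: str
    params: tuple[tuple[str, str], ...]  # (param name, semantic type)


_HANDLERS: dict[str, tuple[EndpointDescriptor, callable]] = {}


def endpoint(category: str, name: str, params: tuple[tuple[str, str], ...] = ()):
    def deco(fn):
        if name in _HANDLERS:
            raise ValueError(f"duplicate endpoint {name}")
        _HANDLERS[name] = (EndpointDescriptor(category, name, params), fn)
        return fn
    return deco


def catalog() -> list[EndpointDescriptor]:
    return [desc for desc, _ in _HANDLERS.values()]


# -- parameter coercion --------------------------------------------------

def _get(params: dict, name: str, kind: str = "str", default=None, required: bool = True):
    if name not in params:
        if required and default is None:
            raise InputError(f"missing parameter {name!r}")
        return default
    raw = params[name][0]
    if kind == "int":
        try:
            return int(raw)
        except ValueError:
            raise InputError(f"parameter {name!r} must be an integer")
    if kind == "bool":
        low = raw.lower()
        if low in ("true", "false"):
            return low == "true"
        raise InputError(f"parameter {name!r} must be true or false")
    return raw


def _page(params: dict) -> tuple[int, int]:
    limit = _get(params, "limit", "int", default=DEFAULT_CAP, required=False)
    offset = _get(params, "offset", "int", default=0, required=False)
    return limit, offset


# -- serialization -------------------------------------------------------

def _pair_json(store: Store, pair) -> dict:
    d = as_dict(pair)
    d["from_gene_ref"] = store.gene_by_id(pair.from_gene).gn_ref_id
    d["to_gene_ref"] = store.gene_by_id(pair.to_gene).gn_ref_id
    return d


def _membership_json(store: Store, m) -> dict:
    d = as_dict(m)
    d["gn_ref_id"] = store.gene_by_id(m.gn_id).gn_ref_id
    d["sp_name"] = store.species_by_id(m.sp_id).sp_name
    return d


def _need_species(store: Store, name: str):
    sp = store.species_by_name(name)
    if sp is None:
        raise NotFoundError(f"unknown species {name!r}")
    return sp


def _need_gene(store: Store, gn_id: int):
    gene = store.gene_by_id(gn_id)
    if gene is None:
        raise NotFoundError(f"unknown gene id {gn_id}")
    return gene


def _need_algorithm(store: Store, name: str):
    alg = store.algorithm_by_name(name)
    if alg is None:
        raise NotFoundError(f"unknown algorithm {name!r}")
    return alg


def _gene_for_ode(store: Store, ode_gene_id: int):
    """Resolve an external gene key to its normalized gene record."""
    rows = store.gw_genes_by_ode_id(ode_gene_id)
    if not rows:
        raise NotFoundError(f"unknown external gene id {ode_gene_id}")
    for row in rows:
        gdb = store.genedb_by_id(row.gdb_id)
        if gdb is None:
            continue
        gene = store.gene_by_ref(id_mapping.gw_ref_to_agr_ref(row.ode_ref_id, gdb))
        if gene is not None:
            return gene
    raise NotFoundError(f"external gene id {ode_gene_id} maps to no normalized gene")


# -- Genes (9) -----------------------------------------------------------

@endpoint("Genes", "all_genes", (("limit", "int"), ("offset", "int")))
def _all_genes(store, p):
    limit, offset = _page(p)
    return [as_dict(g) for g in store.all_genes(limit, offset)]


@endpoint("Genes", "gene_by_id", (("gn_id", "int"),))
def _gene_by_id(store, p):
    return as_dict(_need_gene(store, _get(p, "gn_id", "int")))


@endpoint("Genes", "gene_by_ref_id", (("gn_ref_id", "str"),))
def _gene_by_ref_id(store, p):
    gene = store.gene_by_ref(_get(p, "gn_ref_id"))
    if gene is None:
        raise NotFoundError("unknown gene accession")
    return as_dict(gene)


@endpoint("Genes", "genes_by_species_id", (("sp_id", "int"),))
def _genes_by_species_id(store, p):
    sp_id = _get(p, "sp_id", "int")
    if store.species_by_id(sp_id) is None:
        raise NotFoundError(f"unknown species id {sp_id}")
    return [as_dict(g) for g in store.genes_by_species(sp_id)]


@endpoint("Genes", "genes_by_species_name", (("sp_name", "str"),))
def _genes_by_species_name(store, p):
    sp = _need_species(store, _get(p, "sp_name"))
    return [as_dict(g) for g in store.genes_by_species(sp.sp_id)]


@endpoint("Genes", "genes_by_algorithm", (("alg_name", "str"),))
def _genes_by_algorithm(store, p):
    alg = _need_algorithm(store, _get(p, "alg_name"))
    return [as_dict(g) for g in store.genes_by_algorithm(alg.alg_id)]


@endpoint("Genes", "genes_by_prefix", (("gn_prefix", "str"),))
def _genes_by_prefix(store, p):
    return [as_dict(g) for g in store.genes_by_prefix(_get(p, "gn_prefix"))]


@endpoint("Genes", "gene_count_by_species", ())
def _gene_count_by_species(store, p):
    return store.gene_count_by_species()


@endpoint("Genes", "species_name_of_gene", (("gn_id", "int"),))
def _species_name_of_gene(store, p):
    gene = _need_gene(store, _get(p, "gn_id", "int"))
    return {"gn_id": gene.gn_id, "sp_name": store.species_by_id(gene.sp_id).sp_name}


# -- Species (4) ---------------------------------------------------------

@endpoint("Species", "all_species", ())
def _all_species(store, p):
    return [as_dict(s) for s in store.all_species()]


@endpoint("Species", "species_by_id", (("sp_id", "int"),))
def _species_by_id(store, p):
    sp = store.species_by_id(_get(p, "sp_id", "int"))
    if sp is None:
        raise NotFoundError("unknown species id")
    return as_dict(sp)


@endpoint("Species", "species_by_name", (("sp_name", "str"),))
def _species_by_name(store, p):
    return as_dict(_need_species(store, _get(p, "sp_name")))


@endpoint("Species", "species_by_taxon", (("taxon_id", "int"),))
def _species_by_taxon(store, p):
    sp = store.species_by_taxon(_get(p, "taxon_id", "int"))
    if sp is None:
        raise NotFoundError("unknown taxon id")
    return as_dict(sp)


# -- Algorithms (3) ------------------------------------------------------

@endpoint("Algorithms", "all_algorithms", ())
def _all_algorithms(store, p):
    return [as_dict(a) for a in store.all_algorithms()]


@endpoint("Algorithms", "algorithm_by_id", (("alg_id", "int"),))
def _algorithm_by_id(store, p):
    alg = store.algorithm_by_id(_get(p, "alg_id", "int"))
    if alg is None:
        raise NotFoundError("unknown algorithm id")
    return as_dict(alg)


@endpoint("Algorithms", "algorithm_by_name", (("alg_name", "str"),))
def _algorithm_by_name(store, p):
    return as_dict(_need_algorithm(store, _get(p, "alg_name")))


# -- Orthology (14) ------------------------------------------------------

@endpoint("Orthology", "all_orthologs", (("limit", "int"), ("offset", "int")))
def _all_orthologs(store, p):
    limit, offset = _page(p)
    return [_pair_json(store, o) for o in store.all_pairs(limit, offset)]


@endpoint("Orthology", "ortholog_by_id", (("ort_id", "int"),))
def _ortholog_by_id(store, p):
    pair = store.pair_by_id(_get(p, "ort_id", "int"))
    if pair is None:
        raise NotFoundError("unknown ortholog id")
    return _pair_json(store, pair)


@endpoint("Orthology", "orthologs_by_from_gene", (("gn_id", "int"),))
def _orthologs_by_from_gene(store, p):
    gene = _need_gene(store, _get(p, "gn_id", "int"))
    return [_pair_json(store, o) for o in store.pairs_where("from_gene = ?", (gene.gn_id,))]


@endpoint("Orthology", "orthologs_by_to_gene", (("gn_id", "int"),))
def _orthologs_by_to_gene(store, p):
    gene = _need_gene(store, _get(p, "gn_id", "int"))
    return [_pair_json(store, o) for o in store.pairs_where("to_gene = ?", (gene.gn_id,))]


@endpoint("Orthology", "orthologs_by_from_and_to_gene", (("from_gn_id", "int"), ("to_gn_id", "int")))
def _orthologs_by_from_and_to_gene(store, p):
    f = _need_gene(store, _get(p, "from_gn_id", "int"))
    t = _need_gene(store, _get(p, "to_gn_id", "int"))
    return [_pair_json(store, o)
            for o in store.pairs_where("from_gene = ? AND to_gene = ?", (f.gn_id, t.gn_id))]


@endpoint("Orthology", "orthologs_by_from_gene_best", (("gn_id", "int"), ("best", "bool")))
def _orthologs_by_from_gene_best(store, p):
    gene = _need_gene(store, _get(p, "gn_id", "int"))
    best = _get(p, "best", "bool")
    return [_pair_json(store, o)
            for o in store.pairs_where("from_gene = ? AND is_best = ?", (gene.gn_id, int(best)))]


@endpoint("Orthology", "orthologs_by_from_to_best",
          (("from_gn_id", "int"), ("to_gn_id", "int"), ("best", "bool")))
def _orthologs_by_from_to_best(store, p):
    f = _need_gene(store, _get(p, "from_gn_id", "int"))
    t = _need_gene(store, _get(p, "to_gn_id", "int"))
    best = _get(p, "best", "bool")
    return [_pair_json(store, o) for o in store.pairs_where(
        "from_gene = ? AND to_gene = ? AND is_best = ?", (f.gn_id, t.gn_id, int(best)))]


@endpoint("Orthology", "orthologs_by_from_to_revised",
          (("from_gn_id", "int"), ("to_gn_id", "int"), ("revised", "bool")))
def _orthologs_by_from_to_revised(store, p):
    f = _need_gene(store, _get(p, "from_gn_id", "int"))
    t = _need_gene(store, _get(p, "to_gn_id", "int"))
    revised = _get(p, "revised", "bool")
    return [_pair_json(store, o) for o in store.pairs_where(
        "from_gene = ? AND to_gene = ? AND is_best_revised = ?", (f.gn_id, t.gn_id, int(revised)))]


@endpoint("Orthology", "orthologs_by_from_species", (("sp_name", "str"),))
def _orthologs_by_from_species(store, p):
    sp = _need_species(store, _get(p, "sp_name"))
    return [_pair_json(store, o) for o in store.pairs_by_species(from_sp=sp.sp_id)]


@endpoint("Orthology", "orthologs_by_to_species", (("sp_name", "str"),))
def _orthologs_by_to_species(store, p):
    sp = _need_species(store, _get(p, "sp_name"))
    return [_pair_json(store, o) for o in store.pairs_by_species(to_sp=sp.sp_id)]


@endpoint("Orthology", "get_ortholog_by_to_and_from_species",
          (("from_sp_name", "str"), ("to_sp_name", "str")))
def _get_ortholog_by_to_and_from_species(store, p):
    """All pairs from one species' genes to another's, e.g. every ortholog
    call from an added species to a canonical one."""
    f = _need_species(store, _get(p, "from_sp_name"))
    t = _need_species(store, _get(p, "to_sp_name"))
    return [_pair_json(store, o) for o in store.pairs_by_species(from_sp=f.sp_id, to_sp=t.sp_id)]


@endpoint("Orthology", "orthologs_by_species_pair_and_algorithm",
          (("from_sp_name", "str"), ("to_sp_name", "str"), ("alg_name", "str")))
def _orthologs_by_species_pair_and_algorithm(store, p):
    f = _need_species(store, _get(p, "from_sp_name"))
    t = _need_species(store, _get(p, "to_sp_name"))
    alg = _need_algorithm(store, _get(p, "alg_name"))
    return [_pair_json(store, o)
            for o in store.pairs_by_species(from_sp=f.sp_id, to_sp=t.sp_id, alg_id=alg.alg_id)]


@endpoint("Orthology", "orthologs_by_min_algorithm_matches", (("min_matches", "int"),))
def _orthologs_by_min_algorithm_matches(store, p):
    n = _get(p, "min_matches", "int")
    return [_pair_json(store, o) for o in store.pairs_where("num_algorithms_match >= ?", (n,))]


@endpoint("Orthology", "orthologs_by_source", (("ort_source", "str"),))
def _orthologs_by_source(store, p):
    return [_pair_json(store, o)
            for o in store.pairs_where("ort_source = ?", (_get(p, "ort_source"),))]


# -- Homology (6) --------------------------------------------------------

@endpoint("Homology", "all_homology", (("limit", "int"), ("offset", "int")))
def _all_homology(store, p):
    limit, offset = _page(p)
    rows = store.all_memberships()[offset:offset + limit]
    return [_membership_json(store, m) for m in rows]


@endpoint("Homology", "homology_by_cluster", (("hom_id", "int"),))
def _homology_by_cluster(store, p):
    rows = store.memberships_where("hom_id = ?", (_get(p, "hom_id", "int"),))
    if not rows:
        raise NotFoundError("unknown cluster id")
    return [_membership_json(store, m) for m in rows]


@endpoint("Homology", "homology_by_gene", (("gn_id", "int"),))
def _homology_by_gene(store, p):
    gene = _need_gene(store, _get(p, "gn_id", "int"))
    return [_membership_json(store, m)
            for m in store.memberships_where("gn_id = ?", (gene.gn_id,))]


@endpoint("Homology", "homology_by_species", (("sp_id", "int"),))
def _homology_by_species(store, p):
    sp_id = _get(p, "sp_id", "int")
    if store.species_by_id(sp_id) is None:
        raise NotFoundError(f"unknown species id {sp_id}")
    return [_membership_json(store, m) for m in store.memberships_where("sp_id = ?", (sp_id,))]


@endpoint("Homology", "homology_by_cluster_and_species", (("hom_id", "int"), ("sp_id", "int")))
def _homology_by_cluster_and_species(store, p):
    return [_membership_json(store, m) for m in store.memberships_where(
        "hom_id = ? AND sp_id = ?", (_get(p, "hom_id", "int"), _get(p, "sp_id", "int")))]


@endpoint("Homology", "homology_by_source", (("hom_source", "str"),))
def _homology_by_source(store, p):
    return [_membership_json(store, m)
            for m in store.memberships_where("hom_source = ?", (_get(p, "hom_source"),))]


# -- Integration (14) ----------------------------------------------------

@endpoint("Integration", "agr_to_ode_gene", (("agr_ref", "str"),))
def _agr_to_ode_gene(store, p):
    return as_dict(id_mapping.agr_ref_to_ode_gene(store, _get(p, "agr_ref")))


@endpoint("Integration", "ode_to_agr_gene", (("ode_gene_id", "int"),))
def _ode_to_agr_gene(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    return as_dict(gene)


@endpoint("Integration", "gw_genes_by_genedb", (("gdb_name", "str"),))
def _gw_genes_by_genedb(store, p):
    gdb = store.genedb_by_name(_get(p, "gdb_name"))
    if gdb is None:
        raise NotFoundError("unknown genedb source")
    return [as_dict(g) for g in store.gw_genes_by_gdb(gdb.gdb_id)]


@endpoint("Integration", "gw_gene_by_ref", (("ode_ref_id", "str"), ("gdb_id", "int")))
def _gw_gene_by_ref(store, p):
    row = store.gw_gene_by_ref(_get(p, "ode_ref_id"), _get(p, "gdb_id", "int"))
    if row is None:
        raise NotFoundError("unknown external accession")
    return as_dict(row)


@endpoint("Integration", "species_map_all", ())
def _species_map_all(store, p):
    return [as_dict(m) for m in store.species_map()]


@endpoint("Integration", "species_map_agr_to_gw", (("sp_id", "int"),))
def _species_map_agr_to_gw(store, p):
    sp_id = _get(p, "sp_id", "int")
    gw = store.gw_id_for_sp(sp_id)
    if gw is None:
        raise NotFoundError("species not mapped")
    return {"sp_id": sp_id, "gw_sp_id": gw}


@endpoint("Integration", "species_map_gw_to_agr", (("gw_sp_id", "int"),))
def _species_map_gw_to_agr(store, p):
    gw_sp_id = _get(p, "gw_sp_id", "int")
    sp_id = store.sp_id_for_gw(gw_sp_id)
    if sp_id is None:
        raise NotFoundError("external species not mapped")
    return {"sp_id": sp_id, "gw_sp_id": gw_sp_id}


@endpoint("Integration", "orthologs_by_ode_gene", (("ode_gene_id", "int"),))
def _orthologs_by_ode_gene(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    return [_pair_json(store, o) for o in store.pairs_where(
        "from_gene = ? OR to_gene = ?", (gene.gn_id, gene.gn_id))]


@endpoint("Integration", "best_orthologs_by_ode_gene", (("ode_gene_id", "int"),))
def _best_orthologs_by_ode_gene(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    return [_pair_json(store, o) for o in store.pairs_where(
        "from_gene = ? AND is_best = 1", (gene.gn_id,))]


@endpoint("Integration", "has_ortholog_by_ode_gene", (("ode_gene_id", "int"),))
def _has_ortholog_by_ode_gene(store, p):
    ode = _get(p, "ode_gene_id", "int")
    try:
        gene = _gene_for_ode(store, ode)
    except NotFoundError:
        return {"ode_gene_id": ode, "has_ortholog": False}
    pairs = store.pairs_where("from_gene = ? OR to_gene = ?", (gene.gn_id, gene.gn_id))
    return {"ode_gene_id": ode, "has_ortholog": bool(pairs)}


@endpoint("Integration", "homology_by_ode_gene", (("ode_gene_id", "int"),))
def _homology_by_ode_gene(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    own = store.memberships_where("gn_id = ?", (gene.gn_id,))
    if not own:
        return []
    return [_membership_json(store, m)
            for m in store.memberships_where("hom_id = ?", (own[0].hom_id,))]


@endpoint("Integration", "genedb_sources", ())
def _genedb_sources(store, p):
    return [as_dict(g) for g in store.all_genedb()]


@endpoint("Integration", "orthologous_species_of_ode_gene", (("ode_gene_id", "int"),))
def _orthologous_species_of_ode_gene(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    partners = set()
    for o in store.pairs_where("from_gene = ? OR to_gene = ?", (gene.gn_id, gene.gn_id)):
        other = o.to_gene if o.from_gene == gene.gn_id else o.from_gene
        partners.add(store.gene_by_id(other).sp_id)
    return [as_dict(store.species_by_id(sp_id)) for sp_id in sorted(partners)]


@endpoint("Integration", "orthologs_from_ode_gene_to_species",
          (("ode_gene_id", "int"), ("sp_name", "str")))
def _orthologs_from_ode_gene_to_species(store, p):
    gene = _gene_for_ode(store, _get(p, "ode_gene_id", "int"))
    sp = _need_species(store, _get(p, "sp_name"))
    return [_pair_json(store, o) for o in store.pairs_where(
        "from_gene = ? AND to_gene IN (SELECT gn_id FROM gene WHERE sp_id = ?)",
        (gene.gn_id, sp.sp_id))]


# -- WSGI plumbing -------------------------------------------------------

def create_app(store: Store):
    """Build the WSGI application over a store."""

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "")
        params = parse_qs(environ.get("QUERY_STRING", ""))
        if not path.startswith(BASE_PATH + "/"):
            return _respond(start_response, 404, {"error": "not_found", "detail": "unknown path"})
        name = path[len(BASE_PATH) + 1:].strip("/")
        if name == "_catalog":
            return _respond(start_response, 200, [
                {"category": d.category, "name": d.name,
                 "params": [{"name": n, "type": t} for n, t in d.params]}
                for d in catalog()])
        if name not in _HANDLERS:
            return _respond(start_response, 404,
                            {"error": "not_found", "detail": f"unknown endpoint {name!r}"})
        _, handler = _HANDLERS[name]
        try:
            payload = handler(store, params)
            return _respond(start_response, 200, payload)
        except NotFoundError as exc:
            return _respond(start_response, 404, {"error": "not_found", "detail": str(exc)})
        except InputError as exc:
            return _respond(start_response, 400, {"error": "bad_request", "detail": str(exc)})

    return app


_STATUS = {200: "200 OK", 400: "400 Bad Request", 404: "404 Not Found"}


def _respond(start_response, status: int, payload):
    body = json.dumps(payload).encode("utf-8")
    start_response(_STATUS[status], [("Content-Type", "application/json"),
                                     ("Content-Length", str(len(body)))])
    return [body]


def request(app, name: str, **params) -> tuple[int, object]:
    """Call an endpoint through the WSGI interface without a socket.

    Returns (HTTP status code, decoded JSON payload).
    """
    from urllib.parse import urlencode

    environ = {
        "REQUEST_METHOD": "GET",
        "PATH_INFO": f"{BASE_PATH}/{name}",
        "QUERY_STRING": urlencode(params),
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    chunks = app(environ, start_response)
    body = b"".join(chunks)
    return captured["status"], json.loads(body.decode("utf-8"))


def serve(store: Store, host: str = "127.0.0.1", port: int = 8000) -> None:
    """Run the service on a blocking single-threaded HTTP server."""
    from wsgiref.simple_server import make_server

    app = create_app(store)
    with make_server(host, port, app) as httpd:
        log.info("serving %d endpoints on http://%s:%d%s/", len(_HANDLERS), host, port, BASE_PATH)
        httpd.serve_forever()
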