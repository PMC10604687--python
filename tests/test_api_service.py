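"""Endpoint catalog conformance and per-endpoint filter soundness.

Every endpoint is exercised through the WSGI interface on the pipeline
fixture and compared with an oracle that filters full Python-side table
dumps, independently of the SQL the handlers run.
"""

import json

import pytest

from orthonorm import Store
from orthonorm.api_service import catalog, create_app, request
from orthonorm.id_mapping import gw_ref_to_agr_ref

EXPECTED_CATEGORY_SIZES = {
    "Genes": 9, "Species": 4, "Algorithms": 3,
    "Orthology": 14, "Homology": 6, "Integration": 14,
}


class Ctx:
    """Fixture samples plus full table dumps for oracle-side filtering."""

    def __init__(self, pipeline, app):
        self.app = app
        store = self.store = pipeline.store
        self.genes = store.all_genes()
        self.species = store.all_species()
        self.algorithms = store.all_algorithms()
        self.pairs = store.all_pairs()
        self.memberships = store.all_memberships()
        self.gene_by_id = {g.gn_id: g for g in self.genes}
        self.sp_by_id = {s.sp_id: s for s in self.species}
        self.agr_pair = next(p for p in self.pairs if p.ort_source == "agr")
        self.added_pair = next(p for p in self.pairs if p.ort_source.startswith("added:"))
        self.gene0 = self.gene_by_id[self.agr_pair.from_gene]
        self.alg0 = self.algorithms[0]
        self.pair_algs = {p.ort_id: {a.alg_id for a in store.algorithms_of_pair(p.ort_id)}
                          for p in self.pairs}
        self.genedb = store.all_genedb()
        self.gw_genes = [g for gdb in self.genedb for g in store.gw_genes_by_gdb(gdb.gdb_id)]
        gdb_by_id = {g.gdb_id: g for g in self.genedb}
        # external key of a normalized gene that participates in pairs
        self.ode_gene = None
        paired = {p.from_gene for p in self.pairs} | {p.to_gene for p in self.pairs}
        for gw in self.gw_genes:
            gene = store.gene_by_ref(gw_ref_to_agr_ref(gw.ode_ref_id, gdb_by_id[gw.gdb_id]))
            if gene is not None and gene.gn_id in paired:
                self.ode_gene = (gw, gene)
                break
        assert self.ode_gene is not None

    def call(self, name, **params):
        status, payload = request(self.app, name, **params)
        assert status == 200, payload
        return payload

    def species_of(self, gn_id):
        return self.gene_by_id[gn_id].sp_id

    def partners_of(self, gn_id):
        return [p for p in self.pairs if gn_id in (p.from_gene, p.to_gene)]


@pytest.fixture(scope="module")
def ctx(pipeline, app):
    return Ctx(pipeline, app)


def pair_ids(payload):
    return {p["ort_id"] for p in payload}


def gene_ids(payload):
    return {g["gn_id"] for g in payload}


def test_catalog_has_fifty_routes_in_six_categories():
    descriptors = catalog()
    assert len(descriptors) == 50
    names = [d.name for d in descriptors]
    assert len(set(names)) == 50
    by_cat = {}
    for d in descriptors:
        by_cat.setdefault(d.category, []).append(d.name)
    assert {k: len(v) for k, v in by_cat.items()} == EXPECTED_CATEGORY_SIZES


def test_introspection_route_lists_catalog(app):
    status, payload = request(app, "_catalog")
    assert status == 200
    assert len(payload) == 50
    assert {c["category"] for c in payload} == set(EXPECTED_CATEGORY_SIZES)


def test_responses_round_trip_as_json(ctx):
    for name in ("all_species", "all_algorithms", "gene_count_by_species", "species_map_all"):
        payload = ctx.call(name)
        assert json.loads(json.dumps(payload)) == payload


def test_unknown_entity_distinguishable_from_empty_result(app):
    status, payload = request(app, "genes_by_species_name", sp_name="Vulpes vulpes")
    assert status == 404 and payload["error"] == "not_found"
    status, payload = request(app, "genes_by_prefix", gn_prefix="NOPE")
    assert status == 200 and payload == []


def test_same_species_query_returns_empty_list(app):
    status, payload = request(app, "get_ortholog_by_to_and_from_species",
                              from_sp_name="Homo sapiens", to_sp_name="Homo sapiens")
    assert status == 200 and payload == []


def test_list_endpoints_on_empty_database_return_empty_lists():
    empty_app = create_app(Store())
    for name in ("all_genes", "all_species", "all_algorithms", "all_orthologs",
                 "all_homology", "species_map_all", "genedb_sources",
                 "gene_count_by_species"):
        status, payload = request(empty_app, name)
        assert status == 200 and payload == []


def test_added_species_pairs_render_native_namespaces(ctx):
    """Pairs from an added species carry that species' native accession
    prefix while the partner keeps its own (e.g. Entrez vs HGNC)."""
    added = [sp for sp in ctx.species if sp.sp_source == "added"]
    found = False
    for sp in added:
        payload = ctx.call("orthologs_by_from_species", sp_name=sp.sp_name)
        for item in payload:
            prefix = ctx.gene_by_id[item["from_gene"]].gn_prefix
            assert item["from_gene_ref"].startswith(prefix)
            found = True
    assert found


# ---- per-endpoint oracle equivalence -----------------------------------

def _orc_all_genes(ctx):
    assert gene_ids(ctx.call("all_genes", limit=7)) == {g.gn_id for g in ctx.genes[:7]}

def _orc_gene_by_id(ctx):
    g = ctx.genes[0]
    assert ctx.call("gene_by_id", gn_id=g.gn_id)["gn_ref_id"] == g.gn_ref_id

def _orc_gene_by_ref_id(ctx):
    g = ctx.genes[-1]
    assert ctx.call("gene_by_ref_id", gn_ref_id=g.gn_ref_id)["gn_id"] == g.gn_id

def _orc_genes_by_species_id(ctx):
    sp = ctx.species[0]
    expect = {g.gn_id for g in ctx.genes if g.sp_id == sp.sp_id}
    assert gene_ids(ctx.call("genes_by_species_id", sp_id=sp.sp_id)) == expect

def _orc_genes_by_species_name(ctx):
    sp = ctx.species[1]
    expect = {g.gn_id for g in ctx.genes if g.sp_id == sp.sp_id}
    assert gene_ids(ctx.call("genes_by_species_name", sp_name=sp.sp_name.upper())) == expect

def _orc_genes_by_algorithm(ctx):
    expect = set()
    for p in ctx.pairs:
        if ctx.alg0.alg_id in ctx.pair_algs[p.ort_id]:
            expect.update((p.from_gene, p.to_gene))
    assert gene_ids(ctx.call("genes_by_algorithm", alg_name=ctx.alg0.alg_name)) == expect

def _orc_genes_by_prefix(ctx):
    expect = {g.gn_id for g in ctx.genes if g.gn_prefix == "HGNC"}
    assert gene_ids(ctx.call("genes_by_prefix", gn_prefix="HGNC")) == expect

def _orc_gene_count_by_species(ctx):
    got = {row["sp_id"]: row["n_genes"] for row in ctx.call("gene_count_by_species")}
    expect = {sp.sp_id: sum(1 for g in ctx.genes if g.sp_id == sp.sp_id) for sp in ctx.species}
    assert got == expect

def _orc_species_name_of_gene(ctx):
    g = ctx.gene0
    got = ctx.call("species_name_of_gene", gn_id=g.gn_id)
    assert got == {"gn_id": g.gn_id, "sp_name": ctx.sp_by_id[g.sp_id].sp_name}

def _orc_all_species(ctx):
    assert {s["sp_id"] for s in ctx.call("all_species")} == set(ctx.sp_by_id)

def _orc_species_by_id(ctx):
    sp = ctx.species[2]
    assert ctx.call("species_by_id", sp_id=sp.sp_id)["sp_name"] == sp.sp_name

def _orc_species_by_name(ctx):
    sp = ctx.species[2]
    assert ctx.call("species_by_name", sp_name=sp.sp_name)["sp_id"] == sp.sp_id

def _orc_species_by_taxon(ctx):
    sp = ctx.species[3]
    assert ctx.call("species_by_taxon", taxon_id=sp.sp_taxon_id)["sp_id"] == sp.sp_id

def _orc_all_algorithms(ctx):
    assert {a["alg_name"] for a in ctx.call("all_algorithms")} == {a.alg_name for a in ctx.algorithms}

def _orc_algorithm_by_id(ctx):
    a = ctx.algorithms[-1]
    assert ctx.call("algorithm_by_id", alg_id=a.alg_id)["alg_name"] == a.alg_name

def _orc_algorithm_by_name(ctx):
    a = ctx.algorithms[-1]
    assert ctx.call("algorithm_by_name", alg_name=a.alg_name)["alg_id"] == a.alg_id

def _orc_all_orthologs(ctx):
    assert pair_ids(ctx.call("all_orthologs", limit=11)) == {p.ort_id for p in ctx.pairs[:11]}

def _orc_ortholog_by_id(ctx):
    p = ctx.agr_pair
    got = ctx.call("ortholog_by_id", ort_id=p.ort_id)
    assert (got["from_gene"], got["to_gene"]) == (p.from_gene, p.to_gene)

def _orc_orthologs_by_from_gene(ctx):
    g = ctx.gene0
    expect = {p.ort_id for p in ctx.pairs if p.from_gene == g.gn_id}
    assert pair_ids(ctx.call("orthologs_by_from_gene", gn_id=g.gn_id)) == expect

def _orc_orthologs_by_to_gene(ctx):
    g = ctx.gene0
    expect = {p.ort_id for p in ctx.pairs if p.to_gene == g.gn_id}
    assert pair_ids(ctx.call("orthologs_by_to_gene", gn_id=g.gn_id)) == expect

def _orc_orthologs_by_from_and_to_gene(ctx):
    p = ctx.agr_pair
    got = ctx.call("orthologs_by_from_and_to_gene", from_gn_id=p.from_gene, to_gn_id=p.to_gene)
    assert pair_ids(got) == {p.ort_id}

def _orc_orthologs_by_from_gene_best(ctx):
    g = ctx.gene0
    for best in (True, False):
        expect = {p.ort_id for p in ctx.pairs if p.from_gene == g.gn_id and p.is_best is best}
        got = ctx.call("orthologs_by_from_gene_best", gn_id=g.gn_id, best=str(best).lower())
        assert pair_ids(got) == expect

def _orc_orthologs_by_from_to_best(ctx):
    p = ctx.agr_pair
    got = ctx.call("orthologs_by_from_to_best", from_gn_id=p.from_gene,
                   to_gn_id=p.to_gene, best=str(p.is_best).lower())
    assert pair_ids(got) == {p.ort_id}

def _orc_orthologs_by_from_to_revised(ctx):
    p = ctx.agr_pair
    got = ctx.call("orthologs_by_from_to_revised", from_gn_id=p.from_gene,
                   to_gn_id=p.to_gene, revised=str(p.is_best_revised).lower())
    assert pair_ids(got) == {p.ort_id}

def _orc_orthologs_by_from_species(ctx):
    sp = ctx.species[0]
    expect = {p.ort_id for p in ctx.pairs if ctx.species_of(p.from_gene) == sp.sp_id}
    assert pair_ids(ctx.call("orthologs_by_from_species", sp_name=sp.sp_name)) == expect

def _orc_orthologs_by_to_species(ctx):
    sp = ctx.species[0]
    expect = {p.ort_id for p in ctx.pairs if ctx.species_of(p.to_gene) == sp.sp_id}
    assert pair_ids(ctx.call("orthologs_by_to_species", sp_name=sp.sp_name)) == expect

def _orc_get_ortholog_by_to_and_from_species(ctx):
    f_sp = ctx.species_of(ctx.added_pair.from_gene)
    t_sp = ctx.species_of(ctx.added_pair.to_gene)
    expect = {p.ort_id for p in ctx.pairs
              if ctx.species_of(p.from_gene) == f_sp and ctx.species_of(p.to_gene) == t_sp}
    got = ctx.call("get_ortholog_by_to_and_from_species",
                   from_sp_name=ctx.sp_by_id[f_sp].sp_name,
                   to_sp_name=ctx.sp_by_id[t_sp].sp_name)
    assert pair_ids(got) == expect and ctx.added_pair.ort_id in expect

def _orc_orthologs_by_species_pair_and_algorithm(ctx):
    f_sp = ctx.species_of(ctx.agr_pair.from_gene)
    t_sp = ctx.species_of(ctx.agr_pair.to_gene)
    expect = {p.ort_id for p in ctx.pairs
              if ctx.species_of(p.from_gene) == f_sp and ctx.species_of(p.to_gene) == t_sp
              and ctx.alg0.alg_id in ctx.pair_algs[p.ort_id]}
    got = ctx.call("orthologs_by_species_pair_and_algorithm",
                   from_sp_name=ctx.sp_by_id[f_sp].sp_name,
                   to_sp_name=ctx.sp_by_id[t_sp].sp_name, alg_name=ctx.alg0.alg_name)
    assert pair_ids(got) == expect

def _orc_orthologs_by_min_algorithm_matches(ctx):
    n = 5
    expect = {p.ort_id for p in ctx.pairs if p.num_algorithms_match >= n}
    assert pair_ids(ctx.call("orthologs_by_min_algorithm_matches", min_matches=n)) == expect

def _orc_orthologs_by_source(ctx):
    source = ctx.added_pair.ort_source
    expect = {p.ort_id for p in ctx.pairs if p.ort_source == source}
    assert pair_ids(ctx.call("orthologs_by_source", ort_source=source)) == expect

def _orc_all_homology(ctx):
    got = ctx.call("all_homology", limit=10**9)
    assert {(m["hom_id"], m["gn_id"]) for m in got} == {
        (m.hom_id, m.gn_id) for m in ctx.memberships}

def _orc_homology_by_cluster(ctx):
    hom_id = ctx.memberships[0].hom_id
    expect = {m.gn_id for m in ctx.memberships if m.hom_id == hom_id}
    assert {m["gn_id"] for m in ctx.call("homology_by_cluster", hom_id=hom_id)} == expect

def _orc_homology_by_gene(ctx):
    m0 = ctx.memberships[0]
    got = ctx.call("homology_by_gene", gn_id=m0.gn_id)
    assert [(m["hom_id"], m["gn_id"]) for m in got] == [(m0.hom_id, m0.gn_id)]

def _orc_homology_by_species(ctx):
    sp_id = ctx.memberships[0].sp_id
    expect = {(m.hom_id, m.gn_id) for m in ctx.memberships if m.sp_id == sp_id}
    got = ctx.call("homology_by_species", sp_id=sp_id)
    assert {(m["hom_id"], m["gn_id"]) for m in got} == expect

def _orc_homology_by_cluster_and_species(ctx):
    m0 = ctx.memberships[0]
    expect = {m.gn_id for m in ctx.memberships
              if m.hom_id == m0.hom_id and m.sp_id == m0.sp_id}
    got = ctx.call("homology_by_cluster_and_species", hom_id=m0.hom_id, sp_id=m0.sp_id)
    assert {m["gn_id"] for m in got} == expect

def _orc_homology_by_source(ctx):
    expect = {(m.hom_id, m.gn_id) for m in ctx.memberships if m.hom_source == "added"}
    got = ctx.call("homology_by_source", hom_source="added")
    assert {(m["hom_id"], m["gn_id"]) for m in got} == expect and expect

def _orc_agr_to_ode_gene(ctx):
    gw, gene = ctx.ode_gene
    got = ctx.call("agr_to_ode_gene", agr_ref=gene.gn_ref_id)
    assert got["ode_gene_id"] == gw.ode_gene_id

def _orc_ode_to_agr_gene(ctx):
    gw, gene = ctx.ode_gene
    assert ctx.call("ode_to_agr_gene", ode_gene_id=gw.ode_gene_id)["gn_ref_id"] == gene.gn_ref_id

def _orc_gw_genes_by_genedb(ctx):
    gdb = next(g for g in ctx.genedb if g.gdb_name == "HGNC")
    expect = {g.ode_gene_id for g in ctx.gw_genes if g.gdb_id == gdb.gdb_id}
    got = ctx.call("gw_genes_by_genedb", gdb_name="HGNC")
    assert {g["ode_gene_id"] for g in got} == expect

def _orc_gw_gene_by_ref(ctx):
    gw, _ = ctx.ode_gene
    got = ctx.call("gw_gene_by_ref", ode_ref_id=gw.ode_ref_id, gdb_id=gw.gdb_id)
    assert got["ode_gene_id"] == gw.ode_gene_id

def _orc_species_map_all(ctx):
    got = ctx.call("species_map_all")
    assert {(m["sp_id"], m["gw_sp_id"]) for m in got} == {
        (m.sp_id, m.gw_sp_id) for m in ctx.store.species_map()}

def _orc_species_map_agr_to_gw(ctx):
    entry = ctx.store.species_map()[0]
    assert ctx.call("species_map_agr_to_gw", sp_id=entry.sp_id)["gw_sp_id"] == entry.gw_sp_id

def _orc_species_map_gw_to_agr(ctx):
    entry = ctx.store.species_map()[0]
    assert ctx.call("species_map_gw_to_agr", gw_sp_id=entry.gw_sp_id)["sp_id"] == entry.sp_id

def _orc_orthologs_by_ode_gene(ctx):
    gw, gene = ctx.ode_gene
    expect = {p.ort_id for p in ctx.partners_of(gene.gn_id)}
    assert pair_ids(ctx.call("orthologs_by_ode_gene", ode_gene_id=gw.ode_gene_id)) == expect

def _orc_best_orthologs_by_ode_gene(ctx):
    gw, gene = ctx.ode_gene
    expect = {p.ort_id for p in ctx.pairs if p.from_gene == gene.gn_id and p.is_best}
    assert pair_ids(ctx.call("best_orthologs_by_ode_gene", ode_gene_id=gw.ode_gene_id)) == expect

def _orc_has_ortholog_by_ode_gene(ctx):
    gw, _ = ctx.ode_gene
    assert ctx.call("has_ortholog_by_ode_gene", ode_gene_id=gw.ode_gene_id)["has_ortholog"] is True
    assert ctx.call("has_ortholog_by_ode_gene", ode_gene_id=10**9)["has_ortholog"] is False

def _orc_homology_by_ode_gene(ctx):
    gw, gene = ctx.ode_gene
    own = [m for m in ctx.memberships if m.gn_id == gene.gn_id]
    expect = {m.gn_id for m in ctx.memberships if own and m.hom_id == own[0].hom_id}
    got = ctx.call("homology_by_ode_gene", ode_gene_id=gw.ode_gene_id)
    assert {m["gn_id"] for m in got} == expect

def _orc_genedb_sources(ctx):
    assert {g["gdb_name"] for g in ctx.call("genedb_sources")} == {
        g.gdb_name for g in ctx.genedb}

def _orc_orthologous_species_of_ode_gene(ctx):
    gw, gene = ctx.ode_gene
    expect = set()
    for p in ctx.partners_of(gene.gn_id):
        other = p.to_gene if p.from_gene == gene.gn_id else p.from_gene
        expect.add(ctx.species_of(other))
    got = ctx.call("orthologous_species_of_ode_gene", ode_gene_id=gw.ode_gene_id)
    assert {s["sp_id"] for s in got} == expect

def _orc_orthologs_from_ode_gene_to_species(ctx):
    gw, gene = ctx.ode_gene
    partner = next(p for p in ctx.pairs if p.from_gene == gene.gn_id)
    sp = ctx.sp_by_id[ctx.species_of(partner.to_gene)]
    expect = {p.ort_id for p in ctx.pairs
              if p.from_gene == gene.gn_id and ctx.species_of(p.to_gene) == sp.sp_id}
    got = ctx.call("orthologs_from_ode_gene_to_species",
                   ode_gene_id=gw.ode_gene_id, sp_name=sp.sp_name)
    assert pair_ids(got) == expect


_ORACLES = {name[len("_orc_"):]: fn for name, fn in list(globals().items())
            if name.startswith("_orc_")}


@pytest.mark.parametrize("name", sorted(d.name for d in catalog()))
def test_endpoint_matches_table_scan_oracle(name, ctx):
    """Each catalog endpoint returns exactly what an independent scan of the
    full tables predicts for its filter."""
    assert name in _ORACLES, f"no oracle written for endpoint {name}"
    _ORACLES[name](ctx)
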