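"""Shared fixtures: one synthetic data set pushed through the full pipeline.

The pipeline store is session-scoped and treated as read-only by tests;
anything that mutates tables builds its own store.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from orthonorm import (
    FixtureSpec,
    Store,
    augment,
    build_clusters,
    generate_agr_fixture,
    generate_gw_fixture,
    ingest,
    read_clusters_csv,
)
from orthonorm.agr_ingest import parse_orthology_text
from orthonorm.api_service import create_app
from orthonorm.id_mapping import load_gw_tables


@dataclass
class Pipeline:
    store: Store
    spec: FixtureSpec
    agr_truth: object
    gw_truth: object
    ingest_report: object
    augment_report: object
    clusters: dict


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def agr_fixture(spec):
    return generate_agr_fixture(spec)


@pytest.fixture(scope="session")
def gw_fixture(spec):
    return generate_gw_fixture(spec)


@pytest.fixture(scope="session")
def gw_dir(spec, gw_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("gw")
    for name, text in gw_fixture[0].items():
        (d / name).write_text(text)
    return d


def run_pipeline(spec, agr_fixture, gw_fixture, gw_dir) -> Pipeline:
    tsv, agr_truth = agr_fixture
    _, gw_truth = gw_fixture
    store = Store()
    ingest_report = ingest(store, parse_orthology_text(tsv))
    load_gw_tables(store, gw_dir / "gene.csv", gw_dir / "species.csv", gw_dir / "genedb.csv")
    clusters = read_clusters_csv(gw_dir / "clusters.csv")
    augment_report = augment(store, clusters, [(n, t) for n, t, _ in spec.added_species])
    built = build_clusters(store)
    return Pipeline(store, spec, agr_truth, gw_truth, ingest_report, augment_report, built)


@pytest.fixture(scope="session")
def pipeline(spec, agr_fixture, gw_fixture, gw_dir) -> Pipeline:
    return run_pipeline(spec, agr_fixture, gw_fixture, gw_dir)


@pytest.fixture(scope="session")
def app(pipeline):
    return create_app(pipeline.store)


def refs_of(store: Store, gene_ids) -> frozenset:
    return frozenset(store.gene_by_id(g).gn_ref_id for g in gene_ids)
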