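"""Shared fixtures: seeded synthetic structures, their contact relations,
loaded databases and the reference oracle."""

from __future__ import annotations

import pytest

from gspq import (OracleDb, PreprocessConfig, SchemaVariant, SynthConfig,
                  build_schema, connect, generate_proteins, load_structure,
                  preprocess_chain, select_primary_chain)

ALL_VARIANTS = [
    SchemaVariant("normalized", False),
    SchemaVariant("normalized", True),
    SchemaVariant("denormalized", False),
    SchemaVariant("denormalized", True),
]


def make_relations(models, cutoff: float = 7.0):
    cfg = PreprocessConfig(cutoff=cutoff)
    return [preprocess_chain(select_primary_chain(m), cfg, protein_id=m.pdb_id)
            for m in models]


def build_conn(relations, variant: SchemaVariant = SchemaVariant()):
    conn = connect()
    build_schema(conn, variant)
    for rel in relations:
        load_structure(conn, rel)
    return conn


@pytest.fixture(scope="session")
def models():
    """Eight small synthetic structures (seeded, deterministic)."""
    return generate_proteins(SynthConfig(seed=11, n_proteins=8))


@pytest.fixture(scope="session")
def relations(models):
    return make_relations(models)


@pytest.fixture(scope="session")
def oracle_db(relations):
    return OracleDb.from_relations(relations)


@pytest.fixture(scope="session")
def denorm_conn(relations):
    return build_conn(relations, SchemaVariant("denormalized", True))
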