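"""Cross-checking the SQL pipeline against its independent references.

Each function here runs one verification protocol end to end on freshly
generated synthetic data and reports how many trials agreed:

* :func:`sql_oracle_agreement` -- the central correctness property: the
  SQL engine's hit sets equal the brute-force matcher's, over seeded
  random (pattern, database) pairs plus a deterministic battery covering
  all 16 node-edge-node forms;
* :func:`variant_equivalence` -- hit sets are identical across the four
  schema variants (normalized/denormalized x indexed/unindexed);
* :func:`planted_recovery` -- every planted motif instance is found;
* :func:`preprocess_agreement` -- contact/adjacency records equal a plain
  double-loop all-pairs recomputation and respect the cutoff.

These are the protocols the test suite asserts at 100% agreement; they
are exposed as library functions so reports can recompute them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import PreprocessConfig
from .oracle import OracleDb, oracle_match
from .patterns import decompose, zinc_finger_pattern
from .store import SchemaVariant, build_schema, connect, load_structure
from .synth import SynthConfig, form_battery, generate_proteins, \
    plant_in_database, random_pattern
from .translate import execute_pattern, make_hit
from .pdbio import select_primary_chain
from .contacts import preprocess_chain


# composition concentrated on the symbols the random-pattern pool draws
# from, so specific-residue patterns regularly match something and the
# equivalence checks exercise non-empty hit sets, not just empty ones
_SUITE_WEIGHTS = {"CYS": 2.0, "HIS": 2.0, "LEU": 2.0, "ARG": 2.0,
                  "GLU": 1.0, "GLY": 1.0, "SER": 1.0, "LYS": 1.0,
                  "ALA": 1.0, "VAL": 1.0}


@dataclass
class AgreementReport:
    agreed: int = 0
    total: int = 0
    forms_covered: set = field(default_factory=set)
    mismatches: list = field(default_factory=list)

    @property
    def pct(self) -> float:
        return 100.0 * self.agreed / self.total if self.total else 0.0


def _relations(models, cutoff: float = 7.0):
    cfg = PreprocessConfig(cutoff=cutoff)
    return [preprocess_chain(select_primary_chain(m), cfg, protein_id=m.pdb_id)
            for m in models]


def _loaded_conn(relations, variant: SchemaVariant = SchemaVariant()):
    conn = connect()
    build_schema(conn, variant)
    for rel in relations:
        load_structure(conn, rel)
    return conn


def sql_oracle_agreement(seed: int, n_databases: int = 10,
                         patterns_per_db: int = 10,
                         n_proteins: int = 6) -> AgreementReport:
    """Exact hit-set equality of the SQL engine and the brute-force
    matcher over random (pattern, database) pairs.

    The 16-form battery runs against the first two databases so every
    subpattern shape is exercised; a zinc-finger instance is planted into
    one protein per database so ligand-bearing patterns see non-empty
    results.
    """
    rng = np.random.default_rng([seed, 101])
    rep = AgreementReport()
    for d in range(n_databases):
        cfg = SynthConfig(seed=int(rng.integers(2**31)), n_proteins=n_proteins,
                          amino_weights=_SUITE_WEIGHTS)
        models = generate_proteins(cfg)
        plant_in_database(models, zinc_finger_pattern(), 1, cfg,
                          rng=np.random.default_rng([seed, 7, d]))
        rels = _relations(models)
        db = OracleDb.from_relations(rels)
        conn = _loaded_conn(rels)
        patterns = [random_pattern(rng, pattern_id=f"db{d}-r{i}")
                    for i in range(patterns_per_db)]
        if d < 2:
            patterns += form_battery()
        for p in patterns:
            rep.forms_covered |= {sp.form for sp in decompose(p)}
            got = set(execute_pattern(conn, p))
            want = set(oracle_match(p, db))
            rep.total += 1
            if got == want:
                rep.agreed += 1
            else:
                rep.mismatches.append((p.pattern_id, len(got), len(want)))
        conn.close()
    return rep


def variant_equivalence(seed: int, n_proteins: int = 6,
                        n_random: int = 10) -> AgreementReport:
    """Identical hit sets across the four schema variants on one fixture
    set."""
    rng = np.random.default_rng([seed, 202])
    cfg = SynthConfig(seed=int(rng.integers(2**31)), n_proteins=n_proteins,
                      amino_weights=_SUITE_WEIGHTS)
    models = generate_proteins(cfg)
    plant_in_database(models, zinc_finger_pattern(), 2, cfg,
                      rng=np.random.default_rng([seed, 8]))
    rels = _relations(models)
    conns = [_loaded_conn(rels, SchemaVariant(layout, indexed))
             for layout in ("normalized", "denormalized")
             for indexed in (False, True)]
    patterns = form_battery() + [zinc_finger_pattern()] + [
        random_pattern(rng, pattern_id=f"v{i}") for i in range(n_random)]
    rep = AgreementReport()
    for p in patterns:
        rep.forms_covered |= {sp.form for sp in decompose(p)}
        sets = [frozenset(execute_pattern(c, p)) for c in conns]
        rep.total += 1
        if len(set(sets)) == 1:
            rep.agreed += 1
        else:
            rep.mismatches.append((p.pattern_id, [len(s) for s in sets]))
    for c in conns:
        c.close()
    return rep


def planted_recovery(seed: int, ks: tuple[int, ...] = (1, 5, 20)) -> AgreementReport:
    """All k planted zinc-finger instances are present in the hit set
    (the planted bindings are a subset of the hits and there are >= k of
    them)."""
    rep = AgreementReport()
    zf = zinc_finger_pattern()
    for k in ks:
        cfg = SynthConfig(seed=int(np.random.default_rng([seed, 303, k])
                                   .integers(2**31)),
                          n_proteins=k + 2)
        models = generate_proteins(cfg)
        planted = plant_in_database(models, zf, k, cfg,
                                    rng=np.random.default_rng([seed, 9, k]))
        conn = _loaded_conn(_relations(models))
        hits = set(execute_pattern(conn, zf))
        conn.close()
        expected = {make_hit(i.protein_id, i.binding)
                    for i in planted.instances}
        rep.total += k
        ok = expected <= hits and len(hits) >= k
        rep.agreed += k if ok else len(expected & hits)
        if not ok:
            rep.mismatches.append((k, len(expected & hits), len(hits)))
    return rep


def preprocess_agreement(seed: int, n_chains: int = 50,
                         cutoff: float = 7.0) -> AgreementReport:
    """Contact and adjacency record sets equal a plain double-loop
    all-pairs recomputation, and no emitted distance exceeds the cutoff."""
    rng = np.random.default_rng([seed, 404])
    rep = AgreementReport()
    for i in range(n_chains):
        cfg = SynthConfig(seed=int(rng.integers(2**31)), n_proteins=1,
                          ligand_probability=0.8)
        (model,) = generate_proteins(cfg)
        chain = select_primary_chain(model)
        rel = preprocess_chain(chain, PreprocessConfig(cutoff=cutoff),
                               protein_id=model.pdb_id)
        ok = (_brute_amino(chain, cutoff) ==
              {(r.amino1_number, r.amino2_number): round(r.dist, 9)
               for r in rel.amino_distances})
        ok &= (_brute_ligand(chain, cutoff) ==
               {(r.ligand_number, r.amino_number): round(r.dist, 9)
                for r in rel.ligand_distances})
        ok &= [(r.amino1_number, r.amino2_number) for r in rel.next_records] \
            == [(j, j + 1) for j in range(1, len(chain.residues))]
        ok &= all(r.dist <= cutoff for r in rel.amino_distances)
        ok &= all(r.dist <= cutoff for r in rel.ligand_distances)
        rep.total += 1
        if ok:
            rep.agreed += 1
        else:
            rep.mismatches.append(model.pdb_id)
    return rep


def _min_dist(atoms_a, atoms_b) -> float:
    return min(math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))
               for p in atoms_a for q in atoms_b)


def _brute_amino(chain, cutoff):
    out = {}
    res = chain.residues
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            d = _min_dist(res[i].atoms, res[j].atoms)
            if d <= cutoff:
                out[(i + 1, j + 1)] = round(d, 9)
    return out


def _brute_ligand(chain, cutoff):
    out = {}
    for h in chain.hetgroups:
        for r in chain.residues:
            d = _min_dist(h.atoms, r.atoms)
            if d <= cutoff:
                out[(h.author_number, r.seq_index)] = round(d, 9)
    return out
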