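"""SQL compilation and execution: templates, composition, semantics."""

import numpy as np
import pytest

from gspq import (PatternGraph, SchemaVariant, amino, any_amino, build_schema,
                  compose_sql, connect, decompose, distance, execute_pattern,
                  gap, ligand, next_edge, oracle_match, subquery_sql,
                  zinc_finger_pattern)
from gspq.patterns import UNBOUNDED
from gspq.synth import form_battery, random_pattern
from gspq.translate import QueryTimeout, TranslateError
from tests.conftest import build_conn


def _single(p):
    (sp,) = decompose(p)
    return sp


class TestSubquerySql:
    def test_ligand_distance_template(self):
        p = PatternGraph("p", [ligand("L", "ZN"), amino("A", "CYS")],
                         [distance("L", "A")])
        sql = subquery_sql(_single(p))
        assert "FROM distance_ligand_amino" in sql
        assert "ligand_symbol = 'ZN'" in sql
        assert "amino_symbol = 'CYS'" in sql
        assert "dist BETWEEN 0.5 AND 7.0" in sql

    def test_wildcard_predicates_elided(self):
        p = PatternGraph("p", [any_amino("X"), any_amino("Y")],
                         [next_edge("X", "Y")])
        sql = subquery_sql(_single(p))
        assert "FROM next_amino_amino" in sql
        assert "symbol =" not in sql and "class =" not in sql

    def test_polarity_filter_uses_class_column(self):
        p = PatternGraph("p", [any_amino("X", "positively charged"),
                               amino("Y", "GLU")], [distance("X", "Y")])
        sql = subquery_sql(_single(p))
        assert "amino1_class = 'positively charged'" in sql
        assert "amino2_symbol = 'GLU'" in sql

    def test_gap_upper_clause_omitted_when_unbounded(self):
        p = PatternGraph("p", [amino("X", "CYS"), amino("Y", "HIS")],
                         [gap("X", "Y", min=2, max=UNBOUNDED)])
        sql = subquery_sql(_single(p))
        assert "a2.number - a1.number - 1 >= 2" in sql
        assert "BETWEEN" not in sql

    @pytest.mark.parametrize("layout", ["denormalized", "normalized"])
    def test_all_sixteen_forms_instantiate(self, layout):
        for p in form_battery():
            sql = subquery_sql(_single(p), layout=layout)
            assert sql.startswith("SELECT") and "protein_id" in sql

    def test_unknown_layout_is_an_error(self):
        with pytest.raises(TranslateError):
            subquery_sql(_single(form_battery()[0]), layout="columnar")


class TestComposeSql:
    def test_zinc_finger_composition(self):
        cq = compose_sql(zinc_finger_pattern())
        assert cq.aliases == [f"SQ{i}" for i in range(1, 7)]
        # each shared node induces at least one ON equality
        for nid in ("ZN", "CYS1", "HIS2", "ANY3"):
            assert f".{nid}_id = SQ" in cq.sql
        assert cq.sql.startswith("SELECT DISTINCT")

    def test_single_edge_pattern_has_no_node_sharing(self):
        p = PatternGraph("p", [ligand("L", "ZN"), amino("A", "CYS")],
                         [distance("L", "A")])
        cq = compose_sql(p)
        assert cq.aliases == ["SQ1"]
        assert "_id = SQ1." not in cq.sql.split("ORDER BY")[0].split("INNER")[0]

    def test_edge_free_node_gets_an_anchor_subquery(self):
        p = PatternGraph("p", [amino("A", "CYS")], [])
        cq = compose_sql(p)
        assert "FROM aminoacid" in cq.sql and cq.projection["A"]

    def test_disconnected_pattern_warns(self):
        p = PatternGraph("p", [amino("A", "CYS"), amino("B", "HIS"),
                               amino("C", "GLY"), amino("D", "SER")],
                         [next_edge("A", "B"), next_edge("C", "D")])
        with pytest.warns(UserWarning, match="disconnected"):
            cq = compose_sql(p)
        assert cq.warnings

    def test_bad_order_rejected(self):
        with pytest.raises(TranslateError, match="permutation"):
            compose_sql(zinc_finger_pattern(), order=[0, 1])


class TestExecute:
    def test_empty_database_yields_no_hits(self):
        conn = connect()
        build_schema(conn, SchemaVariant())
        assert execute_pattern(conn, zinc_finger_pattern()) == []

    def test_subquery_order_does_not_change_results(self, relations, denorm_conn):
        p = zinc_finger_pattern()
        base = set(execute_pattern(denorm_conn, p))
        rng = np.random.default_rng(0)
        for _ in range(4):
            order = list(rng.permutation(len(p.edges)))
            assert set(execute_pattern(denorm_conn, p,
                                       order=[int(i) for i in order])) == base

    def test_widening_a_distance_window_never_removes_hits(self, denorm_conn):
        narrow = PatternGraph("n", [ligand("L", "ZN"), amino("A", "CYS")],
                              [distance("L", "A", 0.5, 4.0)])
        wide = PatternGraph("w", [ligand("L", "ZN"), amino("A", "CYS")],
                            [distance("L", "A", 0.5, 7.0)])
        assert set(execute_pattern(denorm_conn, narrow)) <= \
            set(execute_pattern(denorm_conn, wide))

    def test_widening_a_gap_window_never_removes_hits(self, denorm_conn):
        def gp(mx):
            return PatternGraph("g", [any_amino("X"), any_amino("Y")],
                                [gap("X", "Y", min=1, max=mx)])
        hits3 = set(execute_pattern(denorm_conn, gp(3)))
        hits9 = set(execute_pattern(denorm_conn, gp(9)))
        unbounded = set(execute_pattern(denorm_conn, gp(UNBOUNDED)))
        assert hits3 <= hits9 <= unbounded

    def test_unbounded_gap_matches_oracle(self, denorm_conn, oracle_db):
        p = PatternGraph("g", [amino("X", "CYS"), any_amino("Y")],
                         [gap("X", "Y", min=1, max=UNBOUNDED)])
        assert set(execute_pattern(denorm_conn, p)) == set(oracle_match(p, oracle_db))

    def test_injectivity_forbids_binding_one_residue_twice(self, denorm_conn,
                                                           oracle_db):
        # a CYS-x(1,5)-CYS style pair: two distinct Amino nodes
        p = PatternGraph("cc", [amino("C1", "CYS"), amino("C2", "CYS")],
                         [gap("C1", "C2", min=1, max=5)])
        strict = set(execute_pattern(denorm_conn, p))
        loose = set(execute_pattern(denorm_conn, p, allow_repeats=True))
        assert strict <= loose
        for h in strict:
            b = h.binding_dict
            assert b["C1"] != b["C2"]
        assert strict == set(oracle_match(p, oracle_db))
        assert loose == set(oracle_match(p, oracle_db, allow_repeats=True))

    def test_limit_truncates_deterministically(self, denorm_conn):
        p = PatternGraph("a", [any_amino("X")], [])
        full = execute_pattern(denorm_conn, p)
        assert execute_pattern(denorm_conn, p, limit=5) == full[:5]

    def test_hits_are_deterministically_ordered(self, denorm_conn):
        p = zinc_finger_pattern()
        a = execute_pattern(denorm_conn, p)
        b = execute_pattern(denorm_conn, p)
        assert a == b
        assert a == sorted(a, key=lambda h: (h.protein_id, h.binding))

    def test_timeout_is_distinct_from_empty(self, denorm_conn):
        # combinatorial cross-join: five unconstrained wildcard nodes
        p = PatternGraph("heavy", [any_amino(f"W{i}") for i in range(5)], [])
        with pytest.warns(UserWarning), pytest.raises(QueryTimeout):
            execute_pattern(denorm_conn, p, timeout=0.02)
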