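"""Pattern model: validation, decomposition, sizing, JSON round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gspq import (ALL_FORMS, UNBOUNDED, EdgeSpec, PatternGraph, amino,
                  any_amino, any_ligand, count_elements, decompose, distance,
                  gap, ligand, next_edge, read_pattern, validate_pattern,
                  write_pattern, zinc_finger_pattern)
from gspq.patterns import (PatternFormatError, PatternSchemaError,
                           PatternValidationError)
from gspq.synth import form_battery, random_pattern


class TestValidation:
    def test_zinc_finger_is_valid(self):
        assert validate_pattern(zinc_finger_pattern()).ok

    @pytest.mark.parametrize("nodes,edges,fragment", [
        # Gap lower bound must be at least one residue
        ([amino("X", "CYS"), amino("Y", "HIS")],
         [gap("X", "Y", min=0, max=3)], "Gap min"),
        # Distance window must be ordered
        ([amino("X", "CYS"), amino("Y", "HIS")],
         [distance("X", "Y", min=0.5, max=0.4)], "max 0.4 < min 0.5"),
        ([amino("X", "CYS"), amino("X", "HIS")], [], "duplicate node id"),
        ([ligand("L", "ZN"), any_ligand("M")], [], "at most one ligand"),
        ([amino("X", "XXX")], [], "unknown amino-acid code"),
        ([any_amino("X", "positively")], [], "unknown polarity"),
        ([amino("X", "CYS")], [next_edge("X", "Y")], "names no node"),
        ([amino("X", "CYS"), amino("Y", "CYS")],
         [EdgeSpec("Next", "X", "Y", min=1)], "no min/max"),
        ([ligand("L", "ZN"), amino("X", "CYS")],
         [next_edge("L", "X")], "amino-kind nodes only"),
        ([ligand("L", "ZN"), amino("X", "CYS")],
         [gap("L", "X", min=1)], "amino-kind nodes only"),
        ([amino("X", "CYS")], [distance("X", "X")], "distinct nodes"),
    ])
    def test_violations_name_the_offender(self, nodes, edges, fragment):
        rep = validate_pattern(PatternGraph("bad", nodes, edges))
        assert not rep.ok
        assert any(fragment in v.message for v in rep.violations)

    def test_gap_unbounded_max_is_legal(self):
        p = PatternGraph("g", [amino("X", "CYS"), amino("Y", "HIS")],
                         [gap("X", "Y", min=2, max=UNBOUNDED)])
        assert validate_pattern(p).ok


class TestDecompose:
    def test_zinc_finger_subpattern_forms(self):
        forms = [sp.form for sp in decompose(zinc_finger_pattern())]
        assert forms == [
            "Ligand-Distance-Amino", "Ligand-Distance-Amino",
            "Ligand-Distance-AnyAmino", "Amino-Next-Amino",
            "Amino-Gap-AnyAmino", "Amino-Distance-AnyAmino"]

    def test_ligand_normalized_to_left_slot(self):
        p = PatternGraph("p", [amino("A", "CYS"), ligand("L", "ZN")],
                         [distance("A", "L")])  # ligand on the target side
        (sp,) = decompose(p)
        assert sp.left.node_id == "L" and sp.form == "Ligand-Distance-Amino"

    def test_one_subpattern_per_edge(self):
        rng = np.random.default_rng(5)
        for i in range(25):
            p = random_pattern(rng, pattern_id=f"r{i}")
            assert len(decompose(p)) == len(p.edges)

    def test_invalid_pattern_is_rejected(self):
        p = PatternGraph("bad", [amino("X", "CYS")], [next_edge("X", "Y")])
        with pytest.raises(PatternValidationError):
            decompose(p)

    def test_battery_covers_all_sixteen_forms(self):
        forms = {decompose(p)[0].form for p in form_battery()}
        assert forms == set(ALL_FORMS)
        assert len(ALL_FORMS) == 16


class TestCountElements:
    def test_real_pattern_composition(self):
        # 4 specific residues + 1 ligand + 4 ligand-contact edges
        nodes = [ligand("L", "ZN")] + [amino(f"A{i}", "CYS") for i in range(4)]
        edges = [distance("L", f"A{i}") for i in range(4)]
        assert count_elements(PatternGraph("rp1", nodes, edges)) == 9

    def test_generic_pattern_composition(self):
        # 2 residues + 2 wildcards + 1 ligand + 3 Next + 4 Distance
        nodes = [amino("A1", "CYS"), amino("A2", "HIS"), any_amino("W1"),
                 any_amino("W2"), ligand("L", "GOL")]
        edges = [next_edge("A1", "W1"), next_edge("W1", "A2"),
                 next_edge("A2", "W2"), distance("L", "A1"),
                 distance("L", "A2"), distance("L", "W1"), distance("A1", "A2")]
        assert count_elements(PatternGraph("gp6", nodes, edges)) == 12

    def test_empty_pattern(self):
        assert count_elements(PatternGraph("empty")) == 0

    def test_additive_over_disjoint_union(self):
        a, b = zinc_finger_pattern(), form_battery()[0]
        union = PatternGraph(
            "u",
            a.nodes + [type(n)(**{**n.__dict__,
                                  "node_id": "u_" + n.node_id}) for n in b.nodes],
            a.edges + [type(e)(**{**e.__dict__, "source": "u_" + e.source,
                                  "target": "u_" + e.target}) for e in b.edges])
        assert count_elements(union) == count_elements(a) + count_elements(b)


class TestJson:
    def test_distance_defaults_materialized(self):
        doc = """{"pattern_id": "d", "nodes": [
            {"id": "L", "kind": "Ligand", "code": "ZN"},
            {"id": "A", "kind": "Amino", "name": "CYS"}],
            "edges": [{"kind": "Distance", "source": "L", "target": "A"}]}"""
        p = read_pattern(doc)
        assert (p.edges[0].min, p.edges[0].max) == (0.5, 7.0)

    def test_anyamino_polarity_defaults_to_any(self):
        p = read_pattern('{"pattern_id": "a", "nodes": '
                         '[{"id": "W", "kind": "AnyAmino"}], "edges": []}')
        assert p.nodes[0].polarity == "any"

    def test_gap_null_max_reads_as_unbounded(self):
        doc = """{"pattern_id": "g", "nodes": [
            {"id": "X", "kind": "Amino", "name": "CYS"},
            {"id": "Y", "kind": "Amino", "name": "HIS"}],
            "edges": [{"kind": "Gap", "source": "X", "target": "Y",
                       "min": 2, "max": null}]}"""
        assert read_pattern(doc).edges[0].max == UNBOUNDED

    def test_zinc_finger_round_trips(self):
        p = zinc_finger_pattern()
        assert read_pattern(write_pattern(p)) == p

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_patterns_round_trip(self, seed):
        p = random_pattern(np.random.default_rng(seed))
        assert read_pattern(write_pattern(p)) == p

    @pytest.mark.parametrize("doc,exc", [
        ("{not json", PatternFormatError),
        ('{"pattern_id": "p", "nodes": [], "edges": [], "extra": 1}',
         PatternFormatError),
        ('{"pattern_id": "p", "nodes": [{"id": "X", "kind": "Residue"}], '
         '"edges": []}', PatternSchemaError),
        ('{"pattern_id": "p", "nodes": [{"id": "X", "kind": "Amino", '
         '"name": "CYS", "color": "red"}], "edges": []}', PatternFormatError),
        ('{"pattern_id": "p", "nodes": [{"id": "X", "kind": "Amino", '
         '"name": "CYS"}, {"id": "Y", "kind": "Amino", "name": "HIS"}], '
         '"edges": [{"kind": "Next", "source": "X", "target": "Y", '
         '"min": 1}]}', PatternFormatError),
    ])
    def test_malformed_documents_rejected(self, doc, exc):
        with pytest.raises(exc):
            read_pattern(doc)
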