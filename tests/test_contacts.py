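"""Contact preprocessing against an independent all-pairs brute force."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gspq import (Atom, ChainModel, HetGroup, PreprocessConfig, Residue,
                  SynthConfig, compute_amino_distances,
                  compute_ligand_distances, compute_next, generate_protein,
                  make_ids, polarity_of, residue_min_distance)
from gspq.amino import STANDARD_AMINO_ACIDS
from gspq.contacts import write_records_csv


def brute_min_distance(a, b):
    """Independent oracle: plain double loop over atom pairs."""
    return min(math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))
               for p in a for q in b)


def _res(idx, symbol, coords):
    return Residue(idx, idx, symbol,
                   [Atom(i + 1, "CA", *xyz) for i, xyz in enumerate(coords)])


def _single_atom_chain(positions, symbol="GLY"):
    return ChainModel("A", [_res(i + 1, symbol, [p])
                            for i, p in enumerate(positions)])


class TestMinDistance:
    def test_two_points(self):
        a, b = [Atom(1, "CA", 0, 0, 0)], [Atom(2, "CA", 3, 0, 0)]
        assert residue_min_distance(a, b) == 3.0

    def test_identical_sets_have_zero_distance(self):
        a = [Atom(1, "CA", 1.0, 2.0, 3.0), Atom(2, "CB", 4.0, 5.0, 6.0)]
        assert residue_min_distance(a, a) == 0.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            residue_min_distance([], [Atom(1, "CA", 0, 0, 0)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        a = [Atom(i, "CA", *rng.uniform(0, 10, 3)) for i in range(5)]
        b = [Atom(i, "CA", *rng.uniform(0, 10, 3)) for i in range(7)]
        assert residue_min_distance(a, b) == pytest.approx(
            brute_min_distance(a, b), abs=1e-12)


class TestAminoDistances:
    def test_pair_beyond_cutoff_is_excluded(self):
        chain = _single_atom_chain([(0, 0, 0), (7.5, 0, 0)])
        assert compute_amino_distances(chain, protein_id="P") == []

    def test_pair_within_cutoff_is_included(self):
        chain = _single_atom_chain([(0, 0, 0), (6.9, 0, 0)])
        (rec,) = compute_amino_distances(chain, protein_id="P")
        assert rec.dist == pytest.approx(6.9)
        assert rec.amino1_number == 1 and rec.amino2_number == 2

    def test_matches_bruteforce_on_random_chain(self):
        m = generate_protein(SynthConfig(seed=77, n_proteins=1,
                                         residues_per_chain=(30, 30)))
        chain = m.chains[0]
        recs = compute_amino_distances(chain, protein_id=m.pdb_id)
        got = {(r.amino1_number, r.amino2_number): r.dist for r in recs}
        expected = {}
        res = chain.residues
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                d = brute_min_distance(res[i].atoms, res[j].atoms)
                if d <= 7.0:
                    expected[(i + 1, j + 1)] = d
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)

    def test_all_distances_within_cutoff_and_canonical(self, relations):
        for rel in relations:
            for r in rel.amino_distances:
                assert 0.0 <= r.dist <= 7.0
                assert r.amino1_number < r.amino2_number


class TestLigandDistances:
    def test_ligand_contact_distance(self):
        chain = _single_atom_chain([(0, 0, 0)], symbol="CYS")
        chain.hetgroups.append(HetGroup("ZN", 1001, [Atom(9, "ZN", 2.1, 0, 0)]))
        (rec,) = compute_ligand_distances(chain, protein_id="P")
        assert rec.dist == pytest.approx(2.1)
        assert rec.ligand_symbol == "ZN" and rec.amino_symbol == "CYS"

    def test_chain_without_hetgroups(self):
        chain = _single_atom_chain([(0, 0, 0), (3, 0, 0)])
        assert compute_ligand_distances(chain, protein_id="P") == []

    def test_matches_bruteforce_with_two_hetgroups(self):
        rng = np.random.default_rng(3)
        chain = _single_atom_chain([tuple(rng.uniform(0, 12, 3))
                                    for _ in range(10)])
        for k in range(2):
            chain.hetgroups.append(
                HetGroup("GOL", 1001 + k,
                         [Atom(50 + k, "C1", *rng.uniform(0, 12, 3))]))
        recs = compute_ligand_distances(chain, protein_id="P")
        expected = {(h.author_number, r.seq_index): brute_min_distance(h.atoms, r.atoms)
                    for h in chain.hetgroups for r in chain.residues
                    if brute_min_distance(h.atoms, r.atoms) <= 7.0}
        got = {(r.ligand_number, r.amino_number): r.dist for r in recs}
        assert got.keys() == expected.keys()


class TestNext:
    @pytest.mark.parametrize("n,expected", [(1, 0), (4, 3)])
    def test_record_count(self, n, expected):
        chain = _single_atom_chain([(i * 3.8, 0, 0) for i in range(n)])
        assert len(compute_next(chain, protein_id="P")) == expected

    def test_links_consecutive_seq_indices(self, relations):
        for rel in relations:
            n = len(rel.chain.residues)
            assert len(rel.next_records) == n - 1
            assert [(r.amino1_number, r.amino2_number)
                    for r in rel.next_records] == [(i, i + 1) for i in range(1, n)]


class TestIds:
    def test_atom_id_format(self):
        assert make_ids("1B38", "A", 1, 4) == "1B38_A_1_4"

    def test_amino_id_is_a_prefix_of_its_atom_ids(self):
        assert make_ids("1B38", "A", 1) == "1B38_A_1"
        assert make_ids("1B38", "A", 1, 4).startswith(make_ids("1B38", "A", 1))

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            make_ids("", "A", 1)

    def test_generated_ids_are_unique(self, models):
        for m in models:
            chain = m.chains[0]
            ids = [make_ids(m.pdb_id, chain.chain_id, r.seq_index)
                   for r in chain.residues]
            ids += [make_ids(m.pdb_id, chain.chain_id, h.author_number)
                    for h in chain.hetgroups]
            ids += [make_ids(m.pdb_id, chain.chain_id, r.seq_index, k + 1)
                    for r in chain.residues for k in range(len(r.atoms))]
            assert len(ids) == len(set(ids))


class TestPolarity:
    def test_canonical_examples(self):
        assert polarity_of("ARG") == "positively charged"
        assert polarity_of("GLU") == "negatively charged"
        assert polarity_of("UND") == "unknown"

    def test_classes_partition_the_standard_twenty(self):
        sizes = {}
        for e in STANDARD_AMINO_ACIDS[:-1]:
            sizes[e.polarity] = sizes.get(e.polarity, 0) + 1
        assert sizes == {"non-polar": 9, "polar uncharged": 6,
                         "positively charged": 3, "negatively charged": 2}

    def test_unknown_symbol_is_an_error(self):
        with pytest.raises(KeyError):
            polarity_of("ZZZ")


def test_csv_header_matches_denormalized_columns(relations):
    rel = next(r for r in relations if r.amino_distances)
    buf = io.StringIO()
    write_records_csv(rel.amino_distances, buf)
    header = buf.getvalue().splitlines()[0]
    assert header == ("protein_id,amino1_id,amino1_symbol,amino1_class,"
                      "amino1_number,amino2_id,amino2_symbol,amino2_class,"
                      "amino2_number,dist")
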