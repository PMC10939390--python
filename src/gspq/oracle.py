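"""Brute-force in-memory pattern matcher.

This is the ground-truth reference the SQL pipeline is checked against:
an exhaustive backtracking search over node assignments with the exact
edge semantics of the pattern model.  It consumes the same preprocessing
outputs the store loads (never raw coordinates), so translator and oracle
test identical contact semantics -- a disagreement always points at the
compilation, not at a second distance computation.

Edge checks:

* Distance: the precomputed minimum inter-atomic distance of the pair is
  present (pairs beyond the preprocessing cutoff are treated as absent)
  and lies in [min, max];
* Next: the target's sequence index is exactly source + 1;
* Gap: the number of residues strictly between source and target lies in
  [min, max], unbounded max allowed;
* distinct amino-kind nodes bind distinct residues (injectivity) unless
  ``allow_repeats``.

Intended for the small fixtures of the test suite, not for large
databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contacts import ChainRelations, PreprocessConfig, preprocess_chain
from .patterns import PatternGraph, _Unbounded, require_valid
from .pdbio import StructureModel, select_primary_chain
from .translate import Hit, make_hit


@dataclass(frozen=True)
class _Element:
    element_id: str
    symbol: str  # residue code or het code
    polarity: str | None
    number: int


@dataclass
class _ProteinView:
    residues: list[_Element] = field(default_factory=list)
    hetgroups: list[_Element] = field(default_factory=list)
    aa_dist: dict[tuple[int, int], float] = field(default_factory=dict)
    la_dist: dict[tuple[str, int], float] = field(default_factory=dict)


@dataclass
class OracleDb:
    """Per-protein residue sequences, het groups and precomputed pairwise
    minimum distances, assembled from preprocessing outputs."""

    proteins: dict[str, _ProteinView] = field(default_factory=dict)

    @classmethod
    def from_relations(cls, relations: list[ChainRelations]) -> "OracleDb":
        db = cls()
        for rel in relations:
            view = _ProteinView()
            db.proteins[rel.protein_id] = view
            _fill_view(view, rel)
        return db

    @classmethod
    def from_structures(cls, models: list[StructureModel],
                        cfg: PreprocessConfig = PreprocessConfig()) -> "OracleDb":
        rels = [preprocess_chain(select_primary_chain(m), cfg, protein_id=m.pdb_id)
                for m in models]
        return cls.from_relations(rels)


def _fill_view(view: _ProteinView, rel: ChainRelations) -> None:
    from .amino import polarity_of
    from .contacts import make_ids

    chain = rel.chain
    pid = rel.protein_id
    for r in chain.residues:
        view.residues.append(_Element(
            make_ids(pid, chain.chain_id, r.seq_index), r.symbol,
            polarity_of(r.symbol), r.seq_index))
    for h in chain.hetgroups:
        view.hetgroups.append(_Element(
            make_ids(pid, chain.chain_id, h.author_number), h.code,
            None, h.author_number))
    for rec in rel.amino_distances:
        lo, hi = sorted((rec.amino1_number, rec.amino2_number))
        view.aa_dist[(lo, hi)] = rec.dist
    for rec in rel.ligand_distances:
        view.la_dist[(rec.ligand_id, rec.amino_number)] = rec.dist


def _candidates(node, view: _ProteinView) -> list[_Element]:
    if node.kind == "Amino":
        return [r for r in view.residues if r.symbol == node.name]
    if node.kind == "AnyAmino":
        if node.polarity in (None, "any"):
            return list(view.residues)
        return [r for r in view.residues if r.polarity == node.polarity]
    if node.kind == "Ligand":
        return [h for h in view.hetgroups if h.symbol == node.code]
    return list(view.hetgroups)


def _edge_ok(edge, src: _Element, dst: _Element, view: _ProteinView) -> bool:
    if edge.kind == "Distance":
        if src.polarity is None:  # ligand on the source side
            d = view.la_dist.get((src.element_id, dst.number))
        elif dst.polarity is None:
            d = view.la_dist.get((dst.element_id, src.number))
        else:
            lo, hi = sorted((src.number, dst.number))
            d = view.aa_dist.get((lo, hi))
        return d is not None and edge.min <= d <= edge.max
    if edge.kind == "Next":
        return dst.number == src.number + 1
    k = dst.number - src.number - 1
    if k < edge.min:
        return False
    return isinstance(edge.max, _Unbounded) or k <= edge.max


def oracle_match(p: PatternGraph, db: OracleDb,
                 allow_repeats: bool = False) -> list[Hit]:
    """All matches of a valid pattern, by exhaustive backtracking.

    Output is a deduplicated, deterministically ordered hit list in the
    same normal form the SQL executor produces; it is independent of node
    and edge enumeration order (set semantics).
    """
    require_valid(p)
    hits: set[Hit] = set()
    nodes = _search_order(p)
    edges_by_node: dict[str, list] = {n.node_id: [] for n in p.nodes}
    for e in p.edges:
        edges_by_node[e.source].append(e)
        edges_by_node[e.target].append(e)

    for pid, view in db.proteins.items():
        assignment: dict[str, _Element] = {}

        def consistent(node, elem) -> bool:
            if not allow_repeats and node.is_amino:
                for other in p.nodes:
                    if (other.is_amino and other.node_id != node.node_id
                            and other.node_id in assignment
                            and assignment[other.node_id].element_id == elem.element_id):
                        return False
            for e in edges_by_node[node.node_id]:
                src_id, dst_id = e.source, e.target
                other_id = dst_id if src_id == node.node_id else src_id
                if other_id not in assignment and other_id != node.node_id:
                    continue
                src = elem if src_id == node.node_id else assignment[src_id]
                dst = elem if dst_id == node.node_id else assignment[dst_id]
                if not _edge_ok(e, src, dst, view):
                    return False
            return True

        def backtrack(i: int) -> None:
            if i == len(nodes):
                binding = {nid: el.element_id for nid, el in assignment.items()}
                details = {nid: (el.symbol, el.number)
                           for nid, el in assignment.items()}
                hits.add(make_hit(pid, binding, details))
                return
            node = nodes[i]
            for elem in _candidates(node, view):
                if consistent(node, elem):
                    assignment[node.node_id] = elem
                    backtrack(i + 1)
                    del assignment[node.node_id]

        backtrack(0)
    return sorted(hits, key=lambda h: (h.protein_id, h.binding))


def _search_order(p: PatternGraph):
    """Order nodes so that each one (when possible) is adjacent to an
    already-placed node; keeps the backtracking pruned for connected
    patterns without changing the result set."""
    remaining = {n.node_id: n for n in p.nodes}
    adj: dict[str, set[str]] = {n.node_id: set() for n in p.nodes}
    for e in p.edges:
        adj[e.source].add(e.target)
        adj[e.target].add(e.source)
    order = []
    placed: set[str] = set()
    while remaining:
        # prefer a node connected to a placed one, then the most-constrained
        best = None
        for nid, node in remaining.items():
            score = (len(adj[nid] & placed), len(adj[nid]), nid)
            if best is None or score > best[0]:
                best = (score, nid)
        nid = best[1]
        order.append(remaining.pop(nid))
        placed.add(nid)
    return order
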