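"""Synthetic protein structures with controllable geometry and planted motifs.

The generator emulates the statistical structure the contact pipeline
assumes: residues laid along a self-avoiding random walk with the
canonical ~3.8 A consecutive-CA spacing (so sequence neighbors are always
within the 7 A interaction cutoff), a handful of satellite atoms per
residue, and optional het groups placed a plausible coordination distance
(2.5-6 A) from the backbone.  It does not attempt physically realistic
side-chain geometry or packing; its purpose is to provide structures whose
contact relations are fully known so that pattern-matching results can be
verified exactly.

``plant_pattern`` edits a generated structure so that one complete match
of a given pattern exists by construction: it picks residue positions
satisfying every Next/Gap constraint, rewrites their symbols to the
pattern's node names, and places the ligand so each Distance bound holds
strictly inside its [min, max] window.

``write_pdb`` emits fixed-column PDB text that round-trips through
:func:`gspq.pdbio.parse_pdb` to an identical model (coordinates are
generated pre-rounded to the format's 3 decimals).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import numpy as np

from .amino import STANDARD_AMINO_ACIDS
from .contacts import make_ids, residue_min_distance
from .patterns import (PatternGraph, _Unbounded, amino, any_amino, any_ligand,
                       distance, gap, ligand, next_edge, require_valid,
                       ALL_FORMS, EdgeSpec, NodeSpec, PatternGraph)
from .pdbio import Atom, ChainModel, HetGroup, Residue, StructureModel
from .store import detect_layout

_STANDARD_20 = tuple(e.abbreviation for e in STANDARD_AMINO_ACIDS[:-1])
_BY_CLASS: dict[str, list[str]] = {}
for _e in STANDARD_AMINO_ACIDS[:-1]:
    _BY_CLASS.setdefault(_e.polarity, []).append(_e.abbreviation)

_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CN")
_CA_SPACING = 3.8   # canonical consecutive-CA distance
_MIN_CA_SEP = 3.0   # self-avoidance radius of the walk
_SIDE_RADIUS = 1.2  # satellite atoms stay within this radius of the CA


class SynthError(RuntimeError):
    pass


class PlantError(SynthError):
    """A pattern instance could not be planted; names the blocking edge."""


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give 20-60 residue single-chain
    structures in a 40 A box with roughly one het group per protein."""

    seed: int = 0
    n_proteins: int = 10
    residues_per_chain: tuple[int, int] = (20, 60)
    atoms_per_residue: tuple[int, int] = (3, 6)
    box: float = 40.0
    amino_weights: dict[str, float] | None = None  # default: uniform over 20
    ligand_codes: tuple[str, ...] = ("ZN", "GOL", "SO4", "EDO")
    ligand_probability: float = 0.7

    def __post_init__(self):
        if self.n_proteins < 0 or self.box <= 0:
            raise ValueError("counts must be >= 0 and box > 0")
        if self.box < 3 * _CA_SPACING:
            raise SynthError(f"box {self.box} too small for a walk")


def _rng_for(cfg: SynthConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, index])


def sample_symbols(rng: np.random.Generator, n: int,
                   weights: dict[str, float] | None = None) -> list[str]:
    """Draw residue symbols from the configured composition."""
    if weights:
        codes = sorted(weights)
        p = np.array([weights[c] for c in codes], dtype=float)
        p /= p.sum()
    else:
        codes, p = list(_STANDARD_20), None
    return [str(s) for s in rng.choice(codes, size=n, p=p)]


def _walk(rng: np.random.Generator, n: int, box: float,
          restarts: int = 50) -> np.ndarray:
    """Self-avoiding random walk of CA positions, confined to the box.

    A walk can dead-end; the whole walk is restarted (bounded) when it
    does, which keeps generation deterministic for a fixed rng state.
    """
    for _ in range(restarts):
        pos = _try_walk(rng, n, box)
        if pos is not None:
            return pos
    raise SynthError(f"infeasible geometry: no self-avoiding walk of {n} "
                     f"residues fits a {box} A box")


def _try_walk(rng: np.random.Generator, n: int, box: float):
    pos = np.empty((n, 3))
    pos[0] = box / 2.0
    for i in range(1, n):
        for _ in range(60):
            v = rng.normal(size=3)
            step = pos[i - 1] + v / np.linalg.norm(v) * _CA_SPACING
            if not np.all((step > 1.0) & (step < box - 1.0)):
                continue
            if i > 1 and np.min(np.linalg.norm(pos[:i - 1] - step, axis=1)) < _MIN_CA_SEP:
                continue
            pos[i] = step
            break
        else:
            return None
    return pos


def _sphere_point(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1 / 3)


def generate_protein(cfg: SynthConfig, index: int = 0) -> StructureModel:
    """One deterministic synthetic structure (fixed seed -> identical model)."""
    rng = _rng_for(cfg, index)
    pdb_id = f"S{index:03d}"
    lo, hi = cfg.residues_per_chain
    n = int(rng.integers(lo, hi + 1))
    ca = _walk(rng, n, cfg.box)
    symbols = sample_symbols(rng, n, cfg.amino_weights)
    alo, ahi = cfg.atoms_per_residue
    serial = 1
    residues = []
    for i in range(n):
        k = int(rng.integers(alo, ahi + 1))
        atoms = []
        for j in range(k):
            xyz = ca[i] if j == 0 else ca[i] + _sphere_point(rng, _SIDE_RADIUS)
            x, y, z = np.round(xyz, 3)
            atoms.append(Atom(serial, _ATOM_NAMES[j % len(_ATOM_NAMES)],
                              float(x), float(y), float(z)))
            serial += 1
        residues.append(Residue(i + 1, i + 1, symbols[i], atoms))
    hets = []
    if rng.random() < cfg.ligand_probability and cfg.ligand_codes:
        code = str(rng.choice(list(cfg.ligand_codes)))
        anchor = ca[int(rng.integers(0, n))]
        v = rng.normal(size=3)
        xyz = anchor + v / np.linalg.norm(v) * float(rng.uniform(2.5, 6.0))
        x, y, z = np.round(xyz, 3)
        hets.append(HetGroup(code, 1001,
                             [Atom(serial, _het_atom_name(code), float(x),
                                   float(y), float(z))]))
        serial += 1
    chain = ChainModel("A", residues, hets)
    return StructureModel(pdb_id=pdb_id, chains=[chain])


def generate_proteins(cfg: SynthConfig) -> list[StructureModel]:
    return [generate_protein(cfg, i) for i in range(cfg.n_proteins)]


def _het_atom_name(code: str) -> str:
    # metals keep their element name; organic het groups get a carbon
    return code if len(code) <= 2 and code.isalpha() else "C1"


# ---------------------------------------------------------------------------
# planting

@dataclass
class PlantedInstance:
    protein_id: str
    binding: dict[str, str]  # node_id -> element id


@dataclass
class PlantReport:
    instances: list[PlantedInstance] = field(default_factory=list)


_PLANT_MARGIN = 0.05  # keep planted distances strictly inside [min, max]


def _seq_constraints(p: PatternGraph):
    cons = []
    for e in p.edges:
        if e.kind == "Next":
            cons.append((e, e.source, e.target, 0, 0))
        elif e.kind == "Gap":
            hi = None if isinstance(e.max, _Unbounded) else int(e.max)
            cons.append((e, e.source, e.target, int(e.min), hi))
    return cons


def plant_pattern(model: StructureModel, p: PatternGraph,
                  cfg: SynthConfig | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[StructureModel, PlantReport]:
    """Rewrite ``model`` so it contains one full match of ``p``.

    Residue positions are chosen to satisfy every Next/Gap constraint and
    every residue-residue Distance bound against the existing geometry;
    node symbols are written onto those residues; the ligand (if any) is
    placed so that each of its Distance bounds holds strictly inside
    [min, max].  Raises :class:`PlantError` naming the edge that could not
    be satisfied.
    """
    require_valid(p)
    cfg = cfg or SynthConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chain = max(model.chains, key=lambda c: (c.size, c.chain_id))
    n = len(chain.residues)
    amino_nodes = [nd for nd in p.nodes if nd.is_amino]
    lig_nodes = [nd for nd in p.nodes if nd.is_ligand]
    if len(amino_nodes) > n:
        raise PlantError(f"pattern has {len(amino_nodes)} amino nodes but the "
                         f"chain only {n} residues")

    seq_cons = _seq_constraints(p)
    aa_dist_edges = [e for e in p.edges if e.kind == "Distance"
                     and p.node(e.source).is_amino and p.node(e.target).is_amino]

    assignment = _assign_positions(chain, amino_nodes, seq_cons, aa_dist_edges,
                                   p, rng)

    # rewrite residue symbols to match the nodes
    binding: dict[str, str] = {}
    for nd in amino_nodes:
        r = chain.residues[assignment[nd.node_id]]
        if nd.kind == "Amino":
            r.symbol = nd.name
        else:
            pool = (_BY_CLASS[nd.polarity] if nd.polarity not in (None, "any")
                    else list(_STANDARD_20))
            r.symbol = str(rng.choice(pool))
        binding[nd.node_id] = make_ids(model.pdb_id, chain.chain_id, r.seq_index)

    if lig_nodes:
        nd = lig_nodes[0]
        code = nd.code if nd.kind == "Ligand" else str(rng.choice(list(cfg.ligand_codes)))
        # decoys with the same code would blur the >=k recovery bound
        chain.hetgroups = [h for h in chain.hetgroups if h.code != code]
        number = max([1000] + [h.author_number for h in chain.hetgroups]) + 1
        lig_edges = [e for e in p.edges if e.kind == "Distance"
                     and (e.source == nd.node_id or e.target == nd.node_id)]
        pos = _place_ligand(chain, assignment, nd, lig_edges, rng)
        serial = 1 + max((a.serial for r in chain.residues for a in r.atoms),
                         default=0)
        x, y, z = np.round(pos, 3)
        chain.hetgroups.append(HetGroup(code, number,
                                        [Atom(serial, _het_atom_name(code),
                                              float(x), float(y), float(z))]))
        binding[nd.node_id] = make_ids(model.pdb_id, chain.chain_id, number)

    report = PlantReport([PlantedInstance(model.pdb_id, binding)])
    return model, report


def _assign_positions(chain, amino_nodes, seq_cons, aa_dist_edges, p, rng):
    """Backtracking over 0-based residue indices satisfying the sequence
    constraints and the residue-residue Distance bounds geometrically."""
    n = len(chain.residues)
    order = [nd.node_id for nd in amino_nodes]
    coords = {i: chain.residues[i].atoms for i in range(n)}
    failed_edge = [None]

    def ok(nid: str, idx: int, assigned: dict[str, int]) -> bool:
        for e, s, t, lo, hi in seq_cons:
            if s == nid and t in assigned:
                k = assigned[t] - idx - 1
            elif t == nid and s in assigned:
                k = idx - assigned[s] - 1
            else:
                continue
            if k < lo or (hi is not None and k > hi):
                failed_edge[0] = e
                return False
        for e in aa_dist_edges:
            if e.source == nid and e.target in assigned:
                other = assigned[e.target]
            elif e.target == nid and e.source in assigned:
                other = assigned[e.source]
            else:
                continue
            d = residue_min_distance(coords[idx], coords[other])
            if not (e.min + _PLANT_MARGIN <= d <= e.max - _PLANT_MARGIN):
                failed_edge[0] = e
                return False
        return True

    def search(i: int, assigned: dict[str, int]):
        if i == len(order):
            return dict(assigned)
        nid = order[i]
        for idx in rng.permutation(n):
            idx = int(idx)
            if idx in assigned.values():
                continue
            if ok(nid, idx, assigned):
                assigned[nid] = idx
                got = search(i + 1, assigned)
                if got is not None:
                    return got
                del assigned[nid]
        return None

    got = search(0, {})
    if got is None:
        e = failed_edge[0]
        what = (f"{e.kind} edge {e.source}->{e.target}" if e is not None
                else "the sequence constraints")
        raise PlantError(f"cannot satisfy {what} on a {n}-residue chain")
    return got


def _place_ligand(chain, assignment, node, lig_edges, rng, tries: int = 2000):
    """Sample a ligand position satisfying every ligand Distance bound
    strictly inside its window."""
    targets = []
    for e in lig_edges:
        other = e.target if e.source == node.node_id else e.source
        targets.append((e, chain.residues[assignment[other]].atoms))
    if not targets:
        # unconstrained ligand: drop it near a random residue
        r = chain.residues[int(rng.integers(0, len(chain.residues)))]
        base = np.array([r.atoms[0].x, r.atoms[0].y, r.atoms[0].z])
        v = rng.normal(size=3)
        return base + v / np.linalg.norm(v) * 3.0
    centroid = np.mean([[a.x, a.y, a.z] for _, atoms in targets
                        for a in atoms], axis=0)
    radius = max(float(e.max) for e, _ in targets)
    probe = Atom(0, "X", 0.0, 0.0, 0.0)
    for _ in range(tries):
        pos = np.round(centroid + _sphere_point(rng, radius), 3)
        probe.x, probe.y, probe.z = (float(v) for v in pos)
        for e, atoms in targets:
            d = residue_min_distance([probe], atoms)
            if not (e.min + _PLANT_MARGIN <= d <= e.max - _PLANT_MARGIN):
                bad = e
                break
        else:
            return pos
    raise PlantError(f"cannot place ligand for Distance edge "
                     f"{bad.source}->{bad.target} within "
                     f"[{bad.min}, {bad.max}]")


def plant_in_database(models: list[StructureModel], p: PatternGraph,
                      k: int, cfg: SynthConfig | None = None,
                      rng: np.random.Generator | None = None) -> PlantReport:
    """Plant one instance of ``p`` into each of the first ``k`` models
    (in place); returns the combined report."""
    if k > len(models):
        raise PlantError(f"cannot plant {k} instances into {len(models)} proteins")
    cfg = cfg or SynthConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    report = PlantReport()
    for m in models[:k]:
        _, rep = plant_pattern(m, p, cfg, rng)
        report.instances.extend(rep.instances)
    return report


# ---------------------------------------------------------------------------
# artificial-pattern suggestion

def suggest_artificial_patterns(conn: sqlite3.Connection, n_ligands: int = 3,
                                n_aminos: int = 2) -> list[tuple[str, tuple[str, ...]]]:
    """Rank ligands by the number of distinct proteins containing them and,
    for each, the residue symbols most frequently in contact with it
    (ties broken lexicographically) -- the recipe used to build artificial
    stress-test patterns from database content."""
    layout = detect_layout(conn)
    if layout == "denormalized":
        lig_sql = ("SELECT symbol, COUNT(DISTINCT protein_id) AS n FROM ligand "
                   "GROUP BY symbol ORDER BY n DESC, symbol LIMIT ?")
        am_sql = ("SELECT amino_symbol, COUNT(*) AS n FROM distance_ligand_amino "
                  "WHERE ligand_symbol = ? GROUP BY amino_symbol "
                  "ORDER BY n DESC, amino_symbol LIMIT ?")
    else:
        lig_sql = ("SELECT l.symbol, COUNT(DISTINCT c.protein_id) AS n "
                   "FROM ligand l INNER JOIN chain c ON l.chain_id = c.id "
                   "GROUP BY l.symbol ORDER BY n DESC, l.symbol LIMIT ?")
        am_sql = ("SELECT a.symbol, COUNT(*) AS n "
                  "FROM distance_ligand_amino d "
                  "INNER JOIN ligand l ON d.ligand_id = l.id "
                  "INNER JOIN aminoacid a ON d.amino_id = a.id "
                  "WHERE l.symbol = ? GROUP BY a.symbol "
                  "ORDER BY n DESC, a.symbol LIMIT ?")
    out = []
    for code, _ in conn.execute(lig_sql, (n_ligands,)).fetchall():
        aminos = tuple(sym for sym, _ in
                       conn.execute(am_sql, (code, n_aminos)).fetchall())
        out.append((code, aminos))
    return out


# ---------------------------------------------------------------------------
# PDB writing

def write_pdb(model: StructureModel) -> str:
    """Fixed-column PDB text; ``parse_pdb(write_pdb(m))`` equals ``m`` for
    models whose coordinates are rounded to 3 decimals."""
    lines = [f"HEADER    {'SYNTHETIC STRUCTURE':<40}{'01-JAN-00':<9}   "
             f"{model.pdb_id:<4}".rstrip()]
    for chain in model.chains:
        for r in chain.residues:
            for a in r.atoms:
                lines.append(_atom_line("ATOM", a, r.symbol, chain.chain_id,
                                        r.author_number))
        if chain.residues:
            lines.append("TER")
        for h in chain.hetgroups:
            for a in h.atoms:
                lines.append(_atom_line("HETATM", a, h.code, chain.chain_id,
                                        h.author_number))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _atom_line(tag: str, a: Atom, res: str, chain_id: str, resseq: int) -> str:
    for v in (a.x, a.y, a.z):
        if not -999.999 <= v <= 9999.999:
            raise SynthError(f"coordinate {v} overflows the PDB column width")
    element = a.atom_name.rstrip("0123456789")
    name = a.atom_name if len(element) == 2 else f" {a.atom_name}"
    return (f"{tag:<6}{a.serial:>5} {name:<4}{'':1}{res:>3} {chain_id:1}"
            f"{resseq:>4}{'':1}   {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2}")


# ---------------------------------------------------------------------------
# random patterns for the equivalence suite

_SYMBOL_POOL = ("CYS", "HIS", "LEU", "ARG", "GLU", "GLY", "SER", "LYS")
_POLARITY_POOL = ("non-polar", "polar uncharged", "positively charged",
                  "negatively charged")


def random_pattern(rng: np.random.Generator, max_nodes: int = 6,
                   pattern_id: str = "random") -> PatternGraph:
    """A random valid, connected structural pattern for property testing.

    Symbols come from a small pool so that matches against generated
    structures are common enough to exercise the non-empty paths.
    """
    n_amino = int(rng.integers(1, max_nodes))
    with_ligand = bool(rng.random() < 0.6) and n_amino < max_nodes
    nodes: list[NodeSpec] = []
    for i in range(n_amino):
        if rng.random() < 0.6:
            nodes.append(amino(f"A{i}", str(rng.choice(_SYMBOL_POOL))))
        elif rng.random() < 0.5:
            nodes.append(any_amino(f"A{i}"))
        else:
            nodes.append(any_amino(f"A{i}", str(rng.choice(_POLARITY_POOL))))
    edges: list[EdgeSpec] = []
    for i in range(1, n_amino):
        j = int(rng.integers(0, i))
        edges.append(_random_amino_edge(rng, f"A{j}", f"A{i}"))
    if n_amino >= 2 and rng.random() < 0.3:
        i, j = rng.choice(n_amino, size=2, replace=False)
        edges.append(_random_amino_edge(rng, f"A{int(i)}", f"A{int(j)}"))
    if with_ligand:
        lid = "L0"
        nodes.append(ligand(lid, str(rng.choice(("ZN", "GOL", "SO4", "EDO"))))
                     if rng.random() < 0.6 else any_ligand(lid))
        k = int(rng.integers(1, min(n_amino, 2) + 1))
        for i in rng.choice(n_amino, size=k, replace=False):
            edges.append(distance(lid, f"A{int(i)}", *_distance_bounds(rng)))
    return PatternGraph(pattern_id, nodes, edges)


def _distance_bounds(rng) -> tuple[float, float]:
    lo = float(rng.choice((0.5, 1.0, 2.0)))
    hi = float(rng.choice((4.0, 5.5, 7.0)))
    return lo, hi


def _random_amino_edge(rng, s: str, t: str) -> EdgeSpec:
    kind = str(rng.choice(("Distance", "Next", "Gap"), p=(0.5, 0.25, 0.25)))
    if kind == "Distance":
        return distance(s, t, *_distance_bounds(rng))
    if kind == "Next":
        return next_edge(s, t)
    lo = int(rng.integers(1, 4))
    if rng.random() < 0.3:
        return gap(s, t, min=lo)
    return gap(s, t, min=lo, max=lo + int(rng.integers(0, 4)))


def form_battery() -> list[PatternGraph]:
    """One minimal single-edge pattern per each of the 16 subpattern forms."""
    out = []
    for form in ALL_FORMS:
        lk, ek, rk = form.split("-")
        nodes = [_node_of_kind("X", lk), _node_of_kind("Y", rk)]
        if ek == "Distance":
            e = distance("X", "Y")
        elif ek == "Next":
            e = next_edge("X", "Y")
        else:
            e = gap("X", "Y", min=1, max=3)
        out.append(PatternGraph(f"form-{form}", nodes, [e]))
    return out


def _node_of_kind(nid: str, kind: str) -> NodeSpec:
    if kind == "Amino":
        return amino(nid, "CYS")
    if kind == "AnyAmino":
        return any_amino(nid)
    if kind == "Ligand":
        return ligand(nid, "ZN")
    return any_ligand(nid)
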