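"""Graph-based structural patterns (GSPs).

A structural pattern is a small property graph describing the arrangement of
a protein--ligand binding site: nodes stand for residues (``Amino`` for a
specific residue, ``AnyAmino`` for a wildcard with an optional polarity
filter) or for the bound small molecule (``Ligand`` with a fixed het code,
``AnyLigand`` as a wildcard); edges constrain their arrangement:

``Distance``
    undirected; the minimum inter-atomic distance between the two elements
    lies in ``[min, max]`` angstroms (defaults 0.5 and 7.0);
``Next``
    directed; the target residue immediately follows the source in the chain;
``Gap``
    directed; the number of residues strictly between source and target lies
    in ``[min, max]``, where ``max`` may be unbounded (``*``).

This module defines the pattern data model, validation, JSON (de)serialization
and the decomposition of a pattern into its node-edge-node subpatterns, which
is the unit the SQL translator works on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Union

from .amino import KNOWN_CODES, POLARITY_VALUES

NODE_KINDS = ("Amino", "AnyAmino", "Ligand", "AnyLigand")
EDGE_KINDS = ("Distance", "Next", "Gap")

AMINO_KINDS = ("Amino", "AnyAmino")
LIGAND_KINDS = ("Ligand", "AnyLigand")

DEFAULT_DISTANCE_MIN = 0.5
DEFAULT_DISTANCE_MAX = 7.0


class _Unbounded:
    """Marker for an unbounded Gap ``max`` (written ``*``; JSON ``null``)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "*"

    def __eq__(self, other) -> bool:
        return isinstance(other, _Unbounded)

    def __hash__(self) -> int:
        return hash(_Unbounded)


UNBOUNDED = _Unbounded()

Bound = Union[int, float, _Unbounded]


class PatternError(ValueError):
    """Base class for pattern reading/validation failures."""


class PatternFormatError(PatternError):
    """The pattern document is not well-formed (JSON, structure, keys)."""


class PatternSchemaError(PatternError):
    """The document is well-formed but uses an unknown kind or field value."""


class PatternValidationError(PatternError):
    """An operation requiring a valid pattern received an invalid one."""


@dataclass
class NodeSpec:
    """One pattern node.

    Exactly the kind-appropriate property is set: ``name`` for Amino,
    ``code`` for Ligand, ``polarity`` for AnyAmino; AnyLigand carries none.
    """

    node_id: str
    kind: str
    name: str | None = None
    code: str | None = None
    polarity: str | None = None

    @property
    def is_amino(self) -> bool:
        return self.kind in AMINO_KINDS

    @property
    def is_ligand(self) -> bool:
        return self.kind in LIGAND_KINDS


@dataclass
class EdgeSpec:
    """One pattern edge; ``min``/``max`` are absent (None) for Next edges."""

    kind: str
    source: str
    target: str
    min: float | int | None = None
    max: Bound | None = None


@dataclass
class PatternGraph:
    pattern_id: str
    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[EdgeSpec] = field(default_factory=list)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


@dataclass
class SubPattern:
    """A node-edge-node unit of a pattern, tagged with one of the 16 forms.

    For Distance edges touching the ligand, ``left`` is normalized to the
    ligand-kind node (the edge is undirected); otherwise left/right follow
    the edge's source/target order.
    """

    edge: EdgeSpec
    left: NodeSpec
    right: NodeSpec
    form: str


def _forms() -> tuple[str, ...]:
    out = []
    for lk in LIGAND_KINDS:
        for ak in AMINO_KINDS:
            out.append(f"{lk}-Distance-{ak}")
    for kind in ("Distance", "Next", "Gap"):
        for a in AMINO_KINDS:
            for b in AMINO_KINDS:
                out.append(f"{a}-{kind}-{b}")
    return tuple(out)


#: The 16 legal node-edge-node shapes.
ALL_FORMS = _forms()


@dataclass(frozen=True)
class Violation:
    element: str  # node id, or "edge[i]" for the i-th edge
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def _is_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def validate_pattern(p: PatternGraph) -> ValidationReport:
    """Check every structural invariant of a pattern.

    Violations are returned as data (never raised): each names the offending
    node id or edge position.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for n in p.nodes:
        el = n.node_id if isinstance(n.node_id, str) and n.node_id else "<node>"
        if (not isinstance(n.node_id, str)
                or not re.fullmatch(r"[A-Za-z][A-Za-z0-9_]*", n.node_id or "")):
            out.append(Violation(el, "node id must be a letter followed by "
                                     "letters, digits or underscores"))
        elif n.node_id in seen:
            out.append(Violation(el, "duplicate node id"))
        seen.add(n.node_id if isinstance(n.node_id, str) else el)
        if n.kind not in NODE_KINDS:
            out.append(Violation(el, f"unknown node kind {n.kind!r}"))
            continue
        if n.kind == "Amino":
            if n.name is None:
                out.append(Violation(el, "Amino node requires a name"))
            elif n.name not in KNOWN_CODES:
                out.append(Violation(el, f"unknown amino-acid code {n.name!r}"))
        elif n.name is not None:
            out.append(Violation(el, f"{n.kind} node must not set name"))
        if n.kind == "Ligand":
            if not n.code:
                out.append(Violation(el, "Ligand node requires a code"))
            elif not (n.code.isalnum() and n.code == n.code.upper()
                      and len(n.code) <= 3):
                out.append(Violation(el, f"ligand code {n.code!r} must be "
                                         "upper-case alphanumeric, <=3 chars"))
        elif n.code is not None:
            out.append(Violation(el, f"{n.kind} node must not set code"))
        if n.kind == "AnyAmino":
            if n.polarity not in POLARITY_VALUES:
                out.append(Violation(el, f"unknown polarity {n.polarity!r}"))
        elif n.polarity is not None:
            out.append(Violation(el, f"{n.kind} node must not set polarity"))

    n_ligand = sum(1 for n in p.nodes if n.kind in LIGAND_KINDS)
    if n_ligand > 1:
        out.append(Violation(p.pattern_id or "<pattern>",
                             f"at most one ligand-kind node allowed, got {n_ligand}"))

    by_id = {n.node_id: n for n in p.nodes}
    for i, e in enumerate(p.edges):
        el = f"edge[{i}]"
        if e.kind not in EDGE_KINDS:
            out.append(Violation(el, f"unknown edge kind {e.kind!r}"))
            continue
        endpoints = []
        for role, nid in (("source", e.source), ("target", e.target)):
            node = by_id.get(nid)
            if node is None:
                out.append(Violation(el, f"{role} {nid!r} names no node"))
            else:
                endpoints.append(node)
        if len(endpoints) < 2:
            continue
        a, b = endpoints
        if a.node_id == b.node_id:
            out.append(Violation(el, "edge endpoints must be distinct nodes"))
        if e.kind == "Distance":
            if a.is_ligand and b.is_ligand:
                out.append(Violation(el, "Distance cannot join two ligand nodes"))
            if not _is_number(e.min) or e.min < 0:
                out.append(Violation(el, f"Distance min must be a number >= 0, got {e.min!r}"))
            if not _is_number(e.max):
                out.append(Violation(el, f"Distance max must be a number, got {e.max!r}"))
            elif _is_number(e.min) and e.max < e.min:
                out.append(Violation(el, f"Distance max {e.max} < min {e.min}"))
        else:
            if not (a.is_amino and b.is_amino):
                out.append(Violation(el, f"{e.kind} edges connect amino-kind nodes only"))
            if e.kind == "Next":
                if e.min is not None or e.max is not None:
                    out.append(Violation(el, "Next edges carry no min/max"))
            else:  # Gap
                if not _is_number(e.min) or int(e.min) != e.min or e.min < 1:
                    out.append(Violation(el, f"Gap min must be an integer >= 1, got {e.min!r}"))
                if e.max is UNBOUNDED or isinstance(e.max, _Unbounded):
                    pass
                elif not _is_number(e.max) or int(e.max) != e.max:
                    out.append(Violation(el, f"Gap max must be an integer or '*', got {e.max!r}"))
                elif _is_number(e.min) and e.max < e.min:
                    out.append(Violation(el, f"Gap max {e.max} < min {e.min}"))
    return ValidationReport(out)


def require_valid(p: PatternGraph) -> None:
    """Raise :class:`PatternValidationError` if ``p`` does not validate."""
    rep = validate_pattern(p)
    if not rep.ok:
        msgs = "; ".join(f"{v.element}: {v.message}" for v in rep.violations)
        raise PatternValidationError(f"invalid pattern {p.pattern_id!r}: {msgs}")


def decompose(p: PatternGraph) -> list[SubPattern]:
    """Split a valid pattern into one :class:`SubPattern` per edge.

    Input edge order is preserved; for ligand-touching Distance edges the
    ligand node is normalized to the left slot (Distance is undirected).
    """
    require_valid(p)
    out = []
    for e in p.edges:
        left, right = p.node(e.source), p.node(e.target)
        if e.kind == "Distance" and right.is_ligand:
            left, right = right, left
        form = f"{left.kind}-{e.kind}-{right.kind}"
        assert form in ALL_FORMS, form
        out.append(SubPattern(edge=e, left=left, right=right, form=form))
    return out


def count_elements(p: PatternGraph) -> int:
    """Pattern size: number of nodes plus number of edges."""
    return len(p.nodes) + len(p.edges)


# ---------------------------------------------------------------------------
# convenience constructors

def amino(node_id: str, name: str) -> NodeSpec:
    return NodeSpec(node_id, "Amino", name=name)


def any_amino(node_id: str, polarity: str = "any") -> NodeSpec:
    return NodeSpec(node_id, "AnyAmino", polarity=polarity)


def ligand(node_id: str, code: str) -> NodeSpec:
    return NodeSpec(node_id, "Ligand", code=code)


def any_ligand(node_id: str) -> NodeSpec:
    return NodeSpec(node_id, "AnyLigand")


def distance(source: str, target: str,
             min: float = DEFAULT_DISTANCE_MIN,
             max: float = DEFAULT_DISTANCE_MAX) -> EdgeSpec:
    return EdgeSpec("Distance", source, target, min=min, max=max)


def next_edge(source: str, target: str) -> EdgeSpec:
    return EdgeSpec("Next", source, target)


def gap(source: str, target: str, min: int = 1,
        max: Bound = UNBOUNDED) -> EdgeSpec:
    return EdgeSpec("Gap", source, target, min=min, max=max)


# ---------------------------------------------------------------------------
# JSON dialect

_NODE_KEYS = {"id", "kind", "name", "code", "polarity"}
_EDGE_KEYS = {"kind", "source", "target", "min", "max"}


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise PatternFormatError(f"{where}: unknown keys {sorted(extra)}")


def _read_node(d, i: int) -> NodeSpec:
    where = f"nodes[{i}]"
    if not isinstance(d, dict):
        raise PatternFormatError(f"{where}: expected an object")
    _reject_unknown(d, _NODE_KEYS, where)
    try:
        node_id, kind = d["id"], d["kind"]
    except KeyError as k:
        raise PatternFormatError(f"{where}: missing key {k}") from None
    if kind not in NODE_KINDS:
        raise PatternSchemaError(f"{where}: unknown node kind {kind!r}")
    node = NodeSpec(node_id, kind, name=d.get("name"), code=d.get("code"),
                    polarity=d.get("polarity"))
    if kind == "AnyAmino" and node.polarity is None:
        node.polarity = "any"
    return node


def _read_edge(d, i: int) -> EdgeSpec:
    where = f"edges[{i}]"
    if not isinstance(d, dict):
        raise PatternFormatError(f"{where}: expected an object")
    _reject_unknown(d, _EDGE_KEYS, where)
    try:
        kind, source, target = d["kind"], d["source"], d["target"]
    except KeyError as k:
        raise PatternFormatError(f"{where}: missing key {k}") from None
    if kind not in EDGE_KINDS:
        raise PatternSchemaError(f"{where}: unknown edge kind {kind!r}")
    mn, mx = d.get("min"), d.get("max")
    if kind == "Distance":
        mn = DEFAULT_DISTANCE_MIN if mn is None else mn
        mx = DEFAULT_DISTANCE_MAX if mx is None else mx
    elif kind == "Gap":
        mn = 1 if mn is None else mn
        mx = UNBOUNDED if mx is None else mx
    else:  # Next: min/max must be absent
        if "min" in d or "max" in d:
            raise PatternFormatError(f"{where}: Next edges carry no min/max")
    return EdgeSpec(kind, source, target, min=mn, max=mx)


def read_pattern(text: str) -> PatternGraph:
    """Parse the JSON pattern dialect into a :class:`PatternGraph`.

    Distance min/max default to 0.5/7.0 A, Gap min to 1, Gap max to
    unbounded, AnyAmino polarity to ``"any"``; unknown keys are rejected.
    The result is not semantically validated -- run
    :func:`validate_pattern` for that.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise PatternFormatError(f"malformed JSON at line {e.lineno}: {e.msg}") from None
    if not isinstance(doc, dict):
        raise PatternFormatError("top level must be an object")
    _reject_unknown(doc, {"pattern_id", "nodes", "edges"}, "pattern")
    pid = doc.get("pattern_id")
    if not isinstance(pid, str):
        raise PatternFormatError("pattern_id: required string")
    nodes_raw, edges_raw = doc.get("nodes", []), doc.get("edges", [])
    if not isinstance(nodes_raw, list) or not isinstance(edges_raw, list):
        raise PatternFormatError("nodes/edges must be arrays")
    nodes = [_read_node(d, i) for i, d in enumerate(nodes_raw)]
    edges = [_read_edge(d, i) for i, d in enumerate(edges_raw)]
    return PatternGraph(pid, nodes, edges)


def write_pattern(p: PatternGraph) -> str:
    """Serialize a pattern to the JSON dialect (Gap ``max=*`` becomes null)."""
    nodes = []
    for n in p.nodes:
        d: dict = {"id": n.node_id, "kind": n.kind}
        if n.name is not None:
            d["name"] = n.name
        if n.code is not None:
            d["code"] = n.code
        if n.polarity is not None:
            d["polarity"] = n.polarity
        nodes.append(d)
    edges = []
    for e in p.edges:
        d = {"kind": e.kind, "source": e.source, "target": e.target}
        if e.kind != "Next":
            d["min"] = e.min
            d["max"] = None if isinstance(e.max, _Unbounded) else e.max
        edges.append(d)
    return json.dumps({"pattern_id": p.pattern_id, "nodes": nodes,
                       "edges": edges}, indent=2)


def zinc_finger_pattern() -> PatternGraph:
    """The canonical zinc-finger example: a ZN ligand coordinated by a CYS
    and a HIS plus a wildcard residue, with Next/Gap sequence constraints."""
    return PatternGraph(
        "zinc-finger",
        nodes=[ligand("ZN", "ZN"), amino("CYS1", "CYS"),
               amino("HIS2", "HIS"), any_amino("ANY3")],
        edges=[distance("ZN", "CYS1"), distance("ZN", "HIS2"),
               distance("ZN", "ANY3"), next_edge("CYS1", "HIS2"),
               gap("HIS2", "ANY3", min=1, max=UNBOUNDED),
               distance("CYS1", "ANY3")],
    )
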