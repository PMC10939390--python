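"""Compiling structural patterns into SQL and executing them.

Every node-edge-node subpattern maps to one SQL subquery built from a
per-form template; the full pattern is the INNER JOIN of all subqueries
over a ``protein`` anchor, with explicit ON conditions equating protein
ids everywhere and element ids wherever two subqueries touch the same
pattern node.  Additional predicates enforce injectivity between distinct
amino-kind nodes (so a C-x(2,4)-C style pattern cannot bind one cysteine
twice); ``allow_repeats=True`` disables that for comparison.

On the denormalized layout each Distance/Next subquery is a single-table
filter; on the normalized layout the same templates join back through
aminoacid/ligand/chain for symbols and provenance.  Gap subqueries are a
self-join of ``aminoacid`` on the same protein with a bound on the
number-difference (upper clause omitted for an unbounded gap).

Undirected Distance semantics come from the symmetric storage of
``distance_amino_amino`` (both orientations present), not from OR
predicates, so every generated subquery stays a conjunctive,
index-friendly filter.

Results are deduplicated bindings (``SELECT DISTINCT`` over the projected
ids) in a deterministic order (protein id, then bound element ids).
"""

from __future__ import annotations

import sqlite3
import time
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .patterns import (PatternGraph, SubPattern, _Unbounded, decompose,
                       require_valid)
from .store import detect_layout


class TranslateError(ValueError):
    pass


class QueryTimeout(RuntimeError):
    """The statement exceeded its time budget (distinct from an empty result)."""


@dataclass(frozen=True)
class Hit:
    """One match: a protein plus a binding of every pattern node to an
    element provenance id.  Equality and hashing consider the binding only;
    ``details`` carries each bound element's symbol and sequence number."""

    protein_id: str
    binding: tuple[tuple[str, str], ...]  # (node_id, element_id), sorted
    details: Mapping[str, tuple[str, int]] = field(compare=False, hash=False,
                                                   default_factory=dict)

    @property
    def binding_dict(self) -> dict[str, str]:
        return dict(self.binding)


def make_hit(protein_id: str, binding: Mapping[str, str],
             details: Mapping[str, tuple[str, int]] | None = None) -> Hit:
    return Hit(protein_id, tuple(sorted(binding.items())), dict(details or {}))


@dataclass
class CompiledQuery:
    sql: str
    aliases: list[str]  # SQ1..SQn, decompose order unless reordered
    projection: dict[str, tuple[str, str, str]]  # node_id -> column names
    node_order: list[str]
    warnings: list[str] = field(default_factory=list)


def _num(x) -> str:
    return repr(int(x)) if isinstance(x, int) else repr(float(x))


def _amino_preds(node, sym_col: str, class_col: str) -> list[str]:
    if node.kind == "Amino":
        return [f"{sym_col} = '{node.name}'"]
    if node.kind == "AnyAmino" and node.polarity not in (None, "any"):
        return [f"{class_col} = '{node.polarity}'"]
    return []


def _ligand_preds(node, sym_col: str) -> list[str]:
    if node.kind == "Ligand":
        return [f"{sym_col} = '{node.code}'"]
    return []


def _select(cols: list[str], table: str, preds: list[str]) -> str:
    sql = f"SELECT {', '.join(cols)}\nFROM {table}"
    if preds:
        sql += "\nWHERE " + "\n  AND ".join(preds)
    return sql


def subquery_sql(sp: SubPattern, layout: str = "denormalized") -> str:
    """SQL for one node-edge-node subpattern.

    The subquery projects ``protein_id`` plus ``<node>_id``,
    ``<node>_symbol`` and ``<node>_number`` for each touched node.
    """
    if layout == "denormalized":
        return _subquery_denormalized(sp)
    if layout == "normalized":
        return _subquery_normalized(sp)
    raise TranslateError(f"unknown layout {layout!r}")


def _subquery_denormalized(sp: SubPattern) -> str:
    e, left, right = sp.edge, sp.left, sp.right
    ln, rn = left.node_id, right.node_id
    if e.kind == "Distance" and left.is_ligand:
        cols = ["protein_id",
                f"ligand_id AS {ln}_id", f"ligand_symbol AS {ln}_symbol",
                f"ligand_number AS {ln}_number",
                f"amino_id AS {rn}_id", f"amino_symbol AS {rn}_symbol",
                f"amino_number AS {rn}_number"]
        preds = [f"dist BETWEEN {_num(e.min)} AND {_num(e.max)}"]
        preds += _ligand_preds(left, "ligand_symbol")
        preds += _amino_preds(right, "amino_symbol", "amino_class")
        return _select(cols, "distance_ligand_amino", preds)
    if e.kind in ("Distance", "Next"):
        table = "distance_amino_amino" if e.kind == "Distance" else "next_amino_amino"
        cols = ["protein_id",
                f"amino1_id AS {ln}_id", f"amino1_symbol AS {ln}_symbol",
                f"amino1_number AS {ln}_number",
                f"amino2_id AS {rn}_id", f"amino2_symbol AS {rn}_symbol",
                f"amino2_number AS {rn}_number"]
        preds = []
        if e.kind == "Distance":
            preds.append(f"dist BETWEEN {_num(e.min)} AND {_num(e.max)}")
        preds += _amino_preds(left, "amino1_symbol", "amino1_class")
        preds += _amino_preds(right, "amino2_symbol", "amino2_class")
        return _select(cols, table, preds)
    if e.kind == "Gap":
        cols = ["a1.protein_id AS protein_id",
                f"a1.id AS {ln}_id", f"a1.symbol AS {ln}_symbol",
                f"a1.number AS {ln}_number",
                f"a2.id AS {rn}_id", f"a2.symbol AS {rn}_symbol",
                f"a2.number AS {rn}_number"]
        preds = [_gap_pred(e)]
        preds += _amino_preds(left, "a1.symbol", "a1.class")
        preds += _amino_preds(right, "a2.symbol", "a2.class")
        table = ("aminoacid AS a1 INNER JOIN aminoacid AS a2 "
                 "ON a2.protein_id = a1.protein_id")
        return _select(cols, table, preds)
    raise TranslateError(f"unsupported form {sp.form!r}")


def _gap_pred(e) -> str:
    expr = "a2.number - a1.number - 1"
    if isinstance(e.max, _Unbounded):
        return f"{expr} >= {_num(e.min)}"
    return f"({expr}) BETWEEN {_num(e.min)} AND {_num(e.max)}"


def _subquery_normalized(sp: SubPattern) -> str:
    e, left, right = sp.edge, sp.left, sp.right
    ln, rn = left.node_id, right.node_id
    if e.kind == "Distance" and left.is_ligand:
        cols = ["c.protein_id AS protein_id",
                f"l.id AS {ln}_id", f"l.symbol AS {ln}_symbol",
                f"l.number AS {ln}_number",
                f"a.id AS {rn}_id", f"a.symbol AS {rn}_symbol",
                f"a.number AS {rn}_number"]
        table = ("distance_ligand_amino AS d "
                 "INNER JOIN ligand AS l ON d.ligand_id = l.id "
                 "INNER JOIN aminoacid AS a ON d.amino_id = a.id "
                 "INNER JOIN chain AS c ON a.chain_id = c.id")
        preds = [f"d.dist BETWEEN {_num(e.min)} AND {_num(e.max)}"]
        preds += _ligand_preds(left, "l.symbol")
        preds += _amino_preds(right, "a.symbol", "a.class")
        return _select(cols, table, preds)
    if e.kind in ("Distance", "Next"):
        rel = "distance_amino_amino" if e.kind == "Distance" else "next_amino_amino"
        cols = ["c.protein_id AS protein_id",
                f"a1.id AS {ln}_id", f"a1.symbol AS {ln}_symbol",
                f"a1.number AS {ln}_number",
                f"a2.id AS {rn}_id", f"a2.symbol AS {rn}_symbol",
                f"a2.number AS {rn}_number"]
        table = (f"{rel} AS d "
                 "INNER JOIN aminoacid AS a1 ON d.amino1_id = a1.id "
                 "INNER JOIN aminoacid AS a2 ON d.amino2_id = a2.id "
                 "INNER JOIN chain AS c ON a1.chain_id = c.id")
        preds = []
        if e.kind == "Distance":
            preds.append(f"d.dist BETWEEN {_num(e.min)} AND {_num(e.max)}")
        preds += _amino_preds(left, "a1.symbol", "a1.class")
        preds += _amino_preds(right, "a2.symbol", "a2.class")
        return _select(cols, table, preds)
    if e.kind == "Gap":
        cols = ["c.protein_id AS protein_id",
                f"a1.id AS {ln}_id", f"a1.symbol AS {ln}_symbol",
                f"a1.number AS {ln}_number",
                f"a2.id AS {rn}_id", f"a2.symbol AS {rn}_symbol",
                f"a2.number AS {rn}_number"]
        table = ("aminoacid AS a1 "
                 "INNER JOIN aminoacid AS a2 ON a2.chain_id = a1.chain_id "
                 "INNER JOIN chain AS c ON a1.chain_id = c.id")
        preds = [_gap_pred(e)]
        preds += _amino_preds(left, "a1.symbol", "a1.class")
        preds += _amino_preds(right, "a2.symbol", "a2.class")
        return _select(cols, table, preds)
    raise TranslateError(f"unsupported form {sp.form!r}")


def _node_anchor_sql(node, layout: str) -> str:
    """Anchor subquery for an edge-free node (not produced by decompose)."""
    n = node.node_id
    if node.is_amino:
        if layout == "denormalized":
            cols = ["protein_id", f"id AS {n}_id", f"symbol AS {n}_symbol",
                    f"number AS {n}_number"]
            preds = _amino_preds(node, "symbol", "class")
            return _select(cols, "aminoacid", preds)
        cols = ["c.protein_id AS protein_id", f"a.id AS {n}_id",
                f"a.symbol AS {n}_symbol", f"a.number AS {n}_number"]
        table = "aminoacid AS a INNER JOIN chain AS c ON a.chain_id = c.id"
        return _select(cols, table, _amino_preds(node, "a.symbol", "a.class"))
    if layout == "denormalized":
        cols = ["protein_id", f"id AS {n}_id", f"symbol AS {n}_symbol",
                f"number AS {n}_number"]
        return _select(cols, "ligand", _ligand_preds(node, "symbol"))
    cols = ["c.protein_id AS protein_id", f"l.id AS {n}_id",
            f"l.symbol AS {n}_symbol", f"l.number AS {n}_number"]
    table = "ligand AS l INNER JOIN chain AS c ON l.chain_id = c.id"
    return _select(cols, table, _ligand_preds(node, "l.symbol"))


def _connected_components(p: PatternGraph) -> int:
    parent = {n.node_id: n.node_id for n in p.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in p.edges:
        a, b = find(e.source), find(e.target)
        if a != b:
            parent[a] = b
    return len({find(n.node_id) for n in p.nodes})


def _indent(sql: str) -> str:
    return "\n".join("  " + line for line in sql.splitlines())


def compose_sql(p: PatternGraph, order: Sequence[int] | None = None,
                layout: str = "denormalized", allow_repeats: bool = False,
                limit: int | None = None) -> CompiledQuery:
    """Compose the full pattern query.

    ``order`` permutes the subqueries (default: pattern edge order; the
    result set is invariant, the runtime need not be).  Edge-free nodes get
    anchor subqueries appended after the edge subqueries.
    """
    require_valid(p)
    subs = decompose(p)
    if order is not None:
        if sorted(order) != list(range(len(subs))):
            raise TranslateError(
                f"order must be a permutation of 0..{len(subs) - 1}, got {order!r}")
        subs = [subs[i] for i in order]

    warns: list[str] = []
    if p.nodes and _connected_components(p) > 1:
        warns.append("pattern is disconnected: components are combined with "
                     "cross-join semantics within each protein")
        warnings.warn(warns[-1], stacklevel=2)

    # subquery texts plus the nodes each one touches
    pieces: list[tuple[str, list]] = [
        (subquery_sql(sp, layout), [sp.left, sp.right]) for sp in subs]
    touched = {n.node_id for sp in subs for n in (sp.left, sp.right)}
    for node in p.nodes:
        if node.node_id not in touched:
            pieces.append((_node_anchor_sql(node, layout), [node]))

    aliases = [f"SQ{i + 1}" for i in range(len(pieces))]
    first_alias: dict[str, str] = {}
    joins = ["FROM (SELECT id AS protein_id FROM protein) AS SQ"]
    for alias, (sql, nodes) in zip(aliases, pieces):
        conds = [f"{alias}.protein_id = SQ.protein_id"]
        for node in nodes:
            nid = node.node_id
            if nid in first_alias:
                conds.append(f"{alias}.{nid}_id = {first_alias[nid]}.{nid}_id")
            else:
                first_alias[nid] = alias
        joins.append(f"INNER JOIN (\n{_indent(sql)}\n) AS {alias} ON "
                     + " AND ".join(conds))

    node_order = [n.node_id for n in p.nodes]
    select_cols = ["SQ.protein_id AS protein_id"]
    projection: dict[str, tuple[str, str, str]] = {}
    for nid in node_order:
        src = first_alias[nid]
        projection[nid] = (f"{nid}_id", f"{nid}_symbol", f"{nid}_number")
        select_cols += [f"{src}.{nid}_id AS {nid}_id",
                        f"{src}.{nid}_symbol AS {nid}_symbol",
                        f"{src}.{nid}_number AS {nid}_number"]

    where: list[str] = []
    if not allow_repeats:
        amino_ids = [n.node_id for n in p.nodes if n.is_amino]
        for i in range(len(amino_ids)):
            for j in range(i + 1, len(amino_ids)):
                a, b = amino_ids[i], amino_ids[j]
                where.append(f"{first_alias[a]}.{a}_id <> {first_alias[b]}.{b}_id")

    sql = "SELECT DISTINCT " + ",\n  ".join(select_cols) + "\n" + "\n".join(joins)
    if where:
        sql += "\nWHERE " + "\n  AND ".join(where)
    sql += "\nORDER BY protein_id" + "".join(f", {nid}_id" for nid in node_order)
    if limit is not None:
        sql += f"\nLIMIT {int(limit)}"
    return CompiledQuery(sql=sql, aliases=aliases, projection=projection,
                         node_order=node_order, warnings=warns)


def execute_pattern(conn: sqlite3.Connection, p: PatternGraph,
                    limit: int | None = None, timeout: float | None = None,
                    order: Sequence[int] | None = None,
                    allow_repeats: bool = False) -> list[Hit]:
    """Run a pattern against a loaded database and return its hits in a
    deterministic order (protein id, then binding ids).

    Raises :class:`QueryTimeout` when ``timeout`` (seconds) is exceeded.
    """
    layout = detect_layout(conn)
    cq = compose_sql(p, order=order, layout=layout,
                     allow_repeats=allow_repeats, limit=limit)
    if timeout is not None:
        deadline = time.monotonic() + timeout
        conn.set_progress_handler(lambda: time.monotonic() > deadline, 1000)
    try:
        rows = conn.execute(cq.sql).fetchall()
    except sqlite3.OperationalError as e:
        if timeout is not None and "interrupt" in str(e).lower():
            raise QueryTimeout(f"pattern {p.pattern_id!r} exceeded "
                               f"{timeout} s") from None
        raise
    finally:
        if timeout is not None:
            conn.set_progress_handler(None, 0)

    hits = []
    for row in rows:
        protein_id = row[0]
        binding: dict[str, str] = {}
        details: dict[str, tuple[str, int]] = {}
        for k, nid in enumerate(cq.node_order):
            eid, sym, num = row[1 + 3 * k: 4 + 3 * k]
            binding[nid] = eid
            details[nid] = (sym, num)
        hits.append(make_hit(protein_id, binding, details))
    return hits
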