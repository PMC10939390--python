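"""Relational storage for protein contact data.

Two schema layouts are supported, mirroring the two designs a pattern
engine can run on:

``normalized``
    ten narrow tables (protein, chain, standard_amino, aminoacid, ligand,
    atom_amino, atom_ligand, distance_amino_amino, distance_ligand_amino,
    next_amino_amino) with primary/foreign keys; pattern subqueries must
    join back to aminoacid/ligand/chain for symbols and provenance.

``denormalized``
    the three relation tables widened with redundant protein ids, residue
    symbols, polarity classes and sequence numbers, so every node-edge-node
    subquery is a single-table filter.  The slim ``aminoacid`` and
    ``ligand`` tables are retained: Gap subqueries and edge-free pattern
    nodes need element anchors that the wide contact tables cannot provide
    (a contact-free ligand has no row in distance_ligand_amino).

Either layout can be built with B-tree indexes on the attributes the
pattern subqueries filter and join on: 12 indexes across the three wide
tables for the denormalized layout, and the basic set (aminoacid.symbol,
ligand.symbol and the six relation-table id columns) for the normalized
one.

Loading is transactional and idempotent per protein: residue--residue
contact records are expanded symmetrically (both orientations stored) so
that undirected Distance constraints compile to plain conjunctive filters.

The backend is an embedded SQL engine (sqlite3), one file per database
(or in-memory); all generated SQL sticks to the common dialect.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import astuple, dataclass, field
from typing import IO, Iterable

from .amino import STANDARD_AMINO_ACIDS, polarity_of
from .contacts import ChainRelations, make_ids

LAYOUTS = ("normalized", "denormalized")


@dataclass(frozen=True)
class SchemaVariant:
    layout: str = "denormalized"
    indexed: bool = True

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")


class StoreError(RuntimeError):
    pass


_WIDE_AMINO_PAIR = (
    "protein_id TEXT NOT NULL, "
    "amino1_id TEXT NOT NULL, amino1_symbol TEXT NOT NULL, "
    "amino1_class TEXT NOT NULL, amino1_number INTEGER NOT NULL, "
    "amino2_id TEXT NOT NULL, amino2_symbol TEXT NOT NULL, "
    "amino2_class TEXT NOT NULL, amino2_number INTEGER NOT NULL"
)

_TABLES_NORMALIZED = {
    "protein": "id TEXT PRIMARY KEY, name TEXT",
    "chain": ("id TEXT PRIMARY KEY, "
              "protein_id TEXT NOT NULL REFERENCES protein(id), "
              "name TEXT NOT NULL"),
    "standard_amino": ("symbol TEXT PRIMARY KEY, abbreviation TEXT NOT NULL UNIQUE, "
                       "name TEXT NOT NULL, class TEXT NOT NULL"),
    "aminoacid": ("id TEXT PRIMARY KEY, "
                  "chain_id TEXT NOT NULL REFERENCES chain(id), "
                  "symbol TEXT NOT NULL REFERENCES standard_amino(abbreviation), "
                  "class TEXT NOT NULL, number INTEGER NOT NULL"),
    "ligand": ("id TEXT PRIMARY KEY, "
               "chain_id TEXT NOT NULL REFERENCES chain(id), "
               "symbol TEXT NOT NULL, number INTEGER NOT NULL"),
    "atom_amino": ("id TEXT PRIMARY KEY, "
                   "amino_id TEXT NOT NULL REFERENCES aminoacid(id), "
                   "number INTEGER NOT NULL, name TEXT NOT NULL, "
                   "x REAL NOT NULL, y REAL NOT NULL, z REAL NOT NULL"),
    "atom_ligand": ("id TEXT PRIMARY KEY, "
                    "ligand_id TEXT NOT NULL REFERENCES ligand(id), "
                    "number INTEGER NOT NULL, name TEXT NOT NULL, "
                    "x REAL NOT NULL, y REAL NOT NULL, z REAL NOT NULL"),
    "distance_amino_amino": ("amino1_id TEXT NOT NULL REFERENCES aminoacid(id), "
                             "amino2_id TEXT NOT NULL REFERENCES aminoacid(id), "
                             "dist REAL NOT NULL"),
    "distance_ligand_amino": ("ligand_id TEXT NOT NULL REFERENCES ligand(id), "
                              "amino_id TEXT NOT NULL REFERENCES aminoacid(id), "
                              "dist REAL NOT NULL"),
    "next_amino_amino": ("amino1_id TEXT NOT NULL REFERENCES aminoacid(id), "
                         "amino2_id TEXT NOT NULL REFERENCES aminoacid(id)"),
}

_TABLES_DENORMALIZED = {
    "protein": "id TEXT PRIMARY KEY, name TEXT",
    "standard_amino": _TABLES_NORMALIZED["standard_amino"],
    "aminoacid": ("id TEXT PRIMARY KEY, protein_id TEXT NOT NULL, "
                  "symbol TEXT NOT NULL, class TEXT NOT NULL, "
                  "number INTEGER NOT NULL"),
    "ligand": ("id TEXT PRIMARY KEY, protein_id TEXT NOT NULL, "
               "symbol TEXT NOT NULL, number INTEGER NOT NULL"),
    "distance_amino_amino": _WIDE_AMINO_PAIR + ", dist REAL NOT NULL",
    "distance_ligand_amino": ("protein_id TEXT NOT NULL, "
                              "ligand_id TEXT NOT NULL, ligand_symbol TEXT NOT NULL, "
                              "ligand_number INTEGER NOT NULL, "
                              "amino_id TEXT NOT NULL, amino_symbol TEXT NOT NULL, "
                              "amino_class TEXT NOT NULL, amino_number INTEGER NOT NULL, "
                              "dist REAL NOT NULL"),
    "next_amino_amino": _WIDE_AMINO_PAIR,
}

# the 12 filtered/joined attributes of the three wide tables
_INDEXES_DENORMALIZED = [
    ("distance_amino_amino", c) for c in
    ("amino1_id", "amino1_symbol", "amino2_id", "amino2_symbol")
] + [
    ("distance_ligand_amino", c) for c in
    ("ligand_id", "ligand_symbol", "amino_id", "amino_symbol")
] + [
    ("next_amino_amino", c) for c in
    ("amino1_id", "amino1_symbol", "amino2_id", "amino2_symbol")
]

# basic index set for the normalized layout: symbol lookups + join columns
_INDEXES_NORMALIZED = [
    ("aminoacid", "symbol"), ("ligand", "symbol"),
    ("distance_amino_amino", "amino1_id"), ("distance_amino_amino", "amino2_id"),
    ("distance_ligand_amino", "ligand_id"), ("distance_ligand_amino", "amino_id"),
    ("next_amino_amino", "amino1_id"), ("next_amino_amino", "amino2_id"),
]


@dataclass
class DDLReport:
    tables: list[str]
    indexes: list[str]
    ddl: str


@dataclass
class LoadReport:
    protein_id: str
    rows: dict[str, int] = field(default_factory=dict)


def connect(path: str = ":memory:") -> sqlite3.Connection:
    """Open (or create) an embedded database file."""
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def _table_defs(variant: SchemaVariant) -> dict[str, str]:
    return _TABLES_NORMALIZED if variant.layout == "normalized" else _TABLES_DENORMALIZED


def _index_defs(variant: SchemaVariant) -> list[tuple[str, str]]:
    if not variant.indexed:
        return []
    return _INDEXES_NORMALIZED if variant.layout == "normalized" else _INDEXES_DENORMALIZED


def schema_ddl(variant: SchemaVariant) -> str:
    """The CREATE statements for a layout, without executing them."""
    stmts = [f"CREATE TABLE {name} ({cols});" for name, cols in _table_defs(variant).items()]
    for table, col in _index_defs(variant):
        stmts.append(f"CREATE INDEX idx_{table}_{col} ON {table} ({col});")
    return "\n".join(stmts)


def existing_tables(conn: sqlite3.Connection) -> set[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type = 'table'").fetchall()
    return {r[0] for r in rows}


def detect_layout(conn: sqlite3.Connection) -> str:
    """Infer the layout of a built database from its table set."""
    tables = existing_tables(conn)
    if "chain" in tables:
        return "normalized"
    if "distance_amino_amino" in tables:
        return "denormalized"
    raise StoreError("database has no recognizable schema (run build_schema first)")


def build_schema(conn: sqlite3.Connection, variant: SchemaVariant,
                 force: bool = False) -> DDLReport:
    """Create the tables and (optionally) indexes of a layout and seed the
    21-row ``standard_amino`` reference table.

    Refuses to touch a database that already contains conflicting tables
    unless ``force`` is set, in which case they are dropped first.
    """
    defs = _table_defs(variant)
    conflicts = existing_tables(conn) & set(defs)
    if conflicts:
        if not force:
            raise StoreError(
                f"tables already exist: {sorted(conflicts)} (use force to rebuild)")
        for name in _drop_order(variant):
            conn.execute(f"DROP TABLE IF EXISTS {name}")
    ddl = schema_ddl(variant)
    conn.executescript(ddl)
    conn.executemany(
        "INSERT INTO standard_amino (symbol, abbreviation, name, class) "
        "VALUES (?, ?, ?, ?)",
        [(e.symbol, e.abbreviation, e.name, e.polarity) for e in STANDARD_AMINO_ACIDS])
    conn.commit()
    return DDLReport(
        tables=list(defs),
        indexes=[f"idx_{t}_{c}" for t, c in _index_defs(variant)],
        ddl=ddl)


def _drop_order(variant: SchemaVariant) -> list[str]:
    # children before parents, FK-safe
    return list(reversed(list(_table_defs(variant))))


def _delete_protein(conn: sqlite3.Connection, layout: str, protein_id: str) -> None:
    if layout == "normalized":
        conn.execute(
            "DELETE FROM distance_amino_amino WHERE amino1_id IN "
            "(SELECT a.id FROM aminoacid a JOIN chain c ON a.chain_id = c.id "
            " WHERE c.protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM distance_ligand_amino WHERE ligand_id IN "
            "(SELECT l.id FROM ligand l JOIN chain c ON l.chain_id = c.id "
            " WHERE c.protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM next_amino_amino WHERE amino1_id IN "
            "(SELECT a.id FROM aminoacid a JOIN chain c ON a.chain_id = c.id "
            " WHERE c.protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM atom_amino WHERE amino_id IN "
            "(SELECT a.id FROM aminoacid a JOIN chain c ON a.chain_id = c.id "
            " WHERE c.protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM atom_ligand WHERE ligand_id IN "
            "(SELECT l.id FROM ligand l JOIN chain c ON l.chain_id = c.id "
            " WHERE c.protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM aminoacid WHERE chain_id IN "
            "(SELECT id FROM chain WHERE protein_id = ?)", (protein_id,))
        conn.execute(
            "DELETE FROM ligand WHERE chain_id IN "
            "(SELECT id FROM chain WHERE protein_id = ?)", (protein_id,))
        conn.execute("DELETE FROM chain WHERE protein_id = ?", (protein_id,))
        conn.execute("DELETE FROM protein WHERE id = ?", (protein_id,))
    else:
        for table in ("distance_amino_amino", "distance_ligand_amino",
                      "next_amino_amino", "aminoacid", "ligand"):
            conn.execute(f"DELETE FROM {table} WHERE protein_id = ?", (protein_id,))
        conn.execute("DELETE FROM protein WHERE id = ?", (protein_id,))


def load_structure(conn: sqlite3.Connection, relations: ChainRelations,
                   protein_name: str | None = None) -> LoadReport:
    """Bulk-load one protein's preprocessed relations in a single
    transaction.

    Residue-pair contact records are stored in BOTH orientations
    (symmetric expansion), so an undirected Distance constraint needs no
    OR over orientations.  Re-loading the same protein replaces its rows.
    """
    layout = detect_layout(conn)
    pid = relations.protein_id
    chain = relations.chain
    report = LoadReport(protein_id=pid)
    try:
        # sqlite3 opens the transaction implicitly at the first DML statement
        _delete_protein(conn, layout, pid)
        conn.execute("INSERT INTO protein (id, name) VALUES (?, ?)",
                     (pid, protein_name or pid))
        report.rows["protein"] = 1
        if layout == "normalized":
            _load_normalized(conn, relations, report)
        else:
            _load_denormalized(conn, relations, report)
        conn.commit()
    except sqlite3.IntegrityError as e:
        conn.rollback()
        raise StoreError(f"integrity violation loading protein {pid}: {e}") from e
    except Exception:
        conn.rollback()
        raise
    return report


def _symmetric(records) -> Iterable[tuple]:
    for r in records:
        t = astuple(r)
        yield t
        # swap the amino1_* and amino2_* column groups (protein_id first,
        # optional dist last)
        yield t[:1] + t[5:9] + t[1:5] + t[9:]


def _load_denormalized(conn, relations: ChainRelations, report: LoadReport) -> None:
    pid, chain = relations.protein_id, relations.chain
    amino_rows = [
        (make_ids(pid, chain.chain_id, r.seq_index), pid, r.symbol,
         _class_of(r.symbol), r.seq_index)
        for r in chain.residues]
    conn.executemany("INSERT INTO aminoacid VALUES (?, ?, ?, ?, ?)", amino_rows)
    ligand_rows = [
        (make_ids(pid, chain.chain_id, h.author_number), pid, h.code, h.author_number)
        for h in chain.hetgroups]
    conn.executemany("INSERT INTO ligand VALUES (?, ?, ?, ?)", ligand_rows)
    daa = list(_symmetric(relations.amino_distances))
    conn.executemany(
        "INSERT INTO distance_amino_amino VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)", daa)
    dla = [astuple(r) for r in relations.ligand_distances]
    conn.executemany(
        "INSERT INTO distance_ligand_amino VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)", dla)
    naa = [astuple(r) for r in relations.next_records]
    conn.executemany("INSERT INTO next_amino_amino VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)", naa)
    report.rows.update({
        "aminoacid": len(amino_rows), "ligand": len(ligand_rows),
        "distance_amino_amino": len(daa), "distance_ligand_amino": len(dla),
        "next_amino_amino": len(naa)})


def _load_normalized(conn, relations: ChainRelations, report: LoadReport) -> None:
    pid, chain = relations.protein_id, relations.chain
    chain_id = f"{pid}_{chain.chain_id}"
    conn.execute("INSERT INTO chain (id, protein_id, name) VALUES (?, ?, ?)",
                 (chain_id, pid, chain.chain_id))
    amino_rows, atom_amino_rows = [], []
    for r in chain.residues:
        aid = make_ids(pid, chain.chain_id, r.seq_index)
        amino_rows.append((aid, chain_id, r.symbol, _class_of(r.symbol), r.seq_index))
        for k, a in enumerate(r.atoms, start=1):
            atom_amino_rows.append(
                (make_ids(pid, chain.chain_id, r.seq_index, k), aid, k,
                 a.atom_name, a.x, a.y, a.z))
    conn.executemany("INSERT INTO aminoacid VALUES (?, ?, ?, ?, ?)", amino_rows)
    conn.executemany("INSERT INTO atom_amino VALUES (?, ?, ?, ?, ?, ?, ?)",
                     atom_amino_rows)
    ligand_rows, atom_ligand_rows = [], []
    for h in chain.hetgroups:
        lid = make_ids(pid, chain.chain_id, h.author_number)
        ligand_rows.append((lid, chain_id, h.code, h.author_number))
        for k, a in enumerate(h.atoms, start=1):
            atom_ligand_rows.append(
                (make_ids(pid, chain.chain_id, h.author_number, k), lid, k,
                 a.atom_name, a.x, a.y, a.z))
    conn.executemany("INSERT INTO ligand VALUES (?, ?, ?, ?)", ligand_rows)
    conn.executemany("INSERT INTO atom_ligand VALUES (?, ?, ?, ?, ?, ?, ?)",
                     atom_ligand_rows)
    daa = []
    for r in relations.amino_distances:
        daa.append((r.amino1_id, r.amino2_id, r.dist))
        daa.append((r.amino2_id, r.amino1_id, r.dist))
    conn.executemany("INSERT INTO distance_amino_amino VALUES (?, ?, ?)", daa)
    dla = [(r.ligand_id, r.amino_id, r.dist) for r in relations.ligand_distances]
    conn.executemany("INSERT INTO distance_ligand_amino VALUES (?, ?, ?)", dla)
    naa = [(r.amino1_id, r.amino2_id) for r in relations.next_records]
    conn.executemany("INSERT INTO next_amino_amino VALUES (?, ?)", naa)
    report.rows.update({
        "chain": 1, "aminoacid": len(amino_rows), "ligand": len(ligand_rows),
        "atom_amino": len(atom_amino_rows), "atom_ligand": len(atom_ligand_rows),
        "distance_amino_amino": len(daa), "distance_ligand_amino": len(dla),
        "next_amino_amino": len(naa)})


def _class_of(symbol: str) -> str:
    return polarity_of(symbol)


def export_table_csv(conn: sqlite3.Connection, table: str, out: IO[str]) -> None:
    cur = conn.execute(f"SELECT * FROM {table}")
    w = csv.writer(out)
    w.writerow([d[0] for d in cur.description])
    w.writerows(cur)


def import_table_csv(conn: sqlite3.Connection, table: str, src: IO[str]) -> int:
    rows = list(csv.reader(src))
    if not rows:
        return 0
    header, data = rows[0], rows[1:]
    ph = ", ".join("?" for _ in header)
    cols = ", ".join(header)
    conn.executemany(f"INSERT INTO {table} ({cols}) VALUES ({ph})", data)
    conn.commit()
    return len(data)
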