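"""Query benchmarking protocol and improvement reporting.

A query test runs the compiled pattern query three times against a loaded
database and records the fastest wall-clock time, with a per-run timeout
(600 s by default).  Timing wraps statement execution only -- compilation
and result formatting are excluded.  The benchmark never modifies
database contents.

The improvement metric between two database variants is
``(t_db1 - t_db2) / t_db1 * 100``, truncated (not rounded) to two
decimals, matching how published comparison tables are formatted;
negative values mean the second variant was slower.
"""

from __future__ import annotations

import sqlite3
import time
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from typing import Sequence

from .patterns import PatternGraph
from .store import SchemaVariant, existing_tables
from .translate import QueryTimeout, execute_pattern


class BenchmarkError(RuntimeError):
    pass


@dataclass
class BenchmarkResult:
    pattern_id: str
    variant: SchemaVariant | None
    runtimes: list[float] = field(default_factory=list)
    best: float | None = None  # absent when timed out
    timed_out: bool = False
    n_hits: int | None = None


@dataclass
class ImprovementRow:
    pattern_id: str
    n_hits: int | None
    t_db1: float | None
    t_db2: float | None
    pct_improvement: float | None  # absent when either side timed out


def run_query_test(conn: sqlite3.Connection, p: PatternGraph,
                   repeats: int = 3, timeout: float = 600.0,
                   variant: SchemaVariant | None = None) -> BenchmarkResult:
    """Execute ``p`` ``repeats`` times and keep the fastest wall time.

    A run that exceeds ``timeout`` marks the whole test as timed out
    (``best`` stays absent).  Raises :class:`BenchmarkError` when the
    database has no schema.
    """
    if "protein" not in existing_tables(conn):
        raise BenchmarkError("database is missing the pattern tables "
                             "(build and load a schema first)")
    result = BenchmarkResult(pattern_id=p.pattern_id, variant=variant)
    for _ in range(repeats):
        t0 = time.perf_counter()
        try:
            hits = execute_pattern(conn, p, timeout=timeout)
        except QueryTimeout:
            result.timed_out = True
            result.runtimes.append(time.perf_counter() - t0)
            continue
        result.runtimes.append(time.perf_counter() - t0)
        result.n_hits = len(hits)
    if not result.timed_out:
        result.best = min(result.runtimes)
    return result


def improvement(t1: float, t2: float) -> float:
    """Percentage improvement of ``t2`` over ``t1``:
    ``(t1 - t2)/t1 * 100`` truncated to 2 decimals; negative when ``t2``
    is slower."""
    if not t1 > 0:
        raise ValueError(f"baseline runtime must be positive, got {t1}")
    pct = (t1 - t2) / t1 * 100.0
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), ROUND_DOWN))


def compare(db1: Sequence[BenchmarkResult],
            db2: Sequence[BenchmarkResult]) -> list[ImprovementRow]:
    """Pair up per-pattern results of two database variants."""
    by_id = {r.pattern_id: r for r in db2}
    rows = []
    for r1 in db1:
        r2 = by_id.get(r1.pattern_id)
        if r2 is None:
            continue
        pct = None
        if not r1.timed_out and not r2.timed_out:
            pct = improvement(r1.best, r2.best)
        rows.append(ImprovementRow(
            pattern_id=r1.pattern_id,
            n_hits=r1.n_hits if r1.n_hits is not None else r2.n_hits,
            t_db1=r1.best, t_db2=r2.best, pct_improvement=pct))
    return rows


def _cell(t: float | None, timeout: float) -> str:
    return f"{t:.3f}" if t is not None else f">{timeout:g}"


def report(rows: Sequence[ImprovementRow], fmt: str = "tsv",
           timeout: float = 600.0) -> str:
    """Render improvement rows as a TSV or Markdown table; timed-out
    entries are printed as ``>timeout``."""
    if not rows:
        raise ValueError("no results to report")
    header = ["Pattern", "Hits", "DB1", "DB2", "% Imp"]
    body = [[r.pattern_id,
             str(r.n_hits) if r.n_hits is not None else "-",
             _cell(r.t_db1, timeout), _cell(r.t_db2, timeout),
             f"{r.pct_improvement:.2f}" if r.pct_improvement is not None else "-"]
            for r in rows]
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in [header] + body) + "\n"
    if fmt == "markdown":
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join("---" for _ in header) + "|"]
        lines += ["| " + " | ".join(row) + " |" for row in body]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
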