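# Methods

## Pattern semantics

A structural pattern is a property graph over residue and ligand nodes. Its
match semantics, implemented identically in the SQL compiler and the
brute-force matcher, are:

- a `Distance` edge holds when the *minimum inter-atomic distance* between
  the two bound elements lies in [min, max] Å. Distances are only stored up
  to the preprocessing cutoff (7.0 Å by default), so a pattern max above the
  cutoff cannot match pairs the preprocessing discarded — the cutoff is part
  of the data model, not of the query;
- a `Next` edge holds when the target residue's sequence index is exactly
  source + 1;
- a `Gap` edge holds when the count of residues strictly between source and
  target, `index(target) − index(source) − 1`, lies in [min, max]; min ≥ 1,
  and an unbounded max (`*`, JSON `null`) drops the upper clause;
- distinct amino-kind nodes must bind distinct residues (injectivity).
  Without it a `C-x(1,5)-C` pair could bind one cysteine twice;
  `allow_repeats=True` disables the predicate for comparison;
- a hit is a deduplicated binding of *all* pattern nodes in one protein.
  Deduplication matters because the symmetric storage of residue-pair
  distances would otherwise multiply rows.

Sequence positions (`number` columns, Next/Gap arithmetic, provenance ids)
use the *processed* sequence index 1..n of the selected chain, not author
numbering: author numbering has gaps and insertion codes that make
"adjacent" ambiguous, whereas the processed index reproduces exactly what
the loader saw.

## Ingest policy

PDB text is parsed by gemmi; the reduction to the flat model applies: first
MODEL only; altloc blank or `A` only; water (HOH/WAT/DOD) never becomes a
ligand (it would dominate the contact tables meaninglessly); nucleotide
residues are dropped from relation building; non-standard ATOM-record
residues are kept with symbol `UND` (polarity class `unknown`, matched only
by the wildcard polarity); HETATM groups become candidate ligands. Hydrogens,
if present, participate in distance computation like any other atom. The
processed chain is the one maximizing residues + het groups, ties broken by
the lexicographically smallest chain id.

The polarity table partitions the 20 standard residues 9/6/3/2:
non-polar {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY}; polar uncharged
{SER, THR, CYS, TYR, ASN, GLN}; positively charged {LYS, ARG, HIS};
negatively charged {ASP, GLU}. This is the standard hydropathy/charge
classification; HIS is grouped with the positively charged residues.

## Storage and translation choices

- **Symmetric expansion.** `distance_amino_amino` stores both orientations
  of every residue pair. An undirected Distance constraint then compiles to
  a plain conjunctive filter; the alternative (an OR over orientations)
  would defeat single-column indexing. Trade-off: 2× storage on that table.
- **Anchor tables in the denormalized layout.** The slim `aminoacid` and
  `ligand` tables are kept alongside the three wide relation tables: Gap
  subqueries are a self-join of `aminoacid` (a gap is sequence arithmetic,
  not a stored relation), and an edge-free Ligand/AnyLigand node needs an
  anchor because a contact-free ligand has no row in
  `distance_ligand_amino`.
- **Explicit ON conditions.** Joins equate protein ids everywhere and
  element ids wherever two subqueries touch the same node; natural join by
  column name is fragile across aliases.
- **Indexing.** Denormalized + indexed creates 12 single-column B-tree
  indexes: {amino1,amino2}×{id,symbol} on `distance_amino_amino` and
  `next_amino_amino`, {ligand,amino}×{id,symbol} on
  `distance_ligand_amino`. The normalized layout gets the basic set
  instead (symbol lookups on `aminoacid`/`ligand` plus the six relation-
  table id columns), since the wide symbol columns do not exist there.
- **Subquery order.** Default order is pattern edge order; an explicit
  permutation can be supplied because order affects runtime (the result
  set is invariant, which the tests check). No cost-based reordering is
  attempted.
- **Backend.** An embedded SQL engine (sqlite3), one file per database.
  Generated SQL sticks to the common dialect (plain CREATE TABLE/INDEX,
  INNER JOIN, BETWEEN), so it ports to a PostgreSQL-class server, but no
  server backend is wired up.
- Query timeouts are enforced with a progress callback checked every 1000
  VM instructions; a timeout is reported as a distinct outcome, never as an
  empty result.

## Pattern dialect

Patterns are JSON, one per file; unknown keys are rejected (fail-fast).
Defaults are materialized on read: Distance min/max 0.5/7.0 Å, Gap min 1,
Gap max unbounded, AnyAmino polarity `any`. Unbounded Gap max is
serialized as `null` and is an explicit marker object internally, never a
sentinel number. At most one ligand-kind node is allowed per pattern —
every motif this model targets has a single ligand, and allowing two would
make the ligand-contact templates ambiguous — and amino names are
validated against the 21-entry standard table. Validation returns
violations as data (element + message); only operations that require a
valid pattern raise.

## Synthetic data

The generator emulates what the contact pipeline assumes about real
structures, not protein physics:

- residues along a self-avoiding random walk, 3.8 Å consecutive-CA spacing
  (canonical backbone geometry), ≥ 3.0 Å between non-consecutive CAs,
  confined to a 40 Å box; the walk restarts (bounded) when it dead-ends,
  keeping generation deterministic per seed;
- 3–6 atoms per residue within 1.2 Å of the CA, so consecutive residues are
  always within the 7 Å cutoff and contact density decays with sequence
  separation roughly as in a compact chain;
- uniform residue composition by default (configurable weights); one het
  group per protein with probability 0.7, placed 2.5–6 Å from a random CA;
- coordinates are pre-rounded to 3 decimals so written PDB fixtures
  round-trip bit-exactly; same seed → byte-identical files.

Planting searches residue-position assignments satisfying all Next/Gap
constraints and all residue–residue Distance bounds against the existing
geometry, rewrites symbols, and samples a ligand position whose distance to
each constrained residue lies strictly inside its [min, max] window with a
0.05 Å margin (so 3-decimal rounding cannot push a planted distance onto a
boundary). Existing het groups with the planted code are removed from that
protein so that k planted instances imply at least k hits, tightly. What
passing tests on this data shows: the relational pipeline computes exactly
the declared contact/adjacency semantics. What it does not show: robustness
to real-PDB pathologies (multi-model ensembles beyond model 1, exotic
residue chemistry, very large chains) or realistic contact statistics.

## Verification protocols and problem sizes

The suite pins four properties, each at 100% agreement: (i) SQL vs.
brute-force hit-set equality on 132 seeded (pattern, database) pairs — 10
databases of 6 proteins (20–60 residues each), 10 random connected patterns
of ≤ 6 nodes per database plus the deterministic 16-form battery on two of
them, with one planted zinc finger per database and a composition biased
toward the pattern symbol pool so roughly half the pairs have non-empty hit
sets; (ii) identical hit sets across normalized/denormalized ×
indexed/unindexed on 27 patterns; (iii) recovery of k ∈ {1, 5, 20} planted
motifs among k+2 proteins; (iv) contact/adjacency records vs. a plain
double-loop recomputation on 50 chains. These sizes keep the whole suite in
seconds while exercising every template form and both empty and non-empty
result paths; the protocols scale up by parameter if stronger evidence is
wanted.

The improvement metric `(t1 − t2)/t1 × 100` is *truncated* toward zero to
two decimals (Decimal `ROUND_DOWN`), which is how the published comparison
tables it reproduces were formatted; the tests verify all 20 printed rows.

## Known limitations

- Single selected chain per structure; no cross-chain contacts.
- Textual PDB only (no mmCIF/PDBML); gemmi's leniency toward garbage
  numeric fields is inherited (a malformed coordinate may parse as 0.0
  rather than raise, though truncated records do raise with a line number).
- The brute-force oracle is exponential in pattern size by design; it is
  intended for ≤ 6-node patterns on ≤ 60-residue chains.
- Ligand provenance ids reuse the het author number; amino and ligand ids
  live in disjoint tables, so a numeric collision between the two id
  families is harmless, and the generator numbers het groups from 1001 to
  avoid it entirely.
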