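"""Derive artificial stress-test patterns from database content.

The recipe: rank ligand codes by the number of distinct proteins that
contain them, then for each top ligand take the residue symbols most
frequently in contact with it.  Those (ligand, residues) combinations
make patterns that are guaranteed to be common in the database, which is
what makes them useful for stressing query performance.
"""

from gspq import (PatternGraph, SchemaVariant, SynthConfig, amino,
                  build_schema, connect, distance, execute_pattern,
                  generate_proteins, ligand, load_structure, preprocess_chain,
                  select_primary_chain, suggest_artificial_patterns)

cfg = SynthConfig(seed=99, n_proteins=15, ligand_probability=1.0)
models = generate_proteins(cfg)
rels = [preprocess_chain(select_primary_chain(m), protein_id=m.pdb_id)
        for m in models]
conn = connect()
build_schema(conn, SchemaVariant())
for r in rels:
    load_structure(conn, r)

suggestions = suggest_artificial_patterns(conn, n_ligands=3, n_aminos=2)
print("top ligands and their most-contacted residues:")
for code, aminos in suggestions:
    print(f"  {code}: {', '.join(aminos)}")

# turn the top suggestion into a one-ligand/one-residue pattern and run it
code, aminos = suggestions[0]
p = PatternGraph("artificial", [ligand("L", code), amino("A", aminos[0])],
                 [distance("L", "A")])
hits = execute_pattern(conn, p)
print(f"\npattern {code}...{aminos[0]} (contact within 0.5-7 A): "
      f"{len(hits)} hit(s) across {len({h.protein_id for h in hits})} protein(s)")
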