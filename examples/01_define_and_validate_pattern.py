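"""Define a zinc-finger binding-site pattern, validate it and inspect its
node-edge-node decomposition.

The pattern is a small property graph: a ZN ligand in contact (0.5-7 A
minimum inter-atomic distance) with a CYS, a HIS and one wildcard residue,
where the HIS immediately follows the CYS in sequence and the wildcard
comes at least one residue later.
"""

from gspq import (count_elements, decompose, validate_pattern, write_pattern,
                  zinc_finger_pattern)

p = zinc_finger_pattern()
report = validate_pattern(p)
print(f"pattern {p.pattern_id!r}: valid={report.ok}, "
      f"elements={count_elements(p)} ({len(p.nodes)} nodes + {len(p.edges)} edges)")

print("\nsubpatterns (one per edge, the unit the SQL compiler works on):")
for sp in decompose(p):
    print(f"  {sp.left.node_id:>5} --{sp.edge.kind:^8}--> {sp.right.node_id:<5} "
          f"form={sp.form}")

print("\nJSON serialization (round-trips losslessly):")
print(write_pattern(p))
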