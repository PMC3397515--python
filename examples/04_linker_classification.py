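"""Classify the published RadA linker-region CCDA pattern (I71–K88).

The bundled table holds the reported per-residue phi/psi CCDA values for
the 18-residue linker of the S. solfataricus RadA filament. Residues
with zero CCDA in both angles are the rotation axes of the proposed
rotary-motor mechanism; the script prints both groups. The companion
identity check shows the right- and left-handed end states are the same
protein (100% sequence identity).
"""

from radamotor import (classify_rotary, load_reference_linker_table,
                       load_state_sequences, percent_identity)

table = load_reference_linker_table()
cls = classify_rotary(table)
names = dict(zip(table.frame["residue_id"], table.frame["residue_name"]))
fmt = lambda ids: ", ".join(f"{names[i]}{i}" for i in sorted(ids))
print(f"zero-rotary ({len(cls.zero_rotary)}): {fmt(cls.zero_rotary)}")
print(f"rotary      ({len(cls.rotary)}): {fmt(cls.rotary)}")

right, left = load_state_sequences().values()
print(f"\nright- vs left-handed state sequence identity: "
      f"{percent_identity(right, left):.1f}%")
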