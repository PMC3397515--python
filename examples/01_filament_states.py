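"""Build the four toy filament states and compare their geometries.

The four states stand in for the conformations of a RecA/RadA-like
filament rotary cycle: a left-handed helix, a ring-like bend, an
intermediate-twist helix and a right-handed helix. The printed matrix
holds pairwise best-fit Cα RMSDs in Å — every off-diagonal entry is
well above 1 Å, so the states are genuinely distinct targets.
"""

import numpy as np

from radamotor import FilamentSpec, make_state_quartet, superpose, write_pdb

labels = ["left-handed", "ring-like", "intermediate", "right-handed"]
states = make_state_quartet(FilamentSpec(12, 3.8, 100.0, 2.3, with_backbone=True))

print("pairwise fitted C-alpha RMSD (Angstrom):")
print("".join(f"{lab:>14s}" for lab in labels))
for i, lab in enumerate(labels):
    row = [superpose(states[i], states[j], selection=("CA",)).rmsd
           for j in range(4)]
    print(f"{lab:>14s}" + "".join(f"{v:14.2f}" for v in row))

for lab, s in zip(labels, states):
    write_pdb(s, f"{lab.replace('-', '_')}.pdb")
print("\nwrote the four states as PDB files in the current directory")
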