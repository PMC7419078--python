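"""Census the donor-sugar binding site and flag divergent residues.

Builds a toy ligand-bound structure, lists side chains within 5 Å of the
ligand, then maps a binding-site residue across five aligned variants to
flag the classic single-outlier pattern (a lysine against an otherwise
hydrophobic column) as a mutation candidate.
"""

import numpy as np

from ugtshape import Msa, census, divergence
from ugtshape.structure_io import LigandStructure, ProteinAtom


def atom(resid, resname, name, xyz):
    backbone = {"N", "CA", "C", "O", "OXT"}
    return ProteinAtom(resid, resname, name, name not in backbone,
                       np.asarray(xyz, dtype=float))


# Ligand at the origin; residue 5's side chain at 3 Å, residue 9's at 7 Å,
# and a glycine right next to the ligand (no side-chain atoms, never counted).
structure = LigandStructure(
    protein_atoms=[
        atom(5, "LYS", "NZ", (3.0, 0, 0)),
        atom(5, "LYS", "CA", (5.5, 0, 0)),
        atom(7, "GLY", "CA", (1.0, 0, 0)),
        atom(9, "SER", "OG", (7.0, 0, 0)),
    ],
    ligand_atoms=[("C1", np.zeros(3))],
    ligand_resname="UDP",
)
site = census(structure, cutoff=5.0, variant="enzA")
print("Side chains within 5 Å of the ligand:")
for resid, name, dist in site.residues:
    print(f"  residue {resid} ({name}): min side-chain distance {dist:.1f} Å")
print("(the glycine at 1 Å is absent: no side-chain heavy atoms)")

# Five variants aligned over the binding-site region; the reference enzyme
# carries K where every other variant carries a hydrophobic residue.
rows = {
    "enzA": "AAAAKAA",
    "enzB": "AAAALAA",
    "enzC": "AAAALAA",
    "enzD": "AAAAIAA",
    "enzE": "AAAALAA",
}
alignment = Msa(ids=list(rows), sequences=list(rows.values()), reference_index=0)
censuses = {
    v: type(site)(variant=v, cutoff=5.0, residues=[(5, "LYS", 3.0)])
    for v in rows
}
table = divergence(censuses, alignment, reference_variant="enzA")
print("\nDivergence across variants at the census residue:")
print(table.to_frame().to_string(index=False))
print("\n" + table.summary())
print("\nThe K-vs-hydrophobics pattern marks the residue a mutation candidate:"
      "\nswapping the outlier to the consensus class is the rational design.")
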