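"""Featurize a conformational ensemble as binary interface contact matrices.

Expands the bundled UGT interface residue selections, builds a toy
three-residue contact matrix by hand, and shows the 21 → 22 trailing-zero
padding that equalises matrix sizes across variants.
"""

import numpy as np

from ugtshape import INTERFACE_SELECTIONS, contact_matrix, pad_matrix, parse_selection
from ugtshape.contacts import ResidueSelection

print("Interface selection sizes (residues at the enzyme-substrate interface):")
for variant, text in INTERFACE_SELECTIONS.items():
    selection = parse_selection(text)
    print(f"  {variant}: {len(selection):2d} residues   <- '{text}'")

# Three residues on a line at 0, 5 and 12 Å: pairs within 8 Å are contacts.
coords = np.array([[0.0, 0, 0], [0, 0, 5.0], [0, 0, 12.0]])
cm = contact_matrix(coords, [1, 2, 3], ResidueSelection((1, 2, 3)))
print("\nContact matrix of residues at z = 0, 5, 12 Å (cutoff 8 Å, inclusive):")
print(cm.matrix)
print("d(1,2)=5 and d(2,3)=7 are contacts; d(1,3)=12 is not; diagonal is 1.")

padded = pad_matrix(cm, 4)
print("\nAfter padding 3x3 -> 4x4 (trailing zero row/column, original block kept):")
print(padded.matrix)
print(f"padded_from records the pre-padding size: {padded.padded_from}")
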