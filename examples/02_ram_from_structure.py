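"""Build a residue adjacency matrix from 3-D coordinates.

In structure space the distance is Euclidean, from the target
cysteine's sulfur (SG) atom to each residue's alpha carbon.  Here the
coordinates come from the synthetic backbone generator (a 3.8 A-step
self-avoiding walk); with real data they would come from a PDB file via
ramfeat.io.read_pdb_coords.
"""

import numpy as np

from ramfeat import PROTEIN_ALPHABET, rammod
from ramfeat.synthetic import generate_structure

sequence = "MKWVCDWECCWAGHWKLMNP"
target = 5  # the first cysteine
coords = generate_structure(sequence, seed=42, target_position=target)

matrix = rammod(coords, n=4)
w_row = matrix.row("W")
w_mask = matrix.imputed[PROTEIN_ALPHABET.index("W")]
print("tryptophan row (A):", w_row.round(2).tolist())
print("imputed cells:     ", w_mask.tolist())
print("\nThe sequence has 4 tryptophans, so at n=4 no imputation is")
print("needed; types with fewer residues are filled with the row mean.")

# Rigid motions leave the matrix unchanged -- only internal geometry matters.
shifted = type(coords)(
    protein_id=coords.protein_id,
    residues=tuple((p, r, (x + 10, y - 5, z + 2)) for p, r, (x, y, z) in coords.residues),
    target_position=target,
    target_sulfur=tuple(v + d for v, d in zip(coords.target_sulfur, (10, -5, 2))),
)
delta = np.abs(rammod(shifted, n=4).values - matrix.values).max()
print(f"\nmax |change| after translating all atoms: {delta:.2e} A (numerically zero)")
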