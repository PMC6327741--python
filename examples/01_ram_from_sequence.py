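"""Build a residue adjacency matrix from a primary sequence.

The matrix summarises a target residue's neighbourhood: cell (i, j) is
the distance (in sequence positions) to the j-th nearest residue of
type i.  Rows that run out of residues are mean-imputed; a type absent
from the sequence altogether gets the mean of the whole matrix.
"""

from ramfeat import DNA_ALPHABET, TargetSite, ramseq

# A 10-nucleotide example, analysing the first cytosine (position 4).
site = TargetSite(protein_id="chr1", sequence="TAACCCTAAC", position=4)
matrix = ramseq(site, n=4, alphabet=DNA_ALPHABET)

print("sequence:", site.sequence, "  target: position", site.position)
print(f"{'':>4}" + "".join(f"{j + 1:>8}" for j in range(matrix.n)))
for symbol in DNA_ALPHABET.symbols:
    row = matrix.row(symbol)
    mask = matrix.imputed[DNA_ALPHABET.index(symbol)]
    cells = "".join(
        f"{v:>7.2f}{'*' if m else ' '}" for v, m in zip(row, mask)
    )
    print(f"{symbol:>4}{cells}")
print("\n* = imputed. The adenine row reads 1, 2, 4, 5: the nearest")
print("adenines sit 1, 2, 4 and 5 positions from the target cytosine.")
print("Guanine never occurs, so its row is the matrix mean (3).")

# The same operation on a protein uses the 20-letter alphabet:
protein = TargetSite("toy", "MKWVCDWECCW", position=5)
m = ramseq(protein, n=3)
print("\nprotein example, n=3: tryptophan row =", m.row("W").round(2).tolist())
print("(distances from the target cysteine to its 3 nearest tryptophans)")
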