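"""Residue alphabets over which adjacency matrices are built.

A residue adjacency matrix (RAM) has one row per residue type, so the
alphabet — its symbols and their order — is part of the feature contract:
two feature vectors are only comparable if they were vectorized over the
same alphabet in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ResidueAlphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    symbols
        One-letter residue codes, unique, order-significant.
    names
        Full residue names, parallel to ``symbols``.
    """

    symbols: tuple[str, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.names and len(self.names) != len(self.symbols):
            raise ValueError("names must parallel symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)


#: The 20 standard amino acids ordered alphabetically by full name
#: (alanine first, valine last). Row 1 of a protein RAM is alanine and
#: row 20 is valine; every vectorized feature block follows this order.
PROTEIN_ALPHABET = ResidueAlphabet(
    symbols=tuple("ARNDCQEGHILKMFPSTWYV"),
    names=(
        "alanine", "arginine", "asparagine", "aspartate", "cysteine",
        "glutamine", "glutamate", "glycine", "histidine", "isoleucine",
        "leucine", "lysine", "methionine", "phenylalanine", "proline",
        "serine", "threonine", "tryptophan", "tyrosine", "valine",
    ),
)

#: Nucleotide alphabet for applying RAM to DNA: a 4 x n matrix with rows
#: A, T, C and G.
DNA_ALPHABET = ResidueAlphabet(
    symbols=("A", "T", "C", "G"),
    names=("adenine", "thymine", "cytosine", "guanine"),
)

#: Cysteine-only alphabet; with n=6 this reduces RAMseq to the prior
#: "nearest 6 cysteines" (N6C) feature.
CYSTEINE_ONLY = ResidueAlphabet(symbols=("C",), names=("cysteine",))

#: Residue codes that may appear in real sequences but are outside the
#: 20-letter alphabet (unknown, ambiguous, selenocysteine, pyrrolysine).
#: They are skipped, not remapped: selenocysteine is not folded into C.
NONSTANDARD_RESIDUES = frozenset("XBZUOJ*")
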