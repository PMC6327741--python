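"""Residue adjacency matrices (RAM) from sequence and from 3-D structure.

A RAM summarises the neighbourhood of a target residue as an
``|alphabet| x n`` matrix whose cell ``(i, j)`` holds the distance from
the target to the j-th nearest residue of type i.  Two variants exist:

* **RAMseq** — distances are absolute differences of 1-based sequence
  positions, ``|C - AA_j^i|``, computable from the primary sequence alone.
* **RAMmod** — distances are Euclidean, in angstroms, from the target
  cysteine's sulfur (SG) atom to the alpha carbons of neighbouring
  residues, taken from experimental or comparative-model coordinates.

When a protein holds fewer than n residues of some type, the missing
cells of that row are filled with the mean of the row's observed
distances; a type absent from the protein altogether gets the mean of
every observed cell in the whole matrix.  The boolean ``imputed`` mask
records which cells were filled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .alphabets import NONSTANDARD_RESIDUES, PROTEIN_ALPHABET, ResidueAlphabet

__all__ = [
    "TargetSite",
    "StructureCoords",
    "RamMatrix",
    "nth_nearest_distances",
    "impute_row",
    "ramseq",
    "rammod",
    "rammod_missing_structure",
]


@dataclass(frozen=True)
class TargetSite:
    """One labelled residue position within a named sequence.

    ``position`` is 1-based.  ``label`` is 1 for oxidation-susceptible,
    0 for non-susceptible, None when unknown (prediction mode).
    """

    protein_id: str
    sequence: str
    position: int
    label: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.sequence):
            raise ValueError(
                f"position {self.position} outside sequence of length "
                f"{len(self.sequence)} for {self.protein_id!r}"
            )
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def residue(self) -> str:
        return self.sequence[self.position - 1]


@dataclass(frozen=True)
class StructureCoords:
    """Per-residue alpha-carbon coordinates plus the target SG position.

    ``residues`` holds (1-based sequence position, one-letter code,
    (x, y, z) in angstroms) for each residue with a CA atom.
    ``target_sulfur`` is the SG coordinate of the target cysteine, or
    None when the structure lacks a side chain there.
    """

    protein_id: str
    residues: tuple[tuple[int, str, tuple[float, float, float]], ...]
    target_position: int
    target_sulfur: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.residues]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate residue positions in structure")
        for _, _, xyz in self.residues:
            if not all(math.isfinite(v) for v in xyz):
                raise ValueError("non-finite coordinate in structure")


@dataclass
class RamMatrix:
    """An ``|alphabet| x n`` residue adjacency matrix with imputation mask.

    Rows follow the alphabet order; within a row the observed entries
    form a sorted ascending prefix and imputed entries a constant suffix.
    """

    values: np.ndarray
    imputed: np.ndarray
    alphabet: ResidueAlphabet
    source: Literal["seq", "mod"]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.values.shape != self.imputed.shape:
            raise ValueError("values and imputed mask shapes differ")
        if self.values.shape[0] != len(self.alphabet):
            raise ValueError(
                f"expected {len(self.alphabet)} rows, got {self.values.shape[0]}"
            )
        self.n = self.values.shape[1]

    def row(self, symbol: str) -> np.ndarray:
        return self.values[self.alphabet.index(symbol)]

    def flatten(self) -> np.ndarray:
        """Vectorize row-major: type-1 ranks 1..n, then type-2, etc."""
        return self.values.ravel(order="C")

    def column_names(self, prefix: str) -> list[str]:
        return [
            f"{prefix}_{sym}_{j + 1}"
            for sym in self.alphabet.symbols
            for j in range(self.n)
        ]


def nth_nearest_distances(
    positions: Sequence[int], target: int, n: int
) -> list[float]:
    """Distances from ``target`` to its n nearest positions, ascending.

    Returns ``min(n, len(positions))`` values, each ``|target - p|``;
    the distance is positive whether the residue lies before or after
    the target.  Ties are broken by ascending position so the result is
    deterministic, though only the distance enters the matrix.
    """
    if target < 1:
        raise ValueError("target position must be >= 1")
    ranked = sorted((abs(target - p), p) for p in positions)
    return [float(d) for d, _ in ranked[:n]]


def impute_row(
    observed: Sequence[float], n: int, matrix_fallback: float
) -> tuple[np.ndarray, np.ndarray]:
    """Extend a sorted observed prefix to length ``n`` by mean imputation.

    Missing cells take the mean of the observed prefix; an empty prefix
    takes ``matrix_fallback`` (the mean over every observed cell in the
    matrix).  Returns ``(row, imputed_mask)``.
    """
    if len(observed) > n:
        raise ValueError(f"observed prefix longer ({len(observed)}) than n ({n})")
    row = np.empty(n, dtype=float)
    mask = np.zeros(n, dtype=bool)
    k = len(observed)
    row[:k] = observed
    fill = float(np.mean(observed)) if k else float(matrix_fallback)
    row[k:] = fill
    mask[k:] = True
    return row, mask


def _build_matrix(
    per_type_distances: list[list[float]],
    n: int,
    alphabet: ResidueAlphabet,
    source: Literal["seq", "mod"],
    protein_id: str,
) -> RamMatrix:
    """Assemble rows + imputation from per-type sorted distance prefixes."""
    all_observed = [d for row in per_type_distances for d in row]
    if all_observed:
        fallback = float(np.mean(all_observed))
    else:
        # A matrix with no observations at all (e.g. a 1-residue
        # sequence) has no defined mean; fill with 0 and warn.
        fallback = 0.0
        warnings.warn(
            f"{protein_id}: no observed distances in RAM matrix; "
            "filling with 0",
            stacklevel=3,
        )
    values = np.empty((len(alphabet), n), dtype=float)
    mask = np.empty((len(alphabet), n), dtype=bool)
    for i, observed in enumerate(per_type_distances):
        values[i], mask[i] = impute_row(observed, n, fallback)
    return RamMatrix(values=values, imputed=mask, alphabet=alphabet, source=source)


def ramseq(
    site: TargetSite,
    n: int,
    alphabet: ResidueAlphabet = PROTEIN_ALPHABET,
) -> RamMatrix:
    """Sequence-space residue adjacency matrix for one target site.

    For each residue type the row holds the absolute positional
    distances from the target to the n nearest residues of that type,
    the target position itself excluded, with mean imputation of any
    shortfall.  Residues outside the alphabet are skipped (and counted
    in a warning when unexpected symbols occur).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positions_by_type: dict[str, list[int]] = {s: [] for s in alphabet.symbols}
    skipped = 0
    for pos, residue in enumerate(site.sequence, start=1):
        if pos == site.position:
            continue  # self-exclusion: the target never scores itself
        if residue in positions_by_type:
            positions_by_type[residue].append(pos)
        elif residue in PROTEIN_ALPHABET:
            pass  # standard residue outside a restricted alphabet
        else:
            skipped += 1
            if residue not in NONSTANDARD_RESIDUES:
                warnings.warn(
                    f"{site.protein_id}: unexpected residue {residue!r} "
                    f"at position {pos} skipped",
                    stacklevel=2,
                )
    if skipped:
        warnings.warn(
            f"{site.protein_id}: {skipped} residue(s) outside the alphabet "
            "excluded from RAMseq",
            stacklevel=2,
        )
    per_type = [
        nth_nearest_distances(positions_by_type[s], site.position, n)
        for s in alphabet.symbols
    ]
    return _build_matrix(per_type, n, alphabet, "seq", site.protein_id)


def rammod(
    structure: StructureCoords,
    n: int,
    alphabet: ResidueAlphabet = PROTEIN_ALPHABET,
    *,
    exclude_self: bool = True,
    require_sulfur: bool = False,
) -> RamMatrix:
    """Structure-space residue adjacency matrix for one target cysteine.

    Distances are Euclidean (angstroms) from the target cysteine's SG
    atom to each alpha carbon, per residue type, smallest n kept, with
    the same mean-imputation rules as :func:`ramseq`.

    When the structure lacks the SG atom (comparative models sometimes
    omit side chains) the target residue's own alpha carbon is used
    instead, with a warning — or a :class:`ValueError` if
    ``require_sulfur`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    origin = structure.target_sulfur
    if origin is None:
        if require_sulfur:
            raise ValueError(
                f"{structure.protein_id}: no SG atom for target cysteine at "
                f"position {structure.target_position}"
            )
        ca_lookup = {p: xyz for p, _, xyz in structure.residues}
        if structure.target_position not in ca_lookup:
            raise ValueError(
                f"{structure.protein_id}: neither SG nor CA available for "
                f"target position {structure.target_position}"
            )
        origin = ca_lookup[structure.target_position]
        warnings.warn(
            f"{structure.protein_id}: target SG missing; falling back to "
            "the target residue's alpha carbon",
            stacklevel=2,
        )
    ox, oy, oz = origin
    dists_by_type: dict[str, list[tuple[float, int]]] = {
        s: [] for s in alphabet.symbols
    }
    for pos, residue, (x, y, z) in structure.residues:
        if exclude_self and pos == structure.target_position:
            continue
        if residue not in dists_by_type:
            continue
        d = math.sqrt((ox - x) ** 2 + (oy - y) ** 2 + (oz - z) ** 2)
        dists_by_type[residue].append((d, pos))
    per_type = [
        [d for d, _ in sorted(dists_by_type[s])[:n]] for s in alphabet.symbols
    ]
    return _build_matrix(per_type, n, alphabet, "mod", structure.protein_id)


def rammod_missing_structure(
    training_matrices: Sequence[RamMatrix], n: int | None = None
) -> RamMatrix:
    """Fallback RAMmod when no structure could be produced for a protein.

    Every cell is the per-cell mean over the supplied training matrices
    (the mean of all available structure-derived distances); the mask is
    fully imputed.
    """
    if not training_matrices:
        raise ValueError("at least one training RamMatrix is required")
    first = training_matrices[0]
    if n is not None and n != first.n:
        raise ValueError(f"training matrices have n={first.n}, requested n={n}")
    for m in training_matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("training matrices have inconsistent shapes")
        if m.alphabet.symbols != first.alphabet.symbols:
            raise ValueError("training matrices use different alphabets")
    mean = np.mean([m.values for m in training_matrices], axis=0)
    return RamMatrix(
        values=mean,
        imputed=np.ones_like(mean, dtype=bool),
        alphabet=first.alphabet,
        source="mod",
    )
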