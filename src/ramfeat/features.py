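"""Per-site feature vectors: block extraction, assembly and normalization.

Each target cysteine contributes up to six feature blocks:

========  =====================================  ==============
block     source                                 dimensionality
========  =====================================  ==============
RAMseq    sequence adjacency matrix              20 * n_seq
RAMmod    structure adjacency matrix             20 * n_mod
PSSM      log-odds profile window                20 * (2k + 1)
PSS       secondary-structure confidence window  3 * (2k + 1)
PROPKA    thiol pKa scalar (99.99 = disulfide)   1
SASA      sulfur solvent accessibility scalar    1
========  =====================================  ==============

At the defaults n_seq = n_mod = 6, k = 6 the assembled width is
120 + 120 + 260 + 39 + 1 + 1 = 541.  Multi-dimensional blocks can be
normalized per site (z-score or min-max, statistics within that site's
block); one-dimensional blocks are exempt.  A separate per-column
train/test z-score is provided for margin classifiers such as SVMs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .alphabets import PROTEIN_ALPHABET, ResidueAlphabet
from .io import SS_STATE_ORDER, PssmProfile, SsProfile
from .ram import RamMatrix, StructureCoords, TargetSite, ramseq, rammod, rammod_missing_structure

__all__ = [
    "FeatureBlock",
    "FeatureTable",
    "BLOCK_ORDER",
    "PKA_SENTINEL",
    "pssm_window",
    "pss_window",
    "encode_pka",
    "ram_block",
    "assemble",
    "normalize_per_site_block",
    "normalize_columns_train_test",
]

#: Frozen block order of the assembled vector.
BLOCK_ORDER = ("RAMseq", "RAMmod", "PSSM", "PSS", "PROPKA", "SASA")

#: pKa value marking a suspected disulfide bond.
PKA_SENTINEL = 99.99

PkaMode = Literal["sentinel", "mean", "zero"]
NormScheme = Literal["zscore", "minmax"]


@dataclass(frozen=True)
class FeatureBlock:
    """One named block of a site's feature vector."""

    name: str
    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or len(self.values) != len(self.column_names):
            raise ValueError("values and column_names must be parallel 1-D")


@dataclass(frozen=True)
class FeatureTable:
    """Assembled feature matrix over a list of target sites.

    ``matrix`` is (n_sites, width); ``blocks`` maps block name to its
    column slice; ``normalized`` records which per-site scheme, if any,
    has been applied.
    """

    sites: tuple[TargetSite, ...]
    matrix: np.ndarray
    column_names: tuple[str, ...]
    blocks: dict[str, slice]
    normalized: str | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sites), len(self.column_names)):
            raise ValueError("matrix shape inconsistent with sites/columns")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def labels(self) -> np.ndarray:
        """Binary label vector; raises if any site is unlabelled."""
        raw = [s.label for s in self.sites]
        if any(v is None for v in raw):
            raise ValueError("table contains unlabelled sites")
        return np.asarray(raw, dtype=int)

    def block_matrix(self, name: str) -> np.ndarray:
        return self.matrix[:, self.blocks[name]]

    def select_blocks(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to a subset of blocks, keeping the frozen order."""
        keep = [n for n in BLOCK_ORDER if n in names]
        missing = set(names) - set(self.blocks)
        if missing:
            raise KeyError(f"blocks not in table: {sorted(missing)}")
        cols: list[int] = []
        new_blocks: dict[str, slice] = {}
        for n in keep:
            sl = self.blocks[n]
            new_blocks[n] = slice(len(cols), len(cols) + (sl.stop - sl.start))
            cols.extend(range(sl.start, sl.stop))
        return FeatureTable(
            sites=self.sites,
            matrix=self.matrix[:, cols],
            column_names=tuple(self.column_names[i] for i in cols),
            blocks=new_blocks,
            normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# Window blocks

def pssm_window(profile: PssmProfile, position: int, k: int = 6) -> FeatureBlock:
    """Vectorize a 2k+1 profile window centred on ``position``.

    Window positions past either terminus are zero-filled (zero is the
    neutral log-odds score).  Vectorization is position-major: all 20
    residue scores of the leftmost window position first.
    """
    if not 1 <= position <= len(profile):
        raise ValueError(f"position {position} outside profile of length {len(profile)}")
    width = 2 * k + 1
    n_res = profile.scores.shape[1]
    values = np.zeros((width, n_res), dtype=float)
    for w, pos in enumerate(range(position - k, position + k + 1)):
        if 1 <= pos <= len(profile):
            values[w] = profile.scores[pos - 1]
    names = tuple(
        f"PSSM_{off:+d}_{res}"
        for off in range(-k, k + 1)
        for res in profile.residue_order
    )
    return FeatureBlock("PSSM", values.ravel(), names)


def pss_window(profile: SsProfile, position: int, k: int = 6) -> FeatureBlock:
    """Secondary-structure confidence window, 3 * (2k + 1) values."""
    if not 1 <= position <= len(profile):
        raise ValueError(f"position {position} outside profile of length {len(profile)}")
    width = 2 * k + 1
    values = np.zeros((width, 3), dtype=float)
    for w, pos in enumerate(range(position - k, position + k + 1)):
        if 1 <= pos <= len(profile):
            values[w] = profile.scores[pos - 1]
    names = tuple(
        f"PSS_{off:+d}_{state}" for off in range(-k, k + 1) for state in SS_STATE_ORDER
    )
    return FeatureBlock("PSS", values.ravel(), names)


def encode_pka(
    raw_pka: float, mode: PkaMode = "sentinel", dataset_mean: float | None = None
) -> FeatureBlock:
    """Encode the thiol pKa scalar, resolving the 99.99 disulfide sentinel.

    ``sentinel`` passes 99.99 through; ``mean`` replaces it with the
    dataset mean of non-sentinel pKa values; ``zero`` replaces it with 0.
    Non-sentinel values pass through in every mode.
    """
    value = raw_pka
    if np.isclose(raw_pka, PKA_SENTINEL):
        if mode == "zero":
            value = 0.0
        elif mode == "mean":
            if dataset_mean is None:
                raise ValueError("mean mode requires dataset_mean")
            value = dataset_mean
    return FeatureBlock("PROPKA", np.array([value], dtype=float), ("PROPKA",))


def ram_block(name: str, matrix: RamMatrix) -> FeatureBlock:
    """Vectorize a RAM matrix row-major under a block-qualified name."""
    return FeatureBlock(
        name, matrix.flatten(), tuple(matrix.column_names(name))
    )


# ---------------------------------------------------------------------------
# Assembly

def assemble(
    sites: Sequence[TargetSite],
    *,
    n_seq: int = 6,
    n_mod: int = 6,
    k: int = 6,
    structures: Mapping[tuple[str, int], StructureCoords] | None = None,
    pssms: Mapping[str, PssmProfile] | None = None,
    ss2: Mapping[str, SsProfile] | None = None,
    pka: Mapping[tuple[str, int], float] | None = None,
    sasa: Mapping[tuple[str, int], float] | None = None,
    pka_mode: PkaMode = "sentinel",
    alphabet: ResidueAlphabet = PROTEIN_ALPHABET,
) -> FeatureTable:
    """Build the block-structured feature matrix over ``sites``.

    RAMseq is always computed.  The other blocks are included exactly
    when their source mapping is supplied.  A site whose structure is
    missing from ``structures`` receives the per-cell mean of the
    available structure matrices (the fallback for failed comparative
    modelling); missing PSSM/PSS/scalar entries are hard errors listing
    the affected sites.
    """
    if not sites:
        raise ValueError("no sites to assemble")

    blocks_per_site: list[list[FeatureBlock]] = [[] for _ in sites]

    for bi, site in enumerate(sites):
        blocks_per_site[bi].append(
            ram_block("RAMseq", ramseq(site, n_seq, alphabet))
        )

    if structures is not None:
        available: dict[int, RamMatrix] = {}
        for bi, site in enumerate(sites):
            coords = structures.get((site.protein_id, site.position))
            if coords is not None:
                available[bi] = rammod(coords, n_mod, alphabet)
        if not available:
            raise ValueError("structures supplied but none match any site")
        fallback = None
        for bi, site in enumerate(sites):
            m = available.get(bi)
            if m is None:
                if fallback is None:
                    fallback = rammod_missing_structure(list(available.values()))
                m = fallback
            blocks_per_site[bi].append(ram_block("RAMmod", m))

    if pssms is not None:
        missing = [s.protein_id for s in sites if s.protein_id not in pssms]
        if missing:
            raise ValueError(f"missing PSSM profiles for: {sorted(set(missing))}")
        for bi, site in enumerate(sites):
            prof = pssms[site.protein_id]
            if len(prof) != len(site.sequence):
                raise ValueError(
                    f"{site.protein_id}: PSSM length {len(prof)} != sequence "
                    f"length {len(site.sequence)}"
                )
            blocks_per_site[bi].append(pssm_window(prof, site.position, k))

    if ss2 is not None:
        missing = [s.protein_id for s in sites if s.protein_id not in ss2]
        if missing:
            raise ValueError(f"missing PSS profiles for: {sorted(set(missing))}")
        for bi, site in enumerate(sites):
            prof = ss2[site.protein_id]
            if len(prof) != len(site.sequence):
                raise ValueError(
                    f"{site.protein_id}: PSS length {len(prof)} != sequence "
                    f"length {len(site.sequence)}"
                )
            blocks_per_site[bi].append(pss_window(prof, site.position, k))

    if pka is not None:
        missing_k = [
            (s.protein_id, s.position)
            for s in sites
            if (s.protein_id, s.position) not in pka
        ]
        if missing_k:
            raise ValueError(f"missing pKa values for sites: {missing_k}")
        non_sentinel = [
            v for v in pka.values() if not np.isclose(v, PKA_SENTINEL)
        ]
        dataset_mean = float(np.mean(non_sentinel)) if non_sentinel else 0.0
        for bi, site in enumerate(sites):
            blocks_per_site[bi].append(
                encode_pka(pka[(site.protein_id, site.position)], pka_mode, dataset_mean)
            )

    if sasa is not None:
        missing_k = [
            (s.protein_id, s.position)
            for s in sites
            if (s.protein_id, s.position) not in sasa
        ]
        if missing_k:
            raise ValueError(f"missing SASA values for sites: {missing_k}")
        for bi, site in enumerate(sites):
            blocks_per_site[bi].append(
                FeatureBlock(
                    "SASA",
                    np.array([sasa[(site.protein_id, site.position)]], dtype=float),
                    ("SASA",),
                )
            )

    # Freeze block order and validate shape consistency across sites.
    first = blocks_per_site[0]
    order = [b.name for b in first]
    assert order == [n for n in BLOCK_ORDER if n in order]
    block_slices: dict[str, slice] = {}
    column_names: list[str] = []
    for block in first:
        start = len(column_names)
        column_names.extend(block.column_names)
        block_slices[block.name] = slice(start, len(column_names))
    rows = []
    for bi, blocks in enumerate(blocks_per_site):
        names = tuple(n for b in blocks for n in b.column_names)
        if names != tuple(column_names):
            raise ValueError(
                f"site {sites[bi].protein_id}:{sites[bi].position} has "
                "inconsistent block shapes"
            )
        rows.append(np.concatenate([b.values for b in blocks]))
    return FeatureTable(
        sites=tuple(sites),
        matrix=np.vstack(rows),
        column_names=tuple(column_names),
        blocks=block_slices,
    )


def table_from_dataframe(df) -> FeatureTable:
    """Rebuild a FeatureTable from a feature CSV read back as a DataFrame.

    Sequences are not stored in the CSV, so sites carry placeholder
    sequences (sufficient for classification and evaluation, which only
    use the matrix and labels).  Block slices are recovered from the
    block-qualified column names.
    """
    meta_cols = ("protein_id", "position", "label")
    feature_cols = [c for c in df.columns if c not in meta_cols]
    sites = []
    for _, row in df.iterrows():
        pos = int(row["position"])
        label = None if row.isna()["label"] else int(row["label"])
        sites.append(
            TargetSite(
                protein_id=str(row["protein_id"]),
                sequence="X" * pos,
                position=pos,
                label=label,
            )
        )
    blocks: dict[str, slice] = {}
    for name in BLOCK_ORDER:
        idx = [
            i
            for i, c in enumerate(feature_cols)
            if c == name or c.startswith(f"{name}_")
        ]
        if idx:
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError(f"columns of block {name} are not contiguous")
            blocks[name] = slice(idx[0], idx[-1] + 1)
    return FeatureTable(
        sites=tuple(sites),
        matrix=df[feature_cols].to_numpy(dtype=float),
        column_names=tuple(feature_cols),
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Normalization

def _normalize_block_rows(values: np.ndarray, scheme: NormScheme) -> np.ndarray:
    """Normalize each row of a block independently; degenerate rows -> 0."""
    if scheme == "zscore":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    elif scheme == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


def normalize_per_site_block(
    table: FeatureTable,
    scheme: NormScheme = "zscore",
    skip_blocks: Sequence[str] = (),
) -> FeatureTable:
    """Normalize each multi-dimensional block within each site.

    Statistics (mean/sd or min/max) are computed over that one site's
    block values, so feature types are normalized independently of each
    other and of every other data point.  One-dimensional blocks (pKa,
    SASA) are never touched.  Degenerate blocks (zero spread) become 0.
    """
    matrix = table.matrix.copy()
    for name, sl in table.blocks.items():
        if sl.stop - sl.start <= 1 or name in skip_blocks:
            continue
        matrix[:, sl] = _normalize_block_rows(matrix[:, sl], scheme)
    return replace(table, matrix=matrix, normalized=scheme)


def normalize_columns_train_test(
    train: FeatureTable, test: FeatureTable
) -> tuple[FeatureTable, FeatureTable]:
    """Per-column z-score with statistics from the training table only.

    Required for margin-based classifiers (SVM); constant columns map
    to zero in both tables.
    """
    if train.column_names != test.column_names:
        raise ValueError("train and test tables have different columns")
    mean = train.matrix.mean(axis=0)
    sd = train.matrix.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)

    def apply(t: FeatureTable) -> FeatureTable:
        z = np.where(sd > 0, (t.matrix - mean) / safe, 0.0)
        return replace(t, matrix=z, normalized="columns")

    return apply(train), apply(test)
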