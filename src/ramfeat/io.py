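"""Readers and writers for every format the pipeline touches.

Sequence input is FASTA; labelled target sites are a three-column TSV;
3-D coordinates come as fixed-width PDB ATOM records (experimental or
comparative-model output); evolutionary profiles are PSI-BLAST ASCII
PSSM files; secondary-structure confidences are PSIPRED ``.ss2`` files;
per-site pKa and SASA scalars are TSVs; the assembled feature matrix is
written as CSV.  All user-facing positions are 1-based.

Writers exist for each input dialect so synthetic fixtures can be laid
down and round-tripped; they emit exactly the layouts the readers parse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ram import StructureCoords

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureTable

__all__ = [
    "SiteRecord",
    "PssmProfile",
    "SsProfile",
    "read_fasta",
    "write_fasta",
    "read_site_table",
    "write_site_table",
    "read_pdb_coords",
    "write_pdb",
    "read_pssm_ascii",
    "write_pssm_ascii",
    "read_ss2",
    "write_ss2",
    "read_scalar_features",
    "write_scalar_features",
    "write_feature_csv",
    "read_feature_csv",
]

#: 3-letter -> 1-letter codes for the 20 standard residues.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: PSI-BLAST residue-column order for the 20 log-odds columns.
PSSM_RESIDUE_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")


@dataclass(frozen=True)
class SiteRecord:
    """One row of a site table: a labelled position in a named protein."""

    protein_id: str
    position: int
    label: int | None


@dataclass(frozen=True)
class PssmProfile:
    """Per-position 20-vector of log-odds substitution scores.

    ``scores`` has shape (L, 20) with columns in ``residue_order``;
    row r is the profile at 1-based sequence position r + 1.
    """

    scores: np.ndarray
    residue_order: tuple[str, ...] = PSSM_RESIDUE_ORDER

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.residue_order):
            raise ValueError("scores must be (L, |residue_order|)")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class SsProfile:
    """Per-position secondary-structure confidence scores.

    ``scores`` has shape (L, 3) in canonical (helix, strand, coil) order.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 3:
            raise ValueError("scores must be (L, 3)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite secondary-structure score")

    def __len__(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``; ids are the first header token."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper().replace("-", "").replace(".", "")
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site tables

def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a TSV of (protein_id, position, label).

    ``label`` may be 0, 1, or empty/NA for prediction-mode sites.
    Duplicate (protein_id, position) pairs and non-binary labels are
    rejected with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    records: list[SiteRecord] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        pos = int(row["position"])
        if pos < 1:
            raise ValueError(f"row {idx + 2}: position {pos} is not 1-based")
        key = (row["protein_id"], pos)
        if key in seen:
            raise ValueError(f"row {idx + 2}: duplicate site {key}")
        seen.add(key)
        raw = row["label"]
        if pd.isna(raw):
            label = None
        else:
            label = int(raw)
            if label not in (0, 1):
                raise ValueError(f"row {idx + 2}: non-binary label {raw!r}")
        records.append(SiteRecord(row["protein_id"], pos, label))
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "position": r.position,
                "label": "" if r.label is None else r.label,
            }
            for r in records
        ],
        columns=["protein_id", "position", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PDB coordinates

def read_pdb_coords(
    path: str | Path,
    target_position: int,
    chain: str | None = None,
    protein_id: str | None = None,
) -> StructureCoords:
    """Extract per-residue CA coordinates and the target cysteine's SG.

    The first model is used; for disordered atoms the first altloc is
    kept.  Residue numbering is taken from the PDB residue sequence
    number.  Residues carrying insertion codes that would collide with
    an existing number are skipped with a warning.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models in PDB file") from None

    if chain is not None:
        if chain not in model:
            raise ValueError(f"{path}: chain {chain!r} not present")
        chains = [model[chain]]
    else:
        chains = list(model.get_chains())[:1]
    if not chains:
        raise ValueError(f"{path}: no chains in first model")

    residues: list[tuple[int, str, tuple[float, float, float]]] = []
    target_sulfur: tuple[float, float, float] | None = None
    seen_positions: set[int] = set()
    skipped_icode = 0
    for residue in chains[0].get_residues():
        hetflag, resseq, icode = residue.get_id()
        resname = residue.get_resname().strip()
        if resname not in THREE_TO_ONE:
            continue
        if resseq in seen_positions:
            skipped_icode += 1
            continue
        if "CA" not in residue:
            continue
        seen_positions.add(resseq)
        # PDB coordinates carry exactly 3 decimals; rounding recovers the
        # written values from the parser's float32 representation
        ca = residue["CA"].get_coord()
        residues.append(
            (
                int(resseq),
                THREE_TO_ONE[resname],
                tuple(round(float(v), 3) for v in ca),
            )
        )
        if resseq == target_position and "SG" in residue:
            sg = residue["SG"].get_coord()
            target_sulfur = tuple(round(float(v), 3) for v in sg)
    if skipped_icode:
        warnings.warn(
            f"{path}: {skipped_icode} residue(s) with duplicate numbering "
            "(insertion codes) skipped",
            stacklevel=2,
        )
    if not residues:
        raise ValueError(f"{path}: no CA records found")
    return StructureCoords(
        protein_id=protein_id or path.stem,
        residues=tuple(residues),
        target_position=target_position,
        target_sulfur=target_sulfur,
    )


def write_pdb(coords: StructureCoords, path: str | Path, chain: str = "A") -> None:
    """Write CA (and the target SG) atoms as fixed-width PDB ATOM records."""
    lines: list[str] = []
    serial = 1

    def atom_line(name: str, resname: str, resseq: int, xyz: tuple[float, float, float]) -> str:
        nonlocal serial
        x, y, z = xyz
        element = name.strip()[0]
        line = (
            f"ATOM  {serial:>5} {name:<4} {resname:>3} {chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
        )
        serial += 1
        return line

    for pos, one, xyz in sorted(coords.residues):
        resname = ONE_TO_THREE.get(one, "UNK")
        lines.append(atom_line(" CA", resname, pos, xyz))
        if pos == coords.target_position and coords.target_sulfur is not None:
            lines.append(atom_line(" SG", resname, pos, coords.target_sulfur))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm_ascii(path: str | Path) -> PssmProfile:
    """Parse the ASCII PSSM written by psiblast's ``-out_ascii_pssm``.

    The first 20 numeric columns per row (the log-odds block) are kept,
    in the residue order stated on the file's column-header line.
    """
    lines = Path(path).read_text().splitlines()
    header_order: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_order is None:
            if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
                header_order = tuple(tokens[:20])
            continue
        if not tokens[0].isdigit():
            continue  # trailing K/lambda statistics block
        if int(tokens[0]) != expected_pos:
            raise ValueError(
                f"{path}:{lineno}: expected position {expected_pos}, got {tokens[0]}"
            )
        if len(tokens) < 22:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(tokens)} fields, need >= 22)"
            )
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
        expected_pos += 1
    if header_order is None or not rows:
        raise ValueError(f"{path}: no PSSM matrix found")
    return PssmProfile(scores=np.array(rows, dtype=float), residue_order=header_order)


def write_pssm_ascii(
    profile: PssmProfile, sequence: str, path: str | Path
) -> None:
    """Write the psiblast ASCII PSSM dialect (log-odds + percentage blocks)."""
    if len(profile) != len(sequence):
        raise ValueError("profile length does not match sequence length")
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
    ]
    letters = "  ".join(profile.residue_order)
    out.append(f"            {letters}   {letters}")
    for i, (residue, row) in enumerate(zip(sequence, profile.scores), start=1):
        scores = " ".join(f"{int(round(v)):>3d}" for v in row)
        pct = " ".join(f"{0:>3d}" for _ in row)
        out.append(f"{i:>5d} {residue}  {scores}  {pct}  0.00 0.00")
    out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PSIPRED .ss2

#: column order in a .ss2 file is (coil, helix, strand)
_SS2_FILE_ORDER = ("C", "H", "E")
#: canonical in-memory order is (helix, strand, coil)
SS_STATE_ORDER = ("H", "E", "C")


def read_ss2(path: str | Path) -> SsProfile:
    """Parse a PSIPRED VFORMAT ``.ss2`` file into canonical (H, E, C) order."""
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(tokens)}")
        coil, helix, strand = (float(t) for t in tokens[3:6])
        rows.append([helix, strand, coil])
    if not rows:
        raise ValueError(f"{path}: empty .ss2 file")
    return SsProfile(scores=np.array(rows, dtype=float))


def write_ss2(profile: SsProfile, sequence: str, path: str | Path) -> None:
    if len(profile) != len(sequence):
        raise ValueError("profile length does not match sequence length")
    out = ["# PSIPRED VFORMAT (PSIPRED V4.0)", ""]
    for i, (residue, (h, e, c)) in enumerate(zip(sequence, profile.scores), start=1):
        state = _SS2_FILE_ORDER[int(np.argmax([c, h, e]))]
        out.append(f"{i:>4d} {residue} {state}  {c:6.3f} {h:6.3f} {e:6.3f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Scalar per-site features (pKa, SASA)

def read_scalar_features(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a TSV of (protein_id, position, value) into a site-keyed map.

    Values pass through untouched — in particular the 99.99 disulfide
    sentinel used for pKa.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if not {"protein_id", "position", "value"}.issubset(df.columns):
        raise ValueError("scalar table must have columns protein_id, position, value")
    result: dict[tuple[str, int], float] = {}
    for idx, row in df.iterrows():
        key = (row["protein_id"], int(row["position"]))
        if key in result:
            raise ValueError(f"row {idx + 2}: duplicate site {key}")
        result[key] = float(row["value"])
    return result


def write_scalar_features(
    values: Mapping[tuple[str, int], float], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {"protein_id": pid, "position": pos, "value": v}
            for (pid, pos), v in values.items()
        ],
        columns=["protein_id", "position", "value"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assembled feature CSV

def write_feature_csv(table: "FeatureTable", path: str | Path) -> None:
    """Write the assembled feature matrix with block-qualified column names.

    The first three columns are protein_id, position, label; feature
    columns follow in the frozen assembly order.
    """
    meta = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in table.sites],
            "position": [s.position for s in table.sites],
            "label": [s.label if s.label is not None else "" for s in table.sites],
        }
    )
    feats = pd.DataFrame(table.matrix, columns=table.column_names)
    pd.concat([meta, feats], axis=1).to_csv(path, index=False, float_format="%.10g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back; label column becomes nullable integer."""
    df = pd.read_csv(path, dtype={"protein_id": str})
    df["label"] = pd.array(
        [None if pd.isna(v) else int(v) for v in df["label"]], dtype="Int64"
    )
    return df
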