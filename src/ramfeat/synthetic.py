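"""Synthetic proteins, structures and feature fixtures with plantable signal.

Everything the pipeline consumes — FASTA sequences, labelled site
tables, PDB coordinate files, PSI-BLAST ASCII PSSMs, PSIPRED ``.ss2``
files and pKa/SASA scalar tables — can be generated here, so the whole
system is exercisable without downloads or external tool runs.

The scientifically meaningful option is the planted signal.  With
``signal_kind="trp_proximity"`` oxidation-susceptible sites get a
tryptophan planted within ``d_near`` sequence positions while
non-susceptible sites keep every tryptophan at least ``d_far`` away;
the label is then a deterministic function of the tryptophan distance
profile, which is exactly what the adjacency-matrix features measure.
(Tryptophan/cysteine proximity is the feature family that dominates
importance rankings on real redox datasets, so recovery of this signal
is the relevant end-to-end check.)  The signal lives in the sequence,
not in any feature column, so recovering it genuinely exercises the
feature extraction.  ``cys_cluster`` plants an extra cysteine the same
way; ``none`` leaves labels independent of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .io import (
    PssmProfile,
    SiteRecord,
    SsProfile,
    write_fasta,
    write_pdb,
    write_pssm_ascii,
    write_scalar_features,
    write_site_table,
    write_ss2,
)
from .ram import StructureCoords, TargetSite

__all__ = [
    "SyntheticSpec",
    "generate_sequences",
    "generate_structure",
    "generate_pssm_fixture",
    "generate_ss2_fixture",
    "generate_scalar_fixture",
    "write_fixture_tree",
]

SignalKind = Literal["trp_proximity", "cys_cluster", "none"]

#: background alphabet excludes C (placed explicitly) and W (planted).
_BACKGROUND = "ARNDQEGHILKMFPSTYV"
_FULL = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic dataset.

    ``n_proteins`` proteins of length uniform in ``length_range``, each
    carrying a number of target cysteines uniform in ``cys_range``.
    Labels are exactly balanced (``positive_fraction`` of sites positive,
    assigned by seeded permutation).  ``signal_strength`` is the
    probability that a site obeys its class's planting rule; 1.0 plants
    deterministically, 0.0 degrades to no signal.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (80, 200)
    cys_range: tuple[int, int] = (2, 2)
    signal_kind: SignalKind = "trp_proximity"
    signal_strength: float = 1.0
    d_near: int = 3
    d_far: int = 15
    positive_fraction: float = 0.5
    seed: int = 0


def _plant_positions(
    length: int, count: int, rng: np.random.Generator, min_gap: int = 8
) -> list[int]:
    """Choose well-separated 1-based positions away from the termini."""
    lo, hi = min(10, length // 4) + 1, length - min(10, length // 4)
    for _ in range(200):
        picks = sorted(rng.integers(lo, hi + 1, size=count).tolist())
        if all(b - a >= min_gap for a, b in zip(picks, picks[1:])):
            return picks
    return list(range(lo, lo + count * min_gap, min_gap))[:count]


def generate_sequences(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], list[TargetSite]]:
    """Generate proteins and labelled target-cysteine sites per ``spec``.

    Returns ``(sequences, sites)``; identical specs give identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    pending: list[tuple[str, int]] = []  # (protein_id, position)
    seq_chars: dict[str, list[str]] = {}

    for p in range(spec.n_proteins):
        pid = f"synt{p:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if spec.signal_kind == "none":
            chars = list(rng.choice(list(_FULL), size=length))
        else:
            chars = list(rng.choice(list(_BACKGROUND), size=length))
        n_cys = int(rng.integers(spec.cys_range[0], spec.cys_range[1] + 1))
        # with a planted signal, target sites must be far enough apart
        # that one site's near-tryptophan cannot enter another negative
        # site's exclusion zone
        min_gap = 8 if spec.signal_kind == "none" else spec.d_far + spec.d_near + 1
        positions = _plant_positions(length, n_cys, rng, min_gap=min_gap)
        for pos in positions:
            chars[pos - 1] = "C"
            pending.append((pid, pos))
        seq_chars[pid] = chars

    # exactly balanced labels via seeded permutation
    n_sites = len(pending)
    n_pos = int(round(spec.positive_fraction * n_sites))
    labels = np.zeros(n_sites, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    if spec.signal_kind in ("trp_proximity", "cys_cluster"):
        planted = "W" if spec.signal_kind == "trp_proximity" else "C"
        negatives = {
            (pid, pos)
            for (pid, pos), lab in zip(pending, labels)
            if lab == 0
        }

        def violates_negative(pid: str, cand: int) -> bool:
            return any(
                q_pid == pid and abs(q_pos - cand) < spec.d_far
                for q_pid, q_pos in negatives
            )

        for (pid, pos), lab in zip(pending, labels):
            if rng.random() > spec.signal_strength:
                continue
            chars = seq_chars[pid]
            length = len(chars)
            if lab == 1:
                offsets = [
                    o
                    for d in range(1, spec.d_near + 1)
                    for o in (-d, d)
                    if 1 <= pos + o <= length
                    and chars[pos + o - 1] != "C"
                    and not violates_negative(pid, pos + o)
                ]
            else:
                offsets = [
                    o
                    for d in range(spec.d_far, spec.d_far + 12)
                    for o in (-d, d)
                    if 1 <= pos + o <= length
                    and chars[pos + o - 1] != "C"
                    and not violates_negative(pid, pos + o)
                ]
            if offsets:
                chosen = offsets[int(rng.integers(len(offsets)))]
                chars[pos + chosen - 1] = planted

    sites: list[TargetSite] = []
    for (pid, pos), lab in zip(pending, labels):
        sequences[pid] = "".join(seq_chars[pid])
    for (pid, pos), lab in zip(pending, labels):
        sites.append(
            TargetSite(
                protein_id=pid,
                sequence=sequences[pid],
                position=pos,
                label=int(lab),
            )
        )
    return sequences, sites


def generate_structure(
    sequence: str, seed: int, target_position: int, protein_id: str = "synthetic"
) -> StructureCoords:
    """Backbone trace as a self-avoiding 3.8 A-step random walk.

    Consecutive alpha carbons sit exactly 3.8 A apart (the trans
    peptide CA-CA distance); steps that would come within 3.0 A of an
    existing CA are rejected and redrawn.  The target cysteine's SG
    atom is placed 1.8 A off its CA in a random direction.  Coordinates
    are rounded to 3 decimals so PDB round-trips are exact.
    """
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    for _ in range(1, len(sequence)):
        prev = coords[-1]
        for _attempt in range(100):
            step = rng.standard_normal(3)
            step *= 3.8 / np.linalg.norm(step)
            cand = prev + step
            d = np.linalg.norm(np.array(coords) - cand, axis=1)
            if d.min() > 3.0:
                break
        coords.append(cand)
    arr = np.round(np.array(coords), 3)
    residues = tuple(
        (i + 1, res, (float(x), float(y), float(z)))
        for i, (res, (x, y, z)) in enumerate(zip(sequence, arr))
    )
    direction = rng.standard_normal(3)
    direction *= 1.8 / np.linalg.norm(direction)
    sg = np.round(arr[target_position - 1] + direction, 3)
    return StructureCoords(
        protein_id=protein_id,
        residues=residues,
        target_position=target_position,
        target_sulfur=(float(sg[0]), float(sg[1]), float(sg[2])),
    )


def generate_pssm_fixture(sequence: str, seed: int) -> PssmProfile:
    """Integer log-odds profile favouring the observed residue."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(-5, 6, size=(len(sequence), 20)).astype(float)
    order = tuple(_FULL)
    for i, residue in enumerate(sequence):
        if residue in order:
            scores[i, order.index(residue)] += 6
    return PssmProfile(scores=scores, residue_order=order)


def generate_ss2_fixture(sequence: str, seed: int) -> SsProfile:
    """Random helix/strand/coil confidences, rows summing to ~1.

    Scores are rounded to 3 decimals to match the ``.ss2`` on-disk
    precision, so write/read round-trips exactly.
    """
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet([2.0, 1.5, 2.5], size=len(sequence))
    return SsProfile(scores=np.round(raw, 3))


def generate_scalar_fixture(
    sites: Sequence[TargetSite],
    seed: int,
    kind: Literal["pka", "sasa"] = "pka",
    sentinel_fraction: float = 0.15,
    label_shift: float = 0.0,
) -> dict[tuple[str, int], float]:
    """Per-site scalar values in the style of thiol pKa or sulfur SASA.

    pKa draws from N(9.0, 1.5) clipped to [0, 14], with a configurable
    fraction replaced by the 99.99 disulfide sentinel; SASA draws from
    |N(10, 8)|.  ``label_shift`` adds its value to positive-site means
    (an optional, directly-planted signal for calibration tests).
    """
    rng = np.random.default_rng(seed)
    values: dict[tuple[str, int], float] = {}
    for site in sites:
        shift = label_shift if site.label == 1 else 0.0
        if kind == "pka":
            if rng.random() < sentinel_fraction:
                v = 99.99
            else:
                v = float(np.clip(rng.normal(9.0 + shift, 1.5), 0.0, 14.0))
        elif kind == "sasa":
            v = float(abs(rng.normal(10.0 + shift, 8.0)))
        else:
            raise ValueError(f"unknown scalar kind {kind!r}")
        values[(site.protein_id, site.position)] = round(v, 2)
    return values


def write_fixture_tree(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input tree for the pipeline under ``outdir``.

    Layout::

        outdir/
          proteins.fa         sites.tsv
          pka.tsv             sasa.tsv
          pdb/<id>_<pos>.pdb  pssm/<id>.pssm   ss2/<id>.ss2

    Returns a map of the paths written.  All randomness derives from
    ``spec.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("pdb", "pssm", "ss2"):
        (outdir / sub).mkdir(exist_ok=True)

    sequences, sites = generate_sequences(spec)
    rng = np.random.default_rng(spec.seed + 1)

    write_fasta(sequences, outdir / "proteins.fa")
    write_site_table(
        [SiteRecord(s.protein_id, s.position, s.label) for s in sites],
        outdir / "sites.tsv",
    )
    for site in sites:
        child = int(rng.integers(0, 2**31 - 1))
        coords = generate_structure(
            site.sequence, child, site.position, site.protein_id
        )
        write_pdb(coords, outdir / "pdb" / f"{site.protein_id}_{site.position}.pdb")
    for pid, seq in sequences.items():
        child = int(rng.integers(0, 2**31 - 1))
        write_pssm_ascii(generate_pssm_fixture(seq, child), seq, outdir / "pssm" / f"{pid}.pssm")
        child = int(rng.integers(0, 2**31 - 1))
        write_ss2(generate_ss2_fixture(seq, child), seq, outdir / "ss2" / f"{pid}.ss2")
    write_scalar_features(
        generate_scalar_fixture(sites, spec.seed + 2, "pka"), outdir / "pka.tsv"
    )
    write_scalar_features(
        generate_scalar_fixture(sites, spec.seed + 3, "sasa"), outdir / "sasa.tsv"
    )
    return {
        "fasta": outdir / "proteins.fa",
        "sites": outdir / "sites.tsv",
        "pdb_dir": outdir / "pdb",
        "pssm_dir": outdir / "pssm",
        "ss2_dir": outdir / "ss2",
        "pka": outdir / "pka.tsv",
        "sasa": outdir / "sasa.tsv",
    }
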