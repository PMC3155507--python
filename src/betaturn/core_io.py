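"""Domain types and readers/writers for every external format the tool touches.

Conventions: positions are 1-based inclusive in all files and logs; internal
indices are 0-based half-open.  Non-standard amino-acid letters are mapped to
``X`` on input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Secondary-structure states: helix, strand, coil.
SS_STATES = "HEC"

#: The eight shape-string states (clustered phi/psi torsion regions).
SHAPE_STATES = "SRUVKATG"

#: Shape alphabet including X for positions without an assignment.
SHAPE_STATES_X = SHAPE_STATES + "X"

#: Column order of the 20 log-odds values in PSI-BLAST ASCII PSSM output.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"


def normalize_sequence(seq: str) -> str:
    """Uppercase *seq* and map every letter outside the 20-letter alphabet to X."""
    seq = seq.upper()
    return "".join(c if c in AA20 else "X" for c in seq)


@dataclass
class ProteinChain:
    """A protein chain and its optional per-residue 1-D annotations.

    ``ss`` is a 3-state secondary-structure string (H/E/C), ``shape`` an
    8-state shape string (S,R,U,V,K,A,T,G) with X marking unassigned
    positions, and ``turn_residue_mask`` flags residues belonging to at
    least one beta-turn.
    """

    id: str
    sequence: str
    ss: str | None = None
    shape: str | None = None
    turn_residue_mask: Sequence[bool] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA20 + "X")
        if bad:
            raise ValueError(f"chain {self.id!r}: illegal residue letters {sorted(bad)}")
        for name, track, alphabet in (
            ("ss", self.ss, set(SS_STATES)),
            ("shape", self.shape, set(SHAPE_STATES_X)),
        ):
            if track is None:
                continue
            if len(track) != len(self.sequence):
                raise ValueError(
                    f"chain {self.id!r}: {name} length {len(track)} != sequence length {len(self.sequence)}"
                )
            bad = set(track) - alphabet
            if bad:
                raise ValueError(f"chain {self.id!r}: illegal {name} characters {sorted(bad)}")
        if self.turn_residue_mask is not None and len(self.turn_residue_mask) != len(self.sequence):
            raise ValueError(f"chain {self.id!r}: turn mask length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMatrix:
    """An N x 20 substitution-propensity profile aligned to a chain.

    ``values`` holds raw PSI-BLAST log-odds integers when ``scaled`` is
    False, or logistic-squashed reals in [0, 1] when True.  Columns follow
    :data:`PSSM_COLUMNS` order.
    """

    chain_id: str
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"PSSM for {self.chain_id!r}: expected N x 20 matrix, got {self.values.shape}")
        if self.scaled and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError(f"PSSM for {self.chain_id!r}: scaled matrix has entries outside [0, 1]")


@dataclass
class CaTrace:
    """Ordered alpha-carbon coordinates (Angstrom) for one chain."""

    chain_id: str
    coords: np.ndarray
    helix_mask: Sequence[bool] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"trace {self.chain_id!r}: expected N x 3 coordinates")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"trace {self.chain_id!r}: non-finite coordinate")
        if self.helix_mask is not None and len(self.helix_mask) != len(self.coords):
            raise ValueError(f"trace {self.chain_id!r}: helix mask length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class ShapeDatabaseEntry:
    """One record of the shape-string database: a sequence and its 8-state shape string."""

    id: str
    sequence: str
    shape: str

    def __post_init__(self) -> None:
        if len(self.shape) != len(self.sequence):
            raise ValueError(
                f"shape db entry {self.id!r}: shape length {len(self.shape)} != sequence length {len(self.sequence)}"
            )
        for pos, c in enumerate(self.shape):
            if c not in SHAPE_STATES:
                raise ValueError(
                    f"shape db entry {self.id!r}: illegal shape character {c!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read a FASTA file into :class:`ProteinChain` objects.

    The header token before the first whitespace becomes the chain id;
    sequences are uppercased and non-standard letters mapped to X.
    Raises on an empty file and on duplicate ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    chains: list[ProteinChain] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate chain id {rec.id!r}")
        seen.add(rec.id)
        chains.append(ProteinChain(id=rec.id, sequence=normalize_sequence(str(rec.seq))))
    return chains


def write_fasta(path: str | Path, chains: Iterable[ProteinChain], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(f">{chain.id}\n")
            for i in range(0, len(chain.sequence), width):
                fh.write(chain.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(path: str | Path, chain: ProteinChain) -> PSSMatrix:
    """Parse a PSI-BLAST ``-Q`` ASCII matrix file for *chain*.

    Only the first 20-column (log-odds) block is kept; trailing weighted
    percentage and information-content columns are ignored.  Row residue
    letters are cross-checked against the chain sequence.
    """
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 22 or not tokens[0].isdigit():
                continue  # header / footer lines
            if len(tokens[1]) != 1 or not tokens[1].isalpha():
                continue
            try:
                values = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric PSSM cell on line {lineno}: {exc}") from None
            letters.append(tokens[1].upper())
            rows.append(values)
    if len(rows) != len(chain.sequence):
        raise ValueError(
            f"{path}: PSSM has {len(rows)} rows but chain {chain.id!r} has {len(chain.sequence)} residues"
        )
    for i, letter in enumerate(letters):
        expect = chain.sequence[i]
        got = letter if letter in AA20 else "X"
        if got != expect:
            raise ValueError(
                f"{path}: residue letter {letter!r} at position {i + 1} disagrees with chain "
                f"{chain.id!r} residue {expect!r}"
            )
    return PSSMatrix(chain_id=chain.id, values=np.array(rows), scaled=False)


def write_pssm_ascii(path: str | Path, chain: ProteinChain, values: np.ndarray) -> None:
    """Write an N x 20 integer log-odds matrix in PSI-BLAST-like ASCII layout."""
    values = np.asarray(values)
    if values.shape != (len(chain.sequence), 20):
        raise ValueError(f"matrix shape {values.shape} does not match chain length {len(chain.sequence)}")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "  ".join(PSSM_COLUMNS) + "\n")
        for i, (letter, row) in enumerate(zip(chain.sequence, values), start=1):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            # trailing info-content columns mimic real PSI-BLAST output
            fh.write(f"{i:5d} {letter}  {cells}  0.36 0.12\n")


# ---------------------------------------------------------------------------
# Shape-string database
# ---------------------------------------------------------------------------

def read_shape_db(path: str | Path) -> list[ShapeDatabaseEntry]:
    """Read the flat shape database: records of three lines '>id', sequence, shape."""
    entries: list[ShapeDatabaseEntry] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty shape database")
    if len(lines) % 3 != 0:
        raise ValueError(f"{path}: record count is not a multiple of 3 lines")
    for i in range(0, len(lines), 3):
        header, seq, shape = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {header!r}")
        entry_id = header[1:].split()[0]
        entries.append(
            ShapeDatabaseEntry(id=entry_id, sequence=normalize_sequence(seq), shape=shape.upper())
        )
    return entries


def write_shape_db(path: str | Path, entries: Iterable[ShapeDatabaseEntry]) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.id}\n{e.sequence}\n{e.shape}\n")


# ---------------------------------------------------------------------------
# Simple per-chain TSV tracks (secondary structure, shape strings, turns)
# ---------------------------------------------------------------------------

def read_ss_tsv(path: str | Path) -> dict[str, str]:
    """Read 'chain_id<TAB>ss_string' lines (predicted H/E/C strings)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chain_id, ss = line.rstrip("\n").split("\t")[:2]
            out[chain_id] = ss.upper()
    return out


def write_ss_tsv(path: str | Path, ss_by_chain: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for chain_id, ss in ss_by_chain.items():
            fh.write(f"{chain_id}\t{ss}\n")


def read_shapes_tsv(path: str | Path) -> dict[str, str]:
    """Read 'chain_id<TAB>shape_string[<TAB>coverage]' lines."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = fields[1].upper()
    return out


def write_shapes_tsv(path: str | Path, shapes: Mapping[str, tuple[str, float]]) -> None:
    """Write per-chain shape strings with their coverage fraction."""
    with open(path, "w") as fh:
        for chain_id, (shape, coverage) in shapes.items():
            fh.write(f"{chain_id}\t{shape}\t{coverage:.4f}\n")


def read_turns_tsv(path: str | Path) -> dict[str, list[int]]:
    """Read beta-turn intervals (chain_id, 1-based start, 1-based end) into 0-based starts."""
    out: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("chain_id") or line.startswith("#"):
                continue
            chain_id, start, end = line.rstrip("\n").split("\t")[:3]
            s, e = int(start) - 1, int(end) - 1
            if e - s != 3:
                raise ValueError(f"{path}: turn {chain_id} {start}-{end} does not span 4 residues")
            out.setdefault(chain_id, []).append(s)
    for starts in out.values():
        starts.sort()
    return out


def write_turns_tsv(path: str | Path, turns_by_chain: Mapping[str, Sequence[int]]) -> None:
    """Write 0-based turn starts as 1-based inclusive (start, end) intervals."""
    with open(path, "w") as fh:
        fh.write("chain_id\tstart\tend\n")
        for chain_id, starts in turns_by_chain.items():
            for s in sorted(starts):
                fh.write(f"{chain_id}\t{s + 1}\t{s + 4}\n")


# ---------------------------------------------------------------------------
# Alpha-carbon traces
# ---------------------------------------------------------------------------

def read_ca_tsv(path: str | Path) -> dict[str, CaTrace]:
    """Read a 4-column 'chain_id x y z' TSV into per-chain traces (row order preserved)."""
    coords: dict[str, list[tuple[float, float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("chain_id"):
                continue
            chain_id, x, y, z = line.rstrip("\n").split("\t")[:4]
            coords.setdefault(chain_id, []).append((float(x), float(y), float(z)))
    return {cid: CaTrace(chain_id=cid, coords=np.array(rows)) for cid, rows in coords.items()}


def write_ca_tsv(path: str | Path, traces: Iterable[CaTrace]) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tx\ty\tz\n")
        for trace in traces:
            for x, y, z in trace.coords:
                fh.write(f"{trace.chain_id}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")


def read_ca_pdb(path: str | Path) -> dict[str, CaTrace]:
    """Extract CA atoms from minimal PDB ATOM records, one trace per chain id."""
    coords: dict[str, list[tuple[float, float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            if line[12:16].strip() != "CA":
                continue
            chain_id = line[21].strip() or "A"
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            coords.setdefault(chain_id, []).append(xyz)
    if not coords:
        raise ValueError(f"{path}: no CA ATOM records found")
    return {cid: CaTrace(chain_id=cid, coords=np.array(rows)) for cid, rows in coords.items()}


def read_helix_mask_tsv(path: str | Path) -> dict[str, list[bool]]:
    """Read 'chain_id<TAB>mask' lines; mask characters H/1 are helix, anything else is not."""
    out: dict[str, list[bool]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chain_id, mask = line.rstrip("\n").split("\t")[:2]
            out[chain_id] = [c in "H1" for c in mask]
    return out


# ---------------------------------------------------------------------------
# Per-residue predictions
# ---------------------------------------------------------------------------

PREDICTIONS_HEADER = "chain_id\tposition\tresidue\tscore\tlabel"


def write_predictions(
    path: str | Path,
    chains: Sequence[ProteinChain],
    per_residue_scores: Sequence[Sequence[float]],
    per_residue_labels: Sequence[Sequence[bool]],
) -> None:
    """Write per-residue turn predictions as TSV (1-based positions, label T/N)."""
    if not (len(chains) == len(per_residue_scores) == len(per_residue_labels)):
        raise ValueError("chains, scores and labels must have the same length")
    with open(path, "w") as fh:
        fh.write(PREDICTIONS_HEADER + "\n")
        for chain, scores, labels in zip(chains, per_residue_scores, per_residue_labels):
            if len(scores) != len(chain.sequence) or len(labels) != len(chain.sequence):
                raise ValueError(f"chain {chain.id!r}: score/label length mismatch")
            for i, (res, score, label) in enumerate(zip(chain.sequence, scores, labels), start=1):
                fh.write(f"{chain.id}\t{i}\t{res}\t{float(score):.6f}\t{'T' if label else 'N'}\n")


def read_predictions(path: str | Path) -> dict[str, tuple[str, list[float], list[bool]]]:
    """Inverse of :func:`write_predictions`: chain_id -> (sequence, scores, labels)."""
    out: dict[str, tuple[str, list[float], list[bool]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != PREDICTIONS_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            chain_id, pos, res, score, label = line.rstrip("\n").split("\t")
            seq, scores, labels = out.setdefault(chain_id, ("", [], []))
            out[chain_id] = (seq + res, scores, labels)
            scores.append(float(score))
            labels.append(label == "T")
    return out


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
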