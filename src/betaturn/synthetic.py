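"""Deterministic generators for every input the pipeline consumes.

These fixtures let the whole tool build, train and evaluate with zero
downloads.  They emulate the statistical structure the architecture
assumes — positive windows forming two compact feature modes, informative
central residues, homologues carrying transferable shape strings — not
real amino-acid composition, real PSSM marginals or real protein geometry
beyond the turn distance predicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import core_io
from .core_io import AA20, CaTrace, ProteinChain, ShapeDatabaseEntry, SHAPE_STATES
from .features import SampleSet
from .shape import HomologyHit
from .turn_labeling import TurnAnnotation, label_beta_turns, turn_start_set_to_mask

#: Extended-chain step between consecutive alpha-carbons, Angstrom.
CA_STEP = 3.8


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults mirror the conditions the architecture was designed for:
    roughly a quarter of residues inside turns (so window samples come out
    near a 1:3 positive:negative ratio), positives forming two compact
    modes separated by ``cluster_separation`` within-cluster standard
    deviations, and database homologues mutated at ``db_mutation_rate``.
    """

    n_chains: int = 48
    chain_length_range: tuple[int, int] = (44, 60)
    turn_density: float = 0.25
    cluster_separation: float = 10.0
    noise_sd: float = 0.03
    db_mutation_rate: float = 0.1
    n_features: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.chain_length_range
        if lo < 12:
            raise ValueError("chains must have at least 12 residues (one window plus margin)")
        if not (0 <= self.turn_density <= 1 and 0 <= self.db_mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chain_length_range"] = list(self.chain_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        d["chain_length_range"] = tuple(d["chain_length_range"])
        return cls(**d)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

#: In-plane offsets of the 6-residue hairpin template inserted at a turn start.
_TURN_TEMPLATE = np.array(
    [
        (0.0, 0.0),
        (CA_STEP, 0.0),
        (2 * CA_STEP, 0.0),
        (CA_STEP, CA_STEP),       # d(start, start+3) = 3.8*sqrt(2) ~ 5.4 < 7
        (CA_STEP, 2 * CA_STEP),
        (2 * CA_STEP, 3 * CA_STEP),
    ]
)

#: Minimum spacing between requested turn starts the template construction supports.
MIN_TURN_GAP = 6


def make_geometric_chain(
    length: int, turn_starts: Sequence[int], seed: int = 0
) -> tuple[ProteinChain, CaTrace, TurnAnnotation]:
    """Build a Ca trace whose turn set is exactly *turn_starts*.

    The backbone walks an extended line (3.8 Angstrom steps, so
    d(i, i+3) = 11.4 > 7 everywhere) and inserts a hairpin template at each
    requested start, bringing exactly that quadruple under the 7 Angstrom
    cutoff.  The sequence is random; the helix mask is all false.  The
    construction is verified against the distance predicate before
    returning.
    """
    starts = sorted(turn_starts)
    for s in starts:
        if s < 0 or s + 3 >= length:
            raise ValueError(f"turn start {s} does not fit a chain of length {length}")
    for a, b in zip(starts, starts[1:]):
        if b - a < MIN_TURN_GAP:
            raise ValueError(
                f"infeasible geometry: turn starts {a} and {b} closer than {MIN_TURN_GAP} residues"
            )
    coords = np.zeros((length, 3))
    cursor = np.zeros(3)
    pending = list(starts)
    i = 0
    while i < length:
        if pending and i == pending[0]:
            s = pending.pop(0)
            for j, (dx, dy) in enumerate(_TURN_TEMPLATE):
                if s + j < length:
                    coords[s + j] = cursor + np.array([dx, dy, 0.0])
            last = min(s + len(_TURN_TEMPLATE) - 1, length - 1)
            cursor = coords[last]
            i = last + 1
        else:
            coords[i] = cursor
            i += 1
            cursor = cursor + np.array([CA_STEP, 0.0, 0.0])
        if i < length:
            cursor = coords[i - 1] + np.array([CA_STEP, 0.0, 0.0])
    rng = np.random.default_rng(seed)
    chain = ProteinChain(
        id=f"syn{seed}",
        sequence=_random_sequence(rng, length),
        turn_residue_mask=turn_start_set_to_mask(starts, length),
    )
    trace = CaTrace(chain_id=chain.id, coords=coords, helix_mask=[False] * length)
    annotation = label_beta_turns(trace)
    if annotation.turn_starts != starts:
        raise RuntimeError(
            f"geometry construction failed: requested {starts}, realized {annotation.turn_starts}"
        )
    return chain, trace, annotation


# ---------------------------------------------------------------------------
# Feature world (planted two-mode positives)
# ---------------------------------------------------------------------------

def make_feature_world(spec: FixtureSpec) -> tuple[SampleSet, np.ndarray, np.ndarray]:
    """Draw window-like feature vectors with two planted positive modes.

    Positive samples come from two compact Gaussian modes separated by
    ``spec.cluster_separation`` within-mode standard deviations along a
    random direction; negatives are uniform background over the unit cube.
    Sample counts derive from the chain geometry (one window per residue
    position minus window-size-1) and ``turn_density`` sets the positive
    fraction.  Returns (samples, planted_labels, planted_cluster_ids) with
    cluster id -1 for negatives.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_chains)
    windows_per_chain = np.maximum(lengths - 7, 0)
    n_total = int(windows_per_chain.sum())
    n_pos = int(round(spec.turn_density * n_total))
    n_neg = n_total - n_pos
    d = spec.n_features

    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    center = np.full(d, 0.5)
    half_gap = 0.5 * spec.cluster_separation * spec.noise_sd
    c1 = center + half_gap * direction
    c2 = center - half_gap * direction

    n1 = n_pos // 2 + n_pos % 2
    n2 = n_pos // 2
    pos1 = c1 + spec.noise_sd * rng.normal(size=(n1, d))
    pos2 = c2 + spec.noise_sd * rng.normal(size=(n2, d))
    negatives = rng.uniform(0.0, 1.0, size=(n_neg, d))

    X = np.clip(np.vstack([pos1, pos2, negatives]), 0.0, 1.0)
    y = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    cluster_ids = np.concatenate(
        [np.zeros(n1, dtype=int), np.ones(n2, dtype=int), np.full(n_neg, -1, dtype=int)]
    )
    perm = rng.permutation(n_total)
    X, y, cluster_ids = X[perm], y[perm], cluster_ids[perm]

    chain_ids = []
    starts = []
    offset = 0
    for c, nw in enumerate(windows_per_chain):
        chain_ids.extend([f"chain{c:03d}"] * int(nw))
        starts.extend(range(int(nw)))
        offset += int(nw)
    samples = SampleSet(X=X, y=y, chain_ids=chain_ids, starts=np.array(starts), scheme=None)
    return samples, y, cluster_ids


# ---------------------------------------------------------------------------
# Shape world (homology-transfer fixture)
# ---------------------------------------------------------------------------

def _random_shape(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(SHAPE_STATES), size=length))


def make_shape_world(
    spec: FixtureSpec, db_coverage: float = 1.0
) -> tuple[list[ProteinChain], list[ShapeDatabaseEntry], dict[str, str], Callable]:
    """Targets with known shape strings plus a mutated-copy database.

    Each database entry is a copy of one target (under a new id) whose
    sequence AND shape string carry point mutations at
    ``spec.db_mutation_rate``; with ``db_coverage`` < 1 entries are
    truncated to the first fraction of the target, leaving X regions after
    transfer.  The returned mock search backend reports one hit per entry
    derived from the queried target, aligning the covered positions
    one-to-one, with surrogate e-values exp(-matches) — monotone in the
    mutation count.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_length_range
    targets: list[ProteinChain] = []
    reference: dict[str, str] = {}
    db: list[ShapeDatabaseEntry] = []
    parent: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for c in range(spec.n_chains):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        shape = _random_shape(rng, length)
        cid = f"t{c:03d}"
        targets.append(ProteinChain(id=cid, sequence=seq))
        reference[cid] = shape
        cov = max(4, int(round(db_coverage * length)))
        mut_seq = list(seq[:cov])
        mut_shape = list(shape[:cov])
        for i in range(cov):
            if rng.random() < spec.db_mutation_rate:
                mut_seq[i] = str(rng.choice([a for a in AA20 if a != mut_seq[i]]))
            if rng.random() < spec.db_mutation_rate:
                mut_shape[i] = str(rng.choice([s for s in SHAPE_STATES if s != mut_shape[i]]))
        db_id = f"db_{cid}"
        db.append(ShapeDatabaseEntry(id=db_id, sequence="".join(mut_seq), shape="".join(mut_shape)))
        parent[db_id] = cid
        offsets[db_id] = 0

    def mock_backend(chain: ProteinChain, entries: Sequence[ShapeDatabaseEntry]) -> list[HomologyHit]:
        hits: list[HomologyHit] = []
        for entry in entries:
            if parent.get(entry.id) != chain.id:
                continue
            pairs = [(i, i) for i in range(min(len(entry.sequence), len(chain.sequence)))]
            matches = sum(1 for t, d in pairs if chain.sequence[t] == entry.sequence[d])
            hits.append(
                HomologyHit(
                    target_id=chain.id,
                    db_id=entry.id,
                    e_value=max(float(np.exp(-matches)), 5e-324),
                    aligned_pairs=pairs,
                )
            )
        return hits

    mock_backend.name = "mock"  # type: ignore[attr-defined]
    return targets, db, reference, mock_backend


# ---------------------------------------------------------------------------
# Full on-disk study
# ---------------------------------------------------------------------------

def _place_turn_starts(rng: np.random.Generator, length: int, density: float) -> list[int]:
    """Random non-overlapping turn starts at roughly density*length/4 turns."""
    n_turns = max(1, int(round(density * length / 4)))
    starts: list[int] = []
    candidates = list(range(2, length - 5))
    rng.shuffle(candidates)
    for c in candidates:
        if len(starts) >= n_turns:
            break
        if all(abs(c - s) >= MIN_TURN_GAP for s in starts):
            starts.append(c)
    return sorted(starts)


def make_full_study(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a complete miniature study in the tool's external formats.

    Produces chains.fasta, per-chain <id>.pssm files, ss.tsv, shapes.db,
    turns.tsv, ca.tsv and manifest.json under *out_dir*.  The synthetic
    PSSM plants a mean shift on turn-residue rows so the planted signal
    survives window encoding; secondary-structure and shape tracks are
    noisy functions of the turn mask.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_length_range

    chains: list[ProteinChain] = []
    traces: list[CaTrace] = []
    turns_by_chain: dict[str, list[int]] = {}
    ss_by_chain: dict[str, str] = {}
    db_entries: list[ShapeDatabaseEntry] = []
    manifest_chains = []

    for c in range(spec.n_chains):
        length = int(rng.integers(lo, hi + 1))
        starts = _place_turn_starts(rng, length, spec.turn_density)
        chain, trace, annotation = make_geometric_chain(
            length, starts, seed=int(rng.integers(0, 2**31 - 1))
        )
        chain.id = f"c{c:03d}"
        trace.chain_id = chain.id
        mask = np.array(annotation.residue_mask)

        # secondary structure: coil on turns, helix/strand elsewhere, 10% noise
        ss = np.where(mask, "C", np.where(rng.random(length) < 0.5, "H", "E"))
        noise = rng.random(length) < 0.10
        ss[noise] = rng.choice(list("HEC"), size=int(noise.sum()))
        ss_by_chain[chain.id] = "".join(ss)

        # reference shape string: turn-flavored states on turns, 10% noise
        shape = np.where(
            mask,
            rng.choice(list("TK"), size=length),
            rng.choice(list("SRA"), size=length),
        )
        noise = rng.random(length) < 0.10
        shape[noise] = rng.choice(list(SHAPE_STATES), size=int(noise.sum()))
        ref_shape = "".join(shape)

        # database homologue: mutated copy of the chain under a new id
        mut_seq = list(chain.sequence)
        for i in range(length):
            if rng.random() < spec.db_mutation_rate:
                mut_seq[i] = str(rng.choice([a for a in AA20 if a != mut_seq[i]]))
        db_entries.append(
            ShapeDatabaseEntry(id=f"db_{chain.id}", sequence="".join(mut_seq), shape=ref_shape)
        )

        # synthetic PSSM: background integers, +5 shift on the first 8
        # columns of turn-residue rows to plant the signal
        pssm = rng.integers(-7, 8, size=(length, 20)).astype(float)
        pssm[mask, :8] += 5
        core_io.write_pssm_ascii(pssm_dir / f"{chain.id}.pssm", chain, pssm)

        chains.append(chain)
        traces.append(trace)
        turns_by_chain[chain.id] = annotation.turn_starts
        manifest_chains.append(
            {
                "id": chain.id,
                "length": length,
                "turn_starts_0based": annotation.turn_starts,
                "n_turns": len(annotation.turn_starts),
            }
        )

    core_io.write_fasta(out / "chains.fasta", chains)
    core_io.write_ss_tsv(out / "ss.tsv", ss_by_chain)
    core_io.write_shape_db(out / "shapes.db", db_entries)
    core_io.write_turns_tsv(out / "turns.tsv", turns_by_chain)
    core_io.write_ca_tsv(out / "ca.tsv", traces)

    manifest = {
        "spec": spec.to_dict(),
        "n_chains": spec.n_chains,
        "total_turns": sum(len(v) for v in turns_by_chain.values()),
        "chains": manifest_chains,
        "files": {
            "fasta": "chains.fasta",
            "pssm_dir": "pssm",
            "ss": "ss.tsv",
            "shape_db": "shapes.db",
            "turns": "turns.tsv",
            "ca": "ca.tsv",
        },
    }
    core_io.write_json(out / "manifest.json", manifest)
    return manifest
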