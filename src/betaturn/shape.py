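"""Shape-string prediction by e-value-ranked greedy homology transfer.

A target chain is searched against a database of sequences with known
8-state shape strings.  Hits below an e-value threshold are ranked
ascending; walking down the ranking, each hit's aligned database shape
characters are copied onto the still-unassigned target positions.  What
remains uncovered is marked X.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinChain, ShapeDatabaseEntry, SHAPE_STATES_X

logger = logging.getLogger(__name__)

#: Default e-value inclusion threshold for homologous hits.
E_VALUE_THRESHOLD = 1e-5

#: A search backend maps (chain, database) to candidate hits.
SearchBackend = Callable[[ProteinChain, Sequence[ShapeDatabaseEntry]], "list[HomologyHit]"]


@dataclass
class HomologyHit:
    """One local alignment between a target chain and a database entry.

    ``aligned_pairs`` lists (target_pos, db_pos) 0-based index pairs for
    matched columns only; gap columns are absent and both coordinate
    sequences are strictly increasing.
    """

    target_id: str
    db_id: str
    e_value: float
    aligned_pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValueError(f"hit {self.target_id}->{self.db_id}: e-value must be positive")
        for (t0, d0), (t1, d1) in zip(self.aligned_pairs, self.aligned_pairs[1:]):
            if t1 <= t0 or d1 <= d0:
                raise ValueError(
                    f"hit {self.target_id}->{self.db_id}: aligned pairs not strictly increasing"
                )


@dataclass
class ShapeAssignment:
    """A predicted shape string with per-position provenance and coverage."""

    chain_id: str
    shape: str
    source: list[str | None]
    coverage_fraction: float

    def __post_init__(self) -> None:
        if len(self.shape) != len(self.source):
            raise ValueError("shape and source length mismatch")
        bad = set(self.shape) - set(SHAPE_STATES_X)
        if bad:
            raise ValueError(f"illegal shape characters {sorted(bad)}")
        for c, src in zip(self.shape, self.source):
            if (c == "X") != (src is None):
                raise ValueError("position has a source iff its shape character is not X")


def filter_and_rank_hits(
    hits: Iterable[HomologyHit], e_threshold: float = E_VALUE_THRESHOLD
) -> list[HomologyHit]:
    """Keep hits with e-value strictly below *e_threshold*, sorted ascending.

    Ties on e-value are broken by db_id lexicographically for determinism.
    """
    kept = [h for h in hits if h.e_value < e_threshold]
    return sorted(kept, key=lambda h: (h.e_value, h.db_id))


def assign_shape_string(
    target_length: int,
    ranked_hits: Sequence[HomologyHit],
    db_entries: Mapping[str, ShapeDatabaseEntry],
    chain_id: str = "",
) -> ShapeAssignment:
    """Greedy transfer: walk the ranked hits, filling only still-empty positions.

    For each aligned pair (t, d) of each hit in rank order, target position t
    receives the database shape character at d unless an earlier (better
    ranked) hit already claimed it.  Unclaimed positions become X.
    """
    shape: list[str] = ["X"] * target_length
    source: list[str | None] = [None] * target_length
    for hit in ranked_hits:
        entry = db_entries[hit.db_id]
        for t, d in hit.aligned_pairs:
            if t < 0 or t >= target_length:
                raise ValueError(f"hit {hit.target_id}->{hit.db_id}: target position {t} out of range")
            if d < 0 or d >= len(entry.shape):
                raise ValueError(
                    f"hit {hit.target_id}->{hit.db_id}: db position {d} out of range for entry "
                    f"{entry.id!r} of length {len(entry.shape)}"
                )
            if source[t] is None:
                shape[t] = entry.shape[d]
                source[t] = hit.db_id
    covered = sum(1 for s in source if s is not None)
    return ShapeAssignment(
        chain_id=chain_id,
        shape="".join(shape),
        source=source,
        coverage_fraction=covered / target_length if target_length else 0.0,
    )


def predict_shape_string(
    chain: ProteinChain,
    db: Sequence[ShapeDatabaseEntry],
    backend: SearchBackend,
    e_threshold: float = E_VALUE_THRESHOLD,
    exclude_identical_sequences: bool = False,
) -> ShapeAssignment:
    """Search *chain* against *db* and transfer shape characters greedily.

    Self-hits (db id equal to the chain id, and optionally entries with a
    sequence identical to the chain) are excluded before ranking.
    """
    try:
        hits = backend(chain, db)
    except Exception as exc:
        name = getattr(backend, "name", type(backend).__name__)
        raise RuntimeError(f"shape-string search backend {name!r} failed: {exc}") from exc
    excluded = {e.id for e in db if e.id == chain.id}
    if exclude_identical_sequences:
        excluded |= {e.id for e in db if e.sequence == chain.sequence}
    hits = [h for h in hits if h.db_id not in excluded]
    ranked = filter_and_rank_hits(hits, e_threshold)
    entries = {e.id: e for e in db}
    return assign_shape_string(len(chain.sequence), ranked, entries, chain_id=chain.id)


def shape_accuracy(
    predicted: ShapeAssignment | str, reference_shape: str, covered_only: bool = False
) -> float:
    """Fraction of positions where the predicted shape character matches the reference.

    X never matches.  By default the denominator is all positions; with
    ``covered_only`` only non-X (assigned) positions are counted.
    """
    pred = predicted.shape if isinstance(predicted, ShapeAssignment) else predicted
    if len(pred) != len(reference_shape):
        raise ValueError(f"length mismatch: predicted {len(pred)} vs reference {len(reference_shape)}")
    if covered_only:
        positions = [i for i, c in enumerate(pred) if c != "X"]
        if not positions:
            return 0.0
    else:
        positions = range(len(pred))
        if not len(pred):
            raise ValueError("empty shape strings")
    matches = sum(1 for i in positions if pred[i] != "X" and pred[i] == reference_shape[i])
    return matches / len(positions)


# ---------------------------------------------------------------------------
# Search backends
# ---------------------------------------------------------------------------

class BuiltinAlignmentBackend:
    """Deterministic local-alignment search for desk-scale use.

    Smith-Waterman-style local alignment (BLOSUM62, affine gaps) via
    Biopython's PairwiseAligner, with a Karlin-Altschul-style surrogate
    e-value ``K * m * n * exp(-lambda * score)``.  The surrogate preserves
    score order, which is all the greedy transfer consumes; it is not a
    calibrated database e-value.
    """

    name = "builtin"

    def __init__(
        self,
        open_gap_score: float = -11.0,
        extend_gap_score: float = -1.0,
        karlin_lambda: float = 0.267,
        karlin_k: float = 0.041,
    ) -> None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = open_gap_score
        aligner.extend_gap_score = extend_gap_score
        self.aligner = aligner
        self.karlin_lambda = karlin_lambda
        self.karlin_k = karlin_k

    def _e_value(self, score: float, m: int, n: int) -> float:
        e = self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)
        return max(e, 5e-324)  # keep strictly positive

    def __call__(
        self, chain: ProteinChain, db: Sequence[ShapeDatabaseEntry]
    ) -> list[HomologyHit]:
        hits: list[HomologyHit] = []
        for entry in db:
            alignments = self.aligner.align(chain.sequence, entry.sequence)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if aln.score <= 0:
                continue
            pairs: list[tuple[int, int]] = []
            for (t0, t1), (d0, d1) in zip(*aln.aligned):
                pairs.extend(zip(range(t0, t1), range(d0, d1)))
            if not pairs:
                continue
            hits.append(
                HomologyHit(
                    target_id=chain.id,
                    db_id=entry.id,
                    e_value=self._e_value(aln.score, len(chain.sequence), len(entry.sequence)),
                    aligned_pairs=pairs,
                )
            )
        return hits


class PsiBlastBackend:
    """Adapter running an external ``psiblast`` binary against the shape database.

    The database is written to a temporary FASTA, formatted with
    ``makeblastdb``, searched with PSI-BLAST (XML output), and HSP
    alignments converted to aligned index pairs.  Iteration count is
    configurable; the default single iteration matches a plain
    profile-free search against the small transfer database.
    """

    name = "psiblast"

    def __init__(self, num_iterations: int = 1, evalue_cap: float = 10.0) -> None:
        self.num_iterations = num_iterations
        self.evalue_cap = evalue_cap

    def __call__(
        self, chain: ProteinChain, db: Sequence[ShapeDatabaseEntry]
    ) -> list[HomologyHit]:
        import subprocess
        import tempfile
        from pathlib import Path

        from Bio.Blast import NCBIXML

        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            db_fa = tmp_path / "db.fa"
            with open(db_fa, "w") as fh:
                for e in db:
                    fh.write(f">{e.id}\n{e.sequence}\n")
            query_fa = tmp_path / "query.fa"
            query_fa.write_text(f">{chain.id}\n{chain.sequence}\n")
            subprocess.run(
                ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
                check=True,
                capture_output=True,
            )
            out_xml = tmp_path / "out.xml"
            subprocess.run(
                [
                    "psiblast",
                    "-query", str(query_fa),
                    "-db", str(db_fa),
                    "-num_iterations", str(self.num_iterations),
                    "-evalue", str(self.evalue_cap),
                    "-outfmt", "5",
                    "-out", str(out_xml),
                ],
                check=True,
                capture_output=True,
            )
            hits: list[HomologyHit] = []
            with open(out_xml) as fh:
                for record in NCBIXML.parse(fh):
                    for alignment in record.alignments:
                        db_id = alignment.hit_def.split()[0]
                        best = None
                        for hsp in alignment.hsps:
                            if best is None or hsp.expect < best.expect:
                                best = hsp
                        if best is None:
                            continue
                        pairs: list[tuple[int, int]] = []
                        t, d = best.query_start - 1, best.sbjct_start - 1
                        for qc, sc in zip(best.query, best.sbjct):
                            if qc != "-" and sc != "-":
                                pairs.append((t, d))
                            if qc != "-":
                                t += 1
                            if sc != "-":
                                d += 1
                        if not pairs:
                            continue
                        hits.append(
                            HomologyHit(
                                target_id=chain.id,
                                db_id=db_id,
                                e_value=max(float(best.expect), 5e-324),
                                aligned_pairs=pairs,
                            )
                        )
            # keep only the first (final-iteration) record's hits per db id
            dedup: dict[str, HomologyHit] = {}
            for h in hits:
                if h.db_id not in dedup or h.e_value < dedup[h.db_id].e_value:
                    dedup[h.db_id] = h
            return list(dedup.values())


def get_backend(name: str, **kwargs) -> SearchBackend:
    if name == "builtin":
        return BuiltinAlignmentBackend(**kwargs)
    if name == "psiblast":
        return PsiBlastBackend(**kwargs)
    raise ValueError(f"unknown search backend {name!r}")


# ---------------------------------------------------------------------------
# Redundancy reduction (naive identity filter for small fixture sets)
# ---------------------------------------------------------------------------

def filter_by_identity(
    entries: Sequence[ShapeDatabaseEntry], max_identity: float = 0.30
) -> list[ShapeDatabaseEntry]:
    """Greedy all-vs-all identity filter for small entry sets.

    Entries are kept in input order; an entry is dropped when its global
    alignment identity (matches / shorter length) to any kept entry exceeds
    *max_identity*.  Quadratic; intended for fixture-scale databases only.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    kept: list[ShapeDatabaseEntry] = []
    for entry in entries:
        redundant = False
        for other in kept:
            aln = aligner.align(entry.sequence, other.sequence)[0]
            matches = sum(
                1
                for (a0, a1), (b0, b1) in zip(*aln.aligned)
                for i, j in zip(range(a0, a1), range(b0, b1))
                if entry.sequence[i] == other.sequence[j]
            )
            identity = matches / min(len(entry.sequence), len(other.sequence))
            if identity > max_identity:
                redundant = True
                break
        if not redundant:
            kept.append(entry)
    return kept
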