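"""Ground-truth beta-turn annotation from alpha-carbon geometry.

A beta-turn is four consecutive residues i..i+3, not forming an alpha-helix,
with d(Ca_i, Ca_{i+3}) < 7 Angstrom.  These labels are self-consistent
geometric ground truth; they approximate, but do not reproduce, the
hydrogen-bond and dihedral criteria of structure-annotation programs such
as PROMOTIF (turn-type classification is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import CaTrace

#: Default Ca(i)..Ca(i+3) distance cutoff in Angstrom (strict inequality).
DISTANCE_CUTOFF_A = 7.0


@dataclass
class TurnAnnotation:
    """Sorted 0-based turn start indices and the per-residue union mask."""

    chain_id: str
    turn_starts: list[int]
    residue_mask: list[bool]

    def __post_init__(self) -> None:
        n = len(self.residue_mask)
        for s in self.turn_starts:
            if s + 3 >= n:
                raise ValueError(f"turn start {s} overruns chain of length {n}")
        self.turn_starts = sorted(self.turn_starts)


def turn_start_set_to_mask(turn_starts: Sequence[int], length: int) -> list[bool]:
    """Union-of-intervals residue mask: residue r is flagged iff r lies in some [i, i+3]."""
    mask = [False] * length
    for s in turn_starts:
        if s < 0 or s + 3 >= length:
            raise ValueError(f"turn start {s} invalid for chain length {length}")
        for r in range(s, s + 4):
            mask[r] = True
    return mask


def label_beta_turns(
    trace: CaTrace,
    distance_cutoff_A: float = DISTANCE_CUTOFF_A,
    helix_mode: str = "all",
) -> TurnAnnotation:
    """Label beta-turn starts on a Ca trace.

    Start i qualifies iff ``|Ca_i - Ca_{i+3}| < distance_cutoff_A`` (strict)
    and the quadruple is not helical.  ``helix_mode`` controls the helix
    exclusion: ``"all"`` rejects a candidate only when all four residues are
    flagged helix (the weakest reading), ``"any"`` rejects when any of the
    four is helix.  A missing helix mask treats every residue as non-helix.
    Traces shorter than four residues yield an empty annotation.
    """
    if helix_mode not in ("all", "any"):
        raise ValueError(f"unknown helix_mode {helix_mode!r}")
    n = len(trace)
    if n < 4:
        return TurnAnnotation(chain_id=trace.chain_id, turn_starts=[], residue_mask=[False] * n)
    helix = (
        np.asarray(trace.helix_mask, dtype=bool)
        if trace.helix_mask is not None
        else np.zeros(n, dtype=bool)
    )
    coords = trace.coords
    d = np.linalg.norm(coords[3:] - coords[:-3], axis=1)
    starts: list[int] = []
    for i in range(n - 3):
        if d[i] >= distance_cutoff_A:
            continue
        quad = helix[i : i + 4]
        excluded = quad.all() if helix_mode == "all" else quad.any()
        if not excluded:
            starts.append(i)
    return TurnAnnotation(
        chain_id=trace.chain_id,
        turn_starts=starts,
        residue_mask=turn_start_set_to_mask(starts, n),
    )
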