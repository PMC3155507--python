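"""Window feature encoding.

Each sample is a sliding window of 8 residues whose per-residue features are
concatenated N-terminus to C-terminus: 20 logistic-scaled PSSM values, a
3-state one-hot secondary-structure code (H, E, C) and a 9-state one-hot
shape-string code (S, R, U, V, K, A, T, G, X).  A window is positive when
its central four residues form a beta-turn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import ProteinChain, PSSMatrix, SS_STATES, SHAPE_STATES_X

#: Window length used in the headline model.
DEFAULT_WINDOW_SIZE = 8


@dataclass(frozen=True)
class EncodingScheme:
    """Which feature tracks are enabled and how wide the window is.

    The per-residue width is 20*use_pssm + 3*use_ss + 9*use_shape; the full
    sample vector has window_size times that many entries.
    """

    window_size: int = DEFAULT_WINDOW_SIZE
    use_pssm: bool = True
    use_ss: bool = True
    use_shape: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 4 or self.window_size % 2 != 0:
            raise ValueError("window_size must be even and >= 4 so the central four are well-defined")
        if not (self.use_pssm or self.use_ss or self.use_shape):
            raise ValueError("at least one feature track must be enabled")

    @property
    def per_residue_width(self) -> int:
        return 20 * self.use_pssm + 3 * self.use_ss + 9 * self.use_shape

    @property
    def n_features(self) -> int:
        return self.window_size * self.per_residue_width

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingScheme":
        return cls(**d)


@dataclass
class WindowSample:
    """One window's concatenated feature vector, its label and provenance."""

    chain_id: str
    start: int
    features: np.ndarray
    label: bool


def scale_pssm(raw: PSSMatrix) -> PSSMatrix:
    """Squash raw log-odds into [0, 1] with the standard logistic 1/(1+exp(-x)).

    Double scaling is forbidden: an already-scaled matrix raises.
    """
    if raw.scaled:
        raise ValueError(f"PSSM for {raw.chain_id!r} is already scaled")
    with np.errstate(over="ignore"):
        values = 1.0 / (1.0 + np.exp(-raw.values))
    return PSSMatrix(chain_id=raw.chain_id, values=values, scaled=True)


def encode_ss(ss: str) -> np.ndarray:
    """One-hot encode an H/E/C string: helix (1,0,0), strand (0,1,0), coil (0,0,1)."""
    out = np.zeros((len(ss), 3))
    for i, c in enumerate(ss):
        j = SS_STATES.find(c)
        if j < 0:
            raise ValueError(f"illegal secondary-structure character {c!r} at position {i + 1}")
        out[i, j] = 1.0
    return out


def encode_shape(shape: str) -> np.ndarray:
    """One-hot encode a shape string over S,R,U,V,K,A,T,G,X (X in the last column)."""
    out = np.zeros((len(shape), 9))
    for i, c in enumerate(shape):
        j = SHAPE_STATES_X.find(c)
        if j < 0:
            raise ValueError(f"illegal shape character {c!r} at position {i + 1}")
        out[i, j] = 1.0
    return out


def central_four(window_start: int, window_size: int = DEFAULT_WINDOW_SIZE) -> range:
    """Chain positions of the central four residues of a window."""
    offset = window_size // 2 - 2
    return range(window_start + offset, window_start + offset + 4)


def window_label(
    turn_starts: Sequence[int],
    window_start: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    any_overlap: bool = False,
) -> bool:
    """Is a window positive (its central four residues form a beta-turn)?

    Default: positive iff a turn starts exactly at the first central
    position, so the turn's four residues coincide with the central four.
    With ``any_overlap`` a window is positive when any turn interval
    intersects the central four (a looser reading).
    """
    central = central_four(window_start, window_size)
    if any_overlap:
        return any(t <= central[-1] and t + 3 >= central[0] for t in turn_starts)
    return central[0] in set(turn_starts)


def slice_windows(
    chain: ProteinChain,
    pssm_scaled: PSSMatrix | None,
    scheme: EncodingScheme,
    turn_starts: Sequence[int],
    any_overlap: bool = False,
) -> list[WindowSample]:
    """Slide the window N-terminus to C-terminus and emit one sample per fit.

    No terminal padding: a chain of length L yields max(0, L - window_size + 1)
    samples.  The per-residue block layout is [PSSM | SS | shape] for the
    enabled tracks, in that fixed order.
    """
    L = len(chain.sequence)
    tracks: list[np.ndarray] = []
    if scheme.use_pssm:
        if pssm_scaled is None:
            raise ValueError(f"chain {chain.id!r}: missing PSSM track")
        if not pssm_scaled.scaled:
            raise ValueError(f"chain {chain.id!r}: PSSM must be scaled before encoding")
        if len(pssm_scaled.values) != L:
            raise ValueError(f"chain {chain.id!r}: PSSM row count mismatch")
        tracks.append(pssm_scaled.values)
    if scheme.use_ss:
        if chain.ss is None:
            raise ValueError(f"chain {chain.id!r}: missing secondary-structure track")
        tracks.append(encode_ss(chain.ss))
    if scheme.use_shape:
        if chain.shape is None:
            raise ValueError(f"chain {chain.id!r}: missing shape-string track")
        tracks.append(encode_shape(chain.shape))
    per_residue = np.hstack(tracks)  # L x per_residue_width
    w = scheme.window_size
    samples: list[WindowSample] = []
    for start in range(0, L - w + 1):
        feats = per_residue[start : start + w].reshape(-1)
        samples.append(
            WindowSample(
                chain_id=chain.id,
                start=start,
                features=feats,
                label=window_label(turn_starts, start, w, any_overlap=any_overlap),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Sample container
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """A stacked matrix of window samples with provenance and its encoding scheme.

    ``scheme`` may be None for feature vectors that did not come from the
    window encoder (e.g. synthetic feature worlds).
    """

    X: np.ndarray
    y: np.ndarray
    chain_ids: list[str]
    starts: np.ndarray
    scheme: EncodingScheme | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        self.starts = np.asarray(self.starts, dtype=int)
        n = len(self.X)
        if not (len(self.y) == len(self.chain_ids) == len(self.starts) == n):
            raise ValueError("sample arrays have inconsistent lengths")
        if self.scheme is not None and self.X.shape[1] != self.scheme.n_features:
            raise ValueError(
                f"feature width {self.X.shape[1]} does not match scheme ({self.scheme.n_features})"
            )

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_windows(
        cls, windows: Sequence[WindowSample], scheme: EncodingScheme | None = None
    ) -> "SampleSet":
        if not windows:
            raise ValueError("no window samples")
        return cls(
            X=np.vstack([w.features for w in windows]),
            y=np.array([w.label for w in windows], dtype=bool),
            chain_ids=[w.chain_id for w in windows],
            starts=np.array([w.start for w in windows], dtype=int),
            scheme=scheme,
        )

    def save(self, path: str | Path) -> None:
        scheme_json = json.dumps(self.scheme.to_dict()) if self.scheme else ""
        np.savez(
            path,
            X=self.X,
            y=self.y,
            chain_ids=np.array(self.chain_ids),
            starts=self.starts,
            scheme=np.array(scheme_json),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SampleSet":
        with np.load(path, allow_pickle=False) as data:
            scheme_json = str(data["scheme"])
            return cls(
                X=data["X"],
                y=data["y"],
                chain_ids=[str(c) for c in data["chain_ids"]],
                starts=data["starts"],
                scheme=EncodingScheme.from_dict(json.loads(scheme_json)) if scheme_json else None,
            )


def encode_chains(
    chains: Sequence[ProteinChain],
    pssms: dict[str, PSSMatrix],
    scheme: EncodingScheme,
    turns_by_chain: dict[str, Sequence[int]],
    any_overlap: bool = False,
) -> SampleSet:
    """Encode every chain into window samples and stack them into one SampleSet."""
    windows: list[WindowSample] = []
    for chain in chains:
        pssm = pssms.get(chain.id) if scheme.use_pssm else None
        windows.extend(
            slice_windows(
                chain,
                pssm,
                scheme,
                turns_by_chain.get(chain.id, []),
                any_overlap=any_overlap,
            )
        )
    return SampleSet.from_windows(windows, scheme)


# ---------------------------------------------------------------------------
# Plumbing: mapping window scores back to residues, composition report
# ---------------------------------------------------------------------------

def reduce_to_residues(
    chain_length: int,
    window_starts: Sequence[int],
    window_scores: Sequence[float],
    window_size: int = DEFAULT_WINDOW_SIZE,
    threshold: float = 0.5,
) -> tuple[list[float], list[bool]]:
    """Per-residue turn scores from window scores (explicit reducer, plumbing).

    A residue's score is the maximum score over windows whose central four
    residues contain it; residues never centered by any window score 0.
    """
    scores = [0.0] * chain_length
    for start, score in zip(window_starts, window_scores):
        for r in central_four(start, window_size):
            if 0 <= r < chain_length:
                scores[r] = max(scores[r], float(score))
    labels = [s >= threshold for s in scores]
    return scores, labels


def position_composition(
    chains: Sequence[ProteinChain],
    turns_by_chain: dict[str, Sequence[int]],
    track: str = "shape",
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> dict[str, list[dict[str, int]]]:
    """Per-window-position character counts for positive vs negative windows.

    Simple compositional report over the requested track ("sequence", "ss"
    or "shape"); descriptive plumbing, not a statistical analysis.
    """
    pos: list[dict[str, int]] = [dict() for _ in range(window_size)]
    neg: list[dict[str, int]] = [dict() for _ in range(window_size)]
    for chain in chains:
        text = {"sequence": chain.sequence, "ss": chain.ss, "shape": chain.shape}[track]
        if text is None:
            raise ValueError(f"chain {chain.id!r}: missing {track} track")
        starts = turns_by_chain.get(chain.id, [])
        for start in range(0, len(text) - window_size + 1):
            counters = pos if window_label(starts, start, window_size) else neg
            for offset in range(window_size):
                c = text[start + offset]
                counters[offset][c] = counters[offset].get(c, 0) + 1
    return {"positive": pos, "negative": neg}
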