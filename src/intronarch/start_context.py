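"""Translation-initiation context analysis (Kozak-like consensus scoring).

From a collection of 10-nt windows immediately upstream of validated start
codons, a position frequency matrix (PFM, in percent) is built over positions
-10..-1.  A threshold consensus keeps, at each position, every nucleotide
whose frequency reaches the threshold; candidate ATG contexts are then scored
by how many of their 10 positions carry a consensus nucleotide, and the
in-frame ATG with the most favourable context is selected as the likely
initiation codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ContextModel",
    "StartCandidate",
    "POSITIONS",
    "build_pfm",
    "derive_consensus",
    "score_context",
    "find_candidates",
    "select_start",
]

NUCLEOTIDES = ("A", "U", "G", "C")
POSITIONS = tuple(range(-10, 0))
WINDOW = 10
STOPS = {"UAA", "UAG", "UGA"}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def build_pfm(windows: Sequence[str]) -> pd.DataFrame:
    """Column-wise percentage frequencies of a set of 10-nt upstream windows.

    Rows are positions -10..-1, columns A/U/G/C (T is read as U).  Each row
    sums to 100.
    """
    if not windows:
        raise ValueError("no windows supplied")
    counts = {p: {nt: 0 for nt in NUCLEOTIDES} for p in POSITIONS}
    for idx, w in enumerate(windows):
        w = _rna(w)
        if len(w) != WINDOW:
            raise ValueError(f"window {idx} has length {len(w)}, expected {WINDOW}")
        for p, ch in zip(POSITIONS, w):
            if ch not in counts[p]:
                raise ValueError(f"window {idx}: unexpected character {ch!r}")
            counts[p][ch] += 1
    n = len(windows)
    pfm = pd.DataFrame(
        {nt: [100.0 * counts[p][nt] / n for p in POSITIONS] for nt in NUCLEOTIDES},
        index=pd.Index(POSITIONS, name="position"),
    )
    return pfm


def derive_consensus(pfm: pd.DataFrame, threshold: float = 27.0) -> dict[int, frozenset[str]]:
    """Per-position sets of nucleotides whose frequency >= ``threshold`` (%).

    Raising the threshold can only shrink the sets; a position where no
    nucleotide reaches the threshold gets an empty set.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    consensus: dict[int, frozenset[str]] = {}
    for p in pfm.index:
        consensus[int(p)] = frozenset(
            nt for nt in NUCLEOTIDES if nt in pfm.columns and pfm.at[p, nt] >= threshold
        )
    return consensus


@dataclass(frozen=True)
class ContextModel:
    """PFM + threshold consensus for start-codon context scoring."""

    pfm: pd.DataFrame
    n_sequences: int
    threshold: float
    consensus: dict[int, frozenset[str]]

    @classmethod
    def from_windows(cls, windows: Sequence[str], threshold: float = 27.0) -> "ContextModel":
        pfm = build_pfm(windows)
        return cls(pfm, len(windows), threshold, derive_consensus(pfm, threshold))


def score_context(context: str, consensus: Mapping[int, frozenset[str]]) -> int:
    """Number of the 10 upstream positions matching the consensus sets.

    ``context`` is read left to right as positions -10..-1; shorter contexts
    (ATG too close to the 5' end) are right-aligned and missing positions
    count as mismatches.  U and T are equivalent.
    """
    ctx = _rna(context)
    if len(ctx) > WINDOW:
        raise ValueError(f"context longer than {WINDOW} nt")
    offset = WINDOW - len(ctx)
    score = 0
    for i, ch in enumerate(ctx):
        pos = POSITIONS[offset + i]
        if ch in consensus.get(pos, frozenset()):
            score += 1
    return score


@dataclass(frozen=True)
class StartCandidate:
    """A candidate initiation ATG with its upstream context and score."""

    offset: int  # 0-based position of the A of ATG in the input sequence
    context: str
    score: int


def find_candidates(
    cdna: str,
    consensus: Mapping[int, frozenset[str]],
    orf_start: int | None = None,
    all_frames: bool = False,
) -> list[StartCandidate]:
    """Score every candidate initiation ATG of a cDNA.

    Candidates are the ATGs in frame with the annotated open reading frame
    and 5' of its first in-frame stop codon — the set of starts that could
    initiate that ORF.  ``orf_start`` anchors the frame (default: the frame
    of the longest ORF in the sequence).  ``all_frames=True`` widens the
    scan to every ATG in the sequence.
    """
    seq = _rna(cdna)
    candidates: list[StartCandidate] = []
    if all_frames:
        positions = [i for i in range(len(seq) - 2) if seq[i:i + 3] == "AUG"]
    else:
        if orf_start is None:
            orf_start = _longest_orf_start(seq)
        frame = orf_start % 3
        stop_at = len(seq)
        for i in range(orf_start, len(seq) - 2, 3):
            if seq[i:i + 3] in STOPS:
                stop_at = i
                break
        # walk the frame from the 5' end; a stop codon resets the candidate run
        run: list[int] = []
        for i in range(frame, min(stop_at, len(seq) - 2), 3):
            codon = seq[i:i + 3]
            if codon in STOPS:
                run = []
            elif codon == "AUG":
                run.append(i)
        positions = run
    for p in positions:
        ctx = seq[max(0, p - WINDOW):p]
        candidates.append(StartCandidate(p, ctx, score_context(ctx, consensus)))
    return candidates


def _longest_orf_start(seq: str) -> int:
    best_start, best_len = 0, -1
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2 + 1, 3):
            codon = seq[i:i + 3]
            if codon == "AUG" and start is None:
                start = i
            if codon in STOPS and start is not None:
                if i - start > best_len:
                    best_start, best_len = start, i - start
                start = None
        if start is not None and len(seq) - start > best_len:
            best_start, best_len = start, len(seq) - start
    return best_start


def select_start(
    cdna: str,
    consensus: Mapping[int, frozenset[str]],
    orf_start: int | None = None,
    all_frames: bool = False,
) -> StartCandidate:
    """Most favourable in-frame initiation ATG (ties go to the 5'-most)."""
    candidates = find_candidates(cdna, consensus, orf_start=orf_start, all_frames=all_frames)
    if not candidates:
        raise ValueError("no candidate ATG found")
    return max(candidates, key=lambda c: (c.score, -c.offset))
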