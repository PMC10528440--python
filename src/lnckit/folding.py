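"""Secondary-structure prediction with sliding-window segmentation/merging.

The default folder is a Nussinov-style dynamic program that maximizes a
weighted base-pair count (GC=3, AU=2, GU=1, minimum hairpin loop 3 nt) and
reports the negated pair-weight sum as a pseudo-MFE score (arbitrary energy
units, more negative = more stable). It is not a thermodynamic
nearest-neighbour model; it exists so that the windowed
segmentation/integration strategy — the part that makes arbitrarily long
transcripts foldable — can be exercised end to end. Any callable with the
same signature can be plugged in as an alternative backend (e.g. an external
deep folder or ViennaRNA).

Windows of ``window_nt`` bases advance at stride ``window_nt - overlap_nt``
with the last window right-aligned; each window is folded independently and
the per-window pair sets are merged. Where windows disagree, the pair whose
parent window's center is closest to the pair midpoint wins (ties: earlier
window), and pairs that would cross or share a position with an
already-accepted higher-priority pair are dropped, so the merged structure is
always pseudoknot-free.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from numba import njit

MIN_LOOP = 3

#: pair weights, indexed by base codes A=0, C=1, G=2, U=3; ambiguity = -1
_WEIGHTS = np.zeros((4, 4), dtype=np.int32)
_WEIGHTS[2, 1] = _WEIGHTS[1, 2] = 3  # GC
_WEIGHTS[0, 3] = _WEIGHTS[3, 0] = 2  # AU
_WEIGHTS[2, 3] = _WEIGHTS[3, 2] = 1  # GU

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


class FoldingConfigError(ValueError):
    """Raised on invalid window/overlap configuration."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket string, 1-based pair set, and pseudo-MFE score."""

    dotbracket: str
    pairs: frozenset[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        n = len(self.dotbracket)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"pair ({i},{j}) out of range for length {n}")
            if j - i <= MIN_LOOP:
                raise ValueError(f"pair ({i},{j}) violates min_loop={MIN_LOOP}")
            if i in seen or j in seen:
                raise ValueError(f"position shared by multiple pairs at ({i},{j})")
            seen.update((i, j))
        # non-crossing check: nested-interval stack over pairs sorted by opening
        stack: list[int] = []
        for i, j in sorted(self.pairs):
            while stack and stack[-1] < i:
                stack.pop()
            if stack and j > stack[-1]:
                raise ValueError(f"crossing pair ({i},{j})")
            stack.append(j)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map bases to integer codes; ambiguity codes become -1 (unpairable)."""
    return np.array([_CODE.get(b, -1) for b in sequence], dtype=np.int64)


@njit(cache=True)
def _nussinov_dp(enc: np.ndarray, min_loop: int, weights: np.ndarray):
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    dp_t = np.zeros((n, n), dtype=np.int32)  # transpose, for contiguous reads
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = dp[i + 1, j]
            a = enc[i]
            b = enc[j]
            if a >= 0 and b >= 0 and weights[a, b] > 0:
                v = weights[a, b] + dp[i + 1, j - 1]
                if v > best:
                    best = v
            for k in range(i + min_loop + 1, j):
                v = dp[i, k] + dp_t[j, k + 1]
                if v > best:
                    best = v
            dp[i, j] = best
            dp_t[j, i] = best
    return dp


@njit(cache=True)
def _traceback_kernel(
    dp: np.ndarray, enc: np.ndarray, min_loop: int, weights: np.ndarray
) -> np.ndarray:
    """Deterministic traceback: prefer pairing i with the smallest valid j'."""
    n = enc.shape[0]
    out = np.empty((n // 2, 2), dtype=np.int64)
    n_pairs = 0
    stack = np.empty((n + 1, 2), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        while j - i > min_loop:
            if dp[i, j] == dp[i + 1, j]:
                i += 1
                continue
            a = enc[i]
            advanced = False
            for jp in range(i + min_loop + 1, j + 1):
                b = enc[jp]
                if a < 0 or b < 0 or weights[a, b] == 0:
                    continue
                inner = dp[i + 1, jp - 1]
                rest = dp[jp + 1, j] if jp + 1 <= j else 0
                if weights[a, b] + inner + rest == dp[i, j]:
                    out[n_pairs, 0] = i
                    out[n_pairs, 1] = jp
                    n_pairs += 1
                    if jp + 1 <= j:
                        stack[top, 0] = jp + 1
                        stack[top, 1] = j
                        top += 1
                    i, j = i + 1, jp - 1
                    advanced = True
                    break
            if not advanced:  # unreachable by dp optimality
                i += 1
    return out[:n_pairs]


def _traceback(
    dp: np.ndarray, enc: np.ndarray, min_loop: int, weights: np.ndarray
) -> list[tuple[int, int]]:
    arr = _traceback_kernel(dp, enc, min_loop, weights)
    return [(int(i), int(j)) for i, j in arr]


def _dotbracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def fold_mfe(sequence: str, min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Optimal weighted-pairing structure of a whole sequence.

    Maximizes the summed pair weights (GC=3, AU=2, GU=1) over all
    non-crossing structures with hairpin loops of at least ``min_loop``
    unpaired bases; score is the negated optimum. Sequences too short to
    form any pair return the all-unpaired structure.
    """
    n = len(sequence)
    if n < min_loop + 2:
        return SecondaryStructure("." * n, frozenset(), 0.0)
    enc = encode_sequence(sequence)
    dp = _nussinov_dp(enc, min_loop, _WEIGHTS)
    raw_pairs = _traceback(dp, enc, min_loop, _WEIGHTS)
    pairs = frozenset((i + 1, j + 1) for i, j in raw_pairs)
    return SecondaryStructure(_dotbracket(n, pairs), pairs, -float(dp[0, n - 1]))


def window_starts(length: int, window_nt: int, overlap_nt: int) -> list[int]:
    """1-based window start positions: regular stride, last right-aligned."""
    if window_nt < 4:
        raise FoldingConfigError(f"window_nt {window_nt} < 4")
    if not window_nt > overlap_nt >= 0:
        raise FoldingConfigError(
            f"require window_nt > overlap_nt >= 0, got {window_nt}, {overlap_nt}"
        )
    if length <= window_nt:
        return [1]
    stride = window_nt - overlap_nt
    starts = list(range(1, length - window_nt + 1, stride))
    last = length - window_nt + 1
    if starts[-1] != last:
        starts.append(last)
    return starts


def fold_windowed(
    sequence: str,
    window_nt: int = 500,
    overlap_nt: int = 250,
    folder: Callable[[str], SecondaryStructure] = fold_mfe,
) -> SecondaryStructure:
    """Fold a transcript of arbitrary length by overlapping windows.

    Each window is folded by ``folder`` (default :func:`fold_mfe`); pairs are
    mapped to transcript coordinates and merged by window-center proximity to
    the pair midpoint, dropping pairs that cross or share positions with
    higher-priority ones. Identical to ``folder(sequence)`` when the sequence
    fits in one window.
    """
    n = len(sequence)
    starts = window_starts(n, window_nt, overlap_nt)
    if len(starts) == 1:
        sub = folder(sequence)
        return SecondaryStructure(sub.dotbracket, sub.pairs, sub.score)

    candidates: list[tuple[float, int, tuple[int, int], float]] = []
    for w_idx, s in enumerate(starts):
        e = min(s + window_nt - 1, n)
        sub = folder(sequence[s - 1 : e])
        center = (s + e) / 2.0
        for i, j in sub.pairs:
            gi, gj = i + s - 1, j + s - 1
            midpoint = (gi + gj) / 2.0
            a, b = _CODE.get(sequence[gi - 1], -1), _CODE.get(sequence[gj - 1], -1)
            weight = float(_WEIGHTS[a, b]) if a >= 0 and b >= 0 else 0.0
            candidates.append((abs(center - midpoint), w_idx, (gi, gj), weight))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    accepted: set[tuple[int, int]] = set()
    endpoints: list[int] = []  # sorted accepted endpoints
    partner: dict[int, int] = {}
    score = 0.0
    for _, _, pair, weight in candidates:
        i, j = pair
        if i in partner or j in partner:
            continue
        # crossing iff some accepted endpoint inside (i,j) has its partner outside
        lo = bisect.bisect_right(endpoints, i)
        hi = bisect.bisect_left(endpoints, j)
        if any(not i < partner[p] < j for p in endpoints[lo:hi]):
            continue
        accepted.add(pair)
        bisect.insort(endpoints, i)
        bisect.insort(endpoints, j)
        partner[i] = j
        partner[j] = i
        score -= weight
    pairs = frozenset(accepted)
    return SecondaryStructure(_dotbracket(n, pairs), pairs, score)


def transition_frequency(structure: SecondaryStructure) -> float:
    """Fraction of adjacent position pairs whose paired state differs."""
    n = structure.length
    if n == 0:
        raise ValueError("empty structure")
    if n == 1:
        return 0.0
    paired = structure.paired_positions
    states = [p in paired for p in range(1, n + 1)]
    transitions = sum(1 for a, b in zip(states, states[1:]) if a != b)
    return transitions / (n - 1)


def write_ct(
    structure: SecondaryStructure, sequence: str, name: str, path: str | Path
) -> None:
    """Write a structure in CT (connectivity table) format."""
    n = len(sequence)
    partner = {i: j for i, j in structure.pairs}
    partner.update({j: i for i, j in structure.pairs})
    with open(path, "w") as handle:
        handle.write(f"{n}\t{name}\n")
        for p in range(1, n + 1):
            handle.write(
                f"{p}\t{sequence[p - 1]}\t{p - 1}\t{(p + 1) % (n + 1)}\t{partner.get(p, 0)}\t{p}\n"
            )
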