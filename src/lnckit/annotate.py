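"""Interactome prediction: RBP-binding sites, triplex potential, RNA–RNA duplexes.

Three deterministic predictors share the output schemas of the heavyweight
external tools they model, so the surrounding pipeline (scanning, ranking,
reporting) is exercised faithfully:

* :func:`scan_pwm` — log-odds PWM scanning for RNA-binding-protein motifs,
  reporting score, relative score and the matched subsequence per hit.
* :func:`tfp_score` — a bounded [0,1] triplex-forming-potential score driven
  by the longest purine tract (the classic requirement for RNA:DNA triplex
  target sites); an artifact-defined formula, not calibrated against any
  trained triplex model.
* :func:`find_duplex` — ungapped seed-and-extend RNA–RNA hybridization with
  weighted pair energies, plus structure-derived accessibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .folding import SecondaryStructure

BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(BASES)}

#: duplex pair weights (GC=3, AU=2, GU=1), mirroring the folding objective
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

PSEUDOCOUNT = 1e-3
DEFAULT_MIN_RELATIVE_SCORE = 0.8

#: TFP saturation constants: tracts below TFP_FLOOR nt score 0, tracts of
#: TFP_CEIL nt or longer saturate at 1.
TFP_FLOOR = 10
TFP_CEIL = 50


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix for one RBP motif (columns over A,C,G,U)."""

    name: str
    matrix: np.ndarray  # (L, 4) column probabilities
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 3:
            raise ValueError(f"PWM {self.name!r}: need (L>=3, 4) matrix, got {m.shape}")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1")
        object.__setattr__(self, "matrix", m)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-column log2 odds vs background, pseudocount-floored (bits)."""
        p = np.maximum(self.matrix, PSEUDOCOUNT)
        return np.log2(p / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))


@dataclass(frozen=True)
class RbpHit:
    """One PWM hit: 1-based inclusive site with log-odds and relative score."""

    rbp_name: str
    start: int
    end: int
    score: float
    relative_score: float
    matched_sequence: str


@dataclass(frozen=True)
class TriplexScore:
    value: float
    best_tract_start: int  # 1-based; 0 when no purine at all
    best_tract_len: int


@dataclass(frozen=True)
class RnaRnaInteraction:
    target_name: str
    target_length: int
    accessibility_energy: float
    hybridization_energy: float
    interaction_energy: float
    base_pairs: int
    query_site: tuple[int, int]
    target_site: tuple[int, int]


@dataclass(frozen=True)
class Duplex:
    """Ungapped duplex between query and target (1-based inclusive sites)."""

    query_site: tuple[int, int]
    target_site: tuple[int, int]
    base_pairs: int
    hybridization_energy: float


def _encode_onehot(sequence: str) -> np.ndarray:
    """(n, 4) one-hot; ambiguity codes give all-zero rows."""
    out = np.zeros((len(sequence), 4))
    for i, b in enumerate(sequence):
        k = _IDX.get(b)
        if k is not None:
            out[i, k] = 1.0
    return out


def window_scores(sequence: str, pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """(raw log-odds score, relative score) for every window of the sequence.

    Relative score rescales between the minimum and maximum attainable under
    the PWM; a degenerate PWM (max == min) gives relative score 1 everywhere.
    """
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return np.empty(0), np.empty(0)
    lo = pwm.log_odds
    max_score = float(lo.max(axis=1).sum())
    min_score = float(lo.min(axis=1).sum())
    onehot = _encode_onehot(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(onehot, (L, 4))
    scores = windows.reshape(n - L + 1, L * 4) @ lo.ravel()
    if max_score == min_score:
        relative = np.ones_like(scores)
    else:
        relative = (scores - min_score) / (max_score - min_score)
    return scores, relative


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
) -> list[RbpHit]:
    """Scan every window of the sequence against one PWM.

    Window score is the summed log-odds; relative score rescales it between
    the minimum and maximum attainable under the PWM. Windows containing
    ambiguity codes contribute the background log-odds 0 at those positions.
    Hits with relative score >= threshold are returned sorted by start.
    A degenerate PWM (max == min attainable) gives relative score 1 everywhere.
    """
    if not 0.0 <= min_relative_score <= 1.0:
        raise ValueError("min_relative_score must be in [0,1]")
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    scores, relative = window_scores(sequence, pwm)
    hits = []
    for s in range(n - L + 1):
        if relative[s] >= min_relative_score:
            hits.append(
                RbpHit(
                    rbp_name=pwm.name,
                    start=s + 1,
                    end=s + L,
                    score=float(scores[s]),
                    relative_score=float(relative[s]),
                    matched_sequence=sequence[s : s + L],
                )
            )
    return hits


def scan_pwms(
    sequence: str,
    pwms: Sequence[Pwm],
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
) -> list[RbpHit]:
    """Scan against many PWMs; hits sorted by (start, rbp_name)."""
    hits: list[RbpHit] = []
    for pwm in pwms:
        hits.extend(scan_pwm(sequence, pwm, min_relative_score))
    hits.sort(key=lambda h: (h.start, h.rbp_name))
    return hits


def tfp_score(sequence: str) -> TriplexScore:
    """Triplex-forming potential from the longest purine (A/G) tract.

    value = clamp((L_max - 9) / 41, 0, 1): zero below a 10-nt tract, linear
    up to saturation at 50 nt.
    """
    best_len = 0
    best_start = 0
    run = 0
    for i, b in enumerate(sequence):
        if b in "AG":
            run += 1
            if run > best_len:
                best_len = run
                best_start = i - run + 2  # 1-based start of this run
        else:
            run = 0
    value = min(max((best_len - (TFP_FLOOR - 1)) / (TFP_CEIL - TFP_FLOOR + 1), 0.0), 1.0)
    return TriplexScore(value=value, best_tract_start=best_start, best_tract_len=best_len)


def find_duplex(
    query_sequence: str, target_sequence: str, seed_len: int = 6
) -> Optional[Duplex]:
    """Best ungapped antiparallel duplex between query and target.

    Looks for perfect Watson–Crick/GU-complementary seed matches of length
    ``seed_len`` between the query and the reversed target, extends each
    ungapped in both directions while pairs stay complementary, and returns
    the minimum-energy duplex (energy = -sum of pair weights; ties broken by
    leftmost query start, then leftmost target site). None when no seed exists.
    """
    if seed_len < 4:
        raise ValueError("seed_len must be >= 4")
    nq, nt = len(query_sequence), len(target_sequence)
    rt = target_sequence[::-1]  # rt[k] = target[nt-1-k]

    def w(i: int, k: int) -> int:
        return _PAIR_WEIGHT.get((query_sequence[i], rt[k]), 0)

    best: Optional[tuple[float, int, int, Duplex]] = None
    # offset d aligns query[i] with rt[i - d]
    for d in range(-(nt - seed_len), nq - seed_len + 1):
        i0 = max(0, d)
        i1 = min(nq, nt + d)  # exclusive
        if i1 - i0 < seed_len:
            continue
        run = 0
        i = i0
        while i < i1:
            if w(i, i - d) > 0:
                run += 1
            else:
                run = 0
            if run >= seed_len:
                # extend forward to the end of this complementary run
                j = i
                while j + 1 < i1 and w(j + 1, j + 1 - d) > 0:
                    j += 1
                start = i - run + 1
                while start > i0 and w(start - 1, start - 1 - d) > 0:
                    start -= 1  # pragma: no cover - run already maximal
                energy = -float(sum(w(p, p - d) for p in range(start, j + 1)))
                bp = j - start + 1
                q_site = (start + 1, j + 1)
                # rt index k maps to target position nt - k (1-based)
                t_site = (nt - (j - d), nt - (start - d))
                cand = Duplex(q_site, t_site, bp, energy)
                key = (energy, q_site[0], t_site[0])
                if best is None or key < best[:3]:
                    best = (energy, q_site[0], t_site[0], cand)
                run = 0
                i = j  # skip past this run
            i += 1
    return None if best is None else best[3]


def interaction_energy(
    query_sequence: str,
    duplex: Duplex,
    structure: SecondaryStructure,
    target_name: str = "",
    target_length: int = 0,
    alpha: float = 1.0,
) -> RnaRnaInteraction:
    """Combine hybridization with structure-derived accessibility.

    Accessibility energy is ``alpha`` per query-site position that is paired
    in the query's own secondary structure (energy needed to open the site);
    interaction energy = hybridization + accessibility.
    """
    qs, qe = duplex.query_site
    if not (1 <= qs <= qe <= len(query_sequence)):
        raise ValueError(f"query site {duplex.query_site} outside sequence bounds")
    if structure.length != len(query_sequence):
        raise ValueError("structure length does not match query sequence")
    paired = structure.paired_positions
    acc = alpha * sum(1 for p in range(qs, qe + 1) if p in paired)
    return RnaRnaInteraction(
        target_name=target_name,
        target_length=target_length,
        accessibility_energy=acc,
        hybridization_energy=duplex.hybridization_energy,
        interaction_energy=duplex.hybridization_energy + acc,
        base_pairs=duplex.base_pairs,
        query_site=duplex.query_site,
        target_site=duplex.target_site,
    )


def rank_interactions(
    interactions: Sequence[RnaRnaInteraction], n: int = 100
) -> list[RnaRnaInteraction]:
    """Top-n by hybridization energy, ascending (most negative first).

    Ties are broken by target name, lexicographically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(interactions, key=lambda x: (x.hybridization_energy, x.target_name))
    return ordered[:n]


# ---------------------------------------------------------------------------
# MEME-minimal format I/O


def read_meme(path: str | Path) -> list[Pwm]:
    """Read PWMs from a MEME-minimal file (letter-probability matrix blocks)."""
    text = Path(path).read_text()
    background = np.full(4, 0.25)
    bg_match = re.search(
        r"Background letter frequencies.*?\n([\d.eE+\-\s ACGTU]+)\n", text
    )
    if bg_match:
        tokens = bg_match.group(1).split()
        freqs = {tokens[i]: float(tokens[i + 1]) for i in range(0, len(tokens) - 1, 2)}
        background = np.array(
            [freqs.get(b, freqs.get("T" if b == "U" else b, 0.25)) for b in BASES]
        )
    pwms = []
    motif_blocks = re.split(r"^MOTIF +", text, flags=re.M)[1:]
    for block in motif_blocks:
        lines = block.splitlines()
        name = lines[0].split()[0]
        rows = []
        in_matrix = False
        for line in lines[1:]:
            if line.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                vals = line.split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                elif rows:
                    break
        if not rows:
            raise ValueError(f"MOTIF {name}: no letter-probability matrix found")
        matrix = np.array(rows)
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
        pwms.append(Pwm(name=name, matrix=matrix, background=background))
    return pwms


def write_meme(pwms: Sequence[Pwm], path: str | Path, alphabet: str = "ACGU") -> None:
    """Write PWMs in MEME-minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + alphabet + "\n\n")
        fh.write("Background letter frequencies\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(alphabet, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
            fh.write("\n")


def write_hits_tsv(hits: Iterable[RbpHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rbp_name\tstart\tend\tscore\trelative_score\tmatched_sequence\n")
        for h in hits:
            fh.write(
                f"{h.rbp_name}\t{h.start}\t{h.end}\t{h.score:.4f}\t"
                f"{h.relative_score:.4f}\t{h.matched_sequence}\n"
            )


def write_interactions_tsv(
    interactions: Iterable[RnaRnaInteraction], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "target_name\ttarget_length\taccessibility_energy\t"
            "hybridization_energy\tinteraction_energy\tbase_pairs\n"
        )
        for x in interactions:
            fh.write(
                f"{x.target_name}\t{x.target_length}\t{x.accessibility_energy:.2f}\t"
                f"{x.hybridization_energy:.2f}\t{x.interaction_energy:.2f}\t{x.base_pairs}\n"
            )


def write_hits_bed(hits: Iterable[RbpHit], transcript_id: str, path: str | Path) -> None:
    """Hit sites as BED intervals on the transcript (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{transcript_id}\t{h.start - 1}\t{h.end}\t{h.rbp_name}\t{h.score:.3f}\n")
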