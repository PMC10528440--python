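"""Open-reading-frame detection and the per-position ORF indicator track.

ORFs are AUG-initiated and stop-terminated (UAA/UAG/UGA, stop included in the
span), scanned on the forward strand in all three frames — transcripts are
assumed already oriented. The indicator track marks the span of the single
longest ORF with 1s; it feeds both the feature extractor and the recurrent
sequence model as an extra input channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


@dataclass(frozen=True)
class Orf:
    """One ORF: 1-based inclusive span, frame in {0,1,2}."""

    frame: int
    start: int
    end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


def find_orfs(sequence: str) -> list[Orf]:
    """All forward-strand ORFs (AUG … in-frame stop), sorted by start then frame.

    Each AUG is paired with the first in-frame stop downstream; AUGs with no
    in-frame stop before the sequence end are ignored. Minimum length is
    6 nt (start + stop).
    """
    n = len(sequence)
    orfs = []
    for frame in range(3):
        # first in-frame stop at or after each codon index, per frame
        codon_starts = range(frame, n - 2, 3)
        stops = [cs for cs in codon_starts if sequence[cs : cs + 3] in STOP_CODONS]
        si = 0
        for cs in codon_starts:
            if sequence[cs : cs + 3] != START_CODON:
                continue
            while si < len(stops) and stops[si] < cs:
                si += 1
            # stops is ordered; find first stop >= cs+3 (not overlapping start)
            k = si
            while k < len(stops) and stops[k] < cs + 3:
                k += 1
            if k < len(stops):
                orfs.append(Orf(frame=frame, start=cs + 1, end=stops[k] + 3))
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def longest_orf(sequence: str) -> Optional[Orf]:
    """The ORF of maximal length; ties broken by smaller start. None if no ORF."""
    orfs = find_orfs(sequence)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.length_nt, -o.start))


def orf_indicator(sequence: str) -> np.ndarray:
    """Binary track (len == transcript length): 1 on the longest ORF's span."""
    track = np.zeros(len(sequence), dtype=np.int8)
    orf = longest_orf(sequence)
    if orf is not None:
        track[orf.start - 1 : orf.end] = 1
    return track
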