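"""Transcript I/O and coordinate-based consensus matching.

Transcripts are handled as RNA (``T`` is normalized to ``U`` on input) with
1-based inclusive coordinates throughout; a BED export (0-based half-open) is
provided for interoperability with genome-browser tooling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC ambiguity codes tolerated in sequences (kept verbatim; excluded from
#: k-mer counting and treated as unpairable in folding).
AMBIGUITY_CODES = frozenset("NRYSWKMBDHV")
BASES = "ACGU"
_VALID = frozenset(BASES) | AMBIGUITY_CODES


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: id, normalized RNA sequence, optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None  # "coding" | "noncoding" | None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if self.label not in (None, "coding", "noncoding"):
            raise ValueError(f"unknown label {self.label!r} for {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoordinateEntry:
    """Genomic interval of one transcript, 1-based inclusive."""

    id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for {self.id!r}"
            )


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA spelling to RNA (T→U)."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects, in file order.

    The id is the header token up to the first whitespace. Raises
    :class:`FastaParseError` on a file whose first non-blank line is not a
    header, and :class:`ValueError` (naming the id) on an empty entry.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            break
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"{path}: empty sequence entry for id {rec.id!r}")
        records.append(TranscriptRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as FASTA (RNA alphabet, 60-column wrapping)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, label) into a dict."""
    out: dict[str, str] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0] in ("id", "#id"):
                continue
            out[row[0]] = row[1]
    return out


def write_labels(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tlabel\n")
        for r in records:
            handle.write(f"{r.id}\t{r.label or ''}\n")


def filter_by_length(
    records: Sequence[TranscriptRecord], min_nt: int, max_nt: int
) -> list[TranscriptRecord]:
    """Keep records with ``min_nt <= length <= max_nt`` (inclusive bounds)."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt {min_nt} > max_nt {max_nt}")
    return [r for r in records if min_nt <= r.length <= max_nt]


def read_coordinates(path: str | Path) -> list[CoordinateEntry]:
    """Read a TSV coordinate table with header ``id<TAB>start<TAB>end``."""
    entries = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            entries.append(
                CoordinateEntry(row["id"], int(row["start"]), int(row["end"]))
            )
    return entries


def write_bed(entries: Iterable[CoordinateEntry], path: str | Path) -> None:
    """Export intervals as BED (0-based, half-open)."""
    with open(path, "w") as handle:
        for e in entries:
            handle.write(f"{e.id}\t{e.start - 1}\t{e.end}\n")


def match_consensus(
    a: Sequence[CoordinateEntry],
    b: Sequence[CoordinateEntry],
    tolerance_nt: int = 5,
) -> list[tuple[str, str]]:
    """Match intervals between two lists with per-end tolerance.

    A pair (x from ``a``, y from ``b``) is a candidate iff
    ``|x.start - y.start| <= tolerance_nt`` and ``|x.end - y.end| <=
    tolerance_nt``; start and end deviations are checked independently.
    Candidates are resolved greedily by smallest total deviation
    ``|Δstart| + |Δend|`` (ties broken by input order), each entry matched at
    most once. Returns matched (a.id, b.id) pairs.
    """
    if tolerance_nt < 0:
        raise ValueError("tolerance_nt must be >= 0")
    candidates = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            ds = abs(x.start - y.start)
            de = abs(x.end - y.end)
            if ds <= tolerance_nt and de <= tolerance_nt:
                candidates.append((ds + de, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((a[i].id, b[j].id))
    return matches
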