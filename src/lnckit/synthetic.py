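"""Synthetic labeled transcript corpora and PWM fixtures.

The generator plants the signals the classifiers are meant to learn, at
desk scale:

* coding transcripts carry a single long AUG…stop ORF whose length is a
  configured fraction of the transcript (default 50–90% coverage), with
  interior codons drawn from a human-usage-like codon table scaled by a
  bias-strength knob;
* noncoding transcripts are composition-matched to the coding corpus (GC
  drawn to mirror the coding marginal) but have any ORF reaching the
  configured cap (default 150 nt) resampled away, so classifiers must read
  ORF/codon structure rather than base composition.

What this does NOT emulate: splicing isoform structure, expression levels,
repeat content, or real UTR grammar — conclusions from these corpora are
about the pipeline's mechanics, not about GENCODE-scale biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import orf
from .annotate import Pwm
from .features import CodingBiasTables, build_hexamer_table
from .seqio import TranscriptRecord

BASES = np.array(list("ACGU"))

#: Human codon usage, frequency per 1000 codons (standard published table,
#: RNA spelling). Stop codons included for completeness; interior ORF codons
#: are drawn from the sense codons only.
CODON_USAGE_PER_1000 = {
    "UUU": 17.6, "UUC": 20.3, "UUA": 7.7, "UUG": 12.9,
    "CUU": 13.2, "CUC": 19.6, "CUA": 7.2, "CUG": 39.6,
    "AUU": 16.0, "AUC": 20.8, "AUA": 7.5, "AUG": 22.0,
    "GUU": 11.0, "GUC": 14.5, "GUA": 7.1, "GUG": 28.1,
    "UCU": 15.2, "UCC": 17.7, "UCA": 12.2, "UCG": 4.4,
    "CCU": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACU": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCU": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "UAU": 12.2, "UAC": 15.3, "UAA": 1.0, "UAG": 0.8,
    "CAU": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAU": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAU": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "UGU": 10.6, "UGC": 12.6, "UGA": 1.6, "UGG": 13.2,
    "CGU": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGU": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGU": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

SENSE_CODONS = sorted(c for c in CODON_USAGE_PER_1000 if c not in orf.STOP_CODONS)
STOP_CODONS = sorted(orf.STOP_CODONS)


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_class: int = 2000
    length_range: tuple[int, int] = (200, 3000)
    coding_orf_coverage_range: tuple[float, float] = (0.5, 0.9)
    noncoding_max_orf_nt: int = 150
    gc_range: tuple[float, float] = (0.35, 0.65)
    codon_bias_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        clo, chi = self.coding_orf_coverage_range
        glo, ghi = self.gc_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")
        if not (0 < clo <= chi <= 1):
            raise ValueError(f"bad coverage range {self.coding_orf_coverage_range}")
        if not (0 <= glo <= ghi <= 1):
            raise ValueError(f"bad gc_range {self.gc_range}")
        if not 0 <= self.codon_bias_strength <= 1:
            raise ValueError("codon_bias_strength must be in [0,1]")
        if self.noncoding_max_orf_nt > clo * hi:
            raise ValueError(
                "noncoding_max_orf_nt exceeds typical coding ORF lengths; "
                "classes would be indistinguishable"
            )
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


@dataclass(frozen=True)
class DatasetBundle:
    """Labeled shuffled corpus plus the resources its classifiers need."""

    records: list[TranscriptRecord]
    pwms: list[Pwm]
    bias_tables: CodingBiasTables
    config: GeneratorConfig


def _codon_probs(strength: float) -> np.ndarray:
    usage = np.array([CODON_USAGE_PER_1000[c] for c in SENSE_CODONS])
    usage = usage / usage.sum()
    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    p = strength * usage + (1.0 - strength) * uniform
    return p / p.sum()


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _gen_one_coding(
    rng: np.random.Generator, config: GeneratorConfig, codon_p: np.ndarray
) -> str:
    lo, hi = config.length_range
    clo, chi = config.coding_orf_coverage_range
    length = int(rng.integers(lo, hi + 1))
    coverage = rng.uniform(clo, chi)
    n_codons = max(3, int(round(coverage * length / 3)))
    if 3 * n_codons > length:
        n_codons = length // 3
    orf_nt = 3 * n_codons
    gc = rng.uniform(*config.gc_range)
    for _ in range(50):
        interior = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=codon_p)
        orf_seq = "AUG" + "".join(SENSE_CODONS[i] for i in interior) + STOP_CODONS[
            int(rng.integers(3))
        ]
        utr_total = length - orf_nt
        u5 = int(rng.integers(0, utr_total + 1))
        seq = _random_bases(rng, u5, gc) + orf_seq + _random_bases(rng, utr_total - u5, gc)
        longest = orf.longest_orf(seq)
        # UTR sampling can occasionally create an ORF engulfing the planted
        # one; accept only if the longest ORF stays within one codon of plan
        if longest is not None and longest.length_nt <= orf_nt + 3:
            return seq
    raise GenerationError(
        "could not plant a dominant ORF; coverage/length configuration too tight"
    )


def gen_coding(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> list[TranscriptRecord]:
    """Coding-class transcripts: random UTRs flanking a planted biased ORF."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    codon_p = _codon_probs(config.codon_bias_strength)
    return [
        TranscriptRecord(
            id=f"cod_{i:05d}", sequence=_gen_one_coding(rng, config, codon_p),
            label="coding",
        )
        for i in range(config.n_per_class)
    ]


def _gen_one_noncoding(
    rng: np.random.Generator, config: GeneratorConfig, gc: float
) -> str:
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    seq = _random_bases(rng, length, gc)
    cap = config.noncoding_max_orf_nt
    for _ in range(300):
        longest = orf.longest_orf(seq)
        if longest is None or longest.length_nt < cap:
            return seq
        # resample just the offending ORF's span, composition preserved
        s, e = longest.start - 1, longest.end
        seq = seq[:s] + _random_bases(rng, e - s, gc) + seq[e:]
    raise GenerationError(
        f"could not suppress ORFs below {cap} nt; consider a looser cap"
    )


def gen_noncoding(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    match_gc: Optional[Sequence[float]] = None,
) -> list[TranscriptRecord]:
    """Noncoding-class transcripts: ORF-poor, composition-matched.

    When ``match_gc`` is given (one value per record, e.g. the coding
    corpus's empirical GC contents) each record targets the corresponding
    GC; otherwise GC is drawn uniformly from the configured range.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    records = []
    for i in range(config.n_per_class):
        if match_gc is not None:
            gc = float(match_gc[i % len(match_gc)])
        else:
            gc = rng.uniform(*config.gc_range)
        records.append(
            TranscriptRecord(
                id=f"nc_{i:05d}",
                sequence=_gen_one_noncoding(rng, config, gc),
                label="noncoding",
            )
        )
    return records


def gen_pwms(
    n: int,
    length_range: tuple[int, int] = (6, 10),
    seed: int = 0,
) -> list[Pwm]:
    """Random informative PWMs: one dominant base per column (p 0.7–0.97)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        matrix = np.empty((L, 4))
        for col in range(L):
            dom = int(rng.integers(4))
            p = rng.uniform(0.7, 0.97)
            matrix[col] = (1 - p) / 3
            matrix[col, dom] = p
        pwms.append(Pwm(name=f"rbp_{i + 1:03d}", matrix=matrix))
    return pwms


def gen_dataset(config: GeneratorConfig) -> DatasetBundle:
    """Balanced, shuffled corpus with PWMs and hexamer bias tables.

    The bias tables are built from a held-out generated corpus (up to
    300/class, drawn from the same configuration) so the features computed
    on the returned records are not fit on those same records.
    """
    rng = np.random.default_rng(config.seed)
    coding = gen_coding(config, rng)
    coding_gc = [
        (r.sequence.count("G") + r.sequence.count("C")) / r.length for r in coding
    ]
    perm = rng.permutation(len(coding_gc))
    noncoding = gen_noncoding(config, rng, match_gc=[coding_gc[p] for p in perm])

    n_table = min(300, config.n_per_class)
    table_cfg = replace(config, n_per_class=n_table)
    table_coding = [
        replace_id(r, f"tbl_{r.id}") for r in gen_coding(table_cfg, rng)
    ]
    table_noncoding = [
        replace_id(r, f"tbl_{r.id}") for r in gen_noncoding(table_cfg, rng)
    ]
    tables = build_hexamer_table(table_coding, table_noncoding)

    records = coding + noncoding
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    pwms = gen_pwms(5, seed=config.seed + 7)
    return DatasetBundle(records=records, pwms=pwms, bias_tables=tables, config=config)


def replace_id(record: TranscriptRecord, new_id: str) -> TranscriptRecord:
    return TranscriptRecord(id=new_id, sequence=record.sequence, label=record.label)
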