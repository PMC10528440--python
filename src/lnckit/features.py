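"""Three-tier feature hierarchy for coding/noncoding discrimination.

Features come in three groups mirroring how a transcript can be read:

* sequence-based — mono-/di-nucleotide frequencies, GC content, log-length,
  ORF statistics, plus two human-trained coding-bias statistics (the Fickett
  TESTCODE score and the in-frame hexamer usage log-ratio);
* structure-based — pseudo-MFE, per-nucleotide pseudo-MFE, paired fraction,
  paired/unpaired transition frequency and GC fraction of paired positions,
  all from the windowed folder;
* interactome-based — RBP PWM hit density, best relative PWM score, and the
  triplex-forming potential.

Four model configurations select from the roster: HSS (human-specific
standard, all 35 features), SAS (species-agnostic standard, 33 — the two
bias-table features dropped), and HSB/SAB (basic, the top-10 subsets chosen
by recursive feature elimination, vendored in :data:`HSB_FEATURES` /
:data:`SAB_FEATURES` and regenerable via :func:`lnckit.classify.rfe`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import annotate, folding, orf
from .annotate import Pwm
from .seqio import TranscriptRecord

BASES = "ACGU"
CONFIGS = ("HSB", "HSS", "SAB", "SAS")

#: minimum ORF length (nt) counted by the orf_count feature
ORF_COUNT_MIN_NT = 75

# ---------------------------------------------------------------------------
# Fickett (1982) TESTCODE lookup tables.
# Position parameters measure base asymmetry across the three codon
# positions; content parameters measure overall composition. Each raw value
# is mapped through interval thresholds to a coding probability, then
# combined in a weighted sum. Tables are the published constants (spelled on
# the RNA alphabet: U plays the role of T).

_FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "U": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "U": 0.33}
_FICKETT_POSITION_THRESH = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "U": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "U": 0.14}
_FICKETT_CONTENT_THRESH = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


class FeatureConfigError(ValueError):
    """Raised when resources do not match the requested configuration."""


@dataclass(frozen=True)
class CodingBiasTables:
    """Hexamer usage log-ratio table (coding vs noncoding corpora).

    Covers all 4096 hexamers; hexamers absent from either training corpus
    fall back to log-ratio 0.
    """

    hexamer_logratio: Mapping[str, float]

    def lookup(self, hexamer: str) -> float:
        return self.hexamer_logratio.get(hexamer, 0.0)


@dataclass(frozen=True)
class FeatureResources:
    """Bundle of external inputs needed by the extractor."""

    pwms: Sequence[Pwm]
    bias_tables: Optional[CodingBiasTables] = None
    scan_threshold: float = annotate.DEFAULT_MIN_RELATIVE_SCORE
    window_nt: int = 500
    overlap_nt: int = 250


@dataclass(frozen=True)
class FeatureVector:
    values: dict[str, float]
    config: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.config not in CONFIGS:
            raise ValueError(f"unknown config {self.config!r}")
        expected = len(feature_names(self.config))
        if len(self.values) != expected:
            raise ValueError(
                f"{self.config} expects {expected} features, got {len(self.values)}"
            )
        if any(math.isnan(v) for v in self.values.values()):
            raise ValueError("NaN feature value")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


# ---------------------------------------------------------------------------
# individual features


def kmer_frequencies(sequence: str, k: int) -> dict[str, float]:
    """Sliding-window k-mer frequencies, normalized to sum to 1.

    Windows containing ambiguity codes are skipped. A sequence shorter than
    k (or with no unambiguous window) yields the all-zero map.
    """
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    counts = dict.fromkeys(kmers, 0)
    total = 0
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if window in counts:
            counts[window] += 1
            total += 1
    if total == 0:
        return {m: 0.0 for m in kmers}
    return {m: c / total for m, c in counts.items()}


def gc_content(sequence: str) -> float:
    """(G+C) / unambiguous bases; 0 for an all-ambiguous sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    unamb = sum(sequence.count(b) for b in BASES)
    if unamb == 0:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / unamb


def _fickett_lookup(value: float, thresholds, probs) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett (1982) TESTCODE statistic.

    Eight parameters — per-base position asymmetry (max/(min+1) of counts at
    the three codon positions) and per-base content fraction — are each
    mapped through the published lookup tables and combined in the published
    weighted sum. T and U spellings score identically.
    """
    seq = sequence.upper().replace("T", "U")
    score = 0.0
    for base in BASES:
        pos_counts = [seq[off::3].count(base) for off in range(3)]
        pos_value = max(pos_counts) / (min(pos_counts) + 1)
        score += (
            _fickett_lookup(pos_value, _FICKETT_POSITION_THRESH, _FICKETT_POSITION_PROB[base])
            * _FICKETT_POSITION_WEIGHT[base]
        )
        content = seq.count(base) / len(seq) if seq else 0.0
        score += (
            _fickett_lookup(content, _FICKETT_CONTENT_THRESH, _FICKETT_CONTENT_PROB[base])
            * _FICKETT_CONTENT_WEIGHT[base]
        )
    return score


def hexamer_bias(sequence: str, tables: CodingBiasTables) -> float:
    """Mean hexamer log-ratio over in-frame 6-mers.

    The reading frame is that of the longest ORF when one exists, else
    frame 0; 6-mers step by 3 (codon-wise) within the chosen frame.
    """
    if len(sequence) < 6:
        raise ValueError("sequence shorter than 6 nt")
    best = orf.longest_orf(sequence)
    frame = (best.start - 1) % 3 if best is not None else 0
    values = [
        tables.lookup(sequence[i : i + 6])
        for i in range(frame, len(sequence) - 5, 3)
    ]
    if not values:
        return 0.0
    return float(np.mean(values))


def build_hexamer_table(
    coding: Sequence[TranscriptRecord], noncoding: Sequence[TranscriptRecord]
) -> CodingBiasTables:
    """Build the hexamer log-ratio table from labeled corpora.

    Coding counts are taken codon-wise in the frame of each transcript's
    longest ORF; noncoding counts over all frames. Log-ratio =
    log((f_coding + eps)/(f_noncoding + eps)); hexamers unobserved in both
    corpora get 0.
    """
    def count(records: Sequence[TranscriptRecord], in_frame: bool) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in records:
            seq = r.sequence
            if in_frame:
                best = orf.longest_orf(seq)
                frame = (best.start - 1) % 3 if best is not None else 0
                rng = range(frame, len(seq) - 5, 3)
            else:
                rng = range(len(seq) - 5)
            for i in rng:
                h = seq[i : i + 6]
                counts[h] = counts.get(h, 0) + 1
        return counts

    c = count(coding, in_frame=True)
    nc = count(noncoding, in_frame=False)
    tc = sum(c.values()) or 1
    tn = sum(nc.values()) or 1
    eps = 1e-6
    table = {}
    for h in ("".join(p) for p in itertools.product(BASES, repeat=6)):
        fc, fn = c.get(h, 0) / tc, nc.get(h, 0) / tn
        table[h] = 0.0 if (fc == 0 and fn == 0) else math.log((fc + eps) / (fn + eps))
    return CodingBiasTables(hexamer_logratio=table)


def orf_features(sequence: str) -> tuple[float, float, int]:
    """(longest ORF nt, ORF coverage, count of ORFs >= 75 nt)."""
    orfs = orf.find_orfs(sequence)
    longest = max((o.length_nt for o in orfs), default=0)
    coverage = longest / len(sequence)
    count = sum(1 for o in orfs if o.length_nt >= ORF_COUNT_MIN_NT)
    return float(longest), coverage, count


def structure_features(
    sequence: str, window_nt: int = 500, overlap_nt: int = 250
) -> tuple[float, float, float, float, float]:
    """(mfe, mfe_per_nt, paired_fraction, transition_freq, paired_gc_fraction)."""
    st = folding.fold_windowed(sequence, window_nt, overlap_nt)
    n = len(sequence)
    paired = st.paired_positions
    paired_fraction = 2 * len(st.pairs) / n
    tf = folding.transition_frequency(st)
    if paired:
        paired_gc = sum(1 for p in paired if sequence[p - 1] in "GC") / len(paired)
    else:
        paired_gc = 0.0
    return st.score, st.score / n, paired_fraction, tf, paired_gc


def interactome_features(
    sequence: str,
    pwms: Sequence[Pwm],
    scan_threshold: float = annotate.DEFAULT_MIN_RELATIVE_SCORE,
) -> tuple[float, float, float]:
    """(rbp_hit_density per kb, max relative PWM score, triplex potential)."""
    if not pwms:
        raise FeatureConfigError("interactome features require at least one PWM")
    n_hits = 0
    max_rel = 0.0
    for pwm in pwms:
        _, relative = annotate.window_scores(sequence, pwm)
        if relative.size:
            max_rel = max(max_rel, float(relative.max()))
            n_hits += int((relative >= scan_threshold).sum())
    density = n_hits / len(sequence) * 1000.0
    return density, max_rel, annotate.tfp_score(sequence).value


# ---------------------------------------------------------------------------
# rosters and assembly

_MONO = [f"freq_{b}" for b in BASES]
_DI = [f"freq_{a}{b}" for a, b in itertools.product(BASES, repeat=2)]

#: the full human-specific roster, in fixed order (35 features)
HSS_FEATURES: tuple[str, ...] = tuple(
    _MONO
    + _DI
    + [
        "gc_content",
        "log10_length",
        "longest_orf_nt",
        "orf_coverage",
        "orf_count",
        "fickett_score",
        "hexamer_bias",
        "mfe",
        "mfe_per_nt",
        "paired_fraction",
        "transition_freq",
        "paired_gc_fraction",
        "rbp_hit_density",
        "max_pwm_relative_score",
        "tfp",
    ]
)

#: the two features parameterized on human training data
HUMAN_SPECIFIC_FEATURES: tuple[str, ...] = ("fickett_score", "hexamer_bias")

#: species-agnostic roster (33 features)
SAS_FEATURES: tuple[str, ...] = tuple(
    f for f in HSS_FEATURES if f not in HUMAN_SPECIFIC_FEATURES
)

#: Top-10 subsets selected by recursive feature elimination (SHAP-ranked ANN,
#: one feature dropped per round) on the default synthetic dataset; regenerate
#: with ``classify.rfe`` on any labeled corpus. Order is final-rank order.
HSB_FEATURES: tuple[str, ...] = (
    "orf_coverage",
    "hexamer_bias",
    "orf_count",
    "fickett_score",
    "freq_GA",
    "freq_GU",
    "mfe",
    "longest_orf_nt",
    "freq_AG",
    "freq_CA",
)
SAB_FEATURES: tuple[str, ...] = (
    "orf_coverage",
    "freq_GU",
    "freq_UG",
    "freq_CA",
    "longest_orf_nt",
    "freq_CG",
    "orf_count",
    "freq_AA",
    "freq_UA",
    "freq_AG",
)


def feature_names(config: str) -> tuple[str, ...]:
    """The ordered feature roster for a model configuration."""
    try:
        return {
            "HSS": HSS_FEATURES,
            "SAS": SAS_FEATURES,
            "HSB": HSB_FEATURES,
            "SAB": SAB_FEATURES,
        }[config]
    except KeyError:
        raise ValueError(f"unknown config {config!r}") from None


def extract_features(
    record: TranscriptRecord, config: str, resources: FeatureResources
) -> FeatureVector:
    """Assemble the named feature vector for one transcript.

    HS configurations require bias tables in the resources; basic
    configurations compute only their stored top-10 subset's dependencies.
    Degenerate inputs (e.g. all-ambiguous) set the degenerate flag instead
    of raising.
    """
    names = feature_names(config)
    if config in ("HSB", "HSS") and resources.bias_tables is None:
        raise FeatureConfigError(f"{config} requires CodingBiasTables resources")
    seq = record.sequence
    degenerate = gc_content(seq) == 0.0 and not any(b in seq for b in BASES)

    full: dict[str, float] = {}
    needed = set(names)
    mono = kmer_frequencies(seq, 1)
    di = kmer_frequencies(seq, 2) if len(seq) >= 2 else dict.fromkeys(_DI, 0.0)
    for b in BASES:
        full[f"freq_{b}"] = mono[b]
    for d in _DI:
        full[d] = di[d[5:]]
    full["gc_content"] = gc_content(seq)
    full["log10_length"] = math.log10(record.length)
    longest, coverage, count = orf_features(seq)
    full["longest_orf_nt"] = longest
    full["orf_coverage"] = coverage
    full["orf_count"] = float(count)
    if "fickett_score" in needed:
        full["fickett_score"] = fickett_score(seq)
    if "hexamer_bias" in needed:
        full["hexamer_bias"] = (
            hexamer_bias(seq, resources.bias_tables) if len(seq) >= 6 else 0.0
        )
    if needed & {"mfe", "mfe_per_nt", "paired_fraction", "transition_freq", "paired_gc_fraction"}:
        mfe, mfe_nt, pf, tf, pgc = structure_features(
            seq, resources.window_nt, resources.overlap_nt
        )
        full.update(
            mfe=mfe, mfe_per_nt=mfe_nt, paired_fraction=pf,
            transition_freq=tf, paired_gc_fraction=pgc,
        )
    if needed & {"rbp_hit_density", "max_pwm_relative_score", "tfp"}:
        dens, max_rel, tfp = interactome_features(
            seq, resources.pwms, resources.scan_threshold
        )
        full.update(rbp_hit_density=dens, max_pwm_relative_score=max_rel, tfp=tfp)

    values = {name: full[name] for name in names}
    return FeatureVector(values=values, config=config, degenerate=degenerate)


def feature_matrix(
    records: Sequence[TranscriptRecord], config: str, resources: FeatureResources
) -> tuple[np.ndarray, list[str]]:
    """(n_records, n_features) matrix plus the feature-name header."""
    names = list(feature_names(config))
    X = np.array(
        [extract_features(r, config, resources).as_array() for r in records]
    )
    return X, names


def write_feature_matrix(
    X: np.ndarray,
    names: Sequence[str],
    records: Sequence[TranscriptRecord],
    path: str | Path,
) -> None:
    """TSV with a feature-name header row and one row per transcript."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for r, row in zip(records, X):
            fh.write(r.id + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_hexamer_table(tables: CodingBiasTables, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hexamer\tlogratio\n")
        for h in sorted(tables.hexamer_logratio):
            fh.write(f"{h}\t{tables.hexamer_logratio[h]:.6g}\n")


def read_hexamer_table(path: str | Path) -> CodingBiasTables:
    table: dict[str, float] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            h, v = line.split()
            table[h] = float(v)
    return CodingBiasTables(hexamer_logratio=table)
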