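"""Exact global pairwise alignment and read-QC primitives.

This module is the alignment substrate for the whole package: global
(Needleman-Wunsch) protein alignment with affine gaps, alignment
identity on the USEARCH-style denominator (terminal-gap columns
excluded), six-frame translation, paired-read merging and
expected-error trimming, plus thin FASTA/FASTQ readers and writers.

The dynamic programming itself is delegated to Biopython's
``PairwiseAligner`` (a C implementation); scoring defaults to BLOSUM62
with gap open -11 / extend -1, and the matrix is patched so that ``X``
scores 0 against everything (tolerated, mismatch-neutral).  Identity
thresholds, not raw scores, drive every downstream decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import DEFAULT_CONFIG, AnalysisConfig

__all__ = [
    "ScoringScheme",
    "Alignment",
    "QualRead",
    "needleman_wunsch",
    "global_identity",
    "align_stats",
    "translate_6frames",
    "merge_pairs",
    "expected_error_trim",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "load_scoring_matrix",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties + identity convention."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    identity_denominator: str = "exclude_terminal_gaps"
    matrix_path: str | None = None  # NCBI-format matrix file overrides matrix_name

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "ScoringScheme":
        return cls(
            matrix_name=config.matrix_name,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            identity_denominator=config.identity_denominator,
        )


DEFAULT_SCORING = ScoringScheme()

_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def load_scoring_matrix(path) -> substitution_matrices.Array:
    """Load a substitution matrix from an NCBI-format matrix file."""
    with open(path) as fh:
        return substitution_matrices.read(fh)


def _build_matrix(scheme: ScoringScheme) -> substitution_matrices.Array:
    if scheme.matrix_path is not None:
        mat = load_scoring_matrix(scheme.matrix_path)
    else:
        mat = substitution_matrices.load(scheme.matrix_name)
    if "X" in mat.alphabet:  # X is tolerated and mismatch-neutral
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


def get_aligner(scheme: ScoringScheme = DEFAULT_SCORING) -> Align.PairwiseAligner:
    """A cached global ``PairwiseAligner`` for the given scheme."""
    aligner = _ALIGNER_CACHE.get(scheme)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = _build_matrix(scheme)
        aligner.open_gap_score = scheme.gap_open
        aligner.extend_gap_score = scheme.gap_extend
        aligner.mode = "global"
        _ALIGNER_CACHE[scheme] = aligner
    return aligner


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """One optimal global alignment.

    ``identity`` counts matched columns over the column count implied by
    the scheme's denominator convention (terminal-gap columns excluded
    by default, internal gap columns always counted).
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    columns: int


def _check_pair(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")


def _identity_from_counts(counts, scheme: ScoringScheme) -> tuple[float, int]:
    core = counts.identities + counts.mismatches + counts.internal_gaps
    if scheme.identity_denominator == "all_columns":
        denom = core + counts.left_gaps + counts.right_gaps
    else:
        denom = core
    identity = counts.identities / denom if denom else 0.0
    return identity, denom


def align_stats(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCORING
) -> tuple[float, int, float]:
    """``(identity, columns, score)`` of the optimal global alignment.

    Fast path used by the screening loops: no alignment strings are
    materialized.  The pair is aligned in a canonical argument order so
    the reported identity is exactly symmetric even when co-optimal
    tracebacks disagree on the column layout.
    """
    _check_pair(a, b)
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = get_aligner(scheme).align(a, b)[0]
    identity, columns = _identity_from_counts(aln.counts(), scheme)
    return identity, columns, aln.score


def needleman_wunsch(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Optimal global alignment of two protein sequences.

    Affine-gap Needleman-Wunsch over the full dynamic-programming
    matrix; the first optimal traceback reported by the aligner is
    returned (deterministic for given inputs).
    """
    _check_pair(a, b)
    aln = get_aligner(scheme).align(a, b)[0]
    identity, columns = _identity_from_counts(aln.counts(), scheme)
    return Alignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=aln.score,
        identity=identity,
        columns=columns,
    )


def global_identity(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCORING) -> float:
    """Identity of the optimal global alignment (symmetric in a, b)."""
    return align_stats(a, b, scheme)[0]


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_6frames(dna: str) -> tuple[str, str, str, str, str, str]:
    """Translate ``dna`` in all six frames under the standard code.

    Returns peptides for frames +1, +2, +3, -1, -2, -3.  Stop codons are
    emitted as ``*``; any codon containing ``N`` is emitted as ``X``.
    Trailing partial codons are ignored.
    """
    dna = dna.upper()
    frames = []
    for strand_seq in (dna, reverse_complement(dna)):
        for off in range(3):
            sub = strand_seq[off : off + (len(strand_seq) - off) // 3 * 3]
            if sub:
                frames.append(str(Seq(sub).translate()))
            else:
                frames.append("")
    return tuple(frames)


# ---------------------------------------------------------------------------
# quality reads
# ---------------------------------------------------------------------------

@dataclass
class QualRead:
    """A DNA read with per-base Phred quality scores."""

    name: str
    sequence: str
    qualities: np.ndarray  # int array, Phred scale

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError("Phred qualities must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)

    def error_probs(self) -> np.ndarray:
        return np.power(10.0, -self.qualities / 10.0)

    def expected_errors(self) -> float:
        return float(self.error_probs().sum())


def merge_pairs(
    r1: QualRead, r2: QualRead, config: AnalysisConfig = DEFAULT_CONFIG
) -> QualRead | None:
    """Merge a read pair by its best ungapped overlap, or return ``None``.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally.  Candidate overlaps are scored by (fewest mismatches,
    then longest overlap); the merge is accepted iff the best overlap
    spans at least ``merge_min_overlap`` bases with at most
    ``merge_max_diffs`` mismatches.  Staggered overlaps are allowed and
    their overhangs trimmed.  Merged qualities take the higher Phred at
    agreeing positions and the higher-quality base at conflicts.
    """
    if not len(r1) or not len(r2):
        raise ValueError("cannot merge an empty read")
    s2 = reverse_complement(r2.sequence)
    q2 = r2.qualities[::-1]
    a1 = np.frombuffer(r1.sequence.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    n1, n2 = len(a1), len(a2)

    best: tuple[int, int, int] | None = None  # (mismatches, -overlap, shift)
    # shift = index of s2[0] relative to r1[0]; negative = staggered left overhang
    for shift in range(-(n2 - 1), n1):
        lo = max(0, shift)
        hi = min(n1, shift + n2)
        ov = hi - lo
        if ov < config.merge_min_overlap:
            continue
        mism = int((a1[lo:hi] != a2[lo - shift : hi - shift]).sum())
        if mism > config.merge_max_diffs:
            continue
        key = (mism, -ov, shift)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mism, neg_ov, shift = best
    lo = max(0, shift)
    hi = min(n1, shift + n2)

    # consensus over the overlap
    seq1 = np.array(list(r1.sequence))
    seq2 = np.array(list(s2))
    o1s, o1q = seq1[lo:hi], r1.qualities[lo:hi]
    o2s, o2q = seq2[lo - shift : hi - shift], q2[lo - shift : hi - shift]
    agree = o1s == o2s
    cons_seq = np.where(agree | (o1q >= o2q), o1s, o2s)
    cons_q = np.where(agree, np.maximum(o1q, o2q), np.maximum(o1q, o2q))

    parts_s: list[str] = []
    parts_q: list[np.ndarray] = []
    if shift > 0:  # r1-only left flank (kept; a left s2 overhang is trimmed)
        parts_s.append(r1.sequence[:lo])
        parts_q.append(r1.qualities[:lo])
    parts_s.append("".join(cons_seq))
    parts_q.append(cons_q)
    if shift + n2 > n1:  # s2-only right flank (a right r1 overhang is trimmed)
        parts_s.append(s2[hi - shift :])
        parts_q.append(q2[hi - shift :])
    return QualRead(
        name=r1.name,
        sequence="".join(parts_s),
        qualities=np.concatenate(parts_q),
    )


def expected_error_trim(
    read: QualRead, max_ee: float = DEFAULT_CONFIG.max_expected_errors
) -> QualRead:
    """Longest contiguous window with total expected errors strictly below ``max_ee``.

    Expected errors are the sum of per-base error probabilities
    ``10^(-Q/10)``.  Ties go to the leftmost window; the result may be
    empty.  O(n) two-pointer scan.
    """
    probs = read.error_probs()
    n = len(probs)
    best_len, best_start = 0, 0
    left = 0
    total = 0.0
    for right in range(n):
        total += probs[right]
        while left <= right and total >= max_ee:
            total -= probs[left]
            left += 1
        if right - left + 1 > best_len:
            best_len = right - left + 1
            best_start = left
    return QualRead(
        name=read.name,
        sequence=read.sequence[best_start : best_start + best_len],
        qualities=read.qualities[best_start : best_start + best_len],
    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Phred+33 on disk)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered ``{id: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in items
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> Iterator[QualRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield QualRead(
            name=rec.id,
            sequence=str(rec.seq),
            qualities=np.array(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[QualRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
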