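"""Pairwise homology: local alignment, BLAST coverage ratios (BCR), and the
accretion decision rule.

The pan-genome accretion algorithm decides whether a query gene is homologous
to a gene already in the pool by aligning the pair, computing the fraction of
*each* sequence covered by the alignment (the two BCR values), and rejecting
the pair only when *both* coverage ratios fall below a configurable cutoff or
the percent identity is too low.  This module provides that primitive plus a
k-mer prefilter used to skip obviously unrelated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "PairwiseHit",
    "HomologyThresholds",
    "align_pair",
    "compute_bcr",
    "is_homologous",
    "kmer_set",
    "shared_kmer_count",
    "passes_prefilter",
    "write_hits_tsv",
]

_NUC_CHARS = set("ACGTUNRYSWKMBDHV")
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length L
    costs ``gap_open + L * gap_extend``.  For proteins a named substitution
    matrix is used; for nucleotides, match/mismatch scores.
    """

    alphabet: str = "nucleotide"  # or "protein"
    matrix: Optional[str] = None  # e.g. "BLOSUM62" (protein only)
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {self.alphabet!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls(alphabet="nucleotide", match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0)

    @classmethod
    def protein(cls) -> "ScoringScheme":
        return cls(alphabet="protein", matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0)

    @property
    def prefilter_k(self) -> int:
        return 11 if self.alphabet == "nucleotide" else 4


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scheme.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    # affine convention: opening a gap of length 1 costs open + extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class PairwiseHit:
    """One query-vs-subject local alignment summary."""

    query_id: str
    subject_id: str
    identity_pct: float  # over aligned columns, gap columns excluded
    aln_len_query: int  # query residues inside aligned (gap-free) columns
    aln_len_subject: int
    bcr_query: float  # aln_len_query / query length
    bcr_subject: float
    score: float

    def as_row(self) -> tuple:
        return (
            self.query_id,
            self.subject_id,
            round(self.identity_pct, 2),
            round(self.bcr_query, 4),
            round(self.bcr_subject, 4),
            self.score,
        )


@dataclass(frozen=True)
class HomologyThresholds:
    """Cutoffs for the homology decision.

    ``bcr_min`` is the coverage "setting value": a pair is rejected only when
    *both* coverage ratios are below it.  ``identity_min`` is percent identity
    over aligned columns; ``min_len`` is the minimum aligned length in
    residues on the query.
    """

    bcr_min: float = 0.5
    identity_min: float = 70.0
    min_len: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.bcr_min <= 1.0):
            raise ValueError("bcr_min must be in [0, 1]")
        if not (0.0 <= self.identity_min <= 100.0):
            raise ValueError("identity_min must be in [0, 100]")
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")

    @classmethod
    def for_alphabet(cls, alphabet: str, bcr_min: float = 0.5, min_len: int = 30) -> "HomologyThresholds":
        identity = 70.0 if alphabet == "nucleotide" else 50.0
        return cls(bcr_min=bcr_min, identity_min=identity, min_len=min_len)


def _check_sequence(seq: str, alphabet: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    chars = set(seq.upper())
    allowed = _NUC_CHARS if alphabet == "nucleotide" else _PROT_CHARS
    if not chars <= allowed:
        bad = "".join(sorted(chars - allowed))
        raise ValueError(
            f"{name} sequence contains characters {bad!r} not valid for alphabet {alphabet!r}"
        )


def align_pair(
    a: str,
    b: str,
    scoring: Optional[ScoringScheme] = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseHit:
    """Smith-Waterman local alignment of ``a`` (query) against ``b`` (subject).

    Identity is counted over aligned columns with gap columns excluded from
    the denominator (the BLAST convention).  Coverage on each side counts the
    residues of that sequence participating in aligned columns.  When no
    positive-scoring local alignment exists the hit has score 0 and both BCR
    values 0.
    """
    scoring = scoring or ScoringScheme.nucleotide()
    _check_sequence(a, scoring.alphabet, "query")
    _check_sequence(b, scoring.alphabet, "subject")
    a = a.upper()
    b = b.upper()
    if a == b:
        # identical sequences: the full-length gapless alignment is optimal
        # whenever diagonal scores are positive, so skip the quadratic DP
        score = _perfect_score(a, scoring)
        if score > 0:
            return PairwiseHit(query_id, subject_id, 100.0, len(a), len(b), 1.0, 1.0, score)
    aligner = _aligner(scoring)
    try:
        alignments = aligner.align(a, b)
        score = alignments.score
    except Exception:
        score = 0.0
        alignments = None
    if alignments is None or score <= 0 or len(a) == 0 or len(b) == 0:
        return PairwiseHit(query_id, subject_id, 0.0, 0, 0, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        return PairwiseHit(query_id, subject_id, 0.0, 0, 0, 0.0, 0.0, float(score))
    identity_pct = 100.0 * counts.identities / aligned_cols
    # aligned blocks on each sequence; gap-free column residues per side
    blocks_a, blocks_b = aln.aligned
    cov_a = int(sum(end - start for start, end in blocks_a))
    cov_b = int(sum(end - start for start, end in blocks_b))
    bcr_q, bcr_s = compute_bcr(cov_a, len(a), cov_b, len(b))
    return PairwiseHit(query_id, subject_id, identity_pct, cov_a, cov_b, bcr_q, bcr_s, float(score))


def compute_bcr(
    aln_len_query: int, query_len: int, aln_len_subject: int, subject_len: int
) -> tuple[float, float]:
    """Coverage ratio of each side of a hit: aligned residues / sequence length."""
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if not (0 <= aln_len_query <= query_len) or not (0 <= aln_len_subject <= subject_len):
        raise ValueError("aligned length outside [0, sequence length]")
    return aln_len_query / query_len, aln_len_subject / subject_len


def is_homologous(hit: PairwiseHit, th: HomologyThresholds) -> bool:
    """Accretion decision: reject only if *both* BCR values are below
    ``bcr_min``, the identity is below ``identity_min``, or the aligned query
    length is below ``min_len``; accept otherwise."""
    if hit.aln_len_query < th.min_len:
        return False
    if hit.identity_pct < th.identity_min:
        return False
    if hit.bcr_query < th.bcr_min and hit.bcr_subject < th.bcr_min:
        return False
    return True


def _perfect_score(seq: str, scoring: ScoringScheme) -> float:
    if scoring.matrix is None:
        return scoring.match * len(seq)
    matrix = substitution_matrices.load(scoring.matrix)
    return float(sum(matrix[c, c] for c in seq))


def kmer_set(seq: str, k: int) -> frozenset:
    seq = seq.upper()
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def shared_kmer_count(kmers_a: frozenset, kmers_b: frozenset) -> int:
    return len(kmers_a & kmers_b)


def prefilter_min_shared(len_a: int, len_b: int) -> int:
    # scaled with length: at ~3 kb random nucleotide pairs share ~2 11-mers
    # by chance, so a flat threshold would admit most junk pairs at gene
    # lengths in the kb range; homologs at >=70% identity share ~2% of
    # their 11-mers, far above min(L)/200
    return max(3, min(len_a, len_b) // 200)


def passes_prefilter(
    kmers_a: frozenset, kmers_b: frozenset, len_a: int, len_b: int
) -> bool:
    return shared_kmer_count(kmers_a, kmers_b) >= prefilter_min_shared(len_a, len_b)


def write_hits_tsv(hits: Iterable[PairwiseHit], path) -> None:
    """BLAST outfmt-6-like table: query, subject, identity, qcov, scov, score."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tidentity\tqcov\tscov\tscore\n")
        for hit in hits:
            fh.write("\t".join(str(x) for x in hit.as_row()) + "\n")
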