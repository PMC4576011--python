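"""Exact pairwise alignment with Karlin-Altschul E-value scoring.

This is the search engine behind both rounds of the reciprocal ortholog
screen and behind the per-pathway protein-similarity summaries.  Unlike the
heuristic tools normally used at genome scale, the engine computes *exact*
optimal alignments (Smith-Waterman locally, Needleman-Wunsch globally) under
affine gap penalties, so desk-scale results are deterministic and can be
checked against independent oracles.  Externally produced tabular hit files
remain interchangeable through :mod:`florthograph.core_io`.

Scoring conventions
-------------------
A gap of length ``L`` costs ``gap_open + L * gap_extend`` (both negative),
i.e. an opening charge plus a per-residue charge.  The default protein scheme
is BLOSUM62 with gap open -11 / extend -1 and gapped Karlin-Altschul
parameters K = 0.041, lambda = 0.267; the raw score ``S`` converts to

    E = K * m * n * exp(-lambda * S)        (expect value)
    S' = (lambda * S - ln K) / ln 2         (bit score)

where ``m`` is the query length and ``n`` the total residue count of the
database searched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .core_io import HitRecord, SequenceRecord

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "local_align",
    "evalue",
    "bit_score",
    "search",
    "percent_similarity_global",
]

_NEG_INF = -(10**9)


# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------


def _blosum62() -> substitution_matrices.Array:
    return substitution_matrices.load("BLOSUM62")


def _nucleotide_matrix(match: int = 2, mismatch: int = -3) -> substitution_matrices.Array:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and Karlin-Altschul parameters."""

    substitution_matrix: substitution_matrices.Array = field(default_factory=_blosum62)
    gap_open: int = -11
    gap_extend: int = -1
    K: float = 0.041
    lam: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_extend < self.gap_open:
            raise ValueError("gap_extend must be >= gap_open (less penalizing)")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be strictly positive")
        arr = np.asarray(self.substitution_matrix)
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        # Karlin-Altschul parameters for +2/-3 with affine gaps (megablast-era
        # gapped values).
        return cls(substitution_matrix=_nucleotide_matrix(), gap_open=-5,
                   gap_extend=-2, K=0.21, lam=0.99)

    @property
    def alphabet(self) -> str:
        return str(self.substitution_matrix.alphabet)

    def encode(self, residues: str) -> np.ndarray:
        """Residues -> int8 index array into the substitution matrix."""
        table = _encoder_for(self.alphabet)
        try:
            return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
        except KeyError:  # pragma: no cover
            raise ValueError("residue outside scoring-matrix alphabet")

    def matrix_array(self) -> np.ndarray:
        return np.asarray(self.substitution_matrix, dtype=np.int32)


@lru_cache(maxsize=8)
def _encoder_for(alphabet: str) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table


def _check_encoded(enc: np.ndarray, rec: SequenceRecord, scheme: ScoringScheme) -> np.ndarray:
    if (enc < 0).any():
        bad = sorted(set(rec.residues) - set(scheme.alphabet))
        raise ValueError(
            f"sequence {rec.id!r} contains residues {bad} outside the "
            f"scoring-matrix alphabet"
        )
    return enc


# ---------------------------------------------------------------------------
# Smith-Waterman score kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_score_kernel(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
                     gap_open: int, gap_extend: int) -> int:  # pragma: no cover - compiled
    n = b.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, _NEG_INF, dtype=np.int64)
    best = 0
    for i in range(a.shape[0]):
        diag = 0
        F = _NEG_INF
        ai = a[i]
        for j in range(1, n + 1):
            e = E[j] + gap_extend
            e2 = H[j] + gap_open + gap_extend
            E[j] = e if e > e2 else e2
            f = F + gap_extend
            f2 = H[j - 1] + gap_open + gap_extend
            F = f if f > f2 else f2
            h = diag + sub[ai, b[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def sw_score(a: SequenceRecord | str, b: SequenceRecord | str,
             scheme: ScoringScheme | None = None) -> int:
    """Optimal Smith-Waterman local-alignment score (score only, fast path)."""
    scheme = scheme or ScoringScheme.protein_default()
    ra = a.residues if isinstance(a, SequenceRecord) else a
    rb = b.residues if isinstance(b, SequenceRecord) else b
    ea = scheme.encode(ra)
    eb = scheme.encode(rb)
    if (ea < 0).any() or (eb < 0).any():
        raise ValueError("residue outside scoring-matrix alphabet")
    return int(_sw_score_kernel(ea, eb, scheme.matrix_array(),
                                scheme.gap_open, scheme.gap_extend))


# ---------------------------------------------------------------------------
# Alignment results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    """An alignment with derived identity/similarity statistics.

    ``percent_similarity`` counts aligned columns whose substitution score is
    positive (conservative substitutions included); gap columns never count.
    Intervals are 1-based inclusive on the original sequences; an empty
    alignment (no positive-scoring cell in local mode) has score 0, length 0
    and ``evalue = inf``.
    """

    score: float
    bit_score: float
    evalue: float
    percent_identity: float
    percent_similarity: float
    alignment_length: int
    identities: int
    mismatches: int
    gap_opens: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.substitution_matrix
    # Biopython charges open_gap_score for a gap's first residue; our
    # convention charges gap_open + gap_extend for it.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    aligner.mode = mode
    return aligner


def _column_stats(alignment, scheme: ScoringScheme) -> tuple[int, int, int, int, int]:
    """(columns, identities, positives, mismatches, gap_opens) of an alignment."""
    sub = scheme.substitution_matrix
    qa, sa = str(alignment[0]), str(alignment[1])
    columns = len(qa)
    identities = positives = mismatches = gap_opens = 0
    in_gap = False
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            if not in_gap:
                gap_opens += 1
                in_gap = True
            continue
        in_gap = False
        if x == y:
            identities += 1
            positives += 1
        else:
            mismatches += 1
            if sub[x, y] > 0:
                positives += 1
    return columns, identities, positives, mismatches, gap_opens


_EMPTY = dict(
    score=0.0, percent_identity=0.0, percent_similarity=0.0, alignment_length=0,
    identities=0, mismatches=0, gap_opens=0,
    query_interval=(0, 0), subject_interval=(0, 0),
)


def local_align(a: SequenceRecord, b: SequenceRecord,
                scheme: ScoringScheme | None = None,
                m: int | None = None, n: int | None = None) -> AlignmentResult:
    """Optimal local alignment of ``a`` (query) vs ``b`` (subject).

    ``m``/``n`` override the query length / database residue count used for
    the E-value (defaults: the two sequence lengths).  If no cell scores
    positively, an empty alignment with ``evalue = inf`` is returned.
    """
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    scheme = scheme or (ScoringScheme.protein_default() if a.alphabet == "protein"
                        else ScoringScheme.nucleotide_default())
    m = m if m is not None else len(a)
    n = n if n is not None else len(b)
    score = sw_score(a, b, scheme)
    if score <= 0:
        return AlignmentResult(bit_score=bit_score(0.0, scheme), evalue=math.inf, **_EMPTY)
    aligner = _make_aligner(scheme, "local")
    aln = aligner.align(a.residues, b.residues)[0]
    columns, identities, positives, mismatches, gap_opens = _column_stats(aln, scheme)
    (q0, q1), (s0, s1) = aln.aligned[0][[0, -1], [0, 1]], aln.aligned[1][[0, -1], [0, 1]]
    return AlignmentResult(
        score=float(score),
        bit_score=bit_score(score, scheme),
        evalue=evalue(score, m, n, scheme),
        percent_identity=100.0 * identities / columns,
        percent_similarity=100.0 * positives / columns,
        alignment_length=columns,
        identities=identities,
        mismatches=mismatches,
        gap_opens=gap_opens,
        query_interval=(int(q0) + 1, int(q1)),
        subject_interval=(int(s0) + 1, int(s1)),
    )


def evalue(score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expect value ``K * m * n * exp(-lambda * S)``.

    Strictly decreasing in the score and linear in both ``m`` and ``n``; a
    nonpositive score maps to the ``inf`` sentinel.
    """
    scheme = scheme or ScoringScheme.protein_default()
    if score <= 0:
        return math.inf
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def bit_score(score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme.protein_default()
    return (scheme.lam * score - math.log(scheme.K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------


def hit_sort_key(h: HitRecord):
    """Total order for ranked hits: ascending E, descending bit score, subject id."""
    return (h.evalue, -h.bit_score, h.subject_id)


def search(queries: Sequence[SequenceRecord], db: Sequence[SequenceRecord],
           evalue_max: float = 1e-5,
           scheme: ScoringScheme | None = None) -> list[HitRecord]:
    """All query x subject pairs with ``E < evalue_max``.

    The database size ``n`` entering the E-value is the total residue count
    of ``db``.  Hits are emitted query by query (input order), each query's
    hits sorted by ascending E-value, then descending bit score, then subject
    id — a total order, so output is invariant under database ordering.
    Self-comparisons (identical ids) are skipped.
    """
    if not db:
        raise ValueError("database must be nonempty")
    if scheme is None:
        nucleotide = bool(queries) and queries[0].alphabet == "nucleotide"
        scheme = ScoringScheme.nucleotide_default() if nucleotide else ScoringScheme.protein_default()
    n_db = sum(len(s) for s in db)
    sub = scheme.matrix_array()
    enc_db = [_check_encoded(scheme.encode(s.residues), s, scheme) for s in db]
    out: list[HitRecord] = []
    for q in queries:
        enc_q = _check_encoded(scheme.encode(q.residues), q, scheme)
        q_hits: list[HitRecord] = []
        for s, enc_s in zip(db, enc_db):
            if s.id == q.id:
                continue
            score = int(_sw_score_kernel(enc_q, enc_s, sub, scheme.gap_open, scheme.gap_extend))
            E = evalue(score, len(q), n_db, scheme)
            if E >= evalue_max:
                continue
            res = local_align(q, s, scheme, m=len(q), n=n_db)
            q_hits.append(
                HitRecord(
                    query_id=q.id, subject_id=s.id,
                    percent_identity=res.percent_identity,
                    alignment_length=res.alignment_length,
                    mismatches=res.mismatches, gap_opens=res.gap_opens,
                    q_start=res.query_interval[0], q_end=res.query_interval[1],
                    s_start=res.subject_interval[0], s_end=res.subject_interval[1],
                    evalue=E, bit_score=res.bit_score,
                )
            )
        q_hits.sort(key=hit_sort_key)
        out.extend(q_hits)
    return out


# ---------------------------------------------------------------------------
# Global similarity (pathway-level summaries)
# ---------------------------------------------------------------------------


def percent_similarity_global(a: SequenceRecord, b: SequenceRecord,
                              scheme: ScoringScheme | None = None) -> float:
    """Percent of global-alignment columns with a positive substitution score.

    Uses Needleman-Wunsch under the same scheme; symmetric in its arguments.
    Gap columns count toward the denominator but are never positive.
    """
    if not a.residues or not b.residues:
        raise ValueError("sequences must be nonempty")
    scheme = scheme or ScoringScheme.protein_default()
    aligner = _make_aligner(scheme, "global")
    # Canonical argument order guarantees exact symmetry even when several
    # global alignments are co-optimal.
    x, y = sorted((a.residues, b.residues))
    aln = aligner.align(x, y)[0]
    columns, _identities, positives, _mismatches, _gap_opens = _column_stats(aln, scheme)
    return 100.0 * positives / columns


def percent_identity_global(a: SequenceRecord, b: SequenceRecord,
                            scheme: ScoringScheme | None = None) -> float:
    """Percent of global-alignment columns that are identical residues."""
    scheme = scheme or ScoringScheme.protein_default()
    aligner = _make_aligner(scheme, "global")
    x, y = sorted((a.residues, b.residues))
    aln = aligner.align(x, y)[0]
    columns, identities, _p, _m, _g = _column_stats(aln, scheme)
    return 100.0 * identities / columns
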