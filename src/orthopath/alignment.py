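"""Six-frame translation and Smith–Waterman local protein alignment.

Protein queries are compared against unannotated bacterial contigs by
translating each contig in all six reading frames (bacterial code, table
11) and aligning the query locally against every frame with affine-gap
Smith–Waterman. Defaults follow common protein-search practice: BLOSUM62,
gap open 11, gap extension 1, where a gap of length *k* costs
``open + k * extend``.

Scoring of ambiguous symbols: translated frames contain ``*`` (stop) and
``X`` (codon with N); both score the matrix minimum (−4 for BLOSUM62)
against every residue, so stop-rich frames and ambiguous codons can never
inflate a similarity percentage.

Percentage definitions (all computed over the aligned, gapped columns):

* ``identity_pct``  — identical residue columns / aligned columns × 100
* ``similarity_pct`` — (identical + positive-scoring substitution columns)
  / aligned columns × 100 (the BLAST "positives" convention)
* ``query_coverage_pct`` — aligned query span / query length × 100

Gapped columns count in the denominators. Two further percentages
normalize by the *query length* instead of the aligned columns
(``query_identity_pct``, ``query_similarity_pct``): the per-column
percentages describe the alignment itself, while the query-normalized
ones measure how much of the whole query protein is matched — the
quantity a presence/absence call should threshold, since the per-column
similarity of an optimal local alignment of unrelated sequences
concentrates near the scoring matrix's positive-pair rate (≈35% for
BLOSUM62) no matter how tiny the alignment is.

Determinism: the traceback prefers diagonal, then up (gap in subject),
then left (gap in query); among equal-scoring end cells the smallest
``(subject_end, query_end)`` wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import logging

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import NUCLEOTIDE, SequenceRecord

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALIGN_ALPHABET = AA20 + "X*"

_NEG = -(2**40)  # -inf stand-in; safe from int64 overflow

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0, strand: str = "+") -> str:
    """Translate a nucleotide string in one frame of one strand.

    Bacterial/plastid code (table 11). Any codon containing ``N``
    translates to ``X``; stop codons are rendered ``*``. The ``-`` strand
    is reverse-complemented before the frame offset is applied. A sequence
    shorter than one full codon in the requested frame yields ``""``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        nt = reverse_complement(nt)
    s = nt[frame:]
    n_codons = len(s) // 3
    return "".join(
        CODON_TO_AA.get(s[3 * i : 3 * i + 3], "X") for i in range(n_codons)
    )


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six protein readings of a contig."""

    contig_id: str
    strand: str
    frame: int
    residues: str


def six_frame_translate(contig: SequenceRecord) -> list[FrameTranslation]:
    """All six frame translations of a nucleotide contig.

    Frames too short to hold a codon are dropped; a contig shorter than
    3 nt therefore yields no usable frames (logged).
    """
    if contig.alphabet != NUCLEOTIDE:
        raise ValueError(f"contig {contig.id!r} is not a nucleotide record")
    frames = []
    for strand in "+-":
        for frame in (0, 1, 2):
            aa = translate(contig.residues, frame, strand)
            if aa:
                frames.append(FrameTranslation(contig.id, strand, frame, aa))
    if not frames:
        logger.warning("contig %r (<3 nt): no usable reading frames", contig.id)
    return frames


# ---------------------------------------------------------------------------
# Scoring matrices


@dataclass(frozen=True)
class ScoringMatrix:
    """Substitution scores over the 20 amino acids plus ``X`` and ``*``.

    ``X`` and ``*`` score ``ambiguous_score`` (the matrix minimum) against
    everything, themselves included.
    """

    name: str
    scores: np.ndarray  # (22, 22) int32
    ambiguous_score: int

    def __post_init__(self) -> None:
        if self.scores.shape != (len(ALIGN_ALPHABET),) * 2:
            raise ValueError("scoring matrix must be 22x22")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[ALIGN_ALPHABET.index(a), ALIGN_ALPHABET.index(b)])


_ENCODER = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALIGN_ALPHABET):
    _ENCODER[ord(_ch)] = _i


def encode(seq: str) -> np.ndarray:
    """Map residues to matrix row indices (unknown letters become X)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    enc = _ENCODER[arr]
    enc[enc < 0] = ALIGN_ALPHABET.index("X")
    return enc


def _matrix_from_biopython(mat, name: str) -> ScoringMatrix:
    n = len(ALIGN_ALPHABET)
    scores = np.zeros((n, n), dtype=np.int32)
    worst = int(min(mat[a][b] for a in AA20 for b in AA20))
    for i, a in enumerate(ALIGN_ALPHABET):
        for j, b in enumerate(ALIGN_ALPHABET):
            if a in AA20 and b in AA20:
                scores[i, j] = int(mat[a][b])
            else:
                scores[i, j] = worst
    return ScoringMatrix(name, scores, worst)


def blosum62() -> ScoringMatrix:
    """BLOSUM62 with X/* forced to the matrix minimum (−4)."""
    return _matrix_from_biopython(substitution_matrices.load("BLOSUM62"), "BLOSUM62")


def load_matrix(path: str | Path) -> ScoringMatrix:
    """Load a plain-text NCBI-format substitution matrix file."""
    mat = substitution_matrices.read(str(path))
    return _matrix_from_biopython(mat, Path(path).stem)


# ---------------------------------------------------------------------------
# Smith–Waterman


@dataclass(frozen=True)
class LocalAlignment:
    """One optimal local alignment with BLAST-style summary percentages.

    Coordinates are 1-based inclusive in protein space; when the subject
    was a frame translation, ``subject_strand``/``subject_frame`` record
    which reading of the contig was aligned.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: int
    aligned_query: str
    aligned_subject: str
    identity_pct: float
    similarity_pct: float
    query_coverage_pct: float
    query_identity_pct: float = 0.0
    query_similarity_pct: float = 0.0
    subject_strand: str | None = None
    subject_frame: int | None = None

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings differ in length")
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")


@njit(cache=True)
def _sw_score_kernel(q, s, sub, go, ge):  # pragma: no cover - numba
    """Best local score, linear memory.

    ``go`` is the cost of the first residue of a gap (open + extend);
    ``ge`` of each further residue.
    """
    m = q.shape[0]
    n = s.shape[0]
    neg = np.int32(-(2**28))
    go = np.int32(go)
    ge = np.int32(ge)
    H = np.zeros(n + 1, dtype=np.int32)
    F = np.full(n + 1, neg, dtype=np.int32)
    best = np.int32(0)
    zero = np.int32(0)
    for i in range(1, m + 1):
        prev_diag = zero
        e = neg
        subrow = sub[q[i - 1]]
        for j in range(1, n + 1):
            up = H[j]
            e = max(H[j - 1] - go, e - ge)
            f = max(up - go, F[j] - ge)
            F[j] = f
            h = prev_diag + subrow[s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < zero:
                h = zero
            H[j] = h
            prev_diag = up
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_matrix_kernel(q, s, sub, go, ge):  # pragma: no cover - numba
    """Full H/E/F dynamic-programming matrices for traceback."""
    m = q.shape[0]
    n = s.shape[0]
    neg = np.int32(-(2**28))
    go = np.int32(go)
    ge = np.int32(ge)
    zero = np.int32(0)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), neg, dtype=np.int32)
    F = np.full((m + 1, n + 1), neg, dtype=np.int32)
    for i in range(1, m + 1):
        subrow = sub[q[i - 1]]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + subrow[s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < zero:
                h = zero
            H[i, j] = h
    return H, E, F


def _pick_end(H: np.ndarray) -> tuple[int, int, int]:
    best = int(H.max())
    cells = np.argwhere(H == best)
    # smallest (subject_end, query_end)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = cells[order[0]]
    return best, int(i), int(j)


def _traceback(H, E, F, q: str, s: str, sub, go, ge, end_i, end_j):
    i, j = end_i, end_j
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    qe = encode(q)
    se = encode(s)
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub[qe[i - 1], se[j - 1]]:
                aq.append(q[i - 1])
                asub.append(s[j - 1])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # gap in subject, consume query
            aq.append(q[i - 1])
            asub.append("-")
            if F[i, j] == H[i - 1, j] - go:
                i -= 1
                state = "H"
            else:
                i -= 1
        else:  # "E": gap in query, consume subject
            aq.append("-")
            asub.append(s[j - 1])
            if E[i, j] == H[i, j - 1] - go:
                j -= 1
                state = "H"
            else:
                j -= 1
    return "".join(reversed(aq)), "".join(reversed(asub)), i + 1, j + 1


def column_counts(
    aligned_query: str, aligned_subject: str, matrix: ScoringMatrix
) -> tuple[int, int, int]:
    """(identical, identical+positive, total) aligned-column counts."""
    cols = len(aligned_query)
    ident = 0
    similar = 0
    for a, b in zip(aligned_query, aligned_subject):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            similar += 1
        elif matrix.score(a, b) > 0:
            similar += 1
    return ident, similar, cols


def alignment_percentages(
    aligned_query: str, aligned_subject: str, matrix: ScoringMatrix
) -> tuple[float, float]:
    """(identity_pct, similarity_pct) over the gapped columns."""
    ident, similar, cols = column_counts(aligned_query, aligned_subject, matrix)
    return 100.0 * ident / cols, 100.0 * similar / cols


def smith_waterman(
    query: str | SequenceRecord,
    subject: str | SequenceRecord,
    matrix: ScoringMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two protein sequences.

    A gap of length *k* costs ``gap_open + k * gap_extend``. Returns the
    single optimal alignment selected by the documented tie-breaking.
    """
    if isinstance(query, SequenceRecord):
        query_id, query = query.id, query.residues
    if isinstance(subject, SequenceRecord):
        subject_id, subject = subject.id, subject.residues
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    matrix = matrix or blosum62()
    go = gap_open + gap_extend
    qe = encode(query)
    se = encode(subject)
    H, E, F = _sw_matrix_kernel(qe, se, matrix.scores, go, gap_extend)
    score, ei, ej = _pick_end(H)
    if score == 0:
        # no positive-scoring pair anywhere; degenerate empty result
        return LocalAlignment(
            query_id, subject_id, 1, 0, 1, 0, 0, "", "", 0.0, 0.0, 0.0
        )
    aq, asub, qs, ss = _traceback(
        H, E, F, query, subject, matrix.scores, go, gap_extend, ei, ej
    )
    n_ident, n_simil, cols = column_counts(aq, asub, matrix)
    qlen = len(query)
    coverage = 100.0 * (ei - qs + 1) / qlen
    return LocalAlignment(
        query_id, subject_id, qs, ei, ss, ej, score, aq, asub,
        100.0 * n_ident / cols, 100.0 * n_simil / cols, coverage,
        100.0 * n_ident / qlen, 100.0 * n_simil / qlen,
    )


def sw_score(
    query: str,
    subject: str,
    matrix: ScoringMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Score-only Smith–Waterman (linear memory; used for frame scans)."""
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    matrix = matrix or blosum62()
    best = _sw_score_kernel(
        encode(query), encode(subject), matrix.scores, gap_open + gap_extend,
        gap_extend,
    )
    return int(best)


# ---------------------------------------------------------------------------
# Global alignment (used by the center-star MSA)


def global_align(
    a: str,
    b: str,
    matrix: ScoringMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[str, str, int]:
    """Affine-gap global (Needleman–Wunsch/Gotoh) alignment.

    End-to-end alignment of two short protein sequences with the same
    scoring conventions and diagonal-first tie-breaking as
    :func:`smith_waterman`. Returns ``(aligned_a, aligned_b, score)``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    matrix = matrix or blosum62()
    go = gap_open + gap_extend
    ge = gap_extend
    sub = matrix.scores
    ae = encode(a)
    be = encode(b)
    m, n = len(a), len(b)
    H = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -go - (j - 1) * ge
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -go - (i - 1) * ge
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(
                H[i - 1, j - 1] + sub[ae[i - 1], be[j - 1]], E[i, j], F[i, j]
            )
    # traceback, diagonal > up > left
    i, j = m, n
    state = "H"
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[ae[i - 1], be[j - 1]]:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ra.append(a[i - 1])
            rb.append("-")
            if F[i, j] == H[i - 1, j] - go:
                i -= 1
                state = "H"
            else:
                i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            if E[i, j] == H[i, j - 1] - go:
                j -= 1
                state = "H"
            else:
                j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), int(H[m, n])
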