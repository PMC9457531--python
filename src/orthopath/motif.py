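"""Multiple alignment of homolog families and conserved-motif detection.

The multiple alignment is built with the center-star heuristic: the
center is the sequence maximizing its summed pairwise local-alignment
scores against all others, every other sequence is aligned globally to
the center, and the pairwise gap patterns are merged under "once a gap,
always a gap". Center-star is deliberately simple — deterministic,
testable against exhaustive small cases, and adequate for the compact,
indel-poor methyltransferase families this pipeline examines.

Column conservation is the fraction of sequences carrying the modal
(non-gap) residue; gaps count in the denominator, so gappy columns score
low by construction.

Motif patterns use the field's glycine-motif notation: uppercase residue
letters plus ``x``/``X`` as the any-residue wildcard (e.g. ``GCGxG``,
``GxGxG`` for the Rossmann-like SAM-binding loop of N-methyltransferases).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import ScoringMatrix, blosum62, global_align, sw_score
from .io_formats import PROTEIN, SequenceRecord


@dataclass(frozen=True)
class MotifHit:
    """One conserved-motif occurrence in an alignment.

    ``column_start`` is the 1-based alignment column of the first motif
    position; ``matches`` maps each matching sequence id to the exact
    substring it carries there.
    """

    pattern: str
    column_start: int
    matches: dict[str, str]
    conservation: float


@dataclass
class MsaResult:
    """A multiple sequence alignment with per-column conservation."""

    aligned: dict[str, str]
    column_conservation: np.ndarray = field(init=False)
    motif_hits: list[MotifHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        self.column_conservation = _conservation(list(self.aligned.values()))

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.aligned.values())))

    def degapped(self, seq_id: str) -> str:
        return self.aligned[seq_id].replace("-", "")


def _conservation(rows: list[str]) -> np.ndarray:
    """Per-column modal-residue fraction; gaps never count as the mode."""
    n = len(rows)
    out = np.zeros(len(rows[0]) if rows else 0)
    for c in range(out.size):
        counts = Counter(row[c] for row in rows)
        counts.pop("-", None)
        out[c] = (max(counts.values()) / n) if counts else 0.0
    return out


def _merge_into_master(master_rows: dict[str, list[str]], center_key: str,
                       aligned_center: str, aligned_new: str,
                       new_key: str) -> None:
    """Merge one center-vs-new pairwise alignment into the growing MSA.

    ``master_rows[center_key]`` holds the center with previously inserted
    gaps. Columns where the pairwise alignment gaps the center become new
    all-gap columns in every existing row ("once a gap, always a gap").
    """
    master = master_rows[center_key]
    new_row: list[str] = []
    mi = 0  # index into master columns
    for ac, an in zip(aligned_center, aligned_new):
        if ac == "-":
            # insertion relative to the center: new all-gap column
            for row in master_rows.values():
                row.insert(mi, "-")
            new_row.append(an)
            mi += 1
        else:
            # advance past master columns that are center-gaps from
            # earlier merges; the new sequence has no residue there
            while master[mi] == "-":
                new_row.append("-")
                mi += 1
            new_row.append(an)
            mi += 1
    # trailing center-gap columns from earlier merges
    while mi < len(master):
        new_row.append("-")
        mi += 1
    master_rows[new_key] = new_row


def center_star_msa(
    seqs: list[SequenceRecord],
    matrix: ScoringMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> MsaResult:
    """Center-star multiple alignment of two or more protein sequences."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences for an MSA")
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("duplicate sequence ids")
    for s in seqs:
        if s.alphabet != PROTEIN:
            raise ValueError(f"sequence {s.id!r} is not protein")
    matrix = matrix or blosum62()

    # center = maximizer of summed pairwise local scores; tie -> lexicographic id
    ids = [s.id for s in seqs]
    by_id = {s.id: s.residues for s in seqs}
    pair_score: dict[tuple[str, str], int] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sc = sw_score(by_id[a], by_id[b], matrix, gap_open, gap_extend)
            pair_score[(a, b)] = pair_score[(b, a)] = sc
    center = min(
        ids, key=lambda c: (-sum(pair_score[(c, o)] for o in ids if o != c), c)
    )

    master_rows: dict[str, list[str]] = {center: list(by_id[center])}
    for other in sorted(o for o in ids if o != center):
        ac, ao, _ = global_align(
            by_id[center], by_id[other], matrix, gap_open, gap_extend
        )
        _merge_into_master(master_rows, center, ac, ao, other)
    aligned = {i: "".join(master_rows[i]) for i in ids}
    return MsaResult(aligned)


def _validate_pattern(pattern: str) -> str:
    if not pattern:
        raise ValueError("empty motif pattern")
    up = pattern.upper()
    for ch in up:
        if not ch.isalpha():
            raise ValueError(
                f"motif pattern {pattern!r}: only residue letters and the "
                "'x' wildcard are allowed"
            )
    return up


def scan_motif(
    msa: MsaResult, pattern: str, min_conservation: float = 0.8
) -> list[MotifHit]:
    """Locate a wildcard motif conserved across an alignment.

    A window of ``len(pattern)`` consecutive alignment columns is a hit
    when at least ``min_conservation`` of the sequences carry, gap-free,
    residues matching the pattern at every position (``x`` matches any
    residue; other letters must match exactly). Returns hits in column
    order; results do not depend on sequence input order.
    """
    pat = _validate_pattern(pattern)
    width = len(pat)
    n_seq = len(msa.aligned)
    hits = []
    for start in range(msa.n_columns - width + 1):
        matches = {}
        for sid in sorted(msa.aligned):
            window = msa.aligned[sid][start : start + width]
            if "-" in window:
                continue
            if all(p == "X" or p == w for p, w in zip(pat, window)):
                matches[sid] = window
        frac = len(matches) / n_seq
        if frac >= min_conservation:
            hits.append(MotifHit(pattern, start + 1, matches, frac))
    return hits
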