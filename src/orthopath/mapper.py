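"""Enzyme × genome presence/absence mapping.

For each pathway enzyme (a plant protein) and each bacterial genome, the
best local alignment is searched over all contigs and all six reading
frames (or directly against protein records when a proteome is supplied).
An enzyme is called *present* in a genome when the best hit clears both

* a similarity (or identity) threshold — default: strictly more than 30%
  of the query's residues aligned as identities or positive-scoring
  substitutions (the *query-normalized* similarity),
* a query-coverage floor — default 50%, and
* a gap-content cap — default 10% of aligned columns.

Presence thresholds the query-normalized metric rather than the
per-column one because the per-column similarity of an optimal local
alignment of unrelated sequences sits near the scoring matrix's
positive-pair rate (≈35% under BLOSUM62) regardless of how little of the
query it spans; normalizing by query length turns "30% similarity" into
a whole-protein statement that random hits cannot satisfy. The gap cap
closes the remaining loophole: between *unrelated proteins* the aligner
can occasionally stitch positive-scoring islands into a long,
heavily-gapped (20%+ gap columns) alignment that crawls past both other
filters, whereas genuine ortholog alignments are collinear with few
gaps. An ungapped alignment of unrelated sequences cannot reach a
positive score over enough columns to matter, so capping gap content
removes this failure class without touching real detections.

Alignments are allowed to span stop codons (scored at the matrix minimum)
rather than being restricted to clean ORFs: on fragmented or frame-shifted
contigs this favours recall of genuinely present genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .alignment import (
    LocalAlignment,
    ScoringMatrix,
    blosum62,
    six_frame_translate,
    smith_waterman,
    sw_score,
)
from .io_formats import FormatError, NUCLEOTIDE, PROTEIN, SequenceRecord

SIMILARITY = "similarity"
IDENTITY = "identity"


@dataclass(frozen=True)
class PathwayEnzyme:
    """One numbered enzyme of the reference biosynthesis pathway."""

    enzyme_id: str
    name: str
    record: SequenceRecord

    def __post_init__(self) -> None:
        if self.record.alphabet != PROTEIN:
            raise ValueError(f"enzyme {self.enzyme_id!r}: sequence must be protein")
        if len(self.record) < 30:
            raise ValueError(
                f"enzyme {self.enzyme_id!r}: sequence shorter than 30 residues"
            )


@dataclass(frozen=True)
class PresenceParams:
    """Presence-call policy: metric, threshold, coverage floor, gap cap."""

    threshold_pct: float = 30.0
    metric: str = SIMILARITY
    coverage_min_pct: float = 50.0
    gap_open: int = 11
    gap_extend: int = 1
    max_gap_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.metric not in (SIMILARITY, IDENTITY):
            raise ValueError(f"metric must be similarity or identity, got {self.metric!r}")

    def metric_of(self, aln: LocalAlignment) -> float:
        """Query-normalized similarity (or identity) of an alignment."""
        if self.metric == SIMILARITY:
            return aln.query_similarity_pct
        return aln.query_identity_pct

    @staticmethod
    def gap_pct(aln: LocalAlignment) -> float:
        cols = len(aln.aligned_query)
        if cols == 0:
            return 0.0
        gaps = aln.aligned_query.count("-") + aln.aligned_subject.count("-")
        return 100.0 * gaps / cols

    def is_present(self, aln: LocalAlignment | None) -> bool:
        return (
            aln is not None
            and self.metric_of(aln) > self.threshold_pct
            and aln.query_coverage_pct >= self.coverage_min_pct
            and self.gap_pct(aln) <= self.max_gap_pct
        )


_Candidate = tuple[str, str | None, int | None, str]


def _translate_genome(genome: list[SequenceRecord]) -> list[_Candidate]:
    """Protein search space of a genome: six frames per nucleotide contig,
    protein records as-is. Tuples are (subject_id, strand, frame, residues)."""
    candidates: list[_Candidate] = []
    for rec in genome:
        if rec.alphabet == NUCLEOTIDE:
            for ft in six_frame_translate(rec):
                candidates.append((ft.contig_id, ft.strand, ft.frame, ft.residues))
        else:
            candidates.append((rec.id, None, None, rec.residues))
    return candidates


def best_hit(
    enzyme: PathwayEnzyme,
    genome: list[SequenceRecord],
    params: PresenceParams | None = None,
    matrix: ScoringMatrix | None = None,
    _candidates: list[_Candidate] | None = None,
) -> LocalAlignment | None:
    """Maximum-score local alignment of an enzyme over a whole genome.

    Nucleotide records are translated in all six frames; protein records
    are aligned directly. Equal-scoring candidates are resolved by higher
    similarity, then lexicographic subject id, strand and frame. Returns
    ``None`` when no alignment scores above zero.
    """
    if not genome:
        raise ValueError(f"enzyme {enzyme.enzyme_id!r}: empty genome")
    params = params or PresenceParams()
    matrix = matrix or blosum62()
    query = enzyme.record.residues
    candidates = _candidates if _candidates is not None else _translate_genome(genome)

    scored = []
    for sid, strand, frame, residues in candidates:
        if not residues:
            continue
        s = sw_score(query, residues, matrix, params.gap_open, params.gap_extend)
        scored.append((s, sid, strand, frame, residues))
    if not scored:
        return None
    best_score = max(s for s, *_ in scored)
    if best_score <= 0:
        return None

    finalists = []
    for s, sid, strand, frame, residues in scored:
        if s != best_score:
            continue
        aln = smith_waterman(
            query, residues, matrix, params.gap_open, params.gap_extend,
            query_id=enzyme.record.id, subject_id=sid,
        )
        aln = replace(aln, subject_strand=strand, subject_frame=frame)
        finalists.append(aln)
    return min(
        finalists,
        key=lambda a: (
            -a.similarity_pct,
            a.subject_id,
            a.subject_strand or "",
            a.subject_frame if a.subject_frame is not None else -1,
        ),
    )


@dataclass
class PresenceMatrix:
    """Best-similarity grid of pathway enzymes over genomes.

    ``best`` holds the winning alignment per cell (``None`` for a cell with
    no positive-scoring hit, or for matrices re-read from TSV, which retain
    only ``best_metric``). ``present`` applies the policy in ``params``.
    """

    enzymes: list[str]
    genomes: list[str]
    params: PresenceParams
    best: dict[tuple[str, str], LocalAlignment | None] = field(default_factory=dict)
    best_metric: dict[tuple[str, str], float | None] = field(default_factory=dict)
    present: dict[tuple[str, str], bool] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: one row per enzyme, cells ``metric|flag``."""
        rows = []
        for e in self.enzymes:
            row: dict[str, object] = {"enzyme_id": e}
            for g in self.genomes:
                m = self.best_metric[(e, g)]
                flag = int(self.present[(e, g)])
                row[g] = f"{m:.2f}|{flag}" if m is not None else f"NA|{flag}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, params: PresenceParams | None = None) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "enzyme_id" not in df.columns:
            raise FormatError(f"{path}: missing 'enzyme_id' column")
        genomes = [c for c in df.columns if c != "enzyme_id"]
        mat = cls(list(df["enzyme_id"]), genomes, params or PresenceParams())
        for _, row in df.iterrows():
            e = row["enzyme_id"]
            for g in genomes:
                try:
                    val, flag = str(row[g]).split("|")
                except ValueError:
                    raise FormatError(f"{path}: malformed cell {row[g]!r}") from None
                mat.best_metric[(e, g)] = None if val == "NA" else float(val)
                mat.best[(e, g)] = None
                mat.present[(e, g)] = bool(int(flag))
        return mat


def build_presence_matrix(
    pathway: list[PathwayEnzyme],
    genomes: dict[str, list[SequenceRecord]],
    params: PresenceParams | None = None,
    matrix: ScoringMatrix | None = None,
) -> PresenceMatrix:
    """Align every pathway enzyme against every genome and call presence."""
    if not pathway:
        raise ValueError("pathway must contain at least one enzyme")
    if not genomes:
        raise ValueError("at least one genome is required")
    params = params or PresenceParams()
    matrix = matrix or blosum62()
    out = PresenceMatrix(
        [e.enzyme_id for e in pathway], list(genomes), params
    )
    translated = {gid: _translate_genome(recs) for gid, recs in genomes.items()}
    for enz in pathway:
        for gid, records in genomes.items():
            try:
                aln = best_hit(enz, records, params, matrix,
                               _candidates=translated[gid])
            except ValueError as exc:
                raise ValueError(f"genome {gid!r}: {exc}") from exc
            key = (enz.enzyme_id, gid)
            out.best[key] = aln
            out.best_metric[key] = params.metric_of(aln) if aln else None
            out.present[key] = params.is_present(aln)
    return out
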