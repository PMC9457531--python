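"""Taxon-restricted essential-enzyme inference.

Combines the enzyme × genome presence matrix with per-genome evidence
roles. A genome is either

* ``enriched_genus`` — it belongs to a genus whose enrichment tracks
  degradation in the community data (or the user asserts as much),
* ``nondegrader_isolate`` — a cultivable strain recovered from the same
  habitat that fails to degrade the compound, or
* ``other`` — reported but excluded from the inference.

An enzyme present in at least one enriched-genus genome but in **no**
non-degrader isolate is an *essential candidate*: the pathway step it
catalyzes is carried only by the taxa that co-occur with degradation.
This is pure set logic over presence calls, not a statistical test, and
the output is deliberately labelled "candidate".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_formats import FormatError
from .mapper import PresenceMatrix

ENRICHED_GENUS = "enriched_genus"
NONDEGRADER_ISOLATE = "nondegrader_isolate"
OTHER = "other"
_ROLES = (ENRICHED_GENUS, NONDEGRADER_ISOLATE, OTHER)

SHARED = "shared"
ESSENTIAL_CANDIDATE = "essential_candidate"
ABSENT = "absent"
ISOLATE_ONLY = "isolate_only"


@dataclass(frozen=True)
class GenomeRole:
    """Evidence class of one genome."""

    genome_id: str
    genus: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(
                f"genome {self.genome_id!r}: unknown role {self.role!r} "
                f"(expected one of {_ROLES})"
            )


def read_roles(path: str | Path) -> list[GenomeRole]:
    """Read a roles TSV (columns ``genome_id``, ``genus``, ``role``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("genome_id", "genus", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    return [
        GenomeRole(r["genome_id"], r["genus"], r["role"])
        for _, r in df.iterrows()
    ]


def write_roles(roles: list[GenomeRole], path: str | Path) -> None:
    pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in roles],
            "genus": [r.genus for r in roles],
            "role": [r.role for r in roles],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EnzymeClassification:
    """Where one enzyme's orthologs were found, and what that implies."""

    enzyme_id: str
    present_in_enriched: frozenset[str]
    present_in_isolates: frozenset[str]
    present_in_other: frozenset[str]
    classification: str


@dataclass
class EssentialityReport:
    """Partition of the pathway's enzymes by evidence class."""

    rows: list[EnzymeClassification]

    @property
    def essential_candidates(self) -> list[str]:
        return [r.enzyme_id for r in self.rows
                if r.classification == ESSENTIAL_CANDIDATE]

    def by_enzyme(self, enzyme_id: str) -> EnzymeClassification:
        for r in self.rows:
            if r.enzyme_id == enzyme_id:
                return r
        raise KeyError(enzyme_id)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "enzyme_id": [r.enzyme_id for r in self.rows],
                "classification": [r.classification for r in self.rows],
                "present_in_enriched": [
                    ",".join(sorted(r.present_in_enriched)) for r in self.rows
                ],
                "present_in_isolates": [
                    ",".join(sorted(r.present_in_isolates)) for r in self.rows
                ],
                "present_in_other": [
                    ",".join(sorted(r.present_in_other)) for r in self.rows
                ],
            }
        ).to_csv(path, sep="\t", index=False)


def classify_enzymes(
    matrix: PresenceMatrix,
    roles: list[GenomeRole],
    require_all_enriched: bool = False,
) -> EssentialityReport:
    """Partition enzymes into shared / essential-candidate / isolate-only /
    absent from the presence matrix and genome roles.

    ``require_all_enriched=False`` (default) counts an enzyme as carried
    by the enriched group when *any* enriched-genus genome has it;
    ``True`` demands every enriched-genus genome. Genomes with role
    ``other`` are reported but never drive the classification.
    """
    role_of = {r.genome_id: r.role for r in roles}
    missing = [g for g in matrix.genomes if g not in role_of]
    if missing:
        raise ValueError(f"genomes without a role: {missing}")
    enriched_genomes = [g for g in matrix.genomes if role_of[g] == ENRICHED_GENUS]
    isolate_genomes = [g for g in matrix.genomes if role_of[g] == NONDEGRADER_ISOLATE]
    other_genomes = [g for g in matrix.genomes if role_of[g] == OTHER]
    if not enriched_genomes or not isolate_genomes:
        raise ValueError(
            "need at least one enriched_genus and one nondegrader_isolate genome"
        )

    rows = []
    for e in matrix.enzymes:
        in_enriched = frozenset(
            g for g in enriched_genomes if matrix.present[(e, g)]
        )
        in_isolates = frozenset(
            g for g in isolate_genomes if matrix.present[(e, g)]
        )
        in_other = frozenset(g for g in other_genomes if matrix.present[(e, g)])
        if require_all_enriched:
            enriched_hit = len(in_enriched) == len(enriched_genomes)
        else:
            enriched_hit = bool(in_enriched)
        isolate_hit = bool(in_isolates)
        if enriched_hit and not isolate_hit:
            cls = ESSENTIAL_CANDIDATE
        elif enriched_hit and isolate_hit:
            cls = SHARED
        elif isolate_hit:
            cls = ISOLATE_ONLY
        else:
            cls = ABSENT
        rows.append(
            EnzymeClassification(e, in_enriched, in_isolates, in_other, cls)
        )
    return EssentialityReport(rows)
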