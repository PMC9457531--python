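"""Readers and writers for the plain-text formats the pipeline touches.

Every external table is TSV with a header row; sequences are FASTA. All
readers validate eagerly and raise :class:`FormatError` with positional
diagnostics, so that malformed inputs fail at the boundary rather than deep
inside an analysis.

Dialects
--------
* FASTA: the record id is the first whitespace-delimited token of the
  header; ids must be unique within a file; lowercase residues are folded to
  uppercase; ``*`` stop characters in protein records are stripped with a
  logged warning.
* Genus-count TSV: columns ``genus`` then one ``d<day>`` column per
  timepoint (e.g. ``d0  d3  d6``), integer counts.
* Degradation-curve TSV: columns ``day`` and ``conc_ug_per_ml``.
* Homology-hit TSV: columns ``subject_id``, ``similarity_pct`` and
  ``lineage``; the lineage is a semicolon-delimited taxonomy string with
  Greengenes/SILVA-style rank prefixes, from which the ``g__<Genus>`` field
  is extracted.  A hit whose lineage lacks a genus field is kept with
  ``genus=None`` (so denominators stay explicit) and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NT_LETTERS = frozenset("ACGTN")
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_ALPHABETS = {NUCLEOTIDE: NT_LETTERS, PROTEIN: AA_LETTERS}


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry, nucleotide or protein.

    ``id`` is the first whitespace token of the header, ``description`` the
    remainder (possibly empty). ``residues`` are uppercase and restricted to
    the declared alphabet (ACGTN for nucleotide; the 20 amino acids plus X
    for protein).
    """

    id: str
    description: str
    residues: str
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: residue {ch!r} at position {pos} "
                    f"not in {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file; must contain at least one record.
    alphabet
        ``"nucleotide"`` or ``"protein"`` — the caller declares what the
        file holds, and every residue is checked against that alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for raw in SeqIO.parse(str(path), "fasta"):
        residues = str(raw.seq).upper()
        if alphabet == PROTEIN and "*" in residues:
            logger.warning(
                "record %r: stripping %d '*' stop character(s)",
                raw.id, residues.count("*"),
            )
            residues = residues.replace("*", "")
        if raw.id in seen:
            raise FormatError(f"{path}: duplicate record id {raw.id!r}")
        seen.add(raw.id)
        description = raw.description[len(raw.id):].strip()
        try:
            records.append(
                SequenceRecord(raw.id, description, residues, alphabet)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("width must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genus-count tables


@dataclass
class GenusCountTable:
    """Per-sample genus read counts over an ordered series of sampling days."""

    sample_id: str
    timepoints: list[int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise FormatError(f"sample {self.sample_id!r}: no timepoints")
        days = list(self.timepoints)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise FormatError(
                f"sample {self.sample_id!r}: days must be strictly increasing, got {days}"
            )
        n = len(days)
        for genus, row in self.counts.items():
            arr = np.asarray(row, dtype=np.int64)
            if arr.shape != (n,):
                raise FormatError(
                    f"sample {self.sample_id!r}: genus {genus!r} has "
                    f"{arr.size} counts for {n} timepoints"
                )
            if (arr < 0).any():
                raise FormatError(
                    f"sample {self.sample_id!r}: negative count for genus {genus!r}"
                )
            self.counts[genus] = arr

    @property
    def totals(self) -> np.ndarray:
        """Total reads per timepoint (the relative-abundance denominator)."""
        return np.sum([row for row in self.counts.values()], axis=0)


def read_genus_counts(path: str | Path, sample_id: str | None = None) -> GenusCountTable:
    """Read a genus-count TSV (columns ``genus``, ``d<day>``...)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"genus": str})
    if "genus" not in df.columns:
        raise FormatError(f"{path}: missing 'genus' column")
    day_cols = [c for c in df.columns if c != "genus"]
    days = []
    for c in day_cols:
        if not c.startswith("d") or not c[1:].isdigit():
            raise FormatError(f"{path}: bad timepoint column {c!r} (expected d<day>)")
        days.append(int(c[1:]))
    counts = {}
    for _, row in df.iterrows():
        vals = row[day_cols].to_numpy()
        try:
            arr = np.asarray(vals, dtype=np.int64)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-integer count in genus {row['genus']!r}"
            ) from None
        counts[str(row["genus"])] = arr
    return GenusCountTable(sample_id or path.stem, days, counts)


def write_genus_counts(table: GenusCountTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"genus": list(table.counts)}
        | {f"d{d}": [table.counts[g][i] for g in table.counts]
           for i, d in enumerate(table.timepoints)}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Degradation curves


@dataclass
class DegradationCurve:
    """Compound concentration (µg/mL) sampled over days, starting at day 0."""

    sample_id: str
    days: list[int]
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.days) != self.concentrations.size:
            raise FormatError(
                f"curve {self.sample_id!r}: {len(self.days)} days vs "
                f"{self.concentrations.size} concentrations"
            )
        if not self.days or self.days[0] != 0:
            raise FormatError(f"curve {self.sample_id!r}: first day must be 0")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise FormatError(
                f"curve {self.sample_id!r}: days must be strictly increasing"
            )
        if (self.concentrations < 0).any():
            day = self.days[int(np.argmax(self.concentrations < 0))]
            raise FormatError(
                f"curve {self.sample_id!r}: negative concentration at day {day}"
            )


def read_degradation_curve(path: str | Path, sample_id: str | None = None) -> DegradationCurve:
    """Read a degradation-curve TSV (columns ``day``, ``conc_ug_per_ml``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("day", "conc_ug_per_ml"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    return DegradationCurve(
        sample_id or path.stem,
        [int(d) for d in df["day"]],
        df["conc_ug_per_ml"].to_numpy(dtype=float),
    )


def write_degradation_curve(curve: DegradationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"day": curve.days, "conc_ug_per_ml": curve.concentrations}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Homology-hit tables


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit: subject accession, % similarity, taxonomy."""

    subject_id: str
    similarity_pct: float
    lineage: str
    genus: str | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_pct <= 100.0:
            raise FormatError(
                f"hit {self.subject_id!r}: similarity {self.similarity_pct} "
                "outside [0, 100]"
            )


def parse_genus(lineage: str) -> str | None:
    """Extract the genus from a rank-prefixed lineage string.

    Looks for a semicolon-delimited field of the form ``g__<Genus>``;
    returns ``None`` (genus unresolved) when no such non-empty field exists.
    """
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith("g__") and len(part) > 3:
            return part[3:]
    return None


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a homology-hit TSV (``subject_id``, ``similarity_pct``, ``lineage``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "lineage": str})
    for col in ("subject_id", "similarity_pct", "lineage"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    hits = []
    for idx, row in df.iterrows():
        lineage = "" if pd.isna(row["lineage"]) else str(row["lineage"])
        genus = parse_genus(lineage)
        if genus is None:
            logger.warning(
                "%s row %d (%s): lineage has no g__ field; genus unresolved",
                path.name, idx + 2, row["subject_id"],
            )
        try:
            hits.append(
                HitRecord(str(row["subject_id"]), float(row["similarity_pct"]),
                          lineage, genus)
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    hits = list(hits)
    pd.DataFrame(
        {
            "subject_id": [h.subject_id for h in hits],
            "similarity_pct": [h.similarity_pct for h in hits],
            "lineage": [h.lineage for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
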