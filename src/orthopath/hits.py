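"""Genus-level summary of a homology hit table.

Given a tabular list of homology-search hits (subject accession,
% similarity, taxonomy lineage), keep the top N by similarity and report
how the genus-resolved subset distributes over genera. Percentages are
computed on the genus-resolved denominator — hits whose lineage carries
no genus rank are counted in ``total_hits`` but excluded from the
percentage base — and rounded half-up to two decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .io_formats import HitRecord


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def top_n(hits: list[HitRecord], n: int = 500) -> list[HitRecord]:
    """The ``n`` highest-similarity hits (ties by lexicographic subject id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(hits, key=lambda h: (-h.similarity_pct, h.subject_id))[:n]


@dataclass
class GenusDistribution:
    """Per-genus counts and percentages of the genus-resolved hits."""

    total_hits: int
    genus_resolved_count: int
    rows: dict[str, tuple[int, float]]  # genus -> (count, pct_of_resolved)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "genus": list(self.rows),
                "count": [c for c, _ in self.rows.values()],
                "pct_of_resolved": [p for _, p in self.rows.values()],
            }
        ).to_csv(path, sep="\t", index=False)


def genus_fraction(hits: list[HitRecord]) -> GenusDistribution:
    """Distribute genus-resolved hits over genera with rounded percentages.

    Rows are ordered by descending count, then genus name. Raises when no
    hit resolves to a genus (the percentage base would be empty).
    """
    if not hits:
        raise ValueError("empty hit list")
    resolved = [h for h in hits if h.genus is not None]
    if not resolved:
        raise ValueError("no hit resolves to a genus; nothing to distribute")
    counts = Counter(h.genus for h in resolved)
    denom = len(resolved)
    rows = {
        genus: (cnt, _round2_half_up(100.0 * cnt / denom))
        for genus, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    return GenusDistribution(len(hits), denom, rows)
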