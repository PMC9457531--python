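"""Community-level evidence: relative abundance, degradation labels,
and degradation-associated genus calls.

The relative abundance of a genus on a given day is its read count
divided by the total reads of the sample on that day; tables are expected
to account for all reads (an explicit ``other`` bucket), so per-day
fractions sum to one.

A degradation curve is labelled *degraded* when the final concentration
falls to at most ``residual_frac`` (default 10%) of the initial
concentration, and *stable* otherwise; the onset day is the first day on
which the concentration drops below 90% of the initial value.

A genus is *degradation associated* when it is enriched in every degraded
sample but not consistently enriched in the stable samples — the
exclusion mirrors the observation that a genus stimulated in both groups
carries no information about degradation capability. "Enriched" in a
sample means peak abundance of at least ``min_peak`` and at least
``min_fold`` times the baseline (day-0) abundance, floored at one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DegradationCurve, GenusCountTable

DEGRADED = "degraded"
STABLE = "stable"


@dataclass
class AbundanceSeries:
    """Per-genus relative-abundance trajectory of one sample."""

    sample_id: str
    timepoints: list[int]
    abundance: dict[str, np.ndarray]
    depth: np.ndarray  # total reads per timepoint
    degradation_label: str | None = None


def relative_abundance(table: GenusCountTable) -> AbundanceSeries:
    """Normalize genus counts to per-day fractions of total reads."""
    totals = table.totals
    if (totals == 0).any():
        day = table.timepoints[int(np.argmax(totals == 0))]
        raise ValueError(
            f"sample {table.sample_id!r}: zero total reads at day {day}"
        )
    abundance = {g: c / totals for g, c in table.counts.items()}
    return AbundanceSeries(
        table.sample_id, list(table.timepoints), abundance, totals.copy()
    )


def classify_degradation(
    curve: DegradationCurve, residual_frac: float = 0.10
) -> tuple[str, int | None]:
    """Label a curve ``degraded``/``stable``; return the onset day.

    The onset day is the first sampling day with concentration below 90%
    of the initial value; it is ``None`` for stable curves.
    """
    if len(curve.days) < 2:
        raise ValueError(f"curve {curve.sample_id!r}: need at least two timepoints")
    initial = curve.concentrations[0]
    if initial <= 0:
        raise ValueError(f"curve {curve.sample_id!r}: non-positive initial concentration")
    degraded = curve.concentrations[-1] <= residual_frac * initial
    if not degraded:
        return STABLE, None
    below = curve.concentrations < 0.9 * initial
    onset = curve.days[int(np.argmax(below))] if below.any() else None
    return DEGRADED, onset


def label_series(series: AbundanceSeries, curve: DegradationCurve,
                 residual_frac: float = 0.10) -> AbundanceSeries:
    """Attach the degradation label of a sample's curve to its series."""
    series.degradation_label = classify_degradation(curve, residual_frac)[0]
    return series


@dataclass(frozen=True)
class EnrichmentCall:
    """Enrichment summary for one genus across sample groups."""

    genus: str
    peak_day: int
    peak_abundance: float
    baseline_abundance: float
    enriched_in_degraders: bool
    enriched_in_nondegraders: bool

    @property
    def degradation_associated(self) -> bool:
        return self.enriched_in_degraders and not self.enriched_in_nondegraders


def _trajectory(series: AbundanceSeries, genus: str) -> np.ndarray:
    # genus missing from a sample == zero counts
    n = len(series.timepoints)
    return series.abundance.get(genus, np.zeros(n))


def _enriched_in_sample(series: AbundanceSeries, genus: str,
                        min_peak: float, min_fold: float) -> bool:
    traj = _trajectory(series, genus)
    peak = float(traj.max())
    floor = 1.0 / float(series.depth[0])  # pseudo-abundance of one read
    baseline = max(float(traj[0]), floor)
    return peak >= min_peak and peak >= min_fold * baseline


def call_enriched_genera(
    series: list[AbundanceSeries],
    min_peak: float = 0.05,
    min_fold: float = 5.0,
) -> list[EnrichmentCall]:
    """Cross-classify genus enrichment in degraded vs stable samples.

    Every series must carry a degradation label; at least one degraded and
    one stable sample are required. A genus counts as enriched within a
    group only when it is enriched in *every* sample of the group. Peak
    day/abundance and baseline are summarized from the mean trajectory
    over the degraded samples. Output is sorted by genus, so the result is
    invariant to sample and genus ordering.
    """
    degraded = [s for s in series if s.degradation_label == DEGRADED]
    stable = [s for s in series if s.degradation_label == STABLE]
    unlabeled = [s.sample_id for s in series if s.degradation_label is None]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {unlabeled}")
    if not degraded or not stable:
        raise ValueError("need at least one degraded and one stable sample")

    genera = sorted({g for s in series for g in s.abundance})
    calls = []
    for genus in genera:
        mean_traj = np.mean([_trajectory(s, genus) for s in degraded], axis=0)
        peak_idx = int(np.argmax(mean_traj))
        calls.append(
            EnrichmentCall(
                genus=genus,
                peak_day=degraded[0].timepoints[peak_idx],
                peak_abundance=float(mean_traj[peak_idx]),
                baseline_abundance=float(mean_traj[0]),
                enriched_in_degraders=all(
                    _enriched_in_sample(s, genus, min_peak, min_fold)
                    for s in degraded
                ),
                enriched_in_nondegraders=all(
                    _enriched_in_sample(s, genus, min_peak, min_fold)
                    for s in stable
                ),
            )
        )
    return calls
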