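"""Synthetic study generator with known ground truth.

Everything the pipeline consumes can be generated here with a planted
truth, emulating the structure of a soil-water biodegradation study:

* a numbered pathway of random parent enzymes (protein FASTA);
* bacterial genomes (single-contig nucleotide FASTA) carrying diverged
  orthologs of chosen enzyme subsets, reverse-translated with uniform
  synonymous codons and planted on either strand in any frame, plus decoy
  ORFs of unrelated protein;
* genome evidence roles: one uncultivable enriched-genus genome holding
  the full degrader subset, and cultivable non-degrader isolates holding
  the same subset minus the taxon-restricted step — so exactly one
  enzyme is the expected essential candidate;
* genus-count time series in which a focal genus spikes from a near-zero
  baseline to a peak on day 3 of degradation and a successor genus rises
  after it, while a control genus is stimulated in degrading and
  non-degrading samples alike;
* degradation curves with a ~5-day adaptation lag followed by decay to
  ~1% residual within 2–3 days (degrading) or a flat profile (stable);
* homology hit tables with controlled genus composition.

All outputs are fully determined by ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AA20, CODON_TO_AA, blosum62, reverse_complement
from .essentiality import ENRICHED_GENUS, NONDEGRADER_ISOLATE, GenomeRole, write_roles
from .io_formats import (
    NUCLEOTIDE,
    PROTEIN,
    DegradationCurve,
    GenusCountTable,
    HitRecord,
    SequenceRecord,
    parse_genus,
    write_fasta,
    write_genus_counts,
    write_degradation_curve,
    write_hit_table,
)
from .mapper import PathwayEnzyme

# codons per amino acid under the bacterial code, stops excluded
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)

_B62 = blosum62()
# BLOSUM-weighted replacement model: a substitution at residue `a` lands on
# b != a with probability proportional to exp(lambda * s(a, b)), where
# lambda = ln2/2 is BLOSUM62's half-bit scale. Conservative replacements
# dominate but genuinely dissimilar ones occur, as in real divergence.
_SUB_LAMBDA = np.log(2.0) / 2.0
_REPLACEMENTS: dict[str, tuple[list[str], np.ndarray]] = {}
for _a in AA20:
    _pool = [b for b in AA20 if b != _a]
    _w = np.exp([_SUB_LAMBDA * _B62.score(_a, b) for b in _pool])
    _REPLACEMENTS[_a] = (_pool, _w / _w.sum())


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(seq: str, target_identity_pct: float, seed: int) -> tuple[str, float]:
    """Substitute residues to a target percent identity with the input.

    Substitution positions are chosen uniformly; replacements are drawn
    from a BLOSUM62-weighted distribution over the 19 other residues
    (probability ∝ exp(λ·s), λ = ln2/2), never the residue itself, so
    realized identity is exact by count. Returns
    ``(mutated, realized_identity_pct)``; raises when the sequence is too
    short for the target to be reachable within ±2 points (identity moves
    in steps of ``100/len``).
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must be in (0, 100]")
    L = len(seq)
    n_sub = round(L * (1 - target_identity_pct / 100.0))
    realized = 100.0 * (L - n_sub) / L
    if abs(realized - target_identity_pct) > 2.0:
        raise ValueError(
            f"target identity {target_identity_pct}% unreachable within ±2 "
            f"points on a {L}-residue sequence (step {100.0 / L:.1f}%)"
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        pool, probs = _REPLACEMENTS[out[p]]
        out[p] = rng.choice(pool, p=probs)
    return "".join(out), realized


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly chosen synonymous codons (table 11)."""
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def plant_gene(
    genome_nt: str, protein: str, strand: str, position: int, seed: int
) -> tuple[str, int]:
    """Overwrite a genome slice with a reverse-translated coding sequence.

    The CDS replaces ``genome_nt[position : position + 3 * len(protein)]``
    (reverse-complemented first when ``strand`` is ``-``), leaving the
    flanks untouched. Returns the new genome and the reading frame in
    which a six-frame translation of the stated strand reproduces the
    protein verbatim.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    span = 3 * len(protein)
    if position < 0 or position + span > len(genome_nt):
        raise ValueError(
            f"position {position} leaves no room for {span} nt "
            f"in a {len(genome_nt)} nt genome"
        )
    cds = reverse_translate(protein, np.random.default_rng(seed))
    if strand == "-":
        frame = (len(genome_nt) - position - span) % 3
        cds = reverse_complement(cds)
    else:
        frame = position % 3
    return genome_nt[:position] + cds + genome_nt[position + span :], frame


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth record of one planted coding sequence."""

    enzyme_id: str
    contig_id: str
    strand: str
    frame: int
    position: int
    realized_identity_pct: float


class GenomeBuilder:
    """A single-contig genome that tracks planted-gene occupancy."""

    def __init__(self, contig_id: str, length: int, rng: np.random.Generator):
        self.contig_id = contig_id
        self.sequence = "".join(rng.choice(list("ACGT"), size=length))
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []

    def _free(self, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.occupied)

    def plant(self, protein: str, strand: str, position: int | None = None) -> tuple[int, int]:
        """Plant a CDS; auto-place non-overlapping when position is None.

        Returns ``(position, frame)``; raises on overlap with a previous
        plant or when no free slot can be found.
        """
        span = 3 * len(protein)
        if position is None:
            for _ in range(1000):
                cand = int(self.rng.integers(0, len(self.sequence) - span))
                if self._free(cand, cand + span):
                    position = cand
                    break
            else:
                raise ValueError(
                    f"{self.contig_id}: no free slot for a {span} nt gene"
                )
        elif not self._free(position, position + span):
            raise ValueError(
                f"{self.contig_id}: position {position} overlaps a planted gene"
            )
        seed = int(self.rng.integers(0, 2**31 - 1))
        self.sequence, frame = plant_gene(
            self.sequence, protein, strand, position, seed
        )
        self.occupied.append((position, position + span))
        return position, frame

    def record(self) -> SequenceRecord:
        return SequenceRecord(self.contig_id, "", self.sequence, NUCLEOTIDE)


# ---------------------------------------------------------------------------
# Whole-study scenario


# isolate genus assignments, mirroring a typical cultivation outcome:
# five Pseudomonas, two Sphingobacterium, one Agrobacterium
_ISOLATE_GENERA = (
    "Pseudomonas", "Sphingobacterium", "Pseudomonas", "Sphingobacterium",
    "Agrobacterium", "Pseudomonas", "Pseudomonas", "Pseudomonas",
)

_ENZYME_NAMES = {"9": "Tetrahydroisoquinoline N-methyltransferase"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the planted comparative-genomics scenario.

    Defaults reproduce the study structure: a 26-step numbered pathway,
    the degradation-associated genome carrying orthologs of enzymes
    {1, 2, 3, 9, 24} and every non-degrader isolate carrying {1, 2, 3, 24},
    so enzyme 9 is the unique expected essential candidate.
    """

    seed: int = 42
    n_enzymes: int = 26
    enzyme_length: int = 200
    enriched_enzyme_subset: tuple[str, ...] = ("1", "2", "3", "9", "24")
    isolate_enzyme_subset: tuple[str, ...] = ("1", "2", "3", "24")
    planted_identity_pct: float = 60.0
    genome_length: int = 50_000
    n_isolates: int = 8
    decoy_orf_density: float = 0.1  # decoy ORFs per kb of genome
    decoy_orf_length: int = 150
    enriched_genus: str = "Methylotenera"

    def __post_init__(self) -> None:
        labels = {str(i + 1) for i in range(self.n_enzymes)}
        for subset in (self.enriched_enzyme_subset, self.isolate_enzyme_subset):
            unknown = set(subset) - labels
            if unknown:
                raise ValueError(f"subset labels {sorted(unknown)} outside pathway")
        if self.n_isolates < 1:
            raise ValueError("need at least one isolate genome")


@dataclass
class ScenarioTruth:
    """What was planted where, and what the pipeline should recover."""

    planted: dict[str, list[PlantedGene]]
    expected_essential_candidates: list[str]
    decoys_per_genome: int


@dataclass
class Scenario:
    config: ScenarioConfig
    enzymes: list[PathwayEnzyme]
    genomes: dict[str, list[SequenceRecord]]
    roles: list[GenomeRole]
    truth: ScenarioTruth


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Build the full planted scenario deterministically from the config."""
    config = config or ScenarioConfig()
    root = np.random.default_rng(config.seed)

    enzymes = []
    parents: dict[str, str] = {}
    for i in range(config.n_enzymes):
        eid = str(i + 1)
        parents[eid] = random_protein(config.enzyme_length, root)
        enzymes.append(
            PathwayEnzyme(
                eid,
                _ENZYME_NAMES.get(eid, f"pathway enzyme {eid}"),
                SequenceRecord(
                    f"enzyme_{eid}", _ENZYME_NAMES.get(eid, ""),
                    parents[eid], PROTEIN,
                ),
            )
        )

    n_decoys = round(config.decoy_orf_density * config.genome_length / 1000)

    def build_genome(genome_id: str, subset: tuple[str, ...],
                     rng: np.random.Generator) -> tuple[list[SequenceRecord], list[PlantedGene]]:
        builder = GenomeBuilder(f"{genome_id}_contig1", config.genome_length, rng)
        planted = []
        for eid in subset:
            mut_seed = int(rng.integers(0, 2**31 - 1))
            mutated, realized = mutate_protein(
                parents[eid], config.planted_identity_pct, mut_seed
            )
            strand = "+" if rng.random() < 0.5 else "-"
            pos, frame = builder.plant(mutated, strand)
            planted.append(
                PlantedGene(eid, builder.contig_id, strand, frame, pos, realized)
            )
        for _ in range(n_decoys):
            decoy = random_protein(config.decoy_orf_length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            builder.plant(decoy, strand)
        return [builder.record()], planted

    genomes: dict[str, list[SequenceRecord]] = {}
    roles: list[GenomeRole] = []
    planted: dict[str, list[PlantedGene]] = {}

    enriched_id = f"{config.enriched_genus}_enriched"
    rng = np.random.default_rng(root.integers(0, 2**31 - 1))
    genomes[enriched_id], planted[enriched_id] = build_genome(
        enriched_id, config.enriched_enzyme_subset, rng
    )
    roles.append(GenomeRole(enriched_id, config.enriched_genus, ENRICHED_GENUS))

    for k in range(config.n_isolates):
        gid = f"J{k + 1}"
        genus = _ISOLATE_GENERA[k % len(_ISOLATE_GENERA)]
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        genomes[gid], planted[gid] = build_genome(
            gid, config.isolate_enzyme_subset, rng
        )
        roles.append(GenomeRole(gid, genus, NONDEGRADER_ISOLATE))

    expected = sorted(
        set(config.enriched_enzyme_subset) - set(config.isolate_enzyme_subset),
        key=int,
    )
    return Scenario(
        config, enzymes, genomes, roles,
        ScenarioTruth(planted, expected, n_decoys),
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Emit enzymes.faa, genomes/<id>.fna, roles.tsv and truth.json."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    write_fasta([e.record for e in scenario.enzymes], outdir / "enzymes.faa")
    for gid, records in scenario.genomes.items():
        write_fasta(records, outdir / "genomes" / f"{gid}.fna")
    write_roles(scenario.roles, outdir / "roles.tsv")
    truth = {
        "planted": {
            gid: [asdict(p) for p in genes]
            for gid, genes in scenario.truth.planted.items()
        },
        "expected_essential_candidates": scenario.truth.expected_essential_candidates,
        "decoys_per_genome": scenario.truth.decoys_per_genome,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# Community time series and degradation curves


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the genus-dynamics and degradation-curve generator.

    Fraction templates are piecewise profiles over the amplicon sampling
    days (0, 3, 6, 10, 14): the focal genus spikes to its peak on day 3
    of degrading samples from a ~0.2% baseline, the successor genus rises
    after day 3, and the control genus is stimulated in both groups (to
    half its degrading-sample level in stable ones). Counts are drawn
    multinomially at ``depth`` reads per day; curves are sampled daily
    over 14 days with a 5-day adaptation lag.
    """

    timepoints: tuple[int, ...] = (0, 3, 6, 10, 14)
    depth: int = 50_000
    n_degrading: int = 3
    n_stable: int = 3
    focal_genus: str = "Methylotenera"
    successor_genus: str = "Novosphingobium"
    control_genus: str = "Flavobacterium"
    initial_conc_ug_per_ml: float = 100.0
    lag_days: int = 5
    jitter_sigma: float = 0.05
    conc_noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.depth < 100:
            raise ValueError("read depth below 100: fractions are meaningless")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at day 0")


_DEGRADING_SAMPLES = ("Xinjiang", "Beijing", "Jiangxi")
_STABLE_SAMPLES = ("Yunnan", "Heilongjiang", "Guangxi")

# fraction templates over days (0, 3, 6, 10, 14)
_DEGRADING_TEMPLATE = {
    "focal":            [0.002, 0.200, 0.080, 0.020, 0.005],
    "successor":        [0.002, 0.030, 0.120, 0.150, 0.100],
    "control":          [0.010, 0.150, 0.100, 0.050, 0.030],
    "Delftia":          [0.001, 0.010, 0.040, 0.080, 0.100],
    "Sphingopyxis":     [0.001, 0.010, 0.030, 0.070, 0.090],
    "Acinetobacter":    [0.100, 0.010, 0.002, 0.001, 0.001],
    "Pseudomonas":      [0.150, 0.120, 0.100, 0.090, 0.080],
    "Stenotrophomonas": [0.080, 0.060, 0.050, 0.050, 0.040],
}
_STABLE_TEMPLATE = {
    "focal":            [0.002, 0.002, 0.002, 0.002, 0.002],
    "successor":        [0.002, 0.002, 0.002, 0.002, 0.002],
    "control":          [0.010, 0.075, 0.050, 0.030, 0.020],
    "Delftia":          [0.001, 0.001, 0.001, 0.001, 0.001],
    "Sphingopyxis":     [0.001, 0.001, 0.001, 0.001, 0.001],
    "Acinetobacter":    [0.100, 0.100, 0.095, 0.095, 0.090],
    "Pseudomonas":      [0.150, 0.130, 0.110, 0.100, 0.090],
    "Stenotrophomonas": [0.080, 0.070, 0.060, 0.050, 0.045],
}


def _sample_counts(
    sample_id: str,
    template: dict[str, list[float]],
    config: CommunityConfig,
    rng: np.random.Generator,
) -> GenusCountTable:
    names = {
        "focal": config.focal_genus,
        "successor": config.successor_genus,
        "control": config.control_genus,
    }
    genera = [names.get(g, g) for g in template]
    fracs = np.array([template[g] for g in template], dtype=float)
    # mild per-sample multiplicative jitter; "other" absorbs the remainder
    jitter = rng.lognormal(0.0, config.jitter_sigma, size=fracs.shape)
    fracs = fracs * jitter
    other = 1.0 - fracs.sum(axis=0)
    if (other <= 0).any():
        raise ValueError("templates exceed unit abundance after jitter")
    probs = np.vstack([fracs, other])
    counts = np.empty_like(probs, dtype=np.int64)
    for d in range(probs.shape[1]):
        counts[:, d] = rng.multinomial(config.depth, probs[:, d] / probs[:, d].sum())
    table = {g: counts[i] for i, g in enumerate(genera + ["other"])}
    return GenusCountTable(sample_id, list(config.timepoints), table)


def _degrading_curve(sample_id: str, config: CommunityConfig,
                     rng: np.random.Generator) -> DegradationCurve:
    c0 = config.initial_conc_ug_per_ml
    lag = config.lag_days
    # lag at the initial level, then rapid decay to ~1% residual
    decay = [0.95, 0.40, 0.05, 0.02]
    conc = [c0] * lag + [c0 * f for f in decay]
    conc += [c0 * 0.01] * (15 - len(conc))
    noise = rng.normal(1.0, config.conc_noise_sigma, size=len(conc))
    values = np.clip(np.array(conc) * noise, 0.0, None)
    return DegradationCurve(sample_id, list(range(15)), values)


def _stable_curve(sample_id: str, config: CommunityConfig,
                  rng: np.random.Generator) -> DegradationCurve:
    c0 = config.initial_conc_ug_per_ml
    noise = rng.normal(1.0, config.conc_noise_sigma, size=15)
    return DegradationCurve(sample_id, list(range(15)), np.clip(c0 * noise, 0.0, None))


def generate_community_series(
    config: CommunityConfig | None = None, seed: int = 0
) -> tuple[dict[str, GenusCountTable], dict[str, DegradationCurve]]:
    """Genus-count tables plus matching degradation curves, per sample."""
    config = config or CommunityConfig()
    rng = np.random.default_rng(seed)
    tables: dict[str, GenusCountTable] = {}
    curves: dict[str, DegradationCurve] = {}
    for k in range(config.n_degrading):
        name = (_DEGRADING_SAMPLES[k] if k < len(_DEGRADING_SAMPLES)
                else f"degrading_{k + 1}")
        tables[name] = _sample_counts(name, _DEGRADING_TEMPLATE, config, rng)
        curves[name] = _degrading_curve(name, config, rng)
    for k in range(config.n_stable):
        name = (_STABLE_SAMPLES[k] if k < len(_STABLE_SAMPLES)
                else f"stable_{k + 1}")
        tables[name] = _sample_counts(name, _STABLE_TEMPLATE, config, rng)
        curves[name] = _stable_curve(name, config, rng)
    return tables, curves


def write_community_series(
    tables: dict[str, GenusCountTable],
    curves: dict[str, DegradationCurve],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        write_genus_counts(table, outdir / f"{name}_counts.tsv")
    for name, curve in curves.items():
        write_degradation_curve(curve, outdir / f"{name}_curve.tsv")


# ---------------------------------------------------------------------------
# Homolog families (for motif analysis)


def generate_homolog_family(
    n: int = 10,
    length: int = 220,
    motif: str = "GCGAG",
    carriage: float = 1.0,
    family_identity_pct: float = 80.0,
    motif_position: int = 60,
    seed: int = 0,
) -> list[SequenceRecord]:
    """A family of substitution-diverged homologs sharing a planted motif.

    ``carriage`` is the fraction of members carrying the motif at the
    shared position; non-carriers hold a fixed motif-free block there.
    Divergence is substitution-only, so the family aligns without gaps
    and the motif occupies the same alignment columns in every carrier.
    """
    if not 0.0 <= carriage <= 1.0:
        raise ValueError("carriage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    parent = list(random_protein(length, rng))
    # scrub accidental pattern occurrences from the parent background
    w = len(motif)
    for i in range(length - w + 1):
        window = parent[i : i + w]
        if all(m == "X" or m == c for m, c in zip(motif.upper(), window)):
            parent[i] = rng.choice([a for a in AA20 if a != parent[i] and a != "G"])
    parent = "".join(parent)
    non_carrier_block = "KLNPQ"[: w] + "K" * max(0, w - 5)

    n_carriers = round(carriage * n)
    records = []
    for k in range(n):
        seq, _ = mutate_protein(
            parent, family_identity_pct, int(rng.integers(0, 2**31 - 1))
        )
        block = motif.upper() if k < n_carriers else non_carrier_block
        block = "".join(
            rng.choice(list(AA20)) if ch == "X" else ch for ch in block
        )
        seq = seq[:motif_position] + block + seq[motif_position + w :]
        records.append(SequenceRecord(f"homolog_{k + 1}", "", seq, PROTEIN))
    return records


# ---------------------------------------------------------------------------
# Homology hit tables


_HIT_GENERA = (
    "Variovorax", "Methylotenera", "Acidovorax", "Ramlibacter", "Rhodoferax",
    "Polaromonas", "Hydrogenophaga", "Janthinobacterium", "Massilia",
    "Herbaspirillum", "Burkholderia", "Cupriavidus", "Ralstonia", "Delftia",
    "Comamonas", "Methylophilus", "Methylovorus", "Thiobacillus", "Sulfuritalea",
    "Azoarcus", "Dechloromonas", "Zoogloea", "Sideroxydans", "Gallionella",
    "Nitrosomonas", "Novosphingobium", "Sphingopyxis", "Sphingobium",
)


def generate_hit_table(
    seed: int = 0,
    n_total: int = 500,
    n_resolved: int = 219,
    focal_genus: str = "Methylotenera",
    focal_count: int = 11,
    top_genus: str = "Variovorax",
    top_count: int = 40,
) -> list[HitRecord]:
    """A homology hit table with controlled genus composition.

    ``n_resolved`` of ``n_total`` hits carry a genus-ranked lineage;
    ``focal_count`` of those belong to the focal genus, ``top_count`` to
    the most-represented genus, and the rest are spread thinly over a
    background genus pool. Similarities decrease from ~95% and every hit
    id is unique, so the table is stable under top-N selection.
    """
    if focal_count + top_count > n_resolved:
        raise ValueError("focal_count + top_count exceed n_resolved")
    if n_resolved > n_total:
        raise ValueError("n_resolved exceeds n_total")
    rng = np.random.default_rng(seed)
    background = [g for g in _HIT_GENERA if g not in (focal_genus, top_genus)]
    genera = [focal_genus] * focal_count + [top_genus] * top_count
    genera += list(rng.choice(background, size=n_resolved - len(genera)))
    lineages = [
        f"d__Bacteria;p__Pseudomonadota;g__{g};s__{g}_sp" for g in genera
    ]
    lineages += ["d__Bacteria;p__Pseudomonadota"] * (n_total - n_resolved)
    rng.shuffle(lineages)
    sims = np.sort(rng.uniform(35.0, 95.0, size=n_total))[::-1]
    return [
        HitRecord(f"WP_{k:09d}", round(float(s), 2), lin, parse_genus(lin))
        for k, (s, lin) in enumerate(zip(sims, lineages))
    ]
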