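# Methods

`orthopath` implements the comparative-genomics argument by which a single
pathway enzyme is identified as the essential, taxon-restricted step of a
microbial biodegradation. This note records the models and procedures, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices taken where the design was open.

## Problem setting

A plant secondary metabolite (berberine, an isoquinoline alkaloid used as a
botanical pesticide) is degraded in some soil-water communities but not
others. Degradation coincides with transient enrichment of particular genera
(a *Methylotenera*-like focal genus peaking around day 3, a
*Novosphingobium*-like successor rising later), while every strain that can
be cultivated from the degrading community fails to degrade the compound on
its own. The computational question: which step of the compound's (reverse)
biosynthetic pathway is carried *only* by the enrichment-associated taxa and
never by the cultivable non-degraders? That step is the candidate essential,
taxon-restricted enzyme — in the motivating system, a tetrahydroisoquinoline
N-methyltransferase.

## Sequence comparison

**Six-frame translation.** Genomes arrive as unannotated nucleotide contigs.
Each contig is read in all six frames under the bacterial/plastid code
(translation table 11). Codons containing `N` translate to `X`; stop codons
are kept as `*` so that alignments may span them (below). Frame lengths are
`floor((L − frame)/3)`.

**Local alignment.** Protein queries are aligned to each frame translation
with affine-gap Smith–Waterman (Gotoh recurrences), BLOSUM62, gap open 11,
gap extension 1 — a gap of length *k* costs `11 + k·1`, matching common
protein-search defaults. `X` and `*` score the matrix minimum (−4) against
everything, themselves included, so stop-rich frames cannot inflate scores.
Tie-breaking is fixed: traceback prefers diagonal, then gap-in-subject, then
gap-in-query; among equal-scoring end cells the smallest
`(subject_end, query_end)` wins. The implementation is exact dynamic
programming (no heuristic seeding) in numba-compiled kernels; its scores are
verified in the test suite against an exhaustive enumeration oracle that
scores every strictly increasing set of aligned column pairs on short
sequences, and translations are verified against Biopython's table-11
translator.

**Alignment statistics.** For an alignment we report, over its gapped
columns: `identity_pct` (identical columns), `similarity_pct` (identical
plus positive-scoring columns — BLAST "positives"), and
`query_coverage_pct` (aligned query span / query length). Two further
statistics normalize by the query length instead:
`query_identity_pct = 100·identical/|query|` and
`query_similarity_pct = 100·positives/|query|`.

**Why presence thresholds the query-normalized similarity.** The optimal
local alignment between a 200-residue random query and a 50 kb random
genome typically spans 15–30 columns of which most are positive — its
*per-column* similarity sits near the BLOSUM62 positive-pair rate
(~35%) and occasionally such meandering alignments stretch past 50%
coverage while staying near 38% per-column similarity. A per-column "> 30%"
rule therefore cannot separate homology from noise. Normalizing positives
by the query length turns the same 30% threshold into a whole-protein
statement: a random best hit reaches ~10–22% (measured over seeded
replicates), a full-length ortholog at 45% identity reaches ~55–60%. The
presence rule is:

```
present  ⇔  query_similarity_pct > 30
        AND query_coverage_pct ≥ 50
        AND gap columns ≤ 10% of aligned columns
```

All cutoffs are configurable (`PresenceParams`); the metric can be
switched to identity. The coverage floor and the gap cap are explicit
extensions — the motivating analysis states only the 30% similarity
cutoff. The coverage floor encodes that a presence call should reflect
most of the protein. The gap cap closes a rarer loophole observed in
planted-truth runs: between *unrelated proteins* (≈10⁻⁴ per pair) the
aligner can stitch positive-scoring islands into a long, heavily gapped
alignment (observed: 197 columns, 23% gaps, query similarity 34.5%,
coverage 91.5%) that crosses both other filters. Genuine ortholog
alignments are collinear with near-zero gap content, and an *ungapped*
alignment of unrelated sequences cannot hold a positive score over
enough columns to matter, so the cap removes this failure class without
touching real detections. The threshold is strict (`>`), per the printed
inequality.

**Best hit.** For each enzyme × genome the maximum-score alignment over all
contigs × frames is retained (protein records, if supplied, are aligned
directly — so annotated proteomes work too). Score ties resolve by higher
per-column similarity, then lexicographic subject id, strand, frame.
Alignments may span stop codons rather than requiring clean ORFs: on
fragmented or frameshifted contigs this favours recall, and the −4 stop
penalty keeps it safe.

**Query length matters.** The default thresholds assume queries of
roughly enzyme length (≥ ~100 residues). For much shorter queries the
30% query-normalized bar drops to a handful of positive columns and
random hits start to cross it; raise the threshold or coverage floor
accordingly.

## Essentiality logic

Genomes carry evidence roles: `enriched_genus` (taxa whose enrichment
tracks degradation; uncultivable in the motivating study),
`nondegrader_isolate` (cultivated strains that fail to degrade), `other`
(reported, ignored). Enzymes partition as:

| class | condition |
|---|---|
| `essential_candidate` | present in ≥1 enriched-genus genome, in no isolate |
| `shared` | present in both groups |
| `isolate_only` | present only in isolates |
| `absent` | present in neither |

By default presence in *any* enriched genome suffices (the motivating study
had one focal genus); `require_all_enriched=True` demands all. This is set
logic, not a hypothesis test — the output says "candidate" deliberately.
Adding isolate evidence is monotone: it can only remove candidates.

## Community evidence

Relative abundance of a genus on a day is its read count over the sample's
total reads that day (tables carry an explicit `other` bucket, so per-day
fractions sum to 1). A degradation curve is `degraded` when the final
concentration is ≤ 10% of the initial (configurable `residual_frac`);
onset is the first day below 90% of initial. Both rules are
scale-invariant.

"Enriched" is not quantified in the motivating study; the pipeline's policy
is: peak abundance ≥ 5% (`min_peak`) and ≥ 5× (`min_fold`) the day-0
baseline, floored at one read (`1/depth`), in *every* sample of a group.
A genus is `degradation_associated` when enriched in all degraded samples
and not consistently enriched in the stable ones — which correctly excludes
a genus stimulated in both groups.

## Motif conservation

Homolog families are aligned with center-star: the center maximizes summed
pairwise Smith–Waterman scores (tie → lexicographic id); others are aligned
to it globally (same scoring and tie-breaks) and merged under "once a gap,
always a gap". Center-star is deterministic and testable against exhaustive
small cases; it is sub-optimal versus progressive aligners, which is
acceptable for the compact, indel-poor methyltransferase families at issue.
Column conservation is the fraction of sequences carrying the modal non-gap
residue (gaps count in the denominator: gappy columns are not conserved).
A motif pattern (`GCGxG`, `GxGxG`; `x` = any residue, the glycine-rich
SAM-binding loop notation) hits a window of ungapped columns when ≥ 80%
(`min_conservation`) of sequences match it gap-free at every position.

## Hit-table distribution

From a homology hit table, the top N = 500 hits by similarity (ties by
subject id) are kept; percentages are computed on the genus-resolved
denominator — hits whose lineage lacks a `g__` field count toward the total
but not the percentage base — and rounded half-up to 2 decimals. With 219
resolved hits of which 11 belong to the focal genus, the focal share is
11/219 = 5.02%; dividing by the top-N total (500) would not reproduce that
figure, which is why the resolved count is the denominator.

## Synthetic data: what it emulates, what it does not

The generator produces every pipeline input with planted truth. Defaults
are the study conditions, fixed once:

* **Pathway**: 26 enzymes (labels "1"–"26"), random 200-residue parents.
  The pathway length is arbitrary; only the subset structure matters.
* **Scenario**: one enriched-genus genome (*Methylotenera*-like) carries
  orthologs of enzymes {1, 2, 3, 9, 24}; eight isolates (five
  *Pseudomonas*, two *Sphingobacterium*, one *Agrobacterium*, echoing a
  typical cultivation outcome) carry {1, 2, 3, 24}. Expected essential
  candidate: enzyme 9, uniquely.
* **Divergence**: orthologs are planted at 60% target identity.
  Substitution positions are uniform; replacements are drawn with
  probability ∝ exp(λ·s(a,b)) over the 19 alternatives (λ = ln 2 / 2,
  BLOSUM62's half-bit scale), so conservative changes dominate but
  dissimilar ones occur. Realized identity is exact by count and recorded
  in the truth file.
* **Genomes**: 50 kb single-contig random ACGT background, planted CDS
  regions reverse-translated with uniform synonymous codons (no
  codon-usage model — downstream works in protein space), either strand,
  any frame, plus ~5 decoy ORFs of unrelated 150-residue protein.
* **Community**: sampling days {0, 3, 6, 10, 14}, 50 000 reads/day,
  multinomial counts around piecewise fraction templates (no ODE — the
  motivating data state no kinetics): focal genus 0.2% → 20% (day 3) → 
  decline; successor rising after day 3; control genus enriched in both
  groups (half-height in stable samples); three degrading and three
  stable samples. Degradation curves: daily for 14 days, 100 µg/mL
  initial, 5-day lag, decay to ~1% residual by day 8, 1% multiplicative
  noise; stable curves flat.
* **Hit tables**: 500 hits, 219 genus-resolved, 11 in the focal genus,
  the largest share in a *Variovorax*-like genus, background spread over
  a fixed genus pool.

Not emulated: realistic genome composition (GC skew, operons, codon
usage), insertions/deletions in ortholog divergence, read-level amplicon
noise and classifier error, chemistry of the compound's decay. Passing
tests on these data therefore demonstrate the *logic* of the pipeline —
recovery of planted truth under controlled divergence and noise — not
performance on real genomes, where fragmented assemblies, paralogs and
compositional bias add failure modes this generator does not produce.

**Detection floor.** Under this divergence model, full-length orthologs
remain detectable well below the planted 60%: at 45% target identity
detection is 100% across seeded replicates, and even 20%-identity
homologs are usually still called present (query similarity ≈ 36%) —
substitution-only divergence keeps full-length positional homology, which
is exactly what the rule measures. The discriminating null is absence of
homology (shuffled or unrelated sequence), where the best-hit metric
stays near 10–22%, far below threshold.

## Numerical choices and degenerate inputs

* Scores are integer; kernels use int32 with a −2²⁸ sentinel for −∞.
* A best hit with score 0 is reported as absent.
* Zero-total read days, empty FASTA files, non-positive initial
  concentrations, missing genome roles, and all-unresolved hit tables are
  errors, not silent defaults.
* Percentages in the hit distribution round half-up (`decimal`), matching
  the printed precision of the figures they reproduce; all other
  percentages are unrounded floats.
* All generators are deterministic under `(config, seed)`; seeds are
  plain integers below 2³¹.

## Problem sizes used in the checks

The end-to-end acceptance check runs ten independently seeded scenarios at
the default study conditions (26 enzymes × 9 genomes × 50 kb, ~5·10⁹ DP
cells per scenario); calibration uses 50 planted and 100 shuffled-decoy
replicates at the same genome size; the alignment oracle check uses 200
random pairs of length ≤ 8, where exhaustive enumeration is exact. These
sizes were chosen so the whole suite completes in minutes on one CPU while
exercising the full-scale study conditions.

## Known limitations

* Presence is inferred from one best local alignment; paralogs and
  multi-domain proteins can satisfy the rule without being functional
  orthologs (no reciprocal-best-hit or synteny evidence).
* Center-star MSA quality degrades with indel-rich families.
* The essentiality inference is set logic over a handful of genomes; it
  cannot distinguish "absent" from "unassembled" and attaches no
  uncertainty to the candidate call.
* The enrichment policy (5%, 5×) is a pipeline default chosen to
  reproduce the qualitative enrichment pattern on the generator; real
  studies should tune it to their depth and replication.
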