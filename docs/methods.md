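# Methods

This note records the models behind each stage, the defaults and why
they hold, what the synthetic generator does and does not emulate, and
the numerical/tie-breaking choices that were genuinely open.

## Marker design and mapping

An ISBP marker is the 150-bp window centred on a TE junction (75 bp of
element, 75 bp of insertion site). Design drops windows that run off
the chromosome or contain N. Uniqueness is enforced by re-mapping each
tag to its source genome and keeping tags with exactly one passing
placement.

Mapping is seed-and-extend: exact 21-mer seeds are located in a sorted
k-mer index of the target; candidate diagonals are clustered within a
15-bp band and verified by bounded edit-distance alignment of the full
query (edlib, infix mode, band-derived edit cap). **Identity is
matches / alignment columns** of that alignment — the usual convention
for short fixed-length queries; since the full query must align, query
coverage is 1 for any reported hit and deleted loci simply produce no
hit. Uniqueness of a mapping is decided by a second-best score gap of
5 matched columns; anything closer is flagged ambiguous.

The guarantee of the seed stage is combinatorial: a query with at most
⌊150/21⌋ − 1 = 6 edits always retains an intact 21-mer. Beyond that,
recovery is probabilistic (as for any seeded mapper); the exhaustive
DP oracle in the test suite therefore plants ≤ 6 substitutions when
asserting exact equivalence.

Threshold presets: anchoring 80% identity / 90% coverage; conservation
90/90; exon search 95/95; a strict dot-plot preset (≤ 2 mismatches, no
indels, full coverage) for collinearity plots.

## Anchoring

Single marker hits are noisy (TE bodies are multi-copy; some tags land
at paralogous junctions). Pairing consecutive hits and requiring
< 50 kb separation on *both* genomes plus reference-chromosome
agreement removes isolated mis-mappings — a mis-mapped marker breaks
both pairs it participates in. Decisions taken where the procedure was
open:

* support denominator = all valid pairs of the scaffold (both gap
  conditions met), not only pairs on the winning chromosome;
* a 50/50 split across two chromosomes → chrUn (the assignment must
  have an unambiguous winner);
* orientation vote tie → keep assembly orientation (+);
* identical medians → longer scaffold first, then lexicographic id;
* pair orientation is derived from marker *order* on scaffold vs
  reference, not from individual hit strands, which is robust to a
  single flipped hit.

Pseudomolecules are oriented scaffolds joined by exactly 100 N; the AGP
writer emits U gap rows (gap type "scaffold", linkage "yes") — the
100 N is a placeholder, not a measured gap, hence the unknown-size
component type. `snap_break_to_gap` relocates a proposed scaffold break
to the nearest internal gap midpoint (tie → lower coordinate), the one
algorithmic fragment of map-based curation kept in scope.

## Haplotype painting

The coloured structure is a **canonical k-mer membership table**, not a
full de Bruijn graph: presence ratios per colour are all the queries
need, and the table has identical query semantics. Canonicalisation
(min of k-mer and reverse complement, 2-bit packed, A<C<G<T) makes
profiles invariant to assembly strand choices.

Defaults: k = 31, 1-kb markers every 20 kb, presence ratio e = 0.95
(inclusive ≥), palette of the 15 most abundant profiles per chromosome,
1-Mb majority merge; locus mode uses 5-kb spacing and e = 0.97. The
marker grid is anchored at offset 0. Windows ≥ 50% N are skipped;
blocks with no valid k-mers classify white.

Why e = 0.95 separates haplotypes at 0.7% divergence: a marker copied
from the same haplotype matches exactly (ratio 1); one stray
substitution removes at most k = 31 of 970 k-mers (ratio ≥ 0.968,
still present); a different founder at 0.7% per-base divergence leaves
≈ 0.986¹⁵⁰... per-k-mer survival (1 − 0.014)³¹ ≈ 0.65, far below
threshold. Two substitutions ≥ 31 bp apart (ratio ≈ 0.936) already
fail, which is the intended stringency.

Open choices declared here: the black/grey classes take precedence
over palette colouring (popcount 1 → black, ≥ 10 → grey, then palette,
then white); the 1-Mb merge operates on raw profiles (majority, tie →
leftmost member) and the merged profile is then classified. Palette
ties at the cut admit the lower bit value.

## Introgression calling

Coverage: alignments with MAPQ < 10 or not in a proper pair are
dropped; each surviving interval contributes its overlap bases to every
bin it intersects (base-exact conservation), and the trailing partial
bin is normalised by its true width. Calls: maximal runs of ≥ 5
consecutive bins whose profile is shared by ≤ 5 cultivars; with a donor
track, a run must show mean depth ≥ 5× the chromosome-median donor
depth. The run-length and coverage-factor thresholds are this package's
own defaults (exposed in `IntroConfig`): they are calibrated so that
single-bin minority noise and diffuse background coverage (non-zero is
expected when donor and host subgenome are related) can never produce a
call, while segments tens of bins long at order-of-magnitude depth
contrast always do. Without a donor track, runs are emitted as
profile-only candidates with `coverage_evidence=False`.

## QC

NGxx follows the Table-style convention: the quantile is taken against
an assumed genome size G (default 15 Gb) and reported as None when the
assembly never reaches it. Contigs are extracted by splitting at every
N (configurable minimum gap length). Telomere arrays are tandem runs of
TTTAGGG (both orientations, both ends, ≤ 1 mismatch per copy allowed
since natural arrays are imperfect) with ≥ 10 copies inside a 10-kb end
window. The k-mer QV re-implements the published Merqury formula —
E = 1 − (1 − b/t)^(1/k) — counting assembly k-mers with multiplicity;
b = 0 reports a declared cap (99) rather than infinity.

## Synthetic panels

The generator emulates exactly the structure the stages depend on:

* **TE structure** — repeat bodies drawn from a 20-motif library
  (500–5,000 bp, ~1% divergence between copies, random strand) fill
  ~50% of the chromosome; flanks are unique random sequence. Bodies are
  therefore multi-mapping while junctions are unique — the ISBP
  property. Densities ≥ 0.9 are rejected (junction uniqueness becomes
  unattainable).
* **Founders and mosaics** — founders are i.i.d. substitution mutants
  of one base chromosome (default 0.7%, the exon-space divergence
  observed between wheat cultivars); cultivars concatenate founder
  segments with exponential lengths (mean 200 kb). Substitution-only
  divergence keeps marker and k-mer arithmetic in closed form; indels
  enter only through explicit structural features (inversions,
  translocation, deletions planted by the exon scenario).
* **Introgressions** — spans replaced by a donor genome at 3%
  divergence; inversions reverse-complement a span; a translocation
  moves one. Truth tables tile every chromosome exactly and are
  asserted to do so.
* **Scaffolds** — chromosomes cut at random breakpoints, shuffled,
  flipped with probability 0.5; truth records source span, orientation
  and rank.
* **Donor reads** — fixed-length intervals placed at Poisson rates
  (depth_in inside introgressions, depth_bg elsewhere) with a
  configured low-MAPQ and improper-pair fraction.
* **Exon sets** — sampled from single-copy (non-TE) space so that a
  planted deletion cannot be rescued by a repeat copy elsewhere;
  deleted/mutated fractions are planted as exact counts, and "mutated"
  exons are substituted deterministically every 8th base (12.5%) so
  their failure at the 95% threshold is certain, not sampled.

Everything is a pure function of the config including its seed.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequencing error and read-level
artefacts, indel polymorphism between cultivars, nested/truncated TE
insertions, homoeologous cross-talk between subgenomes (chromosomes are
independent), segmental duplications, and assembly collapse. Scales are
desk-sized: 2-Mb chromosomes with 10-kb introgression bins stand in for
real chromosomes of hundreds of Mb with 1-Mb bins; all window sizes are
configuration, so the same code runs at either scale.

Workflow scenario choices: the anchoring scenario cuts 40 scaffolds of
≥ 20 kb from a 2-Mb chromosome so each carries several valid pairs (the
regime where exact recovery is the correct expectation). The
introgression scenario uses a panel with a shared haplotype backbone
plus isolated single-bin minority noise, the background against which
the run-length and coverage gates are defined; a heavily mosaic panel
at 11 cultivars over 6 founders instead yields segment-scale minority
runs for rare founders, which only the donor-coverage gate separates
from true introgressions — that regime is exercised by the painting
scenario, while call precision is scored where profile evidence is
actually informative.

## Known limitations

* Queries and k up to 31 only (2-bit uint64 packing); panels up to 64
  cultivars (uint64 colour bitsets).
* The mapper reports infix alignments of the whole query, so partial
  (clipped) hits surface as low identity rather than low coverage;
  `min_coverage` binds only in the aligned-bases conservation mode.
* Seeded mapping beyond 6 edits per 150 bp is heuristic (see above).
* `bin_coverage` is a straightforward per-interval loop — fine for
  binned tracks at desk scale, not a replacement for a depth tool on
  real BAMs.
* The locus mode localises a region by probe majority; tandem
  duplications of the whole locus would confuse the modal-interval
  heuristic.
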