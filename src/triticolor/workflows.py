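"""End-to-end study workflows on synthetic panels with known truth.

Each function generates a panel under the package's standard study
conditions, runs one pipeline stage against it, and scores the result
against the generator's truth tables. They are the backbone of the
validation suite and of the reproduction script.

Problem sizes are desk-scale (2-2.4 Mb chromosomes, 11 cultivars,
6 founders at 0.7% divergence) so each workflow completes in seconds to
a couple of minutes on one CPU while preserving the statistical
structure the stages rely on: hundreds of junction markers per
chromosome, mosaic segments spanning many marker bins, and introgressed
segments tens of bins long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import anchoring
from .haplotyping import HaploConfig, paint_panel
from .introgression import IntroConfig, bin_coverage, call_introgressions
from .markers import MapConfig, design_isbp, filter_unique, map_markers
from .qc import kmer_qv, trusted_kmer_set
from .synthetic import (
    PanelConfig,
    decode_genome,
    delete_spans,
    emit_exon_set,
    fragment_assembly,
    generate_panel,
    mutate_sequence,
    simulate_donor_alignments,
)


def _sub_seed(seed: int, stream: int) -> int:
    return int((seed * 1_000_003 + stream) % (2**31 - 1))


# ---------------------------------------------------------------------------
# anchoring

@dataclass
class AnchoringScore:
    n_scaffolds: int
    chrom_correct: int
    order_exact: bool
    orientation_correct: int

    @property
    def all_correct(self) -> bool:
        return (
            self.chrom_correct == self.n_scaffolds
            and self.order_exact
            and self.orientation_correct == self.n_scaffolds
        )


def anchoring_recovery(
    seed: int, chrom_len: int = 2_000_000, n_scaffolds: int = 40
) -> AnchoringScore:
    """Fragment a cultivar chromosome, anchor the scaffolds back onto the
    reference by marker-pair collinearity, and score chromosome
    assignment, order and orientation against the fragmentation truth."""
    cfg = PanelConfig(chrom_len=chrom_len, seed=_sub_seed(seed, 1))
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    ref = decode_genome(base)
    markers = filter_unique(design_isbp(ref, truth.te_intervals), ref)
    scaffolds, layout_truth = fragment_assembly(
        cultivars["cv01"], cfg, n_pieces=n_scaffolds, min_piece_len=20_000
    )
    scaffold_seqs = {r.id: r.sequence for r in scaffolds}
    hits = map_markers(markers, scaffold_seqs, MapConfig.preset("anchor"))
    by_scaffold: dict[str, list] = {}
    for h in hits:
        by_scaffold.setdefault(h.target_chrom, []).append(h)
    for lst in by_scaffold.values():
        lst.sort(key=lambda h: h.target_start)
    source = {m.id: (m.source_chrom, m.junction_pos) for m in markers}
    pairs = anchoring.pair_adjacent(by_scaffold, source)
    pairs_by_scaffold: dict[str, list] = {}
    for p in pairs:
        pairs_by_scaffold.setdefault(p.scaffold, []).append(p)
    anchors = [
        anchoring.assign_chromosome(s, pairs_by_scaffold.get(s, []))
        for s in scaffold_seqs
    ]
    layout = anchoring.order_scaffolds(
        anchors,
        {s: len(q) for s, q in scaffold_seqs.items()},
        anchoring.AnchorConfig(min_scaffold_len=10_000),
    )
    truth_order = sorted(layout_truth.items(), key=lambda kv: kv[1][4])
    anchor_of = {a.scaffold: a for a in anchors}
    chrom_correct = sum(
        1
        for name, (chrom, *_rest) in layout_truth.items()
        if anchor_of[name].assigned_chrom == chrom
    )
    got = layout.chrom_order.get("chr1A", [])
    order_exact = [s for s, _ in got] == [name for name, _ in truth_order]
    orientation_correct = sum(
        1
        for name, (chrom, s, e, orientation, rank) in layout_truth.items()
        if anchor_of[name].orientation == orientation
    )
    return AnchoringScore(
        n_scaffolds=len(scaffold_seqs),
        chrom_correct=chrom_correct,
        order_exact=order_exact,
        orientation_correct=orientation_correct,
    )


# ---------------------------------------------------------------------------
# haplotype painting

@dataclass
class PaintingScore:
    n_superblocks: int
    superblocks_matching_truth: int
    n_specific_bins: int
    specific_bins_black: int

    @property
    def superblock_recovery(self) -> float:
        return self.superblocks_matching_truth / self.n_superblocks

    @property
    def black_fraction(self) -> float:
        return self.specific_bins_black / self.n_specific_bins


def _truth_profile_bits(truth, names, cultivar: str, chrom: str, pos: int) -> int:
    """Expected presence bitset at a position from the mosaic truth: the
    querying cultivar plus every cultivar carrying the same founder there
    (introgressed positions are private to their carrier)."""
    own_intro = any(
        c == cultivar and ch == chrom and s <= pos < e
        for c, ch, s, e in truth.introgressions
    )
    ci = names.index(cultivar)
    if own_intro:
        return 1 << ci
    f = truth.founder_at(cultivar, chrom, pos)
    bits = 0
    for cj, other in enumerate(names):
        other_intro = any(
            c == other and ch == chrom and s <= pos < e
            for c, ch, s, e in truth.introgressions
        )
        if other_intro:
            continue
        if truth.founder_at(other, chrom, pos) == f:
            bits |= 1 << cj
    return bits


def painting_recovery(
    seed: int,
    chrom_len: int = 2_000_000,
    specific_span: tuple[int, int] = (1_500_000, 1_620_000),
) -> PaintingScore:
    """Paint an 11-cultivar, 6-founder panel and score 1-Mb superblock
    profiles against the mosaic truth; a planted cultivar-specific
    segment (donor introgression, 6 consecutive 20-kb bins) must come
    out black."""
    cfg = PanelConfig(
        chrom_len=chrom_len,
        seed=_sub_seed(seed, 2),
        introgressions=[
            (("cv03",), "chr1A", specific_span[0], specific_span[1] - specific_span[0])
        ],
    )
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    panel = {cv: decode_genome(g)["chr1A"] for cv, g in cultivars.items()}
    names = list(panel)
    hcfg = HaploConfig()
    result = paint_panel(panel, hcfg, chrom="chr1A")

    n_super = 0
    n_match = 0
    for cv in names:
        blocks = result.marker_blocks[cv]
        # expected modal profile per superblock via the same merge rule
        for sb in result.superblocks[cv]:
            members = [
                b for b in blocks if sb.span.start <= b.span.start < sb.span.end
            ]
            from collections import Counter

            expected = [
                _truth_profile_bits(truth, names, cv, "chr1A", b.span.start + hcfg.marker_len // 2)
                for b in members
            ]
            counts = Counter(expected)
            best = max(counts.values())
            modal = next(x for x in expected if counts[x] == best)
            n_super += 1
            n_match += sb.profile is not None and sb.profile.bits == modal
    blocks = result.marker_blocks["cv03"]
    specific = [
        b for b in blocks if specific_span[0] <= b.span.start < specific_span[1]
    ]
    return PaintingScore(
        n_superblocks=n_super,
        superblocks_matching_truth=n_match,
        n_specific_bins=len(specific),
        specific_bins_black=sum(b.cls == "black" for b in specific),
    )


# ---------------------------------------------------------------------------
# introgressions

@dataclass
class IntrogressionScore:
    n_truth: int
    n_calls: int
    matched_truth: int
    matched_calls: int
    max_boundary_error_bins: int

    @property
    def recall(self) -> float:
        return self.matched_truth / self.n_truth

    @property
    def precision(self) -> float:
        return self.matched_calls / self.n_calls if self.n_calls else 0.0


def introgression_recovery(
    seed: int,
    chrom_len: int = 2_400_000,
    bin_len: int = 10_000,
    depth_in: float = 20.0,
    depth_bg: float = 0.2,
) -> IntrogressionScore:
    """Plant three donor segments (10/20/30 bins) in one cultivar on a
    panel sharing a common haplotype backbone, plus isolated single-bin
    minority noise, and score the coverage-supported calls.

    The donor track has a 100x depth contrast between introgressed and
    background windows, mirroring reads of a wild relative mapped onto a
    carrier and non-carrier sequence.
    """
    spans = [
        (200_000, 200_000 + 10 * bin_len),
        (700_000, 700_000 + 20 * bin_len),
        (1_400_000, 1_400_000 + 30 * bin_len),
    ]
    noise = [
        (("cv03",), "chr1A", 100_000, bin_len),
        (("cv05",), "chr1A", 1_200_000, bin_len),
        (("cv01",), "chr1A", 2_200_000, bin_len),  # short run in the carrier too
    ]
    cfg = PanelConfig(
        chrom_len=chrom_len,
        seed=_sub_seed(seed, 3),
        founder_weights=[1.0] + [0.0] * 5,
        introgressions=[(("cv01",), "chr1A", s, e - s) for s, e in spans] + noise,
    )
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    panel = {cv: decode_genome(g)["chr1A"] for cv, g in cultivars.items()}
    hcfg = HaploConfig(spacing=5_000, merge_window=bin_len)
    result = paint_panel(panel, hcfg, chrom="chr1A")
    reads = simulate_donor_alignments(
        {"chr1A": spans},
        {"chr1A": chrom_len},
        depth_in=depth_in,
        depth_bg=depth_bg,
        seed=_sub_seed(seed, 4),
    )
    icfg = IntroConfig(bin_len=bin_len)
    bins = bin_coverage(reads, {"chr1A": chrom_len}, icfg)["chr1A"]
    calls = call_introgressions("cv01", result.superblocks["cv01"], bins, icfg)
    matched_truth = 0
    matched_calls = 0
    max_err = 0
    for s, e in spans:
        hit = [
            c
            for c in calls
            if abs(c.span.start - s) <= bin_len and abs(c.span.end - e) <= bin_len
        ]
        if hit:
            matched_truth += 1
            err = max(
                abs(hit[0].span.start - s) // bin_len,
                abs(hit[0].span.end - e) // bin_len,
            )
            max_err = max(max_err, err)
    for c in calls:
        if any(
            abs(c.span.start - s) <= bin_len and abs(c.span.end - e) <= bin_len
            for s, e in spans
        ):
            matched_calls += 1
    return IntrogressionScore(
        n_truth=len(spans),
        n_calls=len(calls),
        matched_truth=matched_truth,
        matched_calls=matched_calls,
        max_boundary_error_bins=max_err,
    )


# ---------------------------------------------------------------------------
# conservation scenarios

def isbp_conservation_scenario(
    seed: int, chrom_len: int = 500_000, missing_fraction: float = 0.06
) -> tuple[float, int]:
    """Delete a planted fraction of tagged loci from a target genome copy
    and measure the junction-marker conservation rate at the 90/90
    thresholds. Returns (conserved fraction, marker count)."""
    cfg = PanelConfig(chrom_len=chrom_len, seed=_sub_seed(seed, 5))
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    ref = decode_genome(base)
    markers = filter_unique(design_isbp(ref, truth.te_intervals), ref)
    rng = np.random.default_rng(_sub_seed(seed, 6))
    n_del = round(len(markers) * missing_fraction)
    # delete non-overlapping tagged loci (with margin) so each removal
    # destroys exactly one marker
    chosen = []
    for idx in rng.permutation(len(markers)):
        m = markers[idx]
        lo, hi = m.source_span.start - 50, m.source_span.end + 50
        if any(
            other is not m
            and other.source_chrom == m.source_chrom
            and other.source_span.start < hi
            and lo < other.source_span.end
            for other in markers
        ):
            continue
        chosen.append((m.source_chrom, max(0, lo), hi))
        if len(chosen) == n_del:
            break
    target = delete_spans(ref, chosen)
    from .markers import conservation_rate

    rate, perfect, rows = conservation_rate(markers, target)
    return rate, len(markers)


def exon_conservation_scenario(
    seed: int, chrom_len: int = 500_000, n_exons: int = 500,
    del_fraction: float = 0.038,
) -> tuple[float, int]:
    """Plant a known fraction of exon deletions in a target genome and
    measure the 95/95 conservation rate. Returns (conserved fraction,
    exon count)."""
    cfg = PanelConfig(chrom_len=chrom_len, seed=_sub_seed(seed, 7))
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    ref = decode_genome(base)
    exons, target, ledger = emit_exon_set(
        ref, truth.te_intervals, n_exons=n_exons,
        del_fraction=del_fraction, mut_fraction=0.0, seed=_sub_seed(seed, 8),
    )
    from .qc import exon_conservation

    report = exon_conservation(exons, target)
    return report.conserved_fraction, report.n_exons


def consensus_qv_scenario(
    seed: int, genome_len: int = 2_000_000, error_rate: float = 1e-3, k: int = 21
) -> float:
    """k-mer QV of a genome copy mutated at a known per-base error rate,
    scored against the unmutated genome's k-mer set (expected QV =
    -10 log10 rate)."""
    rng = np.random.default_rng(_sub_seed(seed, 9))
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, genome_len)])
    trusted = trusted_kmer_set({"g": genome}, k)
    noisy = mutate_sequence(genome, error_rate, _sub_seed(seed, 10))
    return kmer_qv({"g": noisy}, trusted, k)
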