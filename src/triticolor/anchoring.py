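"""Collinearity-guided pseudomolecule construction.

Scaffolds of a target assembly are anchored onto reference chromosomes
using pairs of adjacent ISBP marker hits. Pairing filters out isolated
mis-mapped markers: a pair is valid only when the two hits are close on
both genomes (< 50 kb) and their source markers share a reference
chromosome. A scaffold is assigned to the chromosome carrying a strict
majority (>= 50% of its valid pairs), ordered by the median reference
position of its pairs, oriented by majority vote, and joined into
pseudomolecules with fixed 100-N gaps. Unassigned scaffolds and those
below the minimum length fall into chrUn.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

from .io import SeqRecord, layout_to_agp_rows, reverse_complement
from .markers import IsbpMarker, MarkerHit


@dataclass
class AnchorConfig:
    max_pair_gap: int = 50_000
    min_support: float = 0.5
    gap_len: int = 100
    min_scaffold_len: int = 30_000

    def __post_init__(self) -> None:
        if min(self.max_pair_gap, self.gap_len, self.min_scaffold_len) <= 0:
            raise ValueError("AnchorConfig fields must be positive")
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")


@dataclass
class MarkerPair:
    scaffold: str
    marker_a: str
    marker_b: str
    scaffold_gap: int
    ref_chrom: str
    ref_gap: int
    ref_mid: float
    pair_orientation: str  # + when reference order equals scaffold order


@dataclass
class ScaffoldAnchor:
    scaffold: str
    assigned_chrom: str  # chromosome name or "chrUn"
    n_valid_pairs: int
    n_pairs_on_assigned: int
    support_fraction: float
    median_ref_pos: float
    orientation: str
    orientation_votes: tuple[int, int]  # (+, -)


@dataclass
class PseudomoleculeLayout:
    chrom_order: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    gap_len: int = 100
    unplaced: list[str] = field(default_factory=list)


def pair_adjacent(
    hits_by_scaffold: dict[str, Sequence[MarkerHit]],
    marker_source: dict[str, tuple[str, int]],
    cfg: AnchorConfig | None = None,
) -> list[MarkerPair]:
    """Emit valid pairs of *consecutive* hits on each scaffold.

    ``marker_source`` maps marker id -> (reference chrom, junction
    position). A pair is valid iff both the scaffold gap and the
    reference gap are below ``max_pair_gap`` and the two markers share a
    reference chromosome. Hits must be sorted by scaffold coordinate.
    """
    cfg = cfg or AnchorConfig()
    pairs: list[MarkerPair] = []
    for scaffold, hits in hits_by_scaffold.items():
        last = None
        for h in hits:
            if last is not None and h.target_start < last.target_start:
                raise ValueError(f"hits on {scaffold} are not sorted")
            last = h
        for a, b in zip(hits, hits[1:]):
            chrom_a, pos_a = marker_source[a.marker_id]
            chrom_b, pos_b = marker_source[b.marker_id]
            if chrom_a != chrom_b:
                continue
            scaffold_gap = b.target_start - a.target_start
            ref_gap = abs(pos_b - pos_a)
            if scaffold_gap >= cfg.max_pair_gap or ref_gap >= cfg.max_pair_gap:
                continue
            pairs.append(
                MarkerPair(
                    scaffold=scaffold,
                    marker_a=a.marker_id,
                    marker_b=b.marker_id,
                    scaffold_gap=scaffold_gap,
                    ref_chrom=chrom_a,
                    ref_gap=ref_gap,
                    ref_mid=(pos_a + pos_b) / 2,
                    pair_orientation="+" if pos_b >= pos_a else "-",
                )
            )
    return pairs


def assign_chromosome(
    scaffold: str, pairs: Sequence[MarkerPair], cfg: AnchorConfig | None = None
) -> ScaffoldAnchor:
    """Majority-chromosome assignment with a strict-winner tie rule.

    The winning chromosome must hold >= ``min_support`` of the
    scaffold's valid pairs *and* strictly more pairs than any other
    chromosome; otherwise the scaffold goes to chrUn. Orientation is the
    majority pair orientation on the assigned chromosome (+ on a tie,
    i.e., keep assembly orientation).
    """
    cfg = cfg or AnchorConfig()
    n_valid = len(pairs)
    if n_valid == 0:
        return ScaffoldAnchor(scaffold, "chrUn", 0, 0, 0.0, -1.0, "+", (0, 0))
    counts = Counter(p.ref_chrom for p in pairs)
    (top_chrom, top_n), *rest = counts.most_common()
    support = top_n / n_valid
    if support < cfg.min_support or (rest and rest[0][1] == top_n):
        return ScaffoldAnchor(scaffold, "chrUn", n_valid, top_n, support, -1.0, "+", (0, 0))
    on = [p for p in pairs if p.ref_chrom == top_chrom]
    plus = sum(p.pair_orientation == "+" for p in on)
    minus = len(on) - plus
    return ScaffoldAnchor(
        scaffold=scaffold,
        assigned_chrom=top_chrom,
        n_valid_pairs=n_valid,
        n_pairs_on_assigned=top_n,
        support_fraction=support,
        median_ref_pos=float(median(p.ref_mid for p in on)),
        orientation="+" if plus >= minus else "-",
        orientation_votes=(plus, minus),
    )


def order_scaffolds(
    anchors: Sequence[ScaffoldAnchor],
    scaffold_lengths: dict[str, int],
    cfg: AnchorConfig | None = None,
) -> PseudomoleculeLayout:
    """Order anchored scaffolds along each chromosome by median reference
    position; ties break by descending length then id. Scaffolds that are
    unassigned or shorter than ``min_scaffold_len`` go to unplaced."""
    cfg = cfg or AnchorConfig()
    seen: set[str] = set()
    for a in anchors:
        if a.scaffold in seen:
            raise ValueError(f"duplicate scaffold {a.scaffold}")
        seen.add(a.scaffold)
    layout = PseudomoleculeLayout(gap_len=cfg.gap_len)
    per_chrom: dict[str, list[ScaffoldAnchor]] = defaultdict(list)
    for a in anchors:
        if (
            a.assigned_chrom == "chrUn"
            or scaffold_lengths[a.scaffold] < cfg.min_scaffold_len
        ):
            layout.unplaced.append(a.scaffold)
        else:
            per_chrom[a.assigned_chrom].append(a)
    for chrom in sorted(per_chrom):
        ordered = sorted(
            per_chrom[chrom],
            key=lambda a: (
                a.median_ref_pos,
                -scaffold_lengths[a.scaffold],
                a.scaffold,
            ),
        )
        layout.chrom_order[chrom] = [(a.scaffold, a.orientation) for a in ordered]
    return layout


def build_pseudomolecule(
    layout: PseudomoleculeLayout, scaffolds: dict[str, str]
) -> tuple[list[SeqRecord], list]:
    """Join oriented scaffolds with fixed-length N gaps.

    Returns (pseudomolecule records, AGP rows).
    """
    records: list[SeqRecord] = []
    for chrom, placements in layout.chrom_order.items():
        parts: list[str] = []
        for scaffold, orientation in placements:
            if scaffold not in scaffolds:
                raise KeyError(f"no sequence for scaffold {scaffold!r}")
            seq = scaffolds[scaffold]
            parts.append(reverse_complement(seq) if orientation == "-" else seq)
        records.append(SeqRecord(chrom, ("N" * layout.gap_len).join(parts)))
    lengths = {name: len(seq) for name, seq in scaffolds.items()}
    return records, layout_to_agp_rows(layout, lengths)


def snap_break_to_gap(
    gaps: Sequence[tuple[int, int]], break_coord: int
) -> tuple[int, int]:
    """The internal scaffold gap whose midpoint is nearest to a proposed
    break coordinate (equidistant -> lower coordinate).

    Splitting at the returned gap removes the gap bases from both
    fragments. With no gaps the caller must split verbatim; that case is
    an error here.
    """
    if not gaps:
        raise ValueError("scaffold has no internal gaps")
    return min(gaps, key=lambda g: (abs((g[0] + g[1]) / 2 - break_coord), g[0]))


def split_scaffold_at_gap(seq: str, gap: tuple[int, int]) -> tuple[str, str]:
    """Split a scaffold at an internal gap, dropping the gap bases."""
    return seq[: gap[0]], seq[gap[1] :]
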