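import numpy as np
import pytest

from conftest import random_dna

from triticolor.anchoring import (
    AnchorConfig,
    MarkerPair,
    PseudomoleculeLayout,
    assign_chromosome,
    build_pseudomolecule,
    order_scaffolds,
    pair_adjacent,
    snap_break_to_gap,
    split_scaffold_at_gap,
)
from triticolor.io import reverse_complement
from triticolor.markers import MarkerHit


def _hit(mid, scaffold, start):
    return MarkerHit(mid, scaffold, start, start + 150, "+", 1.0, 1.0, 0, 0, 150)


def test_pair_adjacent_arithmetic():
    hits = {"s1": [_hit("a", "s1", 1_000), _hit("b", "s1", 20_000)]}
    source = {"a": ("chr1", 101_000), "b": ("chr1", 120_000)}
    pairs = pair_adjacent(hits, source)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.pair_orientation, p.ref_mid, p.scaffold_gap, p.ref_gap) == (
        "+", 110_500.0, 19_000, 19_000,
    )


def test_pair_adjacent_gap_boundary():
    hits = {"s1": [_hit("a", "s1", 0), _hit("b", "s1", 60_000)]}
    source = {"a": ("chr1", 0), "b": ("chr1", 10_000)}
    assert pair_adjacent(hits, source) == []  # 60 kb >= 50 kb


def test_pair_adjacent_reversed_reference_order():
    hits = {"s1": [_hit("a", "s1", 1_000), _hit("b", "s1", 20_000)]}
    source = {"a": ("chr1", 120_000), "b": ("chr1", 101_000)}
    pairs = pair_adjacent(hits, source)
    assert len(pairs) == 1 and pairs[0].pair_orientation == "-"


def test_pair_adjacent_requires_sorted_hits():
    hits = {"s1": [_hit("a", "s1", 20_000), _hit("b", "s1", 1_000)]}
    with pytest.raises(ValueError, match="sorted"):
        pair_adjacent(hits, {"a": ("chr1", 0), "b": ("chr1", 100)})


def _pairs(scaffold, chrom_counts, orientations=None):
    out = []
    i = 0
    for chrom, n in chrom_counts.items():
        for j in range(n):
            o = "+" if orientations is None else orientations[i]
            out.append(
                MarkerPair(scaffold, f"m{i}", f"m{i}b", 10, chrom, 10,
                           1e6 + 1000 * i, o)
            )
            i += 1
    return out


def test_assign_majority_chromosome():
    a = assign_chromosome("s1", _pairs("s1", {"chr1A": 7, "chr1B": 3}))
    assert a.assigned_chrom == "chr1A"
    assert a.support_fraction == pytest.approx(0.7)


def test_assign_tie_goes_to_chrun():
    a = assign_chromosome("s1", _pairs("s1", {"chr1A": 5, "chr1B": 5}))
    assert a.assigned_chrom == "chrUn"


def test_assign_zero_pairs_is_chrun_not_error():
    a = assign_chromosome("s1", [])
    assert a.assigned_chrom == "chrUn" and a.n_valid_pairs == 0


def test_orientation_majority_and_tie():
    a = assign_chromosome("s1", _pairs("s1", {"c": 3}, ["+", "+", "-"]))
    assert a.orientation == "+" and a.orientation_votes == (2, 1)
    b = assign_chromosome("s1", _pairs("s1", {"c": 4}, ["+", "+", "-", "-"]))
    assert b.orientation == "+"  # tie keeps assembly orientation


def test_order_by_median_and_tiebreaks():
    anchors = [
        assign_chromosome("A", [MarkerPair("A", "m", "n", 1, "c", 1, 5e6, "+")]),
        assign_chromosome("B", [MarkerPair("B", "m", "n", 1, "c", 1, 2e6, "+")]),
        assign_chromosome("C", [MarkerPair("C", "m", "n", 1, "c", 1, 2e6, "+")]),
    ]
    lengths = {"A": 60_000, "B": 40_000, "C": 50_000}
    layout = order_scaffolds(anchors, lengths, AnchorConfig(min_scaffold_len=30_000))
    # equal medians 2e6: longer scaffold (C) first
    assert [s for s, _ in layout.chrom_order["c"]] == ["C", "B", "A"]


def test_order_short_scaffolds_unplaced():
    anchors = [
        assign_chromosome("A", [MarkerPair("A", "m", "n", 1, "c", 1, 1e6, "+")]),
    ]
    layout = order_scaffolds(anchors, {"A": 10_000}, AnchorConfig())
    assert layout.unplaced == ["A"] and not layout.chrom_order


def test_order_duplicate_scaffold_errors():
    a = assign_chromosome("A", [MarkerPair("A", "m", "n", 1, "c", 1, 1e6, "+")])
    with pytest.raises(ValueError, match="duplicate"):
        order_scaffolds([a, a], {"A": 50_000})


def test_build_pseudomolecule_lengths_and_gaps(rng):
    scaffolds = {"s1": random_dna(rng, 1_000), "s2": random_dna(rng, 1_000)}
    layout = PseudomoleculeLayout(chrom_order={"chr1": [("s1", "+"), ("s2", "+")]})
    records, rows = build_pseudomolecule(layout, scaffolds)
    assert len(records[0]) == 2_100
    assert records[0].sequence[1_000:1_100] == "N" * 100
    # conservation: total length - gap bases == placed scaffold bases
    assert len(records[0]) - 100 == sum(map(len, scaffolds.values()))


def test_build_single_minus_scaffold_is_revcomp(rng):
    seq = random_dna(rng, 800)
    layout = PseudomoleculeLayout(chrom_order={"chr1": [("s1", "-")]})
    records, _ = build_pseudomolecule(layout, {"s1": seq})
    assert records[0].sequence == reverse_complement(seq)


def test_build_missing_sequence_errors():
    layout = PseudomoleculeLayout(chrom_order={"chr1": [("ghost", "+")]})
    with pytest.raises(KeyError, match="ghost"):
        build_pseudomolecule(layout, {})


def test_snap_break_nearest_gap_and_tie():
    gaps = [(5_000, 5_100), (20_000, 20_100)]
    assert snap_break_to_gap(gaps, 4_990) == (5_000, 5_100)
    # equidistant from midpoints 5050 and 20050 -> lower coordinate
    assert snap_break_to_gap(gaps, 12_550) == (5_000, 5_100)
    with pytest.raises(ValueError):
        snap_break_to_gap([], 10)


def test_split_at_gap_conserves_bases(rng):
    seq = random_dna(rng, 3_000) + "N" * 100 + random_dna(rng, 2_000)
    left, right = split_scaffold_at_gap(seq, (3_000, 3_100))
    assert len(left) + len(right) == len(seq) - 100


def test_robust_to_isolated_mismapped_hits(small_panel):
    """Injecting bogus single hits changes no assignment: the adjacency
    pairing filter drops pairs straddling a mis-mapped marker."""
    rng = np.random.default_rng(0)
    hits = {
        "s1": [_hit(f"m{i}", "s1", 2_000 * i) for i in range(20)],
    }
    source = {f"m{i}": ("chr2B", 1_000_000 + 2_000 * i) for i in range(20)}
    base = assign_chromosome("s1", pair_adjacent(hits, source))
    # replace 2 of 20 hits (10%) with hits whose source is a far locus
    noisy_source = dict(source)
    for i in (5, 13):
        noisy_source[f"m{i}"] = ("chr7D", int(rng.integers(0, 5_000_000)))
    noisy = assign_chromosome("s1", pair_adjacent(hits, noisy_source))
    assert noisy.assigned_chrom == base.assigned_chrom == "chr2B"
    assert noisy.orientation == base.orientation


def test_raising_max_pair_gap_is_monotone():
    hits = {"s1": [_hit(f"m{i}", "s1", 17_000 * i) for i in range(10)]}
    source = {f"m{i}": ("c", 40_000 * i) for i in range(10)}
    n = [
        len(pair_adjacent(hits, source, AnchorConfig(max_pair_gap=g)))
        for g in (20_000, 45_000, 80_000)
    ]
    assert n == sorted(n)
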