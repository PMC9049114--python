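import numpy as np
import pytest

from conftest import random_dna
from oracles import naive_presence_bits

from triticolor.haplotyping import (
    ColoredKmerIndex,
    HaploBlock,
    HaploConfig,
    PresenceProfile,
    build_colored_index,
    classify_block,
    extract_query_markers,
    locus_haplotypes,
    merge_to_superblocks,
    query_presence,
    top_profiles,
)
from triticolor.io import GenomicInterval, reverse_complement


@pytest.fixture(scope="module")
def toy_cfg():
    return HaploConfig(k=4, marker_len=10, spacing=10, e=0.95)


def test_index_hand_enumerated_kmer_count(toy_cfg):
    # ACGTACGTAC: 7 windows, distinct canonical {ACGT, CGTA, GTAC}
    index = build_colored_index({"a": "ACGTACGTAC", "b": "ACGTACGTAC"}, toy_cfg)
    assert len(index) == 3


def test_identical_sequences_share_every_kmer(toy_cfg):
    index = build_colored_index({"a": "ACGTACGTAC", "b": "ACGTACGTAC"}, toy_cfg)
    assert all(int(m) == 0b11 for m in index.masks)


def test_private_kmer_gets_single_colour(toy_cfg):
    index = build_colored_index({"a": "AAAAAAAA", "b": "AAAATTTT"}, toy_cfg)
    # TTTT canonicalises to AAAA; ATTT/TTTA etc. are b-private
    masks = {int(k): int(m) for k, m in zip(index.kmers, index.masks)}
    assert 0b01 in masks.values() or 0b10 in masks.values()
    bit_a = index.colour_bit("a")
    assert any(m == (1 << (1 - bit_a)) for m in masks.values())


def test_index_requires_two_cultivars(toy_cfg):
    with pytest.raises(ValueError):
        build_colored_index({"a": "ACGTACGT"}, toy_cfg)


def test_index_serialisation_roundtrip(tmp_path, toy_cfg):
    index = build_colored_index({"a": "ACGTACGTAC", "b": "TTTACGTACG"}, toy_cfg)
    p = tmp_path / "idx.bin"
    index.save(p)
    back = ColoredKmerIndex.load(p)
    assert back.k == index.k and back.colours == index.colours
    assert np.array_equal(back.kmers, index.kmers)
    assert np.array_equal(back.masks, index.masks)


def test_marker_grid_examples(rng):
    cfg = HaploConfig(marker_len=1_000, spacing=20_000)
    seq = random_dna(rng, 100_000)
    markers = extract_query_markers(seq, cfg)
    assert [m[0].start for m in markers] == [0, 20_000, 40_000, 60_000, 80_000]
    assert extract_query_markers(random_dna(rng, 900), cfg) == []
    # an all-N window is skipped
    seq2 = "N" * 1_000 + seq[: 40_000]
    starts = [m[0].start for m in extract_query_markers(seq2, cfg)]
    assert 0 not in starts


def test_presence_threshold_is_inclusive_ratio(rng):
    cfg = HaploConfig()
    a = random_dna(rng, 5_000)
    b = random_dna(rng, 5_000)
    index = build_colored_index({"a": a, "b": b}, cfg)
    marker = a[1_000:2_000]
    profile = query_presence(marker, index, cfg)
    assert profile.bits & (1 << index.colour_bit("a"))
    assert not profile.bits & (1 << index.colour_bit("b"))


def test_single_snp_keeps_presence_two_spread_snps_lose_it(rng):
    """Worst-case window counting at e=0.95, k=31, 1-kb marker: one SNP
    kills at most 31 of 970 k-mers (ratio >= 0.968), two SNPs >= 31 bp
    apart kill 62 (ratio ~ 0.936)."""
    cfg = HaploConfig()
    a = random_dna(rng, 5_000)
    b = random_dna(rng, 5_000)
    index = build_colored_index({"a": a, "b": b}, cfg)
    marker = list(a[1_000:2_000])
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    marker[500] = flip[marker[500]]
    one_snp = query_presence("".join(marker), index, cfg)
    assert one_snp.bits & (1 << index.colour_bit("a"))
    marker[100] = flip[marker[100]]  # 400 bp away from the other SNP
    two_snps = query_presence("".join(marker), index, cfg)
    assert not two_snps.bits & (1 << index.colour_bit("a"))


def test_presence_monotone_in_e(rng):
    cfg = HaploConfig()
    panel = {f"c{i}": random_dna(rng, 4_000) for i in range(4)}
    index = build_colored_index(panel, cfg)
    from triticolor.synthetic import mutate_sequence

    marker = mutate_sequence(panel["c1"][500:1_500], 0.002, 3)
    prev_bits = None
    for e in (1.0, 0.95, 0.9, 0.8):
        bits = query_presence(marker, index, HaploConfig(e=e)).bits
        if prev_bits is not None:
            assert bits & prev_bits == prev_bits  # lowering e never clears a bit
        prev_bits = bits


def test_strand_invariance_of_profiles(rng):
    cfg = HaploConfig()
    panel = {f"c{i}": random_dna(rng, 4_000) for i in range(3)}
    index = build_colored_index(panel, cfg)
    flipped = dict(panel)
    flipped["c1"] = reverse_complement(panel["c1"])
    index2 = build_colored_index(flipped, cfg)
    for marker in (panel["c0"][0:1_000], panel["c1"][2_000:3_000]):
        assert (
            query_presence(marker, index, cfg).bits
            == query_presence(marker, index2, cfg).bits
        )


def test_query_presence_matches_index_free_oracle(rng):
    cfg = HaploConfig(k=15, marker_len=200, spacing=200, e=0.95)
    panel = {f"c{i}": random_dna(rng, 3_000) for i in range(5)}
    index = build_colored_index(panel, cfg)
    from triticolor.synthetic import mutate_sequence

    for trial in range(30):
        src = panel[f"c{trial % 5}"]
        start = 100 * trial % 2_000
        marker = mutate_sequence(src[start : start + 200], 0.005, trial)
        got = query_presence(marker, index, cfg).bits
        expect = naive_presence_bits(marker, panel, cfg.k, cfg.e)
        assert got == expect


def test_top_profiles_ranking_and_ties():
    cfg = HaploConfig(top_n=2)
    profiles = (
        [PresenceProfile.from_bits(0b111)] * 5
        + [PresenceProfile.from_bits(0b101)] * 3
        + [PresenceProfile.from_bits(0b011)] * 3
        + [PresenceProfile.from_bits(0b1)] * 1
    )
    palette = top_profiles(profiles, cfg)
    # tie at count 3: lower bit value (0b011) enters
    assert palette == [0b111, 0b011]


def test_classify_precedence():
    cfg = HaploConfig(grey_min_share=10, black_share=1)
    palette = [0b1111]
    assert classify_block(PresenceProfile.from_bits(1 << 3), palette, cfg)[0] == "black"
    grey = PresenceProfile.from_bits((1 << 10) - 1)  # 10 cultivars
    assert classify_block(grey, palette, cfg)[0] == "grey"
    col = PresenceProfile.from_bits(0b1111)
    assert classify_block(col, palette, cfg) == ("coloured", 1)
    white = PresenceProfile.from_bits(0b0111)
    assert classify_block(white, palette, cfg)[0] == "white"
    assert classify_block(None, palette, cfg)[0] == "white"


def _block(start, bits, spacing=20_000):
    profile = PresenceProfile.from_bits(bits) if bits is not None else None
    return HaploBlock("c", GenomicInterval("c", start, start + spacing), profile)


def test_merge_modal_and_ties():
    cfg = HaploConfig(merge_window=1_000_000)
    blocks = [_block(i * 20_000, 0b1 if i < 30 else 0b11) for i in range(50)]
    merged = merge_to_superblocks(blocks, cfg)
    assert len(merged) == 1 and merged[0].profile.bits == 0b1
    # 25/25 tie -> leftmost member's profile
    blocks = [_block(i * 20_000, 0b1 if i % 2 else 0b11) for i in range(50)]
    merged = merge_to_superblocks(blocks, cfg)
    assert merged[0].profile.bits == 0b11  # block 0 has 0b11
    # trailing partial tile
    blocks = [_block(i * 20_000, 0b111) for i in range(60)]
    merged = merge_to_superblocks(blocks, cfg)
    assert len(merged) == 2 and merged[1].profile.bits == 0b111


def test_locus_mode_shared_and_missing_and_inverted(rng):
    region = random_dna(rng, 30_000)
    backbone = {f"c{i}": random_dna(rng, 80_000) for i in range(4)}
    panel = dict(backbone)
    panel["c0"] = backbone["c0"][:20_000] + region + backbone["c0"][20_000:]
    panel["c1"] = backbone["c1"][:40_000] + region + backbone["c1"][40_000:]
    panel["c2"] = (
        backbone["c2"][:10_000] + reverse_complement(region) + backbone["c2"][10_000:]
    )
    # c3 lacks the region entirely
    cfg = HaploConfig.locus()
    tracks, loc = locus_haplotypes(region, panel, cfg)
    assert loc["c3"] is None and tracks["c3"] is None
    assert loc["c0"] is not None and loc["c1"] is not None
    assert loc["c2"][3] == "-"
    bits_c0 = [b.profile.bits for b in tracks["c0"] if b.profile]
    bits_c1 = [b.profile.bits for b in tracks["c1"] if b.profile]
    bits_c2 = [b.profile.bits for b in tracks["c2"] if b.profile]
    # the three carriers share one profile across the locus
    assert bits_c0 == bits_c1 == bits_c2
    assert all(bin(b).count("1") == 3 for b in bits_c0)
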