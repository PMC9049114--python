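import numpy as np
import pytest

from triticolor.io import reverse_complement
from triticolor.synthetic import (
    PanelConfig,
    compose_cultivars,
    decode_genome,
    emit_exon_set,
    fragment_assembly,
    generate_panel,
    simulate_donor_alignments,
    simulate_founders,
)


def _mismatch_fraction(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def test_zero_divergence_founders_identical():
    cfg = PanelConfig(chrom_len=50_000, founder_divergence=0.0, n_founders=3, seed=1)
    base, founders, _ = simulate_founders(cfg)
    for f in founders:
        assert np.array_equal(f["chr1A"], base["chr1A"])


def test_founder_pairwise_divergence_matches_expectation(small_panel):
    # two founders each mutated i.i.d. at p: mismatch fraction ~ 2p(1-p)
    cfg = small_panel["cfg"]
    f0 = small_panel["founders"][0]["chr1A"]
    f1 = small_panel["founders"][1]["chr1A"]
    p = cfg.founder_divergence
    expect = 2 * p * (1 - p)
    n = f0.size
    sd = np.sqrt(expect * (1 - expect) / n)
    assert abs(_mismatch_fraction(f0, f1) - expect) < 3 * sd + 2 * p * p


def test_same_seed_is_byte_identical():
    cfg = PanelConfig(chrom_len=60_000, seed=9)
    a = generate_panel(cfg)
    b = generate_panel(cfg)
    assert np.array_equal(a[0]["chr1A"], b[0]["chr1A"])
    for cv in cfg.cultivar_names:
        assert np.array_equal(a[2][cv]["chr1A"], b[2][cv]["chr1A"])


def test_te_density_cap_rejected():
    with pytest.raises(ValueError, match="te_density"):
        PanelConfig(te_density=0.95)


def test_mosaic_truth_tiles_and_shared_founder_means_identity(small_panel):
    truth = small_panel["truth"]
    cfg = small_panel["cfg"]
    truth.check_tiling(cfg.chrom_len)
    cultivars = small_panel["cultivars"]
    # find a position where two cultivars share a founder -> identical bases
    names = cfg.cultivar_names
    checked = 0
    for pos in range(0, cfg.chrom_len, 7_000):
        f = [truth.founder_at(cv, "chr1A", pos) for cv in names]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if f[i] == f[j]:
                    assert (
                        cultivars[names[i]]["chr1A"][pos]
                        == cultivars[names[j]]["chr1A"][pos]
                    )
                    checked += 1
    assert checked > 50


def test_introgression_divergence_matches_donor_rate():
    cfg = PanelConfig(
        chrom_len=300_000,
        seed=21,
        introgressions=[(("cv02",), "chr1A", 50_000, 100_000)],
    )
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    span = slice(50_000, 150_000)
    frac = _mismatch_fraction(cultivars["cv02"]["chr1A"][span], base["chr1A"][span])
    p = cfg.donor_divergence
    sd = np.sqrt(p * (1 - p) / 100_000)
    assert abs(frac - p) < 3 * sd


def test_overlapping_planted_features_error():
    cfg = PanelConfig(
        chrom_len=100_000,
        seed=2,
        introgressions=[
            (("cv01",), "chr1A", 10_000, 20_000),
            (("cv01",), "chr1A", 25_000, 20_000),
        ],
    )
    base, founders, _ = simulate_founders(cfg)
    with pytest.raises(ValueError, match="overlap"):
        compose_cultivars(base, founders, {}, cfg)


def test_inversion_reverse_complements_span():
    cfg = PanelConfig(
        chrom_len=100_000, seed=4, inversions=[(("cv01",), "chr1A", 20_000, 30_000)]
    )
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    cfg_plain = PanelConfig(chrom_len=100_000, seed=4)
    _, _, plain, _, _ = generate_panel(cfg_plain)
    inv = decode_genome(cultivars["cv01"])["chr1A"][20_000:50_000]
    orig = decode_genome(plain["cv01"])["chr1A"][20_000:50_000]
    assert inv == reverse_complement(orig)


def test_fragment_assembly_is_invertible(small_panel):
    cfg = small_panel["cfg"]
    genome = small_panel["cultivars"]["cv05"]
    scaffolds, layout = fragment_assembly(genome, cfg, n_pieces=12, min_piece_len=5_000)
    seqs = {r.id: r.sequence for r in scaffolds}
    by_rank = sorted(layout.items(), key=lambda kv: kv[1][4])
    parts = []
    for name, (chrom, start, end, orientation, rank) in by_rank:
        s = seqs[name]
        parts.append(reverse_complement(s) if orientation == "-" else s)
    assert "".join(parts) == decode_genome(genome)["chr1A"]


def test_fragment_assembly_zero_breakpoints(small_panel):
    cfg = small_panel["cfg"]
    genome = small_panel["cultivars"]["cv02"]
    scaffolds, layout = fragment_assembly(genome, cfg, n_pieces=1)
    assert len(scaffolds) == 1
    chrom, start, end, orientation, rank = layout[scaffolds[0].id]
    expect = decode_genome(genome)["chr1A"]
    got = scaffolds[0].sequence
    assert got == expect or reverse_complement(got) == expect


def test_fragment_orientation_flips_are_balanced():
    cfg = PanelConfig(chrom_len=400_000, seed=17)
    base, *_ = simulate_founders(cfg)
    scaffolds, layout = fragment_assembly(base, cfg, n_pieces=200, min_piece_len=500)
    minus = sum(1 for v in layout.values() if v[3] == "-")
    # binomial(200, 0.5), 3-sigma band
    assert abs(minus - 100) < 3 * np.sqrt(200 * 0.25)


def test_donor_alignments_background_zero_inside_only():
    spans = {"chr1A": [(10_000, 30_000)]}
    reads = simulate_donor_alignments(
        spans, {"chr1A": 100_000}, depth_in=5, depth_bg=0.0, seed=8
    )
    assert reads
    assert all(10_000 <= r.start and r.start < 30_000 for r in reads)


def test_donor_alignment_depth_and_mapq_fractions():
    spans = {"chr1A": [(0, 200_000)]}
    reads = simulate_donor_alignments(
        spans, {"chr1A": 200_000}, depth_in=10, depth_bg=0,
        read_len=150, seed=8, low_mapq_frac=0.2,
    )
    n = len(reads)
    expect_n = 10 * 200_000 / 150
    assert abs(n - expect_n) < 3 * np.sqrt(expect_n)  # Poisson band
    low = sum(1 for r in reads if r.attrs["mapq"] < 10)
    assert abs(low - 0.2 * n) < 3 * np.sqrt(n * 0.2 * 0.8)


def test_exon_set_classes_and_purity(small_panel):
    genome = small_panel["ref"]
    truth = small_panel["truth"]
    exons, target, ledger = emit_exon_set(
        genome, truth.te_intervals, n_exons=100, del_fraction=0.04,
        mut_fraction=0.0, seed=6,
    )
    assert all(len(e) >= 31 and "N" not in e.sequence for e in exons)
    classes = [row[4] for row in ledger]
    assert classes.count("deleted") == 4  # exact planted count
    assert classes.count("intact") == 96
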