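"""Haplotype-block painting with a coloured canonical k-mer index.

Each cultivar of a panel is a "colour". A membership table of canonical
31-mers (the lexicographic minimum of a k-mer and its reverse
complement) replaces the full coloured de Bruijn graph: the queries only
need per-colour presence ratios, never graph topology, so the table has
identical query semantics at a fraction of the machinery.

Painting: 1-kb markers are taken every 20 kb (5 kb in locus mode) along
a chromosome and queried against the index; a cultivar is "present" for
a marker when at least a fraction ``e`` (0.95; 0.97 in locus mode) of
the marker's k-mers occur in that cultivar. The resulting
presence/absence profiles are summarised per chromosome by the 15 most
abundant profiles (the palette), merged into 1-Mb superblocks by
majority, and classified: cultivar-specific (black), shared by >= 10
cultivars (grey), palette (coloured), otherwise white.
"""

from __future__ import annotations

import struct
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import GenomicInterval, reverse_complement
from .kmers import canonical_codes, canonical_kmer_set, kmer_codes


@dataclass
class HaploConfig:
    k: int = 31
    marker_len: int = 1_000
    spacing: int = 20_000
    e: float = 0.95
    top_n: int = 15
    merge_window: int = 1_000_000
    grey_min_share: int = 10
    black_share: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.e <= 1:
            raise ValueError("e must be in (0, 1]")
        if self.marker_len <= self.k:
            raise ValueError("marker_len must exceed k")
        if self.spacing < self.marker_len:
            raise ValueError("spacing must be >= marker_len")

    @classmethod
    def locus(cls, **overrides) -> "HaploConfig":
        """Locus-scale preset: 1-kb markers every 5 kb, e = 0.97."""
        base = dict(spacing=5_000, e=0.97, merge_window=5_000)
        base.update(overrides)
        return cls(**base)


@dataclass
class PresenceProfile:
    bits: int
    popcount: int

    @classmethod
    def from_bits(cls, bits: int) -> "PresenceProfile":
        return cls(bits, bin(bits).count("1"))


@dataclass
class HaploBlock:
    chrom: str
    span: GenomicInterval
    profile: Optional[PresenceProfile]
    cls: str = ""  # black | grey | coloured | white
    palette_rank: Optional[int] = None


class ColoredKmerIndex:
    """Canonical k-mer -> colour bitset over up to 64 cultivars."""

    MAGIC = b"TCKI"

    def __init__(self, k: int, colours: Sequence[str], kmers: np.ndarray, masks: np.ndarray):
        self.k = k
        self.colours = list(colours)
        self.kmers = kmers  # sorted unique canonical codes, uint64
        self.masks = masks  # parallel colour bitsets, uint64

    def __len__(self) -> int:
        return self.kmers.size

    def colour_bit(self, name: str) -> int:
        return self.colours.index(name)

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Colour bitset per query code (0 for absent k-mers)."""
        out = np.zeros(codes.size, dtype=np.uint64)
        if self.kmers.size == 0:
            return out
        idx = np.searchsorted(self.kmers, codes)
        idx[idx >= self.kmers.size] = self.kmers.size - 1
        found = self.kmers[idx] == codes
        out[found] = self.masks[idx[found]]
        return out

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.MAGIC)
            fh.write(struct.pack("<BH", self.k, len(self.colours)))
            for name in self.colours:
                raw = name.encode("utf-8")
                fh.write(struct.pack("<H", len(raw)))
                fh.write(raw)
            fh.write(struct.pack("<Q", self.kmers.size))
            fh.write(self.kmers.astype("<u8").tobytes())
            fh.write(self.masks.astype("<u8").tobytes())

    @classmethod
    def load(cls, path) -> "ColoredKmerIndex":
        with open(path, "rb") as fh:
            if fh.read(4) != cls.MAGIC:
                raise ValueError("not a coloured k-mer index file")
            k, n_col = struct.unpack("<BH", fh.read(3))
            colours = []
            for _ in range(n_col):
                (ln,) = struct.unpack("<H", fh.read(2))
                colours.append(fh.read(ln).decode("utf-8"))
            (n_kmers,) = struct.unpack("<Q", fh.read(8))
            kmers = np.frombuffer(fh.read(8 * n_kmers), dtype="<u8").astype(np.uint64)
            masks = np.frombuffer(fh.read(8 * n_kmers), dtype="<u8").astype(np.uint64)
        return cls(k, colours, kmers, masks)


def build_colored_index(
    sequences: dict[str, str], cfg: HaploConfig | None = None
) -> ColoredKmerIndex:
    """Index one chromosome across cultivars: colour bit c is set for a
    canonical k-mer iff cultivar c's sequence contains it on either
    strand."""
    cfg = cfg or HaploConfig()
    if len(sequences) < 2:
        raise ValueError("need at least two cultivars")
    if len(sequences) > 64:
        raise ValueError("at most 64 colours supported")
    colours = list(sequences)
    codes_parts = []
    masks_parts = []
    for ci, name in enumerate(colours):
        seq = sequences[name]
        if len(seq) < cfg.k:
            raise ValueError(f"sequence {name!r} shorter than k")
        u = canonical_kmer_set(seq, cfg.k)
        codes_parts.append(u)
        masks_parts.append(np.full(u.size, np.uint64(1) << np.uint64(ci), dtype=np.uint64))
    codes = np.concatenate(codes_parts)
    masks = np.concatenate(masks_parts)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    masks = masks[order]
    boundary = np.empty(codes.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = codes[1:] != codes[:-1]
    starts = np.nonzero(boundary)[0]
    merged = np.bitwise_or.reduceat(masks, starts)
    return ColoredKmerIndex(cfg.k, colours, codes[starts], merged)


def extract_query_markers(
    sequence: str, cfg: HaploConfig | None = None
) -> list[tuple[GenomicInterval, str]]:
    """Fixed-length markers on a regular grid anchored at offset 0.

    A marker is emitted only when its window lies fully inside the
    chromosome; windows that are >= 50% N are skipped.
    """
    cfg = cfg or HaploConfig()
    out = []
    pos = 0
    n = len(sequence)
    while pos + cfg.marker_len <= n:
        window = sequence[pos : pos + cfg.marker_len]
        if window.count("N") < cfg.marker_len / 2:
            out.append((GenomicInterval("", pos, pos + cfg.marker_len), window))
        pos += cfg.spacing
    return out


def query_presence(
    marker_seq: str, index: ColoredKmerIndex, cfg: HaploConfig | None = None
) -> Optional[PresenceProfile]:
    """Presence bitset of a marker: colour bit set iff the fraction of
    the marker's N-free k-mers found with that colour is >= e.

    Returns None when the marker has no valid k-mers.
    """
    cfg = cfg or HaploConfig()
    codes, _ = kmer_codes(marker_seq, index.k)
    if codes.size == 0:
        return None
    canon = canonical_codes(codes, index.k)
    masks = index.lookup(canon)
    m = codes.size
    bits = 0
    threshold = cfg.e * m
    for ci in range(len(index.colours)):
        hit = ((masks >> np.uint64(ci)) & np.uint64(1)).sum()
        if hit >= threshold:
            bits |= 1 << ci
    return PresenceProfile.from_bits(bits)


def top_profiles(
    profiles: Sequence[Optional[PresenceProfile]], cfg: HaploConfig | None = None
) -> list[int]:
    """The top_n most abundant profiles (by marker count, ties broken by
    ascending bit value), as bit values."""
    cfg = cfg or HaploConfig()
    counts = Counter(p.bits for p in profiles if p is not None)
    if not counts:
        return []
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [bits for bits, _ in ranked[: cfg.top_n]]


def classify_block(
    profile: Optional[PresenceProfile],
    palette: Sequence[int],
    cfg: HaploConfig | None = None,
) -> tuple[str, Optional[int]]:
    """(class, palette rank). Precedence: black, grey, coloured, white."""
    cfg = cfg or HaploConfig()
    if profile is None:
        return "white", None
    if profile.popcount == cfg.black_share:
        return "black", None
    if profile.popcount >= cfg.grey_min_share:
        return "grey", None
    if profile.bits in palette:
        return "coloured", list(palette).index(profile.bits) + 1
    return "white", None


def merge_to_superblocks(
    blocks: Sequence[HaploBlock], cfg: HaploConfig | None = None
) -> list[HaploBlock]:
    """Merge marker-grid blocks into merge_window tiles; each tile takes
    the modal profile of its members (ties -> leftmost member's value).
    The trailing partial tile uses whatever members it has."""
    cfg = cfg or HaploConfig()
    if not blocks:
        return []
    chrom = blocks[0].chrom
    end = max(b.span.end for b in blocks)
    out: list[HaploBlock] = []
    tile_start = 0
    while tile_start < end:
        tile_end = min(tile_start + cfg.merge_window, end)
        members = [b for b in blocks if tile_start <= b.span.start < tile_end]
        if members:
            counts = Counter(
                b.profile.bits if b.profile is not None else None for b in members
            )
            best_count = max(counts.values())
            modal = next(
                b.profile.bits if b.profile is not None else None
                for b in members
                if counts[b.profile.bits if b.profile is not None else None]
                == best_count
            )
            profile = PresenceProfile.from_bits(modal) if modal is not None else None
        else:
            profile = None
        out.append(
            HaploBlock(chrom, GenomicInterval(chrom or ".", tile_start, tile_end)
                       if chrom else GenomicInterval(".", tile_start, tile_end),
                       profile)
        )
        tile_start += cfg.merge_window
    return out


# ---------------------------------------------------------------------------
# chromosome-scale pipeline

@dataclass
class PaintResult:
    palette: list[int]
    marker_blocks: dict[str, list[HaploBlock]] = field(default_factory=dict)
    superblocks: dict[str, list[HaploBlock]] = field(default_factory=dict)


def paint_panel(
    sequences: dict[str, str],
    cfg: HaploConfig | None = None,
    chrom: str = "",
) -> PaintResult:
    """Paint one chromosome across a cultivar panel.

    Builds the coloured index, queries every cultivar's marker grid,
    derives the chromosome-wide palette from the pooled profiles, then
    classifies marker blocks and 1-Mb superblocks per cultivar.
    """
    cfg = cfg or HaploConfig()
    index = build_colored_index(sequences, cfg)
    per_cv_profiles: dict[str, list[tuple[GenomicInterval, Optional[PresenceProfile]]]] = {}
    pooled: list[Optional[PresenceProfile]] = []
    for name, seq in sequences.items():
        rows = []
        for span, mseq in extract_query_markers(seq, cfg):
            profile = query_presence(mseq, index, cfg)
            rows.append((span, profile))
            pooled.append(profile)
        per_cv_profiles[name] = rows
    palette = top_profiles(pooled, cfg)
    result = PaintResult(palette=palette)
    for name, rows in per_cv_profiles.items():
        seq_len = len(sequences[name])
        blocks = []
        for span, profile in rows:
            bin_start = span.start
            bin_end = min(bin_start + cfg.spacing, seq_len)
            block = HaploBlock(
                chrom, GenomicInterval(chrom or name, bin_start, bin_end), profile
            )
            block.cls, block.palette_rank = classify_block(profile, palette, cfg)
            blocks.append(block)
        supers = merge_to_superblocks(blocks, cfg)
        for sb in supers:
            sb.cls, sb.palette_rank = classify_block(sb.profile, palette, cfg)
        result.marker_blocks[name] = blocks
        result.superblocks[name] = supers
    return result


# ---------------------------------------------------------------------------
# locus mode

def locus_haplotypes(
    region_seq: str,
    panel: dict[str, str],
    cfg: HaploConfig | None = None,
    min_probe_support: float = 0.5,
):
    """Locus-scale painting: localise a region in every panel genome by
    probe mapping, then paint the localised regions at 5-kb resolution.

    Returns ``(tracks, localisations)``; *tracks* maps cultivar ->
    list of HaploBlock (None when the region was not localised) and
    *localisations* maps cultivar -> (chrom, start, end, strand) or None.
    """
    from .markers import MapConfig, TargetIndex, search

    cfg = cfg or HaploConfig.locus()
    if len(region_seq) < 10_000:
        raise ValueError("locus mode needs a region of at least 10 kb")
    probes = extract_query_markers(region_seq, cfg)
    map_cfg = MapConfig(min_identity=0.90, min_coverage=0.90)
    localisations: dict[str, Optional[tuple]] = {}
    extracted: dict[str, str] = {}
    for name, seq in panel.items():
        index = TargetIndex({name: seq}, map_cfg.seed_len)
        placements = []
        for _, probe in probes:
            hits = search(probe, index, map_cfg)
            if hits:
                placements.append(hits[0])
        if len(placements) < min_probe_support * len(probes):
            localisations[name] = None
            continue
        strand = Counter(h.strand for h in placements).most_common(1)[0][0]
        centers = np.array([h.target_start for h in placements])
        center = np.median(centers)
        inliers = [
            h for h in placements if abs(h.target_start - center) <= 2 * len(region_seq)
        ]
        start = min(h.target_start for h in inliers)
        end = max(h.target_end for h in inliers)
        localisations[name] = (name, start, end, strand)
        sub = seq[start:end]
        extracted[name] = reverse_complement(sub) if strand == "-" else sub
    tracks: dict[str, Optional[list[HaploBlock]]] = {n: None for n in panel}
    if len(extracted) >= 2:
        index = build_colored_index(extracted, cfg)
        for name, sub in extracted.items():
            blocks = []
            for span, mseq in extract_query_markers(sub, cfg):
                profile = query_presence(mseq, index, cfg)
                block = HaploBlock(name, span, profile)
                blocks.append(block)
            tracks[name] = blocks
    return tracks, localisations
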