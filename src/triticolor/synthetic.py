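"""Synthetic cultivar panels with known truth.

The generator emulates the statistical structure a repeat-rich polyploid
panel presents to the downstream stages:

* a TE-rich base chromosome in which repeat *bodies* recur genome-wide
  (drawn from a small shared library, ~1% internal divergence between
  copies) while the junction flanks between insertions are unique — the
  property junction-marker design relies on;
* a set of founder haplotypes derived from the base by i.i.d.
  substitution at ``founder_divergence`` (0.7% by default, the
  exon-space divergence observed between hexaploid wheat cultivars);
* cultivars built as mosaics of founder segments with exponential
  segment lengths, optionally carrying introgressions from a more
  divergent donor genome, large inversions and a translocation;
* scaffold sets produced by fragmenting a genome at random breakpoints
  with shuffled order and random orientation;
* donor-read coverage tracks and exon sets with planted deletions and
  mutations.

Divergence is substitution-only so that marker and k-mer arithmetic has
closed-form expectations; indels enter only through explicit structural
features. Every output is a pure function of the config (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GenomicInterval, SeqRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    out = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (out == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


def mutate_array(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at *rate*; each hit moves to one of the other
    three bases uniformly."""
    out = arr.copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
    return out


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """String-level convenience wrapper around :func:`mutate_array`."""
    rng = np.random.default_rng(seed)
    return _decode(mutate_array(_encode(seq), rate, rng))


@dataclass
class PanelConfig:
    n_cultivars: int = 11
    chrom_names: Sequence[str] = ("chr1A",)
    chrom_len: int = 2_000_000
    n_founders: int = 6
    founder_divergence: float = 0.007
    segment_len_mean: int = 200_000
    donor_divergence: float = 0.03
    # (cultivar names, chrom, start, length)
    introgressions: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    # (cultivar, src_chrom, src_start, src_len, dest_chrom, dest_pos)
    translocation: Optional[tuple] = None
    te_density: float = 0.5
    te_body_lengths: tuple[int, int] = (500, 5_000)
    te_library_size: int = 20
    te_internal_divergence: float = 0.01
    scaffold_len_mean: int = 50_000
    founder_weights: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.founder_divergence <= 0.1:
            raise ValueError("founder_divergence must be in [0, 0.1]")
        if not 0 <= self.donor_divergence <= 0.1:
            raise ValueError("donor_divergence must be in [0, 0.1]")
        if self.te_density >= 0.9:
            raise ValueError(
                "te_density >= 0.9 leaves too little unique junction flank"
            )
        for feats in (self.introgressions, self.inversions):
            for _, chrom, start, length in feats:
                if chrom not in self.chrom_names:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if not (0 <= start and start + length <= self.chrom_len):
                    raise ValueError("planted feature outside chromosome")

    @property
    def cultivar_names(self) -> list[str]:
        return [f"cv{i + 1:02d}" for i in range(self.n_cultivars)]

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("introgressions", "inversions"):
            if key in data:
                data[key] = [tuple(x) for x in data[key]]
        if data.get("translocation"):
            data["translocation"] = tuple(data["translocation"])
        return cls(**data)


@dataclass
class PanelTruth:
    """Machine-readable record of everything the generator planted."""

    # (cultivar, chrom) -> list of (start, end, founder index)
    mosaic: dict = field(default_factory=dict)
    # list of (cultivar, chrom, start, end)
    introgressions: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    translocations: list = field(default_factory=list)
    # chrom -> list of (start, end) on the shared base coordinates
    te_intervals: dict = field(default_factory=dict)
    # scaffold -> (source chrom, source start, source end, orientation, rank)
    scaffold_layout: dict = field(default_factory=dict)

    def check_tiling(self, chrom_len: int) -> None:
        for (cv, chrom), spans in self.mosaic.items():
            pos = 0
            for start, end, _ in spans:
                if start != pos or end <= start:
                    raise AssertionError(
                        f"mosaic truth for {cv}/{chrom} does not tile at {pos}"
                    )
                pos = end
            if pos != chrom_len:
                raise AssertionError(f"mosaic truth for {cv}/{chrom} short: {pos}")

    def founder_at(self, cultivar: str, chrom: str, pos: int) -> int:
        for start, end, f in self.mosaic[(cultivar, chrom)]:
            if start <= pos < end:
                return f
        raise KeyError(f"position {pos} outside mosaic truth")


# ---------------------------------------------------------------------------
# founders

def simulate_founders(cfg: PanelConfig):
    """Base chromosome + founder haplotypes + TE intervals.

    Returns ``(base, founders, te_intervals)`` where *base* maps chrom ->
    uint8 array, *founders* is a list of such maps, and te_intervals maps
    chrom -> list of (start, end) spans of planted repeat bodies.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    lo, hi = cfg.te_body_lengths
    library = [
        rng.integers(0, 4, rng.integers(lo, hi + 1)).astype(np.uint8)
        for _ in range(cfg.te_library_size)
    ]
    base: dict[str, np.ndarray] = {}
    te_intervals: dict[str, list[tuple[int, int]]] = {}
    mean_body = (lo + hi) / 2
    # mean unique flank length that realises te_density
    mean_flank = max(200, int(mean_body * (1 - cfg.te_density) / cfg.te_density))
    for chrom in cfg.chrom_names:
        parts: list[np.ndarray] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        while pos < cfg.chrom_len:
            flank_len = max(100, int(rng.exponential(mean_flank)))
            parts.append(rng.integers(0, 4, flank_len).astype(np.uint8))
            pos += flank_len
            if pos >= cfg.chrom_len:
                break
            body = library[rng.integers(len(library))]
            body = mutate_array(body, cfg.te_internal_divergence, rng)
            if rng.random() < 0.5:
                body = (3 - body)[::-1]  # insert on the minus strand
            parts.append(body)
            spans.append((pos, min(pos + body.size, cfg.chrom_len)))
            pos += body.size
        seq = np.concatenate(parts)[: cfg.chrom_len]
        base[chrom] = seq
        te_intervals[chrom] = [(s, e) for s, e in spans if e <= cfg.chrom_len]
    founders = [
        {c: mutate_array(a, cfg.founder_divergence, rng) for c, a in base.items()}
        for _ in range(cfg.n_founders)
    ]
    return base, founders, te_intervals


# ---------------------------------------------------------------------------
# cultivars

def compose_cultivars(base, founders, te_intervals, cfg: PanelConfig):
    """Mosaic cultivars + donor genome + truth.

    Returns ``(cultivars, donor, truth)``; *cultivars* maps cultivar name
    -> chrom -> uint8 array and *donor* is the divergent donor genome on
    base coordinates.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    donor = {c: mutate_array(a, cfg.donor_divergence, rng) for c, a in base.items()}
    truth = PanelTruth(te_intervals=dict(te_intervals))
    weights = None
    if cfg.founder_weights is not None:
        weights = np.asarray(cfg.founder_weights, dtype=float)
        weights = weights / weights.sum()
    cultivars: dict[str, dict[str, np.ndarray]] = {}
    for cv in cfg.cultivar_names:
        genome: dict[str, np.ndarray] = {}
        for chrom in cfg.chrom_names:
            spans: list[tuple[int, int, int]] = []
            parts: list[np.ndarray] = []
            pos = 0
            while pos < cfg.chrom_len:
                seg = max(1_000, int(rng.exponential(cfg.segment_len_mean)))
                end = min(pos + seg, cfg.chrom_len)
                f = int(rng.choice(cfg.n_founders, p=weights))
                parts.append(founders[f][chrom][pos:end])
                spans.append((pos, end, f))
                pos = end
            genome[chrom] = np.concatenate(parts)
            truth.mosaic[(cv, chrom)] = spans
        cultivars[cv] = genome

    # planted features; overlap on one cultivar/chrom is an error
    planted: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def _claim(cv: str, chrom: str, start: int, end: int) -> None:
        for s, e in planted.setdefault((cv, chrom), []):
            if start < e and s < end:
                raise ValueError(
                    f"planted features overlap on {cv}/{chrom}: "
                    f"[{start},{end}) vs [{s},{e})"
                )
        planted[(cv, chrom)].append((start, end))

    for cvs, chrom, start, length in cfg.introgressions:
        for cv in cvs:
            _claim(cv, chrom, start, start + length)
            cultivars[cv][chrom][start : start + length] = donor[chrom][
                start : start + length
            ]
            truth.introgressions.append((cv, chrom, start, start + length))
    for cvs, chrom, start, length in cfg.inversions:
        for cv in cvs:
            _claim(cv, chrom, start, start + length)
            span = cultivars[cv][chrom][start : start + length]
            cultivars[cv][chrom][start : start + length] = (3 - span)[::-1]
            truth.inversions.append((cv, chrom, start, start + length))
    if cfg.translocation is not None:
        cv, src_chrom, src_start, src_len, dest_chrom, dest_pos = cfg.translocation
        src = cultivars[cv][src_chrom]
        moved = src[src_start : src_start + src_len].copy()
        cultivars[cv][src_chrom] = np.concatenate(
            [src[:src_start], src[src_start + src_len :]]
        )
        dest = cultivars[cv][dest_chrom]
        cultivars[cv][dest_chrom] = np.concatenate(
            [dest[:dest_pos], moved, dest[dest_pos:]]
        )
        truth.translocations.append(
            (cv, src_chrom, src_start, src_start + src_len, dest_chrom, dest_pos)
        )
    truth.check_tiling(cfg.chrom_len)
    return cultivars, donor, truth


# ---------------------------------------------------------------------------
# scaffolding

def fragment_assembly(
    genome: dict[str, np.ndarray],
    cfg: PanelConfig,
    n_pieces: Optional[int] = None,
    min_piece_len: int = 5_000,
    seed_stream: int = 3,
):
    """Cut each chromosome into scaffolds, shuffle and randomly flip them.

    With ``n_pieces`` set, each chromosome is cut into exactly that many
    pieces, each at least ``min_piece_len`` long (remaining length is
    spread with exponential weights); otherwise piece lengths are drawn
    exponentially with mean ``cfg.scaffold_len_mean``.

    Returns ``(scaffolds, layout)``; *scaffolds* is a list of
    :class:`SeqRecord` in shuffled order and *layout* maps scaffold id ->
    (source chrom, start, end, orientation, rank in true order).
    """
    rng = np.random.default_rng([cfg.seed, seed_stream])
    # (chrom, start, end, rank within chrom) in true order
    pieces: list[tuple[str, int, int, int]] = []
    for chrom, arr in genome.items():
        n = arr.size
        if n_pieces is not None:
            if n_pieces * min_piece_len > n:
                raise ValueError("chromosome too short for requested pieces")
            w = rng.exponential(1.0, n_pieces)
            extra = np.floor(w / w.sum() * (n - n_pieces * min_piece_len)).astype(int)
            lens = extra + min_piece_len
            lens[-1] += n - lens.sum()
        else:
            lens_list: list[int] = []
            left = n
            while left > 0:
                ln = max(min_piece_len, int(rng.exponential(cfg.scaffold_len_mean)))
                lens_list.append(min(ln, left))
                left -= lens_list[-1]
            lens = np.array(lens_list)
        pos = 0
        for rank, ln in enumerate(lens):
            pieces.append((chrom, pos, pos + int(ln), rank))
            pos += int(ln)
    order = rng.permutation(len(pieces))
    flips = rng.random(len(pieces)) < 0.5
    scaffolds: list[SeqRecord] = []
    layout: dict[str, tuple] = {}
    for out_i, idx in enumerate(order):
        chrom, start, end, rank = pieces[idx]
        arr = genome[chrom][start:end]
        orientation = "-" if flips[idx] else "+"
        if orientation == "-":
            arr = (3 - arr)[::-1]
        name = f"scaffold_{out_i + 1:04d}"
        scaffolds.append(SeqRecord(name, _decode(arr)))
        layout[name] = (chrom, start, end, orientation, rank)
    return scaffolds, layout


# ---------------------------------------------------------------------------
# donor coverage

def simulate_donor_alignments(
    intro_spans: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    depth_in: float,
    depth_bg: float,
    read_len: int = 150,
    seed: int = 0,
    low_mapq_frac: float = 0.1,
    improper_frac: float = 0.05,
) -> list[GenomicInterval]:
    """Donor-read intervals at rate depth_in inside introgressed spans and
    depth_bg elsewhere; a configured fraction gets mapq < 10 and a
    configured fraction loses the proper-pair flag."""
    rng = np.random.default_rng([seed, 4])
    out: list[GenomicInterval] = []

    def _emit(chrom: str, start: int, end: int, depth: float) -> None:
        span = end - start
        if depth <= 0 or span <= 0:
            return
        n_reads = rng.poisson(depth * span / read_len)
        starts = rng.integers(start, max(start + 1, end - read_len), n_reads)
        mapqs = np.where(
            rng.random(n_reads) < low_mapq_frac,
            rng.integers(0, 10, n_reads),
            60,
        )
        proper = rng.random(n_reads) >= improper_frac
        for s, q, p in zip(starts, mapqs, proper):
            out.append(
                GenomicInterval(
                    chrom,
                    int(s),
                    min(int(s) + read_len, chrom_lengths[chrom]),
                    "+",
                    {"mapq": int(q), "proper_pair": bool(p)},
                )
            )

    for chrom, total in chrom_lengths.items():
        spans = sorted(intro_spans.get(chrom, []))
        pos = 0
        for s, e in spans:
            _emit(chrom, pos, s, depth_bg)
            _emit(chrom, s, e, depth_in)
            pos = e
        _emit(chrom, pos, total, depth_bg)
    return out


# ---------------------------------------------------------------------------
# exon sets

def emit_exon_set(
    genome: dict[str, str],
    te_intervals: dict[str, list[tuple[int, int]]],
    n_exons: int,
    del_fraction: float,
    mut_fraction: float,
    seed: int = 0,
    len_range: tuple[int, int] = (60, 400),
):
    """Exons sampled from single-copy (non-TE) space + a derived target
    genome in which exact planted fractions are deleted or mutated past
    the 95% identity threshold.

    Mutated exons are substituted at every 8th base (12.5% divergence) so
    their failure at the threshold is deterministic, not sampled.

    Returns ``(exons, target_genome, ledger)`` where *ledger* is a list of
    (exon id, chrom, start, end, class) with class in
    {intact, deleted, mutated}.
    """
    rng = np.random.default_rng([seed, 5])
    chroms = sorted(genome)
    # candidate single-copy space
    spans: list[tuple[str, int, int]] = []
    tries = 0
    while len(spans) < n_exons and tries < 50 * n_exons:
        tries += 1
        chrom = chroms[rng.integers(len(chroms))]
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, len(genome[chrom]) - ln))
        end = start + ln
        if any(start < te_e and te_s < end
               for te_s, te_e in te_intervals.get(chrom, [])):
            continue
        if any(start < e and s < end for c, s, e in spans if c == chrom):
            continue
        if "N" in genome[chrom][start:end]:
            continue
        spans.append((chrom, start, end))
    if len(spans) < n_exons:
        raise RuntimeError("could not place the requested number of exons")
    spans.sort()
    n_del = round(n_exons * del_fraction)
    n_mut = round(n_exons * mut_fraction)
    classes = ["deleted"] * n_del + ["mutated"] * n_mut
    classes += ["intact"] * (n_exons - len(classes))
    rng.shuffle(classes)
    exons: list[SeqRecord] = []
    ledger: list[tuple] = []
    edits: dict[str, list[tuple]] = {c: [] for c in chroms}
    for i, ((chrom, start, end), cls) in enumerate(zip(spans, classes)):
        seq = genome[chrom][start:end]
        exon_id = f"exon_{i + 1:05d}"
        exons.append(SeqRecord(exon_id, seq))
        ledger.append((exon_id, chrom, start, end, cls))
        if cls != "intact":
            edits[chrom].append((start, end, cls))
    target: dict[str, str] = {}
    for chrom in chroms:
        seq = genome[chrom]
        for start, end, cls in sorted(edits[chrom], reverse=True):
            if cls == "deleted":
                seq = seq[:start] + seq[end:]
            else:
                chunk = list(seq[start:end])
                for j in range(0, len(chunk), 8):
                    chunk[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chunk[j]]
                seq = seq[:start] + "".join(chunk) + seq[end:]
        target[chrom] = seq
    return exons, target, ledger


def delete_spans(genome: dict[str, str], spans: list[tuple[str, int, int]]):
    """Remove (chrom, start, end) spans from a genome copy (true deletions)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spans:
        per_chrom.setdefault(chrom, []).append((s, e))
    out = dict(genome)
    for chrom, lst in per_chrom.items():
        seq = out[chrom]
        for s, e in sorted(lst, reverse=True):
            seq = seq[:s] + seq[e:]
        out[chrom] = seq
    return out


def decode_genome(genome: dict[str, np.ndarray]) -> dict[str, str]:
    """uint8 base arrays -> strings, for handing to the analysis stages."""
    return {c: _decode(a) for c, a in genome.items()}


def generate_panel(cfg: PanelConfig):
    """Run the full generator: founders -> cultivars -> truth.

    Returns ``(base, founders, cultivars, donor, truth)`` with all
    genomes as chrom -> uint8 array maps (use :func:`decode_genome` for
    strings).
    """
    base, founders, te_intervals = simulate_founders(cfg)
    cultivars, donor, truth = compose_cultivars(base, founders, te_intervals, cfg)
    return base, founders, cultivars, donor, truth
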