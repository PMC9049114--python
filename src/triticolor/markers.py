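"""ISBP junction-marker design and approximate marker mapping.

An ISBP (insertion site-based polymorphism) marker is a 150-bp tag
spanning the junction between a transposable element and its insertion
site, 75 bp on each side. TE bodies are multi-copy but their insertion
junctions are locus-specific, so these tags are uniquely mappable even
in a repeat-dominated genome and can anchor scaffolds by collinearity.

Mapping uses seed-and-extend: exact ``seed_len``-mer seeds located via a
sorted k-mer index of the target, candidate loci verified by bounded
edit-distance alignment of the full query (edlib, infix mode). Identity
is computed over alignment columns. The engine is shared with the exon
conservation search (variable-length queries).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .io import GenomicInterval, SeqRecord, reverse_complement
from .kmers import kmer_codes

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class MapConfig:
    min_identity: float = 0.90
    min_coverage: float = 0.90
    seed_len: int = 21
    max_mismatches: Optional[int] = None  # dot-plot preset: substitutions only
    min_second_best_gap: int = 5  # score units (matched columns)
    band: int = 15
    max_candidates: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be in (0, 1]")

    @classmethod
    def preset(cls, name: str) -> "MapConfig":
        presets = {
            "anchor": cls(min_identity=0.80, min_coverage=0.90),
            "conserve": cls(min_identity=0.90, min_coverage=0.90),
            "exon": cls(min_identity=0.95, min_coverage=0.95),
            "dotplot": cls(min_identity=0.98, min_coverage=1.0, max_mismatches=2),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
        return presets[name]


@dataclass
class IsbpMarker:
    id: str
    source_chrom: str
    junction_pos: int  # 0-based offset of the TE junction
    side: str  # 5prime | 3prime
    sequence: str
    source_span: GenomicInterval

    def __post_init__(self) -> None:
        if "N" in self.sequence:
            raise ValueError(f"marker {self.id} contains N")


@dataclass
class MarkerHit:
    marker_id: str
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    query_coverage: float
    mismatches: int
    edits: int
    score: int  # matched columns
    is_unique: bool = True


class TargetIndex:
    """Sorted exact-seed index over a genome (dict chrom -> sequence)."""

    def __init__(self, genome: dict[str, str], seed_len: int = 21):
        if seed_len > 31:
            raise ValueError("seed_len must be <= 31")
        self.seed_len = seed_len
        self.genome = genome
        self._codes: dict[str, np.ndarray] = {}
        self._positions: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            codes, starts = kmer_codes(seq, seed_len)
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._positions[chrom] = starts[order]

    def seed_positions(self, chrom: str, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query offsets, target positions) of exact seed matches."""
        codes = self._codes[chrom]
        lo = np.searchsorted(codes, query_codes, side="left")
        hi = np.searchsorted(codes, query_codes, side="right")
        q_off = []
        t_pos = []
        for qi, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                q_off.append(np.full(b - a, qi))
                t_pos.append(self._positions[chrom][a:b])
        if not q_off:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(q_off), np.concatenate(t_pos)


def _parse_cigar(cigar: str) -> tuple[int, int, int, int, int]:
    """(columns, matches, mismatches, query_consumed, indels)."""
    columns = matches = mismatches = qcons = indels = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
            qcons += n
        elif op in ("X", "M"):
            mismatches += n
            qcons += n
        elif op == "I":  # edlib: I consumes the query
            qcons += n
            indels += n
        elif op == "D":
            indels += n
    return columns, matches, mismatches, qcons, indels


def _cluster_candidates(starts: np.ndarray, tol: int, limit: int) -> list[int]:
    """Collapse candidate start diagonals within *tol* bp; keep at most
    *limit* clusters, largest seed support first."""
    if starts.size == 0:
        return []
    starts = np.sort(starts)
    breaks = np.nonzero(np.diff(starts) > tol)[0] + 1
    groups = np.split(starts, breaks)
    groups.sort(key=len, reverse=True)
    return [int(np.median(g)) for g in groups[:limit]]


def search(
    query: str,
    index: TargetIndex,
    cfg: MapConfig,
) -> list[MarkerHit]:
    """All passing placements of *query* in the indexed genome, best first.

    Hits overlapping on the target (same strand) are deduplicated to the
    best-scoring placement.
    """
    if cfg.seed_len > len(query):
        raise ValueError("seed_len exceeds query length")
    qlen = len(query)
    kmax = int((1 - cfg.min_identity) * qlen) + cfg.band
    hits: list[MarkerHit] = []
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        qcodes, qstarts = kmer_codes(qseq, cfg.seed_len)
        if qcodes.size == 0:
            continue
        for chrom, tseq in index.genome.items():
            q_off, t_pos = index.seed_positions(chrom, qcodes)
            if t_pos.size == 0:
                continue
            cand = t_pos - qstarts[q_off]
            for start in _cluster_candidates(cand, cfg.band, cfg.max_candidates):
                lo = max(0, start - cfg.band)
                hi = min(len(tseq), start + qlen + cfg.band)
                res = edlib.align(qseq, tseq[lo:hi], mode="HW", task="path", k=kmax)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                columns, matches, mism, qcons, indels = _parse_cigar(res["cigar"])
                identity = matches / columns if columns else 0.0
                coverage = qcons / qlen
                if identity < cfg.min_identity or coverage < cfg.min_coverage:
                    continue
                if cfg.max_mismatches is not None and (
                    mism > cfg.max_mismatches or indels > 0
                ):
                    continue
                hits.append(
                    MarkerHit(
                        marker_id="",
                        target_chrom=chrom,
                        target_start=lo + loc[0],
                        target_end=lo + loc[1] + 1,
                        strand=strand,
                        identity=identity,
                        query_coverage=coverage,
                        mismatches=mism,
                        edits=res["editDistance"],
                        score=matches,
                    )
                )
    # deduplicate overlapping placements, best score wins
    hits.sort(key=lambda h: (-h.score, h.target_chrom, h.target_start))
    kept: list[MarkerHit] = []
    for h in hits:
        if any(
            k.target_chrom == h.target_chrom
            and k.target_start < h.target_end
            and h.target_start < k.target_end
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# ISBP design

def design_isbp(
    genome: dict[str, str],
    te_intervals: dict[str, list[tuple[int, int]]],
    flank: int = 75,
) -> list[IsbpMarker]:
    """One marker per TE junction (insertion start and end), spanning
    *flank* bases on each side of the junction.

    Markers that would run off the chromosome or that contain N are
    dropped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    markers: list[IsbpMarker] = []
    for chrom, spans in te_intervals.items():
        seq = genome[chrom]
        n = len(seq)
        prev = -1
        for start, end in spans:
            if start < prev:
                raise ValueError(f"TE intervals on {chrom} are not sorted")
            prev = start
            for junction, side in ((start, "5prime"), (end, "3prime")):
                lo, hi = junction - flank, junction + flank
                if lo < 0 or hi > n:
                    continue
                tag = seq[lo:hi]
                if "N" in tag:
                    continue
                markers.append(
                    IsbpMarker(
                        id=f"{chrom}:{junction}:{side}",
                        source_chrom=chrom,
                        junction_pos=junction,
                        side=side,
                        sequence=tag,
                        source_span=GenomicInterval(chrom, lo, hi, "+"),
                    )
                )
    return markers


def filter_unique(
    markers: Sequence[IsbpMarker],
    genome: dict[str, str],
    cfg: MapConfig | None = None,
    index: TargetIndex | None = None,
) -> list[IsbpMarker]:
    """Keep markers with exactly one passing placement in their source
    genome (which must be the source locus)."""
    cfg = cfg or MapConfig.preset("conserve")
    index = index or TargetIndex(genome, cfg.seed_len)
    out: list[IsbpMarker] = []
    for m in markers:
        hits = search(m.sequence, index, cfg)
        if len(hits) != 1:
            continue
        h = hits[0]
        if (
            h.target_chrom == m.source_chrom
            and h.target_start < m.source_span.end
            and m.source_span.start < h.target_end
        ):
            out.append(m)
    return out


def map_markers(
    markers: Sequence[IsbpMarker],
    target_genome: dict[str, str],
    cfg: MapConfig | None = None,
    index: TargetIndex | None = None,
) -> list[MarkerHit]:
    """Best passing hit per marker; ``is_unique`` is cleared when a second
    placement scores within ``min_second_best_gap`` matched columns."""
    cfg = cfg or MapConfig.preset("anchor")
    index = index or TargetIndex(target_genome, cfg.seed_len)
    out: list[MarkerHit] = []
    for m in markers:
        hits = search(m.sequence, index, cfg)
        if not hits:
            continue
        best = replace(hits[0], marker_id=m.id)
        if len(hits) > 1 and hits[0].score - hits[1].score < cfg.min_second_best_gap:
            best.is_unique = False
        out.append(best)
    return out


def conservation_rate(
    markers: Sequence[IsbpMarker],
    target_genome: dict[str, str],
    cfg: MapConfig | None = None,
    index: TargetIndex | None = None,
    min_aligned_matches: Optional[int] = None,
):
    """Fraction of markers with a passing hit in the target, plus a
    per-marker table.

    ``min_aligned_matches`` switches to the alternate criterion used for
    polishing monitoring (identity threshold over a minimum number of
    aligned nucleotides instead of a query-length fraction). The table
    also carries the perfect-match flag (identity 1.0, full coverage).
    """
    if not markers:
        raise ValueError("empty marker set")
    cfg = cfg or MapConfig.preset("conserve")
    if min_aligned_matches is not None:
        # let low-coverage alignments through; the matches count decides
        cfg = replace(cfg, min_coverage=min(cfg.min_coverage, 0.5))
    index = index or TargetIndex(target_genome, cfg.seed_len)
    rows: list[dict] = []
    n_conserved = 0
    n_perfect = 0
    for m in markers:
        hits = search(m.sequence, index, cfg)
        best = hits[0] if hits else None
        conserved = best is not None
        if conserved and min_aligned_matches is not None:
            conserved = best.score >= min_aligned_matches
        perfect = (
            best is not None
            and best.identity == 1.0
            and best.query_coverage == 1.0
        )
        n_conserved += conserved
        n_perfect += perfect
        rows.append(
            {
                "marker_id": m.id,
                "conserved": conserved,
                "perfect": perfect,
                "identity": best.identity if best else np.nan,
                "coverage": best.query_coverage if best else np.nan,
                "target_chrom": best.target_chrom if best else "",
                "target_start": best.target_start if best else -1,
            }
        )
    return n_conserved / len(markers), n_perfect / len(markers), rows


def markers_to_fasta_records(markers: Iterable[IsbpMarker]) -> list[SeqRecord]:
    return [SeqRecord(m.id, m.sequence) for m in markers]
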