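"""Assembly QC: contiguity statistics, conservation reports, telomere
arrays and k-mer consensus quality (QV).

N50 is the length of the sequence at which the cumulative
sorted-descending length first reaches half the assembly total; NG50
uses half an assumed genome size G instead (15 Gb for hexaploid wheat),
so assemblies of different cumulative size stay comparable. L50/LG50
are the corresponding ranks. NG statistics are undefined (None) when
the assembly never reaches the G quantile.

The k-mer QV estimate follows the Merqury model: if a fraction ``b/t``
of assembly k-mers is absent from a trusted read set, the per-base
error E solves 1 - (1 - E)^k = b/t and QV = -10 log10 E.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import SeqRecord, reverse_complement
from .kmers import canonical_codes, canonical_kmer_set, kmer_codes
from .markers import MapConfig, TargetIndex, search


@dataclass
class QcConfig:
    genome_size_g: int = 15_000_000_000
    exon_min_identity: float = 0.95
    exon_min_coverage: float = 0.95
    exon_min_len: int = 31
    telomere_motif: str = "TTTAGGG"
    telomere_min_copies: int = 10
    telomere_end_window: int = 10_000
    telomere_max_mismatch_per_copy: int = 1
    kmer_k: int = 21
    qv_cap: float = 99.0

    def __post_init__(self) -> None:
        if not self.telomere_motif:
            raise ValueError("telomere motif must be non-empty")
        for t in (self.exon_min_identity, self.exon_min_coverage):
            if not 0 < t <= 1:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class AssemblyStats:
    n_seqs: int
    total_len: int
    n50: int
    l50: int
    n90: int
    l90: int
    ng50: Optional[int]
    lg50: Optional[int]
    ng90: Optional[int]
    lg90: Optional[int]
    longest: int
    pct_n: float


def _nxx(sorted_desc: np.ndarray, cum: np.ndarray, quota: float):
    idx = int(np.searchsorted(cum, quota))
    if idx >= sorted_desc.size:
        return None, None
    return int(sorted_desc[idx]), idx + 1


def assembly_stats(
    lengths: Sequence[int],
    cfg: QcConfig | None = None,
    n_bases: int = 0,
) -> AssemblyStats:
    """Contiguity statistics over sequence lengths (pass ``n_bases`` to
    report the N percentage)."""
    cfg = cfg or QcConfig()
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("no sequences")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    total = int(arr.sum())
    cum = np.cumsum(arr)
    n50, l50 = _nxx(arr, cum, 0.5 * total)
    n90, l90 = _nxx(arr, cum, 0.9 * total)
    ng50, lg50 = _nxx(arr, cum, 0.5 * cfg.genome_size_g)
    ng90, lg90 = _nxx(arr, cum, 0.9 * cfg.genome_size_g)
    return AssemblyStats(
        n_seqs=arr.size,
        total_len=total,
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        ng50=ng50,
        lg50=lg50,
        ng90=ng90,
        lg90=lg90,
        longest=int(arr[0]),
        pct_n=100.0 * n_bases / total if total else 0.0,
    )


def contig_lengths(records: Sequence[SeqRecord]) -> list[int]:
    """Contig lengths obtained by splitting each sequence at every N."""
    from .io import split_at_n

    out: list[int] = []
    for rec in records:
        out.extend(len(iv) for iv in split_at_n(rec, min_gap_len=1))
    return out


# ---------------------------------------------------------------------------
# exon conservation

@dataclass
class ConservationReport:
    n_exons: int
    n_dropped: int  # too short or containing N
    conserved_fraction: float
    mean_hit_identity: float
    identical_fraction: float
    rows: list


def exon_conservation(
    exons: Sequence[SeqRecord],
    target_genome: dict[str, str],
    cfg: QcConfig | None = None,
    same_chrom_map: Optional[dict[str, str]] = None,
) -> ConservationReport:
    """Fraction of exons with a hit at >= 95% identity over >= 95% of
    their length in the target, via the shared seed-and-extend engine.

    ``same_chrom_map`` (exon id -> expected target chromosome) restricts
    the strictly-identical count to exons found on their own chromosome.
    """
    cfg = cfg or QcConfig()
    usable = []
    dropped = 0
    for rec in exons:
        if len(rec) < cfg.exon_min_len or "N" in rec.sequence:
            dropped += 1
        else:
            usable.append(rec)
    if not usable:
        raise ValueError("no usable exons")
    map_cfg = MapConfig(
        min_identity=cfg.exon_min_identity, min_coverage=cfg.exon_min_coverage
    )
    index = TargetIndex(target_genome, map_cfg.seed_len)
    rows = []
    n_cons = 0
    n_ident = 0
    identities = []
    for rec in usable:
        hits = search(rec.sequence, index, map_cfg)
        best = hits[0] if hits else None
        conserved = best is not None
        identical = (
            best is not None
            and best.identity == 1.0
            and best.query_coverage == 1.0
            and (
                same_chrom_map is None
                or same_chrom_map.get(rec.id) == best.target_chrom
            )
        )
        if conserved:
            n_cons += 1
            identities.append(best.identity)
        n_ident += identical
        rows.append((rec.id, conserved, identical,
                     best.identity if best else np.nan,
                     best.target_chrom if best else ""))
    return ConservationReport(
        n_exons=len(usable),
        n_dropped=dropped,
        conserved_fraction=n_cons / len(usable),
        mean_hit_identity=float(np.mean(identities)) if identities else np.nan,
        identical_fraction=n_ident / len(usable),
        rows=rows,
    )


# ---------------------------------------------------------------------------
# telomeres

@dataclass
class TelomereReport:
    chrom: str
    five_prime_copies: int
    three_prime_copies: int

    @property
    def complete(self) -> bool:
        return self.five_prime_copies > 0 and self.three_prime_copies > 0


def _max_tandem_copies(window: str, motif: str, max_mm: int) -> int:
    """Longest tandem run of *motif* (period = len(motif), <= max_mm
    mismatches per copy) anywhere in *window*."""
    m = len(motif)
    best = 0
    n = len(window)
    pos = 0
    while pos + m <= n:
        mm = sum(a != b for a, b in zip(window[pos : pos + m], motif))
        if mm <= max_mm:
            count = 1
            nxt = pos + m
            while nxt + m <= n:
                mm = sum(a != b for a, b in zip(window[nxt : nxt + m], motif))
                if mm > max_mm:
                    break
                count += 1
                nxt += m
            best = max(best, count)
            pos = nxt
        else:
            pos += 1
    return best


def find_telomere_arrays(
    record: SeqRecord, cfg: QcConfig | None = None
) -> TelomereReport:
    """Telomere-repeat tandem arrays within a window of each chromosome
    end; both motif orientations are scanned at both ends and an array
    counts only with at least ``telomere_min_copies`` copies."""
    cfg = cfg or QcConfig()
    if len(record) < 2 * cfg.telomere_end_window:
        raise ValueError("chromosome shorter than twice the end window")
    motifs = (cfg.telomere_motif, reverse_complement(cfg.telomere_motif))
    head = record.sequence[: cfg.telomere_end_window]
    tail = record.sequence[-cfg.telomere_end_window :]
    mm = cfg.telomere_max_mismatch_per_copy
    five = max(_max_tandem_copies(head, m, mm) for m in motifs)
    three = max(_max_tandem_copies(tail, m, mm) for m in motifs)
    if five < cfg.telomere_min_copies:
        five = 0
    if three < cfg.telomere_min_copies:
        three = 0
    return TelomereReport(record.id, five, three)


# ---------------------------------------------------------------------------
# consensus quality

def qv_to_error(qv: float) -> float:
    return 10 ** (-qv / 10)


def error_to_qv(error_rate: float) -> float:
    if not 0 < error_rate < 1:
        raise ValueError("error rate must be in (0, 1)")
    return -10 * np.log10(error_rate)


def qv_to_spacing(qv: float) -> float:
    """Bases per error at a given QV (QV 30 -> exactly 1,000 bp)."""
    return 1.0 / qv_to_error(qv)


def kmer_qv(
    assembly: dict[str, str],
    trusted_kmers: np.ndarray,
    k: int = 21,
    cap: float = 99.0,
) -> float:
    """Merqury-style consensus QV of an assembly against a sorted array
    of trusted canonical k-mer codes (e.g., from reads).

    Assembly k-mers are counted with multiplicity; E = 1 - (1 - b/t)^(1/k)
    with b the absent count and t the total.
    """
    if trusted_kmers.size == 0:
        raise ValueError("empty trusted k-mer set")
    total = 0
    absent = 0
    for seq in assembly.values():
        codes, _ = kmer_codes(seq, k)
        if codes.size == 0:
            continue
        canon = canonical_codes(codes, k)
        idx = np.searchsorted(trusted_kmers, canon)
        idx[idx >= trusted_kmers.size] = trusted_kmers.size - 1
        found = trusted_kmers[idx] == canon
        total += codes.size
        absent += int((~found).sum())
    if total == 0:
        raise ValueError("assembly shorter than k")
    if absent == 0:
        return cap
    err = 1 - (1 - absent / total) ** (1 / k)
    return float(error_to_qv(err))


def trusted_kmer_set(sequences: dict[str, str], k: int = 21) -> np.ndarray:
    """Sorted canonical k-mer codes of a read/reference set."""
    parts = [canonical_kmer_set(seq, k) for seq in sequences.values()]
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
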