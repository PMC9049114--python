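"""Introgression detection from minority haplotype profiles and donor
read coverage.

A chromosomal segment introgressed from a wild relative shows up as a
run of haplotype blocks whose presence profile is restricted to few
cultivars, and — when short reads of the donor species are available —
as strongly elevated donor coverage in the same windows. Coverage is
binned in fixed windows after filtering alignments below MAPQ 10 or not
in a proper pair. Runs of minority blocks at least ``min_run`` bins long
are emitted; with a donor track, only runs whose mean donor depth is at
least ``cov_factor`` times the chromosome-median donor depth, the rest
being flagged as profile-only candidates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GenomicInterval
from .haplotyping import HaploBlock


@dataclass
class IntroConfig:
    bin_len: int = 1_000_000
    min_mapq: int = 10
    proper_only: bool = True
    min_run: int = 5
    cov_factor: float = 5.0
    max_share: int = 5

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.cov_factor <= 1:
            raise ValueError("cov_factor must exceed 1")


@dataclass
class CoverageBins:
    chrom: str
    bin_len: int
    chrom_len: int
    depths: np.ndarray  # mean depth per bin

    @property
    def n_bins(self) -> int:
        return self.depths.size


@dataclass
class IntrogressionCall:
    cultivar: str
    chrom: str
    span: GenomicInterval
    n_bins: int
    mean_donor_depth: float
    profile_bits: Optional[int]
    coverage_evidence: bool


def bin_coverage(
    intervals: Sequence[GenomicInterval],
    chrom_lengths: dict[str, int],
    cfg: IntroConfig | None = None,
) -> dict[str, CoverageBins]:
    """Mean alignment depth per fixed window, after MAPQ / proper-pair
    filtering.

    Each retained interval contributes its overlap bases to every bin it
    intersects, so total contributed bases are conserved exactly. The
    trailing partial bin is normalised by its true length. Intervals
    running past the chromosome end are clipped with a warning.
    """
    cfg = cfg or IntroConfig()
    bases: dict[str, np.ndarray] = {}
    for chrom, total in chrom_lengths.items():
        n_bins = max(1, -(-total // cfg.bin_len))
        bases[chrom] = np.zeros(n_bins)
    for iv in intervals:
        if iv.chrom not in bases:
            raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
        mapq = int(iv.attrs.get("mapq", 60))
        proper = iv.attrs.get("proper_pair", True)
        if isinstance(proper, str):
            proper = proper.lower() in ("1", "true", "yes")
        if mapq < cfg.min_mapq or (cfg.proper_only and not proper):
            continue
        total = chrom_lengths[iv.chrom]
        start, end = iv.start, iv.end
        if end > total:
            warnings.warn(
                f"interval {iv.chrom}:{start}-{end} beyond chromosome end, clipped"
            )
            end = total
        b0 = start // cfg.bin_len
        b1 = (end - 1) // cfg.bin_len
        for b in range(b0, b1 + 1):
            lo = max(start, b * cfg.bin_len)
            hi = min(end, (b + 1) * cfg.bin_len)
            bases[iv.chrom][b] += hi - lo
    out: dict[str, CoverageBins] = {}
    for chrom, arr in bases.items():
        total = chrom_lengths[chrom]
        widths = np.full(arr.size, cfg.bin_len, dtype=float)
        if total % cfg.bin_len:
            widths[-1] = total % cfg.bin_len
        out[chrom] = CoverageBins(chrom, cfg.bin_len, total, arr / widths)
    return out


def call_introgressions(
    cultivar: str,
    superblocks: Sequence[HaploBlock],
    donor_bins: Optional[CoverageBins],
    cfg: IntroConfig | None = None,
) -> list[IntrogressionCall]:
    """Candidate introgressed segments for one cultivar.

    Minority blocks (profile shared by <= max_share cultivars) are
    scanned for maximal runs of at least min_run consecutive bins. With
    a donor coverage track on the same grid, a run becomes a coverage-
    supported call only when its mean donor depth >= cov_factor x the
    chromosome-median donor depth; otherwise it is emitted with
    ``coverage_evidence=False`` (profile-only candidate).
    """
    cfg = cfg or IntroConfig()
    blocks = sorted(superblocks, key=lambda b: b.span.start)
    if donor_bins is not None:
        if donor_bins.bin_len != cfg.bin_len or donor_bins.n_bins < len(blocks):
            raise ValueError("donor coverage bins do not match the block grid")
        median_depth = float(np.median(donor_bins.depths))
    minority = [
        b.profile is not None and 1 <= b.profile.popcount <= cfg.max_share
        for b in blocks
    ]
    calls: list[IntrogressionCall] = []
    i = 0
    while i < len(blocks):
        if not minority[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(blocks) and minority[j + 1]:
            j += 1
        run = blocks[i : j + 1]
        if len(run) >= cfg.min_run:
            profile_bits = Counter(
                b.profile.bits for b in run if b.profile is not None
            ).most_common(1)[0][0]
            span = GenomicInterval(
                run[0].chrom or ".", run[0].span.start, run[-1].span.end
            )
            mean_depth = float("nan")
            evidence = False
            emit = True
            if donor_bins is not None:
                b0 = run[0].span.start // cfg.bin_len
                b1 = (run[-1].span.end - 1) // cfg.bin_len
                mean_depth = float(donor_bins.depths[b0 : b1 + 1].mean())
                evidence = mean_depth >= cfg.cov_factor * max(median_depth, 1e-9)
                emit = evidence  # coverage track supplied: require support
            if emit:
                calls.append(
                    IntrogressionCall(
                        cultivar=cultivar,
                        chrom=run[0].chrom or ".",
                        span=span,
                        n_bins=len(run),
                        mean_donor_depth=mean_depth,
                        profile_bits=profile_bits,
                        coverage_evidence=evidence,
                    )
                )
        i = j + 1
    return calls
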