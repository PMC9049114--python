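"""Sequence and interval I/O shared by every pipeline stage.

Coordinate conventions: everything in memory and in BED is 0-based
half-open; AGP and GFF3 are 1-based inclusive and the readers/writers in
this module are the only place the ±1 arithmetic happens.

Only the {A, C, G, T, N} alphabet is accepted: other IUPAC ambiguity
codes are rejected at read time so that k-mers stay 2-bit codable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SeqRecord:
    """A named uppercase DNA sequence over {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomicInterval:
    """0-based half-open interval with free-form string attributes."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution, N maps to N."""
    bad = set(sequence.upper()) - VALID_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into uppercased records, order preserved.

    Duplicate ids raise; an empty file returns an empty list with a
    warning.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    if not records:
        warnings.warn(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def split_at_n(record: SeqRecord, min_gap_len: int = 1) -> list[GenomicInterval]:
    """Contig intervals of *record*: maximal N-free runs whose flanking
    N-runs are at least ``min_gap_len`` long.

    With the default ``min_gap_len = 1`` every N is a breakpoint, the
    convention used when deriving contig statistics from scaffolds.
    """
    if len(record) == 0:
        raise ValueError("empty record")
    seq = record.sequence
    # N-runs of sufficient length are separators; shorter N-runs stay
    # inside a contig (the contig is then not strictly N-free).
    runs: list[tuple[int, int]] = []  # qualifying N-runs
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_gap_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    out: list[GenomicInterval] = []
    prev = 0
    for s, e in runs:
        if s > prev:
            out.append(GenomicInterval(record.id, prev, s))
        prev = e
    if prev < n:
        out.append(GenomicInterval(record.id, prev, n))
    return out


# ---------------------------------------------------------------------------
# BED and GFF3

def read_bed(path: str | Path, attr_names: Sequence[str] = ()) -> list[GenomicInterval]:
    """Read BED3+; extra columns are mapped onto ``attr_names`` in order.

    Column 6 is used as strand when ``attr_names`` leaves it free and the
    value looks like a strand.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            attrs = {}
            strand = "."
            for name, value in zip(attr_names, cols[3:]):
                if name == "strand":
                    strand = value
                else:
                    attrs[name] = value
            out.append(GenomicInterval(chrom, start, end, strand, attrs))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    attr_names: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            for name in attr_names:
                if name == "strand":
                    cols.append(iv.strand)
                else:
                    cols.append(str(iv.attrs.get(name, ".")))
            fh.write("\t".join(cols) + "\n")


def read_gff3_intervals(
    path: str | Path, feature_types: set[str] | None = None
) -> list[GenomicInterval]:
    """Read GFF3 features as intervals (1-based inclusive -> half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                continue
            if feature_types and cols[2] not in feature_types:
                continue
            attrs = {"source": cols[1], "type": cols[2]}
            if len(cols) > 8:
                for kv in cols[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
            strand = cols[6] if cols[6] in ("+", "-") else "."
            out.append(
                GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), strand, attrs)
            )
    return out


# ---------------------------------------------------------------------------
# AGP v2.1

@dataclass
class AgpRow:
    """One AGP v2.1 row; object coordinates are 1-based inclusive."""

    object: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # W (sequence) or U (gap of unknown size)
    # W fields
    component_id: str = ""
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"
    # U fields
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = [
                self.component_id,
                str(self.component_start),
                str(self.component_end),
                self.orientation,
            ]
        else:
            tail = [str(self.gap_length), self.gap_type, self.linkage, self.evidence]
        return "\t".join(
            [
                self.object,
                str(self.object_start),
                str(self.object_end),
                str(self.part_number),
                self.component_type,
                *tail,
            ]
        )


def layout_to_agp_rows(layout, scaffold_lengths: dict[str, int]) -> list[AgpRow]:
    """Expand a :class:`~triticolor.anchoring.PseudomoleculeLayout` into
    AGP rows with fixed-length U gap rows between neighbour scaffolds.
    """
    rows: list[AgpRow] = []
    for chrom, placements in layout.chrom_order.items():
        pos = 0  # 0-based running offset on the object
        part = 0
        for i, (scaffold, orientation) in enumerate(placements):
            if i > 0:
                part += 1
                rows.append(
                    AgpRow(
                        object=chrom,
                        object_start=pos + 1,
                        object_end=pos + layout.gap_len,
                        part_number=part,
                        component_type="U",
                        gap_length=layout.gap_len,
                    )
                )
                pos += layout.gap_len
            length = scaffold_lengths[scaffold]
            part += 1
            rows.append(
                AgpRow(
                    object=chrom,
                    object_start=pos + 1,
                    object_end=pos + length,
                    part_number=part,
                    component_type="W",
                    component_id=scaffold,
                    component_start=1,
                    component_end=length,
                    orientation=orientation,
                )
            )
            pos += length
    return rows


def write_agp(layout, scaffold_lengths: dict[str, int], path: str | Path) -> None:
    rows = layout_to_agp_rows(layout, scaffold_lengths)
    # sanity: object rows must tile without overlap
    by_obj: dict[str, int] = {}
    for row in rows:
        expect = by_obj.get(row.object, 0) + 1
        if row.object_start != expect:
            raise ValueError(
                f"AGP rows for {row.object} do not tile: expected start {expect}, "
                f"got {row.object_start}"
            )
        by_obj[row.object] = row.object_end
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            base = dict(
                object=cols[0],
                object_start=int(cols[1]),
                object_end=int(cols[2]),
                part_number=int(cols[3]),
                component_type=cols[4],
            )
            if cols[4] == "W":
                rows.append(
                    AgpRow(
                        **base,
                        component_id=cols[5],
                        component_start=int(cols[6]),
                        component_end=int(cols[7]),
                        orientation=cols[8],
                    )
                )
            else:
                rows.append(
                    AgpRow(
                        **base,
                        gap_length=int(cols[5]),
                        gap_type=cols[6],
                        linkage=cols[7],
                        evidence=cols[8] if len(cols) > 8 else "map",
                    )
                )
    return rows


def sequence_from_agp(
    rows: Sequence[AgpRow], scaffolds: dict[str, str]
) -> dict[str, str]:
    """Rebuild object sequences from AGP rows and component sequences."""
    objects: dict[str, list[str]] = {}
    for row in rows:
        parts = objects.setdefault(row.object, [])
        if row.component_type == "U":
            parts.append("N" * row.gap_length)
        else:
            seq = scaffolds[row.component_id][
                row.component_start - 1 : row.component_end
            ]
            if row.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
    return {obj: "".join(parts) for obj, parts in objects.items()}
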