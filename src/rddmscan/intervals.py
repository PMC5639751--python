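"""Coordinate conventions, interval arithmetic, and annotation IO.

All coordinates are internally 0-based, half-open (BED convention).
GFF3 input (1-based, inclusive) is converted at the read boundary and
converted back on write.  Every downstream module consumes the types
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TEAnnotation",
    "SiRNALocus",
    "CLASS_I_SUPERFAMILIES",
    "CLASS_II_SUPERFAMILIES",
    "read_bed",
    "read_gff3",
    "write_bed",
    "write_gff3",
    "read_annotation",
    "intersect",
    "gap_distance",
]

# TE superfamily three-letter codes (Wicker nomenclature as used for maize):
# class I retroelements are RL* (LTR) and RIL (LINE); class II DNA
# transposons are D** (hAT, CACTA, Harbinger, Mutator, Helitron).
CLASS_I_SUPERFAMILIES = frozenset({"RLC", "RLG", "RLX", "RIL"})
CLASS_II_SUPERFAMILIES = frozenset({"DHH", "DTA", "DTC", "DTH", "DTM"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-dependent TSS/TTS semantics.

    TSS is the 5'-most transcribed base: ``start`` on '+', ``end - 1`` on
    '-'.  ``subgenome`` labels the maize whole-genome-duplication
    partition ('sub1' dominant, 'sub2' recessive, 'nonsyntenic',
    'unassigned'); a ``homeolog_partner`` implies membership of a
    retained duplicate pair.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "coding"  # coding | lncRNA | sRNA_precursor
    source: str = "reference"  # reference | de_novo
    subgenome: str = "unassigned"  # sub1 | sub2 | nonsyntenic | unassigned
    homeolog_partner: str | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand is required for genes")
        if self.biotype not in ("coding", "lncRNA", "sRNA_precursor"):
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if self.subgenome not in ("sub1", "sub2", "nonsyntenic", "unassigned"):
            raise ValueError(
                f"gene {self.gene_id}: unknown subgenome {self.subgenome!r}"
            )
        if self.homeolog_partner is not None and self.subgenome not in ("sub1", "sub2"):
            raise ValueError(
                f"gene {self.gene_id}: homeolog partner requires subgenome assignment"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """0-based position of the transcription termination site."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element annotation with class/superfamily labels."""

    interval: GenomicInterval
    superfamily: str
    family: str = ""

    def __post_init__(self) -> None:
        if (
            self.superfamily not in CLASS_I_SUPERFAMILIES
            and self.superfamily not in CLASS_II_SUPERFAMILIES
        ):
            raise ValueError(f"unknown TE superfamily code {self.superfamily!r}")

    @property
    def te_class(self) -> str:
        return "I" if self.superfamily in CLASS_I_SUPERFAMILIES else "II"

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class SiRNALocus:
    """A 24-nt siRNA-producing cluster."""

    interval: GenomicInterval
    locus_id: str = ""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_bed_line(line: str, lineno: int) -> tuple[GenomicInterval, str, float]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:
        fields = line.split()
    if len(fields) < 3:
        raise ValueError(f"malformed BED line {lineno}: need >=3 fields: {line!r}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"malformed BED line {lineno}: {exc}") from None
    name = fields[3] if len(fields) > 3 else ""
    try:
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    except ValueError:
        score = 0.0
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    if end <= start:
        raise ValueError(f"BED line {lineno}: end <= start ({start}, {end})")
    return GenomicInterval(chrom, start, end, strand), name, score


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """Read a BED3/BED6 file into (interval, name, score) records in input order."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            records.append(_parse_bed_line(line, lineno))
    return records


def read_gff3(path: str | Path) -> list[tuple[GenomicInterval, str, dict]]:
    """Read GFF3 into (interval, feature_type, attributes) records.

    1-based inclusive coordinates are converted to 0-based half-open.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 line {lineno}: need 9 fields, got {len(fields)}"
                )
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = fields
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(
                    f"GFF3 line {lineno}: end <= start after conversion "
                    f"({start1}, {end1})"
                )
            attributes = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    attributes[key.strip()] = value.strip()
            if strand not in ("+", "-"):
                strand = "."
            records.append((GenomicInterval(chrom, start, end, strand), ftype, attributes))
    return records


def read_annotation(path: str | Path, format: str) -> list:
    """Read an annotation file in the declared dialect ('bed' or 'gff3')."""
    if format == "bed":
        return read_bed(path)
    if format == "gff3":
        return read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _sorted_records(records, key):
    return sorted(records, key=key)


def write_bed(
    path: str | Path,
    records: Iterable[tuple[GenomicInterval, str, float]],
) -> None:
    """Write (interval, name, score) records as BED6, sorted by (chrom, start)."""
    rows = _sorted_records(list(records), key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score:g}\t{iv.strand}\n"
            )


def write_gff3(
    path: str | Path,
    records: Iterable[tuple[GenomicInterval, str, dict]],
    source: str = "rddmscan",
) -> None:
    """Write (interval, type, attributes) records as GFF3, sorted by (chrom, start)."""
    rows = _sorted_records(list(records), key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in rows:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\t{attr_str}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs (i, j) where ``a[i]`` overlaps ``b[j]``.

    Half-open overlap: abutting intervals do not intersect.  A
    sort-and-sweep per chromosome; output is sorted by (i, j) and is
    independent of input order.
    """
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for entries in by_chrom.values():
        entries.sort(key=lambda e: e[1].start)

    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        entries = by_chrom.get(iv.chrom)
        if not entries:
            continue
        # linear scan within chromosome; fine at annotation scale
        for j, other in entries:
            if other.start >= iv.end:
                break
            if other.end > iv.start:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap between two intervals; 0 if they overlap or abut.

    Raises on different chromosomes (callers pre-filter by chromosome).
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, b.start - a.end, a.start - b.end)
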