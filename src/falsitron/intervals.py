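"""Core genomic coordinate types shared across the pipeline.

All internal coordinates are 0-based half-open on the forward genomic
strand. GFF/GTF records and printed region strings (both 1-based
inclusive) are converted at the I/O boundary only, so every module past
:mod:`falsitron.genome_io` can assume a single convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A located genomic span, 0-based half-open.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
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
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """The genomic interval skipped by a split read or implied between
    consecutive exons of a transcript model.

    ``start`` is the first skipped (intronic) base, ``end`` one past the
    last. Two junctions are the same event only if chrom, start, end and
    strand all agree; an unstranded junction (``'.'``) is compatible with
    either strand (see :meth:`strand_compatible`).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end - self.start < 1:
            raise ValueError(
                f"junction {self.chrom}:{self.start}-{self.end} has length < 1"
            )
        if self.start < 0:
            raise ValueError("junction start must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Strand-blind coordinate key used for grouping."""
        return (self.chrom, self.start, self.end)

    def strand_compatible(self, strand: str) -> bool:
        return self.strand == "." or strand == "." or self.strand == strand

    def matches(self, other: "SpliceJunction") -> bool:
        """Exact coordinate equality with unstranded-matches-either strand."""
        return self.key == other.key and self.strand_compatible(other.strand)

    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TranscriptModel:
    """An ordered exon chain on one strand.

    ``source_label`` records the sequencing protocol the model derives
    from (``cDNA``, ``dcDNA`` or ``dRNA``); it drives the asymmetric
    treatment of RT-based versus direct-RNA evidence downstream.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    source_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev = None
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {exon.chrom}, "
                    f"transcript on {self.chrom}"
                )
            if prev is not None:
                if exon.start < prev.end:
                    raise ValueError(
                        f"transcript {self.transcript_id}: exons unsorted or "
                        f"overlapping near {prev.end}"
                    )
                if exon.start - prev.end < 1:
                    raise ValueError(
                        f"transcript {self.transcript_id}: implied intron of "
                        f"length < 1 at {prev.end}"
                    )
            prev = exon

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple:
        """Implied introns (gaps between consecutive exons), as junctions."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(SpliceJunction(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class AlignedRead:
    """A spliced alignment reduced to its reference-space geometry.

    ``blocks`` are the contiguous aligned reference segments (0-based
    half-open, sorted); gaps between consecutive blocks are the skipped
    intervals produced by N CIGAR operations.
    """

    name: str
    chrom: str
    strand: str
    blocks: tuple
    sequence: Optional[str] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.name} has no aligned blocks")
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"read {self.name}: empty aligned block ({s},{e})")
            if prev_end is not None and s - prev_end < 1:
                raise ValueError(
                    f"read {self.name}: zero-length skip at {prev_end}"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def skips(self) -> tuple:
        """Skipped reference intervals (N operations), 0-based half-open."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )

    def span_overlaps(self, interval: GenomeInterval) -> bool:
        """True if the aligned genomic span (including skips) intersects
        ``interval`` by at least one base."""
        return (
            self.chrom == interval.chrom
            and self.start < interval.end
            and interval.start < self.end
        )
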