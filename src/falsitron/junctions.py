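"""Junction catalogues: split-read support and locus coverage per dataset.

A junction is the reference interval skipped by an N CIGAR operation.
``split_read_count`` counts reads skipping exactly that interval;
``overlapping_read_count`` counts reads whose aligned genomic span
(including skips) intersects the junction interval by at least one base
— both junction-spanning and junction-crossing reads are informative
denominators for relative abundance.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .intervals import AlignedRead, GenomeInterval, SpliceJunction, TranscriptModel


@dataclass(frozen=True)
class JunctionSupport:
    junction: SpliceJunction
    split_read_count: int
    overlapping_read_count: int
    dataset: Optional[str] = None

    def __post_init__(self) -> None:
        if self.split_read_count < 0 or self.overlapping_read_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.split_read_count > self.overlapping_read_count:
            raise ValueError(
                "split_read_count cannot exceed overlapping_read_count "
                f"({self.split_read_count} > {self.overlapping_read_count})"
            )


class _SpanIndex:
    """Sorted per-chromosome read spans for O(log n) overlap counting."""

    def __init__(self, reads: Iterable[AlignedRead]):
        spans: Dict[str, list] = defaultdict(list)
        for r in reads:
            spans[r.chrom].append((r.start, r.end))
        self._starts = {}
        self._ends = {}
        for chrom, pairs in spans.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._starts:
            return 0
        starts = self._starts[chrom]
        ends = self._ends[chrom]
        # intersecting = total - (end <= start of query) - (start >= end of query)
        return int(
            np.searchsorted(starts, end, side="left")
            - np.searchsorted(ends, start, side="right")
        )


def extract_junctions(
    reads: Sequence[AlignedRead],
    dataset: Optional[str] = None,
    stranded: bool = False,
) -> List[JunctionSupport]:
    """Tabulate all distinct skipped intervals across ``reads``.

    With ``stranded=False`` (default) junctions are emitted unstranded:
    long-read protocols do not reliably encode transcript strand in the
    alignment flag, so strand is resolved later against host transcript
    models. Output is sorted by (chrom, start, end, strand) and invariant
    to read input order.
    """
    split: Counter = Counter()
    for r in reads:
        for s, e in set(r.skips):
            strand = r.strand if stranded else "."
            split[(r.chrom, s, e, strand)] += 1
    index = _SpanIndex(reads)
    out = []
    for (chrom, s, e, strand), n in sorted(split.items()):
        out.append(
            JunctionSupport(
                junction=SpliceJunction(chrom, s, e, strand),
                split_read_count=n,
                overlapping_read_count=index.count_overlapping(chrom, s, e),
                dataset=dataset,
            )
        )
    return out


def transcript_junctions(
    models: Iterable[TranscriptModel],
    source_label: Optional[str] = None,
) -> Set[SpliceJunction]:
    """Union of implied introns across all models (optionally restricted to
    one ``source_label``)."""
    out: Set[SpliceJunction] = set()
    for m in models:
        if source_label is not None and m.source_label != source_label:
            continue
        out.update(m.introns())
    return out


def region_coverage(reads: Sequence[AlignedRead], interval: GenomeInterval) -> int:
    """Number of reads whose aligned span intersects ``interval`` by >= 1
    base. A read skipping exactly the interval still counts as covering it."""
    return sum(1 for r in reads if r.span_overlaps(interval))
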