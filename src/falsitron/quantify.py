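"""Relative abundance of artifact junctions and repeat-aware junction
matching in external junction tables.

Two abundance estimators, matching the two data regimes:

* long reads — split reads supporting the junction over all reads
  overlapping the junction coordinates (:func:`relative_abundance`);
* short reads — spliced read count over mean per-base coverage of the
  junction region (:func:`mean_region_coverage` +
  :func:`spliced_abundance`).

Because artifact junctions end in repetitive sequence, external tables
may record the same event with boundaries shifted outwards into the
repeat copies; :func:`shifted_junction_match` tolerates outward shifts
of up to one repeat length per side, as long as the observed intron
length differs from the query's by at most one repeat length.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .intervals import AlignedRead, GenomeInterval, SpliceJunction
from .junctions import region_coverage


@dataclass(frozen=True)
class JunctionMatch:
    query: SpliceJunction
    observed: SpliceJunction
    shift5: int
    shift3: int
    length_delta: int

    def __post_init__(self) -> None:
        if self.shift5 < 0 or self.shift3 < 0:
            raise ValueError("shifts must be outward (non-negative)")
        if self.observed.start != self.query.start - self.shift5:
            raise ValueError("observed.start inconsistent with shift5")
        if self.observed.end != self.query.end + self.shift3:
            raise ValueError("observed.end inconsistent with shift3")


def relative_abundance(
    j: SpliceJunction, reads: Sequence[AlignedRead]
) -> Optional[float]:
    """Split reads supporting ``j`` over reads overlapping its
    coordinates; None (undefined, not 0) when nothing overlaps."""
    overlapping = region_coverage(reads, j.interval())
    if overlapping == 0:
        return None
    split = sum(
        1
        for r in reads
        if r.chrom == j.chrom
        and (j.start, j.end) in r.skips
        and j.strand_compatible(r.strand)
    )
    return split / overlapping


def shifted_junction_match(
    query: SpliceJunction,
    repeat_length: int,
    observed: Iterable[SpliceJunction],
) -> List[JunctionMatch]:
    """All observed junctions expressible as an outward shift of
    ``query`` by (shift5, shift3) in ``[0, repeat_length]`` each, with
    |observed length - query length| <= repeat_length. The exact match
    (0, 0) always qualifies. Inward shifts never qualify."""
    if repeat_length < 0:
        raise ValueError("repeat_length must be >= 0")
    matches = []
    for o in observed:
        if o.chrom != query.chrom or not query.strand_compatible(o.strand):
            continue
        shift5 = query.start - o.start
        shift3 = o.end - query.end
        if not (0 <= shift5 <= repeat_length and 0 <= shift3 <= repeat_length):
            continue
        delta = o.length - query.length
        if abs(delta) > repeat_length:
            continue
        matches.append(
            JunctionMatch(
                query=query,
                observed=o,
                shift5=shift5,
                shift3=shift3,
                length_delta=delta,
            )
        )
    return matches


def mean_region_coverage(
    interval: GenomeInterval,
    per_base_coverage: Sequence[float],
    coverage_start: int = 0,
) -> float:
    """Arithmetic mean of per-base coverage across ``interval``.

    ``per_base_coverage`` must span the interval; ``coverage_start`` is
    the genomic position of its first element."""
    lo = interval.start - coverage_start
    hi = interval.end - coverage_start
    if lo < 0 or hi > len(per_base_coverage):
        raise ValueError("coverage vector does not span the interval")
    return float(np.mean(np.asarray(per_base_coverage, dtype=float)[lo:hi]))


def spliced_abundance(spliced_count: float, mean_coverage: float) -> Optional[float]:
    """Short-read abundance: spliced reads over mean region coverage;
    None when the region has zero coverage."""
    if mean_coverage <= 0:
        return None
    return spliced_count / mean_coverage
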